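"""Cell-lineage gene module derivation from a reference expression atlas.

Given a normalized expression matrix over primary tissues / cell types
(the shape of the FANTOM5 CAGE primary-tissue panel), genes specific to
a tissue are selected by three criteria applied jointly:

1. expression rank in that tissue is in the top three across tissues;
2. cross-tissue Z score in that tissue exceeds ``z_min`` (default 5);
3. specificity score — the number of tissues with Z > 3 — is below
   ``spec_max`` (default 10), so broadly expressed genes are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class AtlasError(ValueError):
    pass


@dataclass
class GeneModule:
    """A named cell lineage with its member genes, ordered by decreasing Z."""

    label: str
    genes: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise AtlasError(f"module {self.label!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def collapse_to_dominant_feature(
    raw: pd.DataFrame, feature_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a feature-level matrix to one row per gene.

    For each gene, keep only the feature (e.g. CAGE peak) with the
    highest mean expression across tissues; exact ties are broken by the
    lexicographically smallest feature id. Genes with no features are
    simply absent from the output.
    """
    unknown = set(raw.index) - set(feature_to_gene)
    if unknown:
        raise AtlasError(f"features without a gene mapping: {sorted(unknown)[:5]}")
    means = raw.mean(axis=1)
    # sort so that within a gene the best (max mean, min feature id) comes first
    order = sorted(raw.index, key=lambda f: (feature_to_gene[f], -means[f], f))
    chosen: dict[str, str] = {}
    for feat in order:
        chosen.setdefault(feature_to_gene[feat], feat)
    genes = sorted(chosen)
    out = raw.loc[[chosen[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene_id")
    return out


def zscore_tissues(atlas: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, pd.Index]:
    """Z-score each gene across tissues.

    Returns the Z matrix and the index of *eligible* genes. Genes with
    zero cross-tissue variance get an all-zero Z row and are excluded
    from module eligibility rather than raising.
    """
    if atlas.shape[1] < 2:
        raise AtlasError("need at least 2 tissues to Z-score")
    values = atlas.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(values)
    z[ok] = (values[ok] - mean[ok]) / sd[ok]
    if (~ok).any():
        log.warning("%d zero-variance genes excluded from module eligibility", (~ok).sum())
    zdf = pd.DataFrame(z, index=atlas.index, columns=atlas.columns)
    return zdf, atlas.index[ok]


def tissue_ranks(atlas: pd.DataFrame) -> pd.DataFrame:
    """Per-gene rank of each tissue (1 = highest expression).

    Ties are resolved deterministically: higher value first, then tissue
    column order.
    """
    values = atlas.to_numpy(dtype=float)
    # stable argsort of descending value; column order breaks exact ties
    order = np.argsort(-values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(values.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, values.shape[1] + 1)
    return pd.DataFrame(ranks, index=atlas.index, columns=atlas.columns)


def specificity_scores(zatlas: pd.DataFrame, z_spec: float = 3.0) -> pd.Series:
    """Number of tissues in which each gene's Z exceeds ``z_spec``."""
    return (zatlas > z_spec).sum(axis=1)


def derive_module(
    zatlas: pd.DataFrame,
    tissue: str,
    *,
    z_min: float = 5.0,
    rank_max: int = 3,
    spec_max: int = 10,
    z_spec: float = 3.0,
    eligible: pd.Index | None = None,
) -> GeneModule:
    """Select genes specific to ``tissue`` from a Z-scored atlas.

    A gene is included iff rank(tissue) <= rank_max, Z(tissue) > z_min and
    specificity score < spec_max (strict, as printed). The returned gene
    list is sorted by decreasing Z in the target tissue.
    """
    if tissue not in zatlas.columns:
        raise AtlasError(f"unknown tissue {tissue!r}")
    ranks = tissue_ranks(zatlas)
    spec = specificity_scores(zatlas, z_spec=z_spec)
    z_t = zatlas[tissue]
    keep = (ranks[tissue] <= rank_max) & (z_t > z_min) & (spec < spec_max)
    if eligible is not None:
        keep &= zatlas.index.isin(eligible)
    genes = z_t[keep].sort_values(ascending=False).index.tolist()
    if not genes:
        log.warning("module %r is empty under criteria", tissue)
    return GeneModule(
        label=tissue,
        genes=genes,
        provenance={"z_min": z_min, "rank_max": rank_max, "spec_max": spec_max,
                    "z_spec": z_spec, "n_genes": len(genes)},
    )


def derive_all_modules(
    zatlas: pd.DataFrame, tissues: Sequence[str] | None = None, **criteria
) -> list[GeneModule]:
    tissues = list(zatlas.columns) if tissues is None else list(tissues)
    return [derive_module(zatlas, t, **criteria) for t in tissues]
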