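"""Module-trait association statistics and cell-type annotation.

Spearman correlations of SVD module scores against clinical,
ultrasonographic and radiographic variables, with Benjamini-Hochberg
FDR applied within a family of all modules for one trait in one
compartment; synovium/blood concordance labels; hypergeometric
enrichment of modules against cell-type marker sets; and Welch-t group
comparisons of module scores (ACPA status, erosion progression, EULAR
response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr

CONCORDANCE_LABELS = ("synovium_only", "blood_only", "both", "neither")


class AssociationError(ValueError):
    pass


def spearman_module_trait(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    traits: list[str] | None = None,
    compartment: str = "synovium",
    min_pairs: int = 6,
) -> pd.DataFrame:
    """Spearman rho of every module against every trait.

    Missing clinical values are handled pairwise-complete, never imputed.
    q values are computed within the family {all modules} x one trait x
    one compartment. Pairs with a constant vector or too few complete
    observations are flagged degenerate (NaN statistics).
    """
    if traits is None:
        traits = [c for c in clinical.columns
                  if pd.api.types.is_numeric_dtype(clinical[c])]
    samples = scores.columns.intersection(clinical.index)
    rows = []
    for trait in traits:
        for mod in scores.index:
            s = scores.loc[mod, samples].astype(float)
            v = clinical.loc[samples, trait].astype(float)
            ok = s.notna() & v.notna()
            n = int(ok.sum())
            degenerate = n < min_pairs or s[ok].nunique() < 2 or v[ok].nunique() < 2
            if degenerate:
                rho = p = np.nan
            else:
                rho, p = stats.spearmanr(s[ok], v[ok])
            rows.append({
                "module": mod, "trait": trait, "compartment": compartment,
                "rho": float(rho) if np.isfinite(rho) else np.nan,
                "p": float(p) if np.isfinite(p) else np.nan,
                "n": n, "degenerate": bool(degenerate),
            })
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for trait in traits:
        mask = out["trait"] == trait
        out.loc[mask, "q"] = np.asarray(bh_fdr(out.loc[mask, "p"].to_numpy()))
    return out


def concordance_classify(
    synovium: pd.DataFrame, blood: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Label each (module, trait) pair by cross-compartment concordance.

    ``both`` requires q < threshold in both compartments with the same
    rho sign; sign-discordant dual-significant pairs are ``neither``.
    """
    key = ["module", "trait"]
    syn = synovium.set_index(key)
    blo = blood.set_index(key)
    missing = syn.index.symmetric_difference(blo.index)
    if len(missing):
        raise AssociationError(f"unmatched (module, trait) keys: {list(missing)[:5]}")
    rows = []
    for k in syn.index:
        qs, qb = syn.loc[k, "q"], blo.loc[k, "q"]
        rs, rb = syn.loc[k, "rho"], blo.loc[k, "rho"]
        sig_s = np.isfinite(qs) and qs < q_threshold
        sig_b = np.isfinite(qb) and qb < q_threshold
        if sig_s and sig_b:
            label = "both" if np.sign(rs) == np.sign(rb) else "neither"
        elif sig_s:
            label = "synovium_only"
        elif sig_b:
            label = "blood_only"
        else:
            label = "neither"
        rows.append({"module": k[0], "trait": k[1], "concordance": label,
                     "rho_synovium": rs, "q_synovium": qs,
                     "rho_blood": rb, "q_blood": qb})
    return pd.DataFrame(rows)


def hypergeom_annotate(
    module_genes: list[str],
    marker_sets: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a module in marker sets.

    p = P(X >= k) with population size |universe|, |marker set|
    successes and |module| draws; BH q across marker-set labels. The
    returned table is sorted by (q, p, label); the first row is the best
    annotation.
    """
    uni = set(universe)
    if not uni:
        raise AssociationError("empty universe")
    mod = set(module_genes)
    if not mod:
        raise AssociationError("empty module")
    if not mod <= uni:
        raise AssociationError(f"module genes outside universe: {sorted(mod - uni)[:5]}")
    N, n_draw = len(uni), len(mod)
    rows = []
    for label in sorted(marker_sets):
        markers = set(marker_sets[label])
        if not markers <= uni:
            raise AssociationError(
                f"marker set {label!r} outside universe: {sorted(markers - uni)[:5]}")
        k = len(mod & markers)
        p = float(stats.hypergeom.sf(k - 1, N, len(markers), n_draw))
        rows.append({"label": label, "overlap": k, "set_size": len(markers), "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.asarray(bh_fdr(out["p"].to_numpy()))
    return out.sort_values(["q", "p", "label"]).reset_index(drop=True)


@dataclass
class GroupTestRow:
    module: str
    effect: float  # standardized mean difference (group1 - group0)
    p: float


def group_module_test(
    scores: pd.DataFrame, grouping: pd.Series, min_per_group: int = 3
) -> pd.DataFrame:
    """Welch two-sample t of module scores between two clinical groups.

    Effect size is the standardized mean difference (pooled-SD Cohen's
    d, second level minus first); BH q across modules.
    """
    grouping = grouping.loc[scores.columns].dropna()
    levels = sorted(grouping.unique())
    if len(levels) != 2:
        raise AssociationError(f"grouping must be binary, got levels {levels}")
    g0 = grouping[grouping == levels[0]].index
    g1 = grouping[grouping == levels[1]].index
    if len(g0) < min_per_group or len(g1) < min_per_group:
        raise AssociationError(
            f"group too small: {levels[0]}={len(g0)}, {levels[1]}={len(g1)} "
            f"(need >={min_per_group})")
    rows = []
    for mod in scores.index:
        a = scores.loc[mod, g0].astype(float).to_numpy()
        b = scores.loc[mod, g1].astype(float).to_numpy()
        t = stats.ttest_ind(b, a, equal_var=False)
        pooled = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                         / (len(a) + len(b) - 2))
        d = (b.mean() - a.mean()) / pooled if pooled > 0 else np.nan
        rows.append({"module": mod, "effect": float(d), "p": float(t.pvalue),
                     "n_0": len(a), "n_1": len(b),
                     "group_0": levels[0], "group_1": levels[1]})
    out = pd.DataFrame(rows).set_index("module")
    out["q"] = np.asarray(bh_fdr(out["p"].to_numpy()))
    return out
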