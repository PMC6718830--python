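"""Three-group differential expression on RNA-seq counts.

The stage mirrors a standard NB-GLM workflow: median-of-ratios size
factors, a per-gene negative-binomial likelihood-ratio test of the
three-pathotype model against a reduced model (optionally with batch/sex
covariates), pairwise group tests, Benjamini-Hochberg FDR, and a six-way
color-class assignment that feeds the polar projection:

* gray — not significant by the three-group LRT (q >= threshold);
* blue / red / green — up-regulated in lymphoid / myeloid / fibroid
  alone versus the minimum-mean reference group;
* purple / yellow / cyan — up in L+M / M+F / L+F versus the reference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import nbglm

log = logging.getLogger(__name__)

GROUPS = ("L", "M", "F")
#: deterministic tie-break order when two groups tie for the minimum mean
_REF_TIE_ORDER = {"F": 0, "M": 1, "L": 2}

PRIMARY_COLOR = {"L": "blue", "M": "red", "F": "green"}
SECONDARY_COLOR = {
    frozenset({"L", "M"}): "purple",
    frozenset({"M", "F"}): "yellow",
    frozenset({"L", "F"}): "cyan",
}


class DEError(ValueError):
    pass


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Genes with a zero count in any sample are excluded from the ratio
    computation. If no gene is expressed in all samples, falls back to
    library-size normalization with a warning.
    """
    y = counts.to_numpy(dtype=float)
    all_pos = (y > 0).all(axis=1)
    if all_pos.any():
        logy = np.log(y[all_pos])
        log_geo = logy.mean(axis=1, keepdims=True)
        ratios = logy - log_geo
        log_sf = np.median(ratios, axis=0)
    else:
        log.warning("no gene with nonzero counts in all samples; "
                    "falling back to library-size normalization")
        lib = y.sum(axis=0)
        if (lib == 0).any():
            raise DEError("sample with zero total counts")
        log_sf = np.log(lib)
    log_sf = log_sf - log_sf.mean()  # geometric mean of factors = 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def rle_transform(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    """Variance-stabilized log expression: log2(count/size_factor + 1).

    A documented stand-in for the regularized-log transform: it preserves
    the normalized log2 scale that module scoring and group-mean Z
    computations assume, without the per-gene shrinkage.
    """
    if sf is None:
        sf = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    return pd.DataFrame(np.log2(norm + 1.0), index=counts.index, columns=counts.columns)


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q values with monotone enforcement.

    Missing (NaN) entries are excluded from the family and returned NaN.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    vals = arr[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise DEError("p values outside [0, 1]")
    m = vals.size
    if m:
        order = np.argsort(vals, kind="stable")
        ranked = vals[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.minimum(q, 1.0)
        qs = np.empty(m)
        qs[order] = q
        out[mask] = qs
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index)
    return out


def _design_matrices(annotations: pd.DataFrame, covariates: list[str] | None):
    """Full (pathotype + covariates) and reduced (covariates-only) designs."""
    n = len(annotations)
    cols = [np.ones(n)]
    names = ["intercept"]
    for cov in covariates or []:
        if cov not in annotations.columns:
            raise DEError(f"covariate {cov!r} missing from sample annotations")
        dummies = pd.get_dummies(annotations[cov].astype(str), prefix=cov, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    reduced = np.column_stack(cols)
    path = pd.get_dummies(
        pd.Categorical(annotations["pathotype"], categories=list(GROUPS)),
        prefix="pathotype", drop_first=True,
    )
    full = np.column_stack([reduced] + [path[c].to_numpy(dtype=float) for c in path.columns])
    return full, reduced


def _check_groups(annotations: pd.DataFrame, min_per_group: int = 2) -> None:
    counts = annotations["pathotype"].value_counts()
    bad = [g for g in GROUPS if counts.get(g, 0) < min_per_group]
    if bad:
        raise DEError(f"groups with <{min_per_group} samples: {bad}")


def fit_nb_lrt(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    covariates: list[str] | None = None,
    sf: pd.Series | None = None,
    dispersion: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of pathotype effect.

    Returns a DataFrame with lrt_p, dispersion and a convergence flag;
    non-converged genes get NaN p (excluded from the FDR family).
    """
    annotations = annotations.loc[counts.columns]
    _check_groups(annotations)
    if sf is None:
        sf = size_factors(counts)
    y = counts.to_numpy(dtype=float)
    offset = np.log(sf.to_numpy())
    if dispersion is None:
        dispersion = nbglm.estimate_dispersion(
            y, sf.to_numpy(), annotations["pathotype"].to_numpy()
        )
    full_X, red_X = _design_matrices(annotations, covariates)
    fit_full = nbglm.fit_nb_glm(y, full_X, offset, dispersion)
    fit_red = nbglm.fit_nb_glm(y, red_X, offset, dispersion)
    df = full_X.shape[1] - red_X.shape[1]
    df_resid = counts.shape[1] - full_X.shape[1]
    p = nbglm.lrt_pvalues(fit_full.loglik, fit_red.loglik, df, df_resid=df_resid)
    ok = fit_full.converged & fit_red.converged
    p = np.where(ok, p, np.nan)
    if (~ok).any():
        log.warning("%d genes failed to converge; p set missing", (~ok).sum())
    return pd.DataFrame(
        {"lrt_p": p, "dispersion": dispersion, "converged": ok}, index=counts.index
    )


def pairwise_test(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    pair: tuple[str, str],
    covariates: list[str] | None = None,
    sf: pd.Series | None = None,
    dispersion: np.ndarray | None = None,
) -> pd.Series:
    """NB LRT p for a two-group comparison (df = 1).

    Size factors and dispersions from the full cohort may be supplied so
    the pairwise tests share the three-group normalization.
    """
    annotations = annotations.loc[counts.columns]
    keep = annotations["pathotype"].isin(pair)
    sub_ann = annotations.loc[keep].copy()
    sub = counts.loc[:, keep[keep].index]
    if sf is None:
        sf_sub = size_factors(sub)
    else:
        sf_sub = sf.loc[sub.columns]
    y = sub.to_numpy(dtype=float)
    offset = np.log(sf_sub.to_numpy())
    if dispersion is None:
        dispersion = nbglm.estimate_dispersion(
            y, sf_sub.to_numpy(), sub_ann["pathotype"].to_numpy()
        )
    n = len(sub_ann)
    red_cols = [np.ones(n)]
    for cov in covariates or []:
        dummies = pd.get_dummies(sub_ann[cov].astype(str), drop_first=True)
        red_cols += [dummies[c].to_numpy(dtype=float) for c in dummies.columns]
    red_X = np.column_stack(red_cols)
    ind = (sub_ann["pathotype"] == pair[1]).to_numpy(dtype=float)
    full_X = np.column_stack([red_X, ind])
    fit_full = nbglm.fit_nb_glm(y, full_X, offset, dispersion)
    fit_red = nbglm.fit_nb_glm(y, red_X, offset, dispersion)
    p = nbglm.lrt_pvalues(fit_full.loglik, fit_red.loglik, 1,
                          df_resid=n - full_X.shape[1])
    p = np.where(fit_full.converged & fit_red.converged, p, np.nan)
    return pd.Series(p, index=counts.index, name=f"p_{pair[0]}_vs_{pair[1]}")


def group_mean_z(expr: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Z across all samples of the log expression matrix,
    averaged within pathotype groups (columns L, M, F)."""
    annotations = annotations.loc[expr.columns]
    vals = expr.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    out = {}
    for g in GROUPS:
        mask = (annotations["pathotype"] == g).to_numpy()
        out[g] = z[:, mask].mean(axis=1)
    return pd.DataFrame(out, index=expr.index)


def assign_color_class(row: pd.Series, q_threshold: float = 0.05) -> str:
    """Color class for one gene of a DE table (see module docstring)."""
    if not np.isfinite(row["lrt_q"]) or row["lrt_q"] >= q_threshold:
        return "gray"
    means = {g: row[f"mean_{g}"] for g in GROUPS}
    ref = min(GROUPS, key=lambda g: (means[g], _REF_TIE_ORDER[g]))
    up = []
    for g in GROUPS:
        if g == ref:
            continue
        q = row[f"q_{g}_vs_ref"]
        lfc = row[f"log2fc_{g}_vs_ref"]
        if np.isfinite(q) and q < q_threshold and lfc > 0:
            up.append(g)
    if len(up) == 1:
        return PRIMARY_COLOR[up[0]]
    if len(up) == 2:
        return SECONDARY_COLOR[frozenset(up)]
    return "gray"  # significant LRT but no pairwise-up call: anomaly


@dataclass
class DEResult:
    """Full three-group DE table plus the matrices downstream stages reuse."""

    table: pd.DataFrame
    expr: pd.DataFrame          # rle-transformed normalized matrix
    annotations: pd.DataFrame
    size_factors: pd.Series
    q_threshold: float


def run_threeway_de(
    counts: pd.DataFrame,
    annotations: pd.DataFrame,
    covariates: list[str] | None = None,
    q_threshold: float = 0.05,
    lfc_min: float = 0.0,
) -> DEResult:
    """Complete three-group DE stage.

    Per gene: three-group LRT q, per-gene reference group (minimum
    normalized mean, ties resolved F < M < L), pairwise q and log2 fold
    change of each non-reference group versus the reference, group mean
    Z scores, and the color class. ``lfc_min`` optionally additionally
    requires |log2fc| > lfc_min versus the reference for the "up" calls.
    """
    annotations = annotations.loc[counts.columns]
    sf = size_factors(counts)
    lrt = fit_nb_lrt(counts, annotations, covariates, sf=sf)
    lrt_q = bh_fdr(lrt["lrt_p"])
    expr = rle_transform(counts, sf)
    gz = group_mean_z(expr, annotations)

    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    group_means = {}
    for g in GROUPS:
        mask = (annotations["pathotype"] == g).to_numpy()
        group_means[g] = norm[:, mask].mean(axis=1)

    pair_p = {}
    for a, b in itertools.combinations(GROUPS, 2):
        pair_p[frozenset({a, b})] = pairwise_test(
            counts, annotations, (a, b), covariates, sf=sf,
            dispersion=lrt["dispersion"].to_numpy(),
        ).to_numpy()
    pair_q = {k: bh_fdr(v) for k, v in pair_p.items()}

    # argmin keeps the first occurrence, so ordering columns F, M, L makes
    # exact mean ties resolve deterministically as F < M < L
    pref = sorted(GROUPS, key=_REF_TIE_ORDER.get)
    mean_pref = np.column_stack([group_means[g] for g in pref])
    ref_labels = np.array(pref)[np.argmin(mean_pref, axis=1)]

    n_genes = counts.shape[0]
    table = pd.DataFrame(index=counts.index)
    table["lrt_p"] = lrt["lrt_p"].to_numpy()
    table["lrt_q"] = np.asarray(lrt_q)
    table["dispersion"] = lrt["dispersion"].to_numpy()
    for g in GROUPS:
        table[f"mean_{g}"] = group_means[g]
        table[f"z_{g}"] = gz[g].to_numpy()
    table["ref_group"] = ref_labels
    for g in GROUPS:
        pq = np.full(n_genes, np.nan)
        pp = np.full(n_genes, np.nan)
        lfc = np.full(n_genes, np.nan)
        for i in range(n_genes):
            r = ref_labels[i]
            if g == r:
                continue
            key = frozenset({g, r})
            pp[i] = pair_p[key][i]
            pq[i] = pair_q[key][i]
            lfc[i] = np.log2((group_means[g][i] + 0.5) / (group_means[r][i] + 0.5))
        table[f"p_{g}_vs_ref"] = pp
        table[f"q_{g}_vs_ref"] = pq
        table[f"log2fc_{g}_vs_ref"] = lfc

    if lfc_min > 0:
        # fold-change gate folded into the "up" requirement
        for g in GROUPS:
            gate = np.abs(table[f"log2fc_{g}_vs_ref"]) > lfc_min
            table.loc[~gate.fillna(False), f"q_{g}_vs_ref"] = np.nan

    table["color_class"] = [
        assign_color_class(row, q_threshold) for _, row in table.iterrows()
    ]
    return DEResult(table=table, expr=expr, annotations=annotations,
                    size_factors=sf, q_threshold=q_threshold)


def cluster_de_genes(
    expr: pd.DataFrame, k: int = 4
) -> tuple[pd.Series, dict]:
    """Ward/Euclidean hierarchical clustering of Z-scaled DE gene rows.

    Returns per-gene cluster labels (1..k) and a heatmap payload with the
    dendrogram leaf order. Default k=4 matches the four-cluster structure
    typically reported for synovial DE genes.
    """
    if expr.shape[0] < 2:
        raise DEError("need at least 2 genes to cluster")
    if k > expr.shape[0]:
        raise DEError(f"k={k} exceeds number of genes {expr.shape[0]}")
    vals = expr.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mean) / sd
    link = hierarchy.linkage(z, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    leaves = hierarchy.leaves_list(link)
    payload = {
        "gene_order": [str(expr.index[i]) for i in leaves],
        "cluster_labels": {str(g): int(l) for g, l in zip(expr.index, labels)},
        "k": int(k),
        "linkage": "ward", "metric": "euclidean",
    }
    return pd.Series(labels, index=expr.index, name="cluster"), payload
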