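"""SVD (eigengene) summarization of gene modules and score comparisons.

A module's per-sample score is the first right-singular vector of the
row-centered module submatrix of the variance-stabilized expression
matrix — the standard eigengene construction. The score has unit norm;
its sign is fixed so the score correlates positively with the module's
mean expression profile.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import GeneModule

log = logging.getLogger(__name__)


class ScoringError(ValueError):
    pass


def svd_score(expr: pd.DataFrame, module: GeneModule,
              max_missing: float = 0.5) -> tuple[pd.Series, dict]:
    """First-right-singular-vector score of a module, one value per sample.

    Module genes absent from the matrix are dropped with a warning when
    fewer than ``max_missing`` of the module is missing, an error
    otherwise. Requires >=2 present genes and >=2 samples.
    """
    present = [g for g in module.genes if g in expr.index]
    missing_frac = 1.0 - len(present) / max(len(module.genes), 1)
    if len(present) < 2:
        raise ScoringError(
            f"module {module.label!r}: {len(present)} genes present in matrix (need >=2)"
        )
    if missing_frac >= max_missing:
        raise ScoringError(
            f"module {module.label!r}: {missing_frac:.0%} of genes missing from matrix"
        )
    if missing_frac > 0:
        log.warning("module %s: %.0f%% of genes missing, dropped",
                    module.label, 100 * missing_frac)
    if expr.shape[1] < 2:
        raise ScoringError("need >=2 samples")

    sub = expr.loc[present].to_numpy(dtype=float)
    centered = sub - sub.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    score = vt[0]
    profile = centered.mean(axis=0)
    if np.dot(score, profile) < 0:
        score = -score
    var_explained = float(s[0] ** 2 / max((s**2).sum(), 1e-300))
    info = {"n_genes_used": len(present), "missing_fraction": missing_frac,
            "variance_explained": var_explained}
    return pd.Series(score, index=expr.columns, name=module.label), info


def score_modules(expr: pd.DataFrame, modules: list[GeneModule],
                  max_missing: float = 0.5) -> pd.DataFrame:
    """Score every module; returns a module x sample matrix."""
    rows = {}
    for m in modules:
        score, _ = svd_score(expr, m, max_missing=max_missing)
        rows[m.label] = score
    return pd.DataFrame(rows).T


@dataclass
class AnovaResult:
    f_p: float
    pairwise_p: dict  # (group_a, group_b) -> Bonferroni-adjusted p


def anova_across_pathotypes(scores: pd.Series, labels: pd.Series) -> AnovaResult:
    """One-way ANOVA across pathotypes with Bonferroni pairwise post-tests.

    Pairwise two-sample t p values are multiplied by the number of
    comparisons and capped at 1.
    """
    labels = labels.loc[scores.index]
    groups = {g: scores[labels == g].to_numpy(dtype=float) for g in labels.unique()}
    sizes = {g: len(v) for g, v in groups.items()}
    if len(groups) < 2 or any(n < 2 for n in sizes.values()):
        raise ScoringError(f"degenerate group sizes for ANOVA: {sizes}")
    f_p = float(stats.f_oneway(*groups.values()).pvalue)
    pairs = list(itertools.combinations(sorted(groups), 2))
    m = len(pairs)
    pairwise = {}
    for a, b in pairs:
        p = float(stats.ttest_ind(groups[a], groups[b], equal_var=True).pvalue)
        pairwise[(a, b)] = min(p * m, 1.0)
    return AnovaResult(f_p=f_p, pairwise_p=pairwise)


def anova_all_modules(scores: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    rows = []
    for mod in scores.index:
        res = anova_across_pathotypes(scores.loc[mod], labels)
        row = {"module": mod, "anova_p": res.f_p}
        for (a, b), p in res.pairwise_p.items():
            row[f"p_{a}_vs_{b}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("module")


@dataclass
class TertileResult:
    table: pd.DataFrame  # per-tertile n, mean score, mean clinical value
    slope: float
    slope_p: float
    n: int
    degenerate: bool = False


def tertile_table(score: pd.Series, clinical: pd.Series) -> TertileResult:
    """Tertile summary of a clinical value against a module score.

    The significance is the two-sided slope p from a simple linear
    regression of the clinical value on the continuous score (the
    tertiles are descriptive only).
    """
    joined = pd.concat({"score": score, "value": clinical}, axis=1).dropna()
    n = len(joined)
    if n < 6:
        raise ScoringError(f"insufficient data: {n} complete pairs (need >=6)")
    s = joined["score"].to_numpy(dtype=float)
    v = joined["value"].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        empty = pd.DataFrame(columns=["n", "mean_score", "mean_value"])
        return TertileResult(table=empty, slope=np.nan, slope_p=np.nan,
                             n=n, degenerate=True)
    q1, q2 = np.quantile(s, [1 / 3, 2 / 3])
    tert = np.where(s <= q1, 1, np.where(s <= q2, 2, 3))
    table = (
        pd.DataFrame({"tertile": tert, "score": s, "value": v})
        .groupby("tertile")
        .agg(n=("score", "size"), mean_score=("score", "mean"), mean_value=("value", "mean"))
    )
    fit = stats.linregress(s, v)
    return TertileResult(table=table, slope=float(fit.slope),
                         slope_p=float(fit.pvalue), n=n)
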