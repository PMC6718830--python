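"""Module-trait correlations, concordance labels, enrichment and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from tripathotype.associations import (
    AssociationError,
    CONCORDANCE_LABELS,
    concordance_classify,
    group_module_test,
    hypergeom_annotate,
    spearman_module_trait,
)

from oracles import hypergeom_tail_oracle


def _scores(values, modules=None):
    values = np.atleast_2d(values)
    modules = modules or [f"m{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=modules,
                        columns=[f"s{i}" for i in range(values.shape[1])])


def test_identity_correlation():
    x = np.linspace(0, 1, 60)
    scores = _scores(x)
    clinical = pd.DataFrame({"ESR": x}, index=scores.columns)
    out = spearman_module_trait(scores, clinical, traits=["ESR"])
    row = out.iloc[0]
    assert row["rho"] == pytest.approx(1.0)
    assert row["p"] < 1e-10
    assert row["q"] == pytest.approx(row["p"])  # single-module family


@given(st.integers(0, 1000))
def test_spearman_invariant_to_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    scores = _scores(x)
    c1 = pd.DataFrame({"CRP": y}, index=scores.columns)
    c2 = pd.DataFrame({"CRP": np.exp(y)}, index=scores.columns)  # strictly monotone
    r1 = spearman_module_trait(scores, c1, traits=["CRP"]).iloc[0]["rho"]
    r2 = spearman_module_trait(scores, c2, traits=["CRP"]).iloc[0]["rho"]
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_pairwise_complete_and_degenerate_handling():
    x = np.arange(20, dtype=float)
    scores = _scores(x)
    clinical = pd.DataFrame({"ESR": x.copy(), "CRP": np.ones(20)}, index=scores.columns)
    clinical.loc["s3":"s7", "ESR"] = np.nan
    out = spearman_module_trait(scores, clinical, traits=["ESR", "CRP"])
    esr = out[out["trait"] == "ESR"].iloc[0]
    assert esr["n"] == 15 and esr["rho"] == pytest.approx(1.0)
    crp = out[out["trait"] == "CRP"].iloc[0]
    assert crp["degenerate"] and np.isnan(crp["rho"])
    # fewer than six complete pairs is degenerate as well
    thin = clinical.copy()
    thin.loc[:, "ESR"] = np.nan
    thin.iloc[:5, 0] = 1.0
    assert spearman_module_trait(scores, thin, traits=["ESR"]).iloc[0]["degenerate"]


def test_null_correlations_hit_nominal_rate():
    rng = np.random.default_rng(1)
    hits = 0
    n_rep = 400
    for _ in range(n_rep):
        x, y = rng.normal(size=(2, 40))
        if stats.spearmanr(x, y).pvalue < 0.05:
            hits += 1
    assert 0.02 < hits / n_rep < 0.09


def _assoc_rows(qs, rhos, compartment):
    return pd.DataFrame({
        "module": [f"m{i}" for i in range(len(qs))],
        "trait": ["ESR"] * len(qs),
        "compartment": compartment,
        "rho": rhos, "q": qs,
    })


def test_concordance_rules():
    syn = _assoc_rows([0.01, 0.01, 0.50, 0.01], [0.5, 0.4, 0.3, 0.6], "synovium")
    blo = _assoc_rows([0.01, 0.50, 0.01, 0.01], [0.5, 0.4, 0.3, -0.6], "blood")
    out = concordance_classify(syn, blo).set_index("module")
    assert out.loc["m0", "concordance"] == "both"
    assert out.loc["m1", "concordance"] == "synovium_only"
    assert out.loc["m2", "concordance"] == "blood_only"
    # dual-significant but sign-discordant -> neither
    assert out.loc["m3", "concordance"] == "neither"
    assert set(out["concordance"]) <= set(CONCORDANCE_LABELS)


def test_concordance_requires_matched_keys():
    syn = _assoc_rows([0.01], [0.5], "synovium")
    blo = _assoc_rows([0.01, 0.02], [0.5, 0.1], "blood")
    with pytest.raises(AssociationError, match="unmatched"):
        concordance_classify(syn, blo)


def test_concordance_labels_partition_all_pairs():
    rng = np.random.default_rng(2)
    n = 30
    syn = _assoc_rows(rng.uniform(size=n), rng.normal(size=n), "synovium")
    blo = _assoc_rows(rng.uniform(size=n), rng.normal(size=n), "blood")
    out = concordance_classify(syn, blo)
    assert len(out) == n and out["concordance"].notna().all()


def test_hypergeom_perfect_overlap_reference_value():
    import math
    universe = [f"g{i}" for i in range(1000)]
    markers = universe[:20]
    out = hypergeom_annotate(markers, {"B": markers}, universe)
    assert out.iloc[0]["p"] == pytest.approx(1 / math.comb(1000, 20), rel=1e-6)
    assert out.iloc[0]["overlap"] == 20


def test_hypergeom_trivia_and_errors():
    universe = [f"g{i}" for i in range(100)]
    out = hypergeom_annotate(universe[:5], {"A": universe[50:60]}, universe)
    assert out.iloc[0]["p"] > 0.5  # zero overlap, small module
    # module = universe forces k = |marker set| and p = 1
    out = hypergeom_annotate(universe, {"A": universe[:10]}, universe)
    assert out.iloc[0]["p"] == pytest.approx(1.0)
    with pytest.raises(AssociationError):
        hypergeom_annotate([], {"A": universe[:3]}, universe)
    with pytest.raises(AssociationError):
        hypergeom_annotate(["missing"], {"A": universe[:3]}, universe)


@given(st.integers(0, 5000))
def test_hypergeom_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    pop = int(rng.integers(10, 60))
    universe = [f"g{i}" for i in range(pop)]
    module = list(rng.choice(universe, size=rng.integers(1, pop // 2 + 1), replace=False))
    markers = list(rng.choice(universe, size=rng.integers(1, pop // 2 + 1), replace=False))
    out = hypergeom_annotate(module, {"A": markers}, universe)
    k = len(set(module) & set(markers))
    expected = hypergeom_tail_oracle(k, pop, len(markers), len(module))
    assert out.iloc[0]["p"] == pytest.approx(expected, rel=1e-9)


def test_group_test_detects_planted_shift():
    rng = np.random.default_rng(3)
    n = 60
    base = rng.normal(size=(5, n))
    groups = pd.Series(["yes"] * 30 + ["no"] * 30,
                       index=[f"s{i}" for i in range(n)])
    base[0, :30] += 1.0  # +1 SD in module m0 for progressors
    scores = _scores(base)
    out = group_module_test(scores, groups)
    assert out.loc["m0", "q"] < 0.05
    assert abs(out.loc["m0", "effect"]) > 0.5


def test_group_test_null_and_validation():
    rng = np.random.default_rng(4)
    scores = _scores(rng.normal(size=(3, 40)))
    same = pd.Series(["a"] * 20 + ["b"] * 20, index=scores.columns)
    out = group_module_test(scores, same)
    assert (out["p"] > 0.001).all()  # no planted effect
    tiny = pd.Series(["a"] * 2 + ["b"] * 38, index=scores.columns)
    with pytest.raises(AssociationError, match="too small"):
        group_module_test(scores, tiny)
    threeway = pd.Series(["a", "b", "c"] * 13 + ["a"], index=scores.columns)
    with pytest.raises(AssociationError, match="binary"):
        group_module_test(scores, threeway)


def test_group_test_permutation_null_rate():
    rng = np.random.default_rng(5)
    hits = 0
    n_rep = 300
    scores = _scores(rng.normal(size=(1, 30)))
    for _ in range(n_rep):
        labels = pd.Series(rng.permutation(["a"] * 15 + ["b"] * 15), index=scores.columns)
        if group_module_test(scores, labels)["p"].iloc[0] < 0.05:
            hits += 1
    assert 0.01 < hits / n_rep < 0.10
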