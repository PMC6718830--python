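"""Synthetic atlas / cohort / follow-up generators and their ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tripathotype import synthetic
from tripathotype.histology import classify, shift_vs_response
from tripathotype.synthetic import (
    AtlasSpec,
    CohortSpec,
    SpecError,
    cohort_pathotype_calls,
    generate_atlas,
    generate_cohort,
    generate_followup,
)


def test_atlas_shapes_and_truth_bookkeeping():
    spec = AtlasSpec(n_tissues=20, n_genes=1000, n_markers_per_tissue=10,
                     n_broad_genes=0, seed=1)
    atlas, truth = generate_atlas(spec)
    assert atlas.shape == (1000, 20)
    assert sum(len(v) for v in truth.marker_map.values()) == 200
    assert (atlas.to_numpy() >= 0).all()


def test_atlas_invalid_specs_rejected():
    with pytest.raises(SpecError, match="marker_effect"):
        generate_atlas(AtlasSpec(marker_effect=0.0))
    with pytest.raises(SpecError, match="exceeds n_genes"):
        generate_atlas(AtlasSpec(n_genes=100, n_tissues=20, n_markers_per_tissue=10))
    with pytest.raises(SpecError, match="noise_sd"):
        generate_atlas(AtlasSpec(noise_sd=0.0))


def test_atlas_deterministic_given_seed():
    a1, _ = generate_atlas(AtlasSpec(n_tissues=20, n_genes=500, n_broad_genes=5, seed=7))
    a2, _ = generate_atlas(AtlasSpec(n_tissues=20, n_genes=500, n_broad_genes=5, seed=7))
    assert a1.equals(a2)
    a3, _ = generate_atlas(AtlasSpec(n_tissues=20, n_genes=500, n_broad_genes=5, seed=8))
    assert not a1.equals(a3)


def test_cohort_shapes_and_planted_classes():
    spec = CohortSpec(n_per_group=(30, 20, 15), n_genes=800,
                      de_class_sizes=(50,) * 6, clinical_effect_map=(), seed=0)
    counts, histology, clinical, truth = generate_cohort(spec, [])
    assert counts.shape == (800, 65)
    assert len(truth.de_class_map) == 300
    # every planted gene appears in exactly one class
    assert len(set(truth.de_class_map)) == 300
    assert set(truth.de_class_map.values()) == set(synthetic.DE_CLASSES)
    assert counts.to_numpy().dtype.kind == "i"


def test_cohort_determinism():
    spec = CohortSpec(n_per_group=(5, 5, 5), n_genes=200, de_class_sizes=(3,) * 6,
                      clinical_effect_map=(), seed=3)
    c1 = generate_cohort(spec, [])
    c2 = generate_cohort(spec, [])
    assert c1[0].equals(c2[0])
    assert c1[2].equals(c2[2])
    assert [h for h in c1[1]] == [h for h in c2[1]]


def test_cohort_spec_validation():
    with pytest.raises(SpecError, match="group sizes"):
        CohortSpec(n_per_group=(2, 5, 5)).validate()
    with pytest.raises(SpecError, match="< n_genes"):
        CohortSpec(n_genes=100, de_class_sizes=(20,) * 6).validate()
    with pytest.raises(SpecError, match="dispersion"):
        CohortSpec(dispersion=0.0).validate()
    with pytest.raises(SpecError, match="universe"):
        from tripathotype.atlas import GeneModule
        generate_cohort(CohortSpec(clinical_effect_map=()),
                        [GeneModule("m", ["NOT_A_GENE"])])


def test_histology_scores_satisfy_their_planted_rule(default_cohort):
    _, _, histology, _, truth = default_cohort
    for h in histology:
        assert classify(h).label == truth.histology_labels[h.sample_id]


def test_planted_fibroid_histology_matches_printed_rule():
    spec = CohortSpec(n_per_group=(3, 3, 10), n_genes=100, de_class_sizes=(0,) * 6,
                      clinical_effect_map=(), ungraded_fraction=0.0, seed=5)
    _, histology, _, truth = generate_cohort(spec, [])
    fibroid = [h for h in histology if truth.group_assignment[h.sample_id] == "F"]
    assert fibroid
    for h in fibroid:
        assert h.CD68SL < 2 and h.CD3 < 1 and h.CD20 < 1 and h.CD138 < 1
        assert classify(h).label == "fibroid"


def test_planted_clinical_rho_within_band():
    # planted Spearman 0.5 against true module activity, n = 65; a single
    # seed's rho has SE ~ 0.11, so the band is checked on the seed average
    from tripathotype.atlas import GeneModule
    genes = synthetic.gene_ids(500)
    mods = [GeneModule("plasma_cell", genes[:10])]
    rhos = []
    for seed in range(20):
        spec = CohortSpec(n_genes=500, de_class_sizes=(0,) * 6,
                          clinical_effect_map=(("plasma_cell", "CCP_titer", 0.5),),
                          seed=seed)
        _, _, clinical, truth = generate_cohort(spec, mods)
        rhos.append(stats.spearmanr(truth.module_activity["plasma_cell"],
                                    clinical["CCP_titer"]).statistic)
    assert 0.42 <= np.mean(rhos) <= 0.58
    assert all(0.2 <= r <= 0.8 for r in rhos)


def test_clinical_effect_map_requires_known_module_and_trait():
    with pytest.raises(SpecError, match="not among"):
        generate_cohort(CohortSpec(
            clinical_effect_map=(("ghost_module", "ESR", 0.5),)), [])


def test_followup_null_strength_uncorrelated():
    rs = []
    for seed in range(10):
        spec = CohortSpec(n_per_group=(30, 30, 30), n_genes=50,
                          de_class_sizes=(0,) * 6, clinical_effect_map=(), seed=seed)
        _, histology, _, _ = generate_cohort(spec, [])
        fup, delta = generate_followup(histology, response_strength=0.0, seed=seed)
        res = shift_vs_response(cohort_pathotype_calls(histology),
                                cohort_pathotype_calls(fup), delta.tolist())
        rs.append(res.r)
    assert np.mean(np.abs(rs)) < 0.15
    assert all(abs(r) < 0.3 for r in rs)


def test_followup_planted_response_recovered():
    rs = []
    for seed in range(10):
        spec = CohortSpec(n_per_group=(30, 30, 30), n_genes=50,
                          de_class_sizes=(0,) * 6, clinical_effect_map=(), seed=seed)
        _, histology, _, _ = generate_cohort(spec, [])
        fup, delta = generate_followup(histology, response_strength=1.0, seed=seed)
        res = shift_vs_response(cohort_pathotype_calls(histology),
                                cohort_pathotype_calls(fup), delta.tolist())
        rs.append(res.r)
    assert all(r > 0.25 for r in rs)


def test_followup_deterministic_and_preserves_ungraded():
    spec = CohortSpec(n_per_group=(10, 10, 10), n_genes=50, de_class_sizes=(0,) * 6,
                      clinical_effect_map=(), ungraded_fraction=0.2, seed=9)
    _, histology, _, truth = generate_cohort(spec, [])
    f1, d1 = generate_followup(histology, 1.0, seed=2)
    f2, d2 = generate_followup(histology, 1.0, seed=2)
    assert f1 == f2 and (d1 == d2).all()
    for h in f1:
        if h.sample_id in truth.ungraded_samples:
            assert classify(h).label == "ungraded"


def test_ungraded_fraction_planted(default_cohort):
    spec, _, histology, _, truth = default_cohort
    n = sum(spec.n_per_group)
    assert len(truth.ungraded_samples) == round(spec.ungraded_fraction * n)
    labels = [classify(h).label for h in histology]
    assert labels.count("ungraded") == len(truth.ungraded_samples)


def test_null_cohort_lrt_pvalues_uniform():
    from tripathotype import de
    spec = CohortSpec(n_per_group=(10, 10, 10), n_genes=2000,
                      de_class_sizes=(0,) * 6, clinical_effect_map=(), seed=42)
    counts, _, _, truth = generate_cohort(spec, [])
    ann = pd.DataFrame({"pathotype": [truth.group_assignment[s] for s in counts.columns]},
                       index=counts.columns)
    res = de.fit_nb_lrt(counts, ann)
    assert stats.kstest(res["lrt_p"].dropna(), "uniform").pvalue > 0.01
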