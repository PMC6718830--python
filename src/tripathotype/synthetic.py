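"""Synthetic cohort and reference-atlas generation with planted ground truth.

Every input the pipeline consumes can be generated here: a primary-tissue
expression atlas with planted tissue-specific marker genes and broadly
expressed decoys, a three-pathotype RNA-seq count cohort with planted
differential genes in six up-regulation classes and planted per-sample
module activities, histology scores consistent with the pathotype rules,
clinical variables with controlled Spearman correlations against module
activities, and a 6-month follow-up with a planted pathotype-shift /
DAS28-response relationship.

All generators are deterministic given their spec's seed; one integer
seed fans out to independent substreams per component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .atlas import GeneModule
from .histology import HistologySample, PathotypeCall, classify, inflammation_ordinal

DE_CLASSES = ("L", "M", "F", "LM", "MF", "LF")
#: expression groups carrying each class's up-regulation
CLASS_UP_GROUPS = {
    "L": ("L",), "M": ("M",), "F": ("F",),
    "LM": ("L", "M"), "MF": ("M", "F"), "LF": ("L", "F"),
}

#: leading atlas tissues named for the cell lineages the study profiles
CELL_TYPE_NAMES = (
    "B_cell", "CD4_T_cell", "CD8_T_cell", "monocyte", "macrophage",
    "plasma_cell", "mast_cell", "synoviocyte", "neutrophil", "NK_cell",
    "dendritic_cell", "endothelial_cell",
)

NUMERIC_TRAITS = (
    "DAS28_ESR", "DAS28_CRP", "ESR", "CRP", "CCP_titer", "RF_titer",
    "VAS_pain", "HAQ", "US_ST_biopsy", "US_PD_biopsy", "US_ST_12",
    "US_PD_12", "sharp_total", "delta_DAS28_CRP", "delta_ESR",
)

#: affine (location, scale) mapping of the standardized latent trait to
#: clinically plausible units; affine maps preserve Spearman rho exactly
_TRAIT_UNITS = {
    "DAS28_ESR": (5.8, 1.3), "DAS28_CRP": (5.5, 1.2), "ESR": (35.0, 18.0),
    "CRP": (20.0, 14.0), "CCP_titer": (150.0, 90.0), "RF_titer": (80.0, 55.0),
    "VAS_pain": (60.0, 18.0), "HAQ": (1.2, 0.55), "US_ST_biopsy": (1.6, 0.7),
    "US_PD_biopsy": (1.3, 0.7), "US_ST_12": (1.2, 0.5), "US_PD_12": (1.0, 0.5),
    "sharp_total": (10.0, 7.0), "delta_DAS28_CRP": (1.2, 1.1),
    "delta_ESR": (8.0, 9.0),
}

_GROUP_TO_LABEL = {"L": "lymphoid", "M": "myeloid", "F": "fibroid"}


class SpecError(ValueError):
    """A generator spec violates one of its invariants."""


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def tissue_names(n: int) -> list[str]:
    named = list(CELL_TYPE_NAMES[:n])
    named += [f"tissue_{i:03d}" for i in range(len(named), n)]
    return named


# ---------------------------------------------------------------------------
# Ground truth container


@dataclass
class GroundTruth:
    marker_map: dict = dc_field(default_factory=dict)       # tissue -> gene list
    broad_genes: list = dc_field(default_factory=list)
    de_class_map: dict = dc_field(default_factory=dict)     # gene -> class
    module_activity: pd.DataFrame | None = None             # sample x module
    planted_rho: dict = dc_field(default_factory=dict)      # (module, trait) -> rho
    group_assignment: dict = dc_field(default_factory=dict) # sample -> L/M/F
    histology_labels: dict = dc_field(default_factory=dict) # sample -> pathotype label
    ungraded_samples: list = dc_field(default_factory=list)
    size_factors: dict = dc_field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d = {
            "marker_map": self.marker_map,
            "broad_genes": self.broad_genes,
            "de_class_map": self.de_class_map,
            "planted_rho": {f"{m}|{t}": r for (m, t), r in self.planted_rho.items()},
            "group_assignment": self.group_assignment,
            "histology_labels": self.histology_labels,
            "ungraded_samples": self.ungraded_samples,
            "size_factors": self.size_factors,
        }
        if self.module_activity is not None:
            d["module_activity"] = {
                "index": list(self.module_activity.index),
                "columns": list(self.module_activity.columns),
                "data": self.module_activity.to_numpy().tolist(),
            }
        return d


# ---------------------------------------------------------------------------
# Reference atlas


@dataclass(frozen=True)
class AtlasSpec:
    """Conditions for the synthetic primary-tissue expression atlas.

    The defaults emulate the scale of a CAGE primary-tissue panel:
    135 tissues, ten planted markers per tissue whose realized
    cross-tissue Z score is calibrated to ``marker_effect`` (default 8
    SD), plus broadly expressed genes elevated in 11 tissues that the
    specificity criteria must exclude.
    """

    n_tissues: int = 135
    n_genes: int = 2000
    n_markers_per_tissue: int = 10
    marker_effect: float = 8.0
    n_broad_genes: int = 100
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_tissues < 2:
            raise SpecError("n_tissues must be >= 2")
        n_markers = self.n_markers_per_tissue * self.n_tissues
        if n_markers + self.n_broad_genes > self.n_genes:
            raise SpecError(
                f"n_markers_per_tissue*n_tissues + n_broad_genes = "
                f"{n_markers + self.n_broad_genes} exceeds n_genes = {self.n_genes}"
            )
        if not self.marker_effect > 5:
            raise SpecError(
                f"marker_effect = {self.marker_effect} must exceed 5 so planted "
                "markers are recoverable by the Z > 5 criterion"
            )
        if not self.noise_sd > 0:
            raise SpecError("noise_sd must be positive")


def _calibrated_elevation(effect: float, n_tissues: int, noise_sd: float) -> float:
    # a single elevated tissue inflates the row SD by the spike itself;
    # solve for the raw elevation whose realized Z equals `effect`,
    # saturating when effect^2 >= n (the small-panel regime)
    shrink = max(1.0 - effect**2 / n_tissues, 0.1)
    return noise_sd * effect / math.sqrt(shrink)


def generate_atlas(spec: AtlasSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Gene x tissue atlas with planted markers and broad decoy genes."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 11])
    genes = gene_ids(spec.n_genes)
    tissues = tissue_names(spec.n_tissues)

    baseline = rng.uniform(5.0, 15.0, size=spec.n_genes)
    values = baseline[:, None] + spec.noise_sd * rng.standard_normal(
        (spec.n_genes, spec.n_tissues))

    truth = GroundTruth()
    delta = _calibrated_elevation(spec.marker_effect, spec.n_tissues, spec.noise_sd)
    idx = 0
    for t_i, tissue in enumerate(tissues):
        marker_genes = genes[idx: idx + spec.n_markers_per_tissue]
        values[idx: idx + spec.n_markers_per_tissue, t_i] += delta
        truth.marker_map[tissue] = marker_genes
        idx += spec.n_markers_per_tissue

    m_broad = min(11, max(spec.n_tissues - 1, 1))
    broad_delta = 30.0 * spec.noise_sd
    for g_i in range(idx, idx + spec.n_broad_genes):
        cols = rng.choice(spec.n_tissues, size=m_broad, replace=False)
        values[g_i, cols] += broad_delta
        truth.broad_genes.append(genes[g_i])

    atlas = pd.DataFrame(np.maximum(values, 0.0), index=pd.Index(genes, name="gene_id"),
                         columns=tissues)
    return atlas, truth


# ---------------------------------------------------------------------------
# Cohort


@dataclass(frozen=True)
class CohortSpec:
    """Conditions for the synthetic three-pathotype count cohort.

    Defaults: 65 samples (25 lymphoid / 20 myeloid / 20 fibroid), 2,000
    genes, 50 planted differential genes in each of the six up-regulation
    classes at log2 effect 2, NB dispersion 0.1, and three planted
    module-trait Spearman correlations of 0.5.
    """

    n_per_group: tuple[int, int, int] = (25, 20, 20)  # (lymphoid, myeloid, fibroid)
    n_genes: int = 2000
    de_class_sizes: tuple[int, int, int, int, int, int] = (50,) * 6
    log2_effect: float = 2.0
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (0.7, 1.4)
    clinical_effect_map: tuple = (
        ("plasma_cell", "CCP_titer", 0.5),
        ("B_cell", "US_ST_biopsy", 0.5),
        ("monocyte", "VAS_pain", 0.5),
    )
    binary_effect_map: tuple = ()
    module_amplitude: float = 1.0  # log2-scale expression swing per SD of activity
    ungraded_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if any(n < 3 for n in self.n_per_group):
            raise SpecError(f"group sizes must be >= 3, got {self.n_per_group}")
        if len(self.de_class_sizes) != len(DE_CLASSES):
            raise SpecError("de_class_sizes must have six entries (L,M,F,LM,MF,LF)")
        if sum(self.de_class_sizes) >= self.n_genes:
            raise SpecError("sum of de_class_sizes must be < n_genes")
        if not self.dispersion > 0:
            raise SpecError("dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise SpecError(f"invalid library_size_range {self.library_size_range}")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha < 1e-12:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=mean * alpha)
    return rng.poisson(lam)


def _sample_histology(rng: np.random.Generator, sample_id: str, label: str) -> HistologySample:
    """Draw scores uniformly inside the rule region of the target label."""
    ri = rng.integers
    if label == "lymphoid":
        if rng.random() < 0.7:  # aggregate route
            scores = dict(cd20_aggregate_grade=int(ri(2, 4)), CD20=int(ri(2, 5)),
                          CD3=int(ri(0, 5)), CD68SL=int(ri(0, 5)),
                          CD68L=int(ri(0, 5)), CD138=int(ri(0, 5)))
        else:  # plasma-cell route (CD138 > 2)
            scores = dict(cd20_aggregate_grade=int(ri(0, 2)), CD20=int(ri(0, 5)),
                          CD3=int(ri(0, 5)), CD68SL=int(ri(0, 5)),
                          CD68L=int(ri(0, 5)), CD138=int(ri(3, 5)))
    elif label == "myeloid":
        if rng.random() < 0.3:  # T-cell-containing myeloid branch
            cd20, cd3 = int(ri(2, 4)), int(ri(1, 5))
        else:
            cd20, cd3 = int(ri(0, 2)), int(ri(0, 5))
        scores = dict(cd20_aggregate_grade=int(ri(0, 2)), CD20=cd20, CD3=cd3,
                      CD68SL=int(ri(2, 5)), CD68L=int(ri(0, 5)), CD138=int(ri(0, 3)))
    elif label == "fibroid":
        scores = dict(cd20_aggregate_grade=0, CD20=0, CD3=0,
                      CD68SL=int(ri(0, 2)), CD68L=int(ri(0, 5)), CD138=0)
    elif label == "ungraded":
        # a rule-gap region: low sublining CD68 blocks M, CD3 >= 1 blocks F,
        # no aggregates and CD138 <= 2 block L
        scores = dict(cd20_aggregate_grade=0, CD20=int(ri(0, 2)), CD3=int(ri(1, 3)),
                      CD68SL=int(ri(0, 2)), CD68L=int(ri(0, 5)), CD138=int(ri(0, 3)))
    else:
        raise SpecError(f"unknown pathotype label {label!r}")
    h = HistologySample(sample_id=sample_id, **scores)
    assert classify(h).label == label, "histology sampler left its rule region"
    return h


def _spearman_to_pearson(rho_s: float) -> float:
    # bivariate-normal relation: rho_s = (6/pi) asin(rho_p / 2)
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def generate_cohort(
    spec: CohortSpec, modules: list[GeneModule] | None = None
) -> tuple[pd.DataFrame, list[HistologySample], pd.DataFrame, GroundTruth]:
    """Counts, histology, clinical table and ground truth for one cohort."""
    spec.validate()
    modules = modules or []
    genes = gene_ids(spec.n_genes)
    universe = set(genes)
    unknown = sorted({g for m in modules for g in m.genes} - universe)
    if unknown:
        raise SpecError(f"module genes outside the generated gene universe: {unknown[:10]}")

    n1, n2, n3 = spec.n_per_group
    n = n1 + n2 + n3
    samples = [f"S{i:03d}" for i in range(n)]
    groups = np.array(["L"] * n1 + ["M"] * n2 + ["F"] * n3)

    rng_counts = np.random.default_rng([spec.seed, 21])
    rng_hist = np.random.default_rng([spec.seed, 22])
    rng_clin = np.random.default_rng([spec.seed, 23])
    rng_act = np.random.default_rng([spec.seed, 24])

    truth = GroundTruth(group_assignment=dict(zip(samples, groups)))

    # --- planted differential classes, drawn outside module genes
    module_gene_set = {g for m in modules for g in m.genes}
    candidates = np.array([g for g in genes if g not in module_gene_set])
    total_de = sum(spec.de_class_sizes)
    if total_de > len(candidates):
        raise SpecError("not enough non-module genes to plant differential classes")
    chosen = rng_counts.choice(candidates, size=total_de, replace=False)
    pos = 0
    for cls, size in zip(DE_CLASSES, spec.de_class_sizes):
        for g in chosen[pos: pos + size]:
            truth.de_class_map[str(g)] = cls
        pos += size

    # --- expression model
    base_mu = np.maximum(np.exp(rng_counts.normal(math.log(30.0), 1.2, size=spec.n_genes)), 1.0)
    sf = rng_counts.uniform(*spec.library_size_range, size=n)
    truth.size_factors = dict(zip(samples, sf))

    log2_eff = np.zeros((spec.n_genes, n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, cls in truth.de_class_map.items():
        up = np.isin(groups, CLASS_UP_GROUPS[cls])
        log2_eff[gene_index[g], up] += spec.log2_effect

    if modules:
        activity = rng_act.standard_normal((n, len(modules)))
        truth.module_activity = pd.DataFrame(
            activity, index=samples, columns=[m.label for m in modules])
        for k, m in enumerate(modules):
            rows = [gene_index[g] for g in m.genes]
            log2_eff[rows, :] += spec.module_amplitude * activity[:, k][None, :]

    mean = base_mu[:, None] * sf[None, :] * np.exp2(log2_eff)
    counts = pd.DataFrame(
        _nb_counts(rng_counts, mean, spec.dispersion).astype(np.int64),
        index=pd.Index(genes, name="gene_id"), columns=samples,
    )

    # --- histology consistent with each sample's pathotype (plus rule-gap samples)
    n_ungraded = int(round(spec.ungraded_fraction * n))
    ungraded_ids = set(rng_hist.choice(samples, size=n_ungraded, replace=False)) \
        if n_ungraded else set()
    histology = []
    for sid, grp in zip(samples, groups):
        label = "ungraded" if sid in ungraded_ids else _GROUP_TO_LABEL[grp]
        histology.append(_sample_histology(rng_hist, sid, label))
        truth.histology_labels[sid] = label
    truth.ungraded_samples = sorted(ungraded_ids)

    # --- clinical traits, Spearman-calibrated against module activity
    clinical = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    mapped = {}
    for mod_label, trait, rho in spec.clinical_effect_map:
        if truth.module_activity is None or mod_label not in truth.module_activity.columns:
            raise SpecError(
                f"clinical_effect_map references module {mod_label!r} "
                "not among the supplied modules")
        if trait not in _TRAIT_UNITS:
            raise SpecError(f"unknown clinical trait {trait!r}")
        rho_p = _spearman_to_pearson(rho)
        a = truth.module_activity[mod_label].to_numpy()
        latent = rho_p * a + math.sqrt(1.0 - rho_p**2) * rng_clin.standard_normal(n)
        loc, scale = _TRAIT_UNITS[trait]
        clinical[trait] = loc + scale * latent
        mapped[trait] = True
        truth.planted_rho[(mod_label, trait)] = rho
    for trait in NUMERIC_TRAITS:
        if trait not in clinical.columns:
            loc, scale = _TRAIT_UNITS[trait]
            clinical[trait] = loc + scale * rng_clin.standard_normal(n)
    clinical = clinical[list(NUMERIC_TRAITS)]

    def _binary(trait: str, levels: tuple[str, str]) -> pd.Series:
        for mod_label, t, shift in spec.binary_effect_map:
            if t == trait:
                a = truth.module_activity[mod_label].to_numpy()
                latent = shift * a + rng_clin.standard_normal(n)
                return pd.Series(np.where(latent > np.median(latent), levels[0], levels[1]),
                                 index=samples)
        return pd.Series(rng_clin.choice(levels, size=n), index=samples)

    clinical["ACPA_status"] = _binary("ACPA_status", ("pos", "neg"))
    clinical["erosion_progressor"] = _binary("erosion_progressor", ("yes", "no"))
    clinical["EULAR_response"] = rng_clin.choice(
        ["good", "moderate", "none"], size=n, p=[0.4, 0.35, 0.25])
    return counts, histology, clinical, truth


# ---------------------------------------------------------------------------
# 6-month follow-up


def generate_followup(
    baseline: list[HistologySample],
    response_strength: float,
    seed: int,
    *,
    slope: float = 1.2,
    noise_sd: float = 1.5,
    mean_improvement: float = 0.8,
) -> tuple[list[HistologySample], pd.Series]:
    """Follow-up histology and per-sample ΔDAS28 (baseline − 6 months).

    Pathotypes tend to shift towards less inflammatory states; when
    ``response_strength`` is positive, ΔDAS28 is coupled to the realized
    ordinal shift (slope × strength), so shift and clinical improvement
    are positively correlated. At ``response_strength=0`` ΔDAS28 is
    independent of the shift. Samples ungraded at baseline stay ungraded.
    """
    if not 0.0 <= response_strength:
        raise SpecError("response_strength must be non-negative")
    rng = np.random.default_rng([seed, 31])
    followup: list[HistologySample] = []
    shifts: list[float] = []
    ids = []
    for h in baseline:
        call = classify(h)
        ids.append(h.sample_id)
        if call.label == "ungraded":
            followup.append(_sample_histology(rng, h.sample_id, "ungraded"))
            shifts.append(np.nan)
            continue
        o_b = inflammation_ordinal(call.label)
        step = int(round(rng.normal(0.6, 0.9)))
        o_f = int(np.clip(o_b - step, 0, 2))
        new_label = {v: k for k, v in
                     {"fibroid": 0, "myeloid": 1, "lymphoid": 2}.items()}[o_f]
        followup.append(_sample_histology(rng, h.sample_id, new_label))
        shifts.append(float(o_b - o_f))
    shifts_a = np.asarray(shifts)
    coupled = np.where(np.isnan(shifts_a), 0.0, shifts_a)
    delta = (mean_improvement + slope * response_strength * coupled
             + noise_sd * rng.standard_normal(len(baseline)))
    return followup, pd.Series(delta, index=ids, name="delta_das28")


def cohort_pathotype_calls(histology: list[HistologySample]) -> list[PathotypeCall]:
    return [classify(h) for h in histology]
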