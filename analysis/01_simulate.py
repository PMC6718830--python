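"""Generate the synthetic study inputs: reference atlas, synovium-like and
blood-like count cohorts, histology scores and clinical tables.

Writes everything under results/data/ with the planted ground truth, so
the downstream numbered analyses can be audited against what was planted.
"""

from pathlib import Path

from tripathotype import atlas as am
from tripathotype import io, synthetic
from tripathotype.histology import write_histology_csv
from tripathotype.synthetic import AtlasSpec, CohortSpec

SEED = 0
OUT = Path("results/data")
MODULE_TISSUES = list(synthetic.CELL_TYPE_NAMES[:6])

#: the blood-like compartment carries weaker planted signal: only the
#: plasma-cell/CCP association survives systemically
BLOOD_SPEC = CohortSpec(
    n_per_group=(25, 22, 20),
    log2_effect=0.4,
    de_class_sizes=(8, 0, 0, 0, 0, 0),
    clinical_effect_map=(("plasma_cell", "CCP_titer", 0.5),),
    seed=SEED + 500,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    atlas_df, atlas_truth = synthetic.generate_atlas(AtlasSpec(seed=SEED))
    z, eligible = am.zscore_tissues(atlas_df)
    modules = [am.derive_module(z, t, eligible=eligible) for t in MODULE_TISSUES]

    syn_spec = CohortSpec(seed=SEED)
    counts, histology, clinical, truth = synthetic.generate_cohort(syn_spec, modules)
    b_counts, b_hist, b_clinical, b_truth = synthetic.generate_cohort(BLOOD_SPEC, modules)

    io.write_matrix_tsv(atlas_df, OUT / "atlas.tsv")
    io.write_gmt(modules, OUT / "modules.gmt")
    io.write_matrix_tsv(counts, OUT / "synovium_counts.tsv")
    io.write_matrix_tsv(b_counts, OUT / "blood_counts.tsv")
    write_histology_csv(histology, OUT / "histology.csv")
    io.write_sample_table_csv(clinical, OUT / "synovium_clinical.csv")
    io.write_sample_table_csv(b_clinical, OUT / "blood_clinical.csv")
    io.write_json(
        {"atlas": atlas_truth.to_json_dict(),
         "synovium": truth.to_json_dict(),
         "blood": b_truth.to_json_dict(),
         "seed": SEED},
        OUT / "truth.json",
    )
    n = counts.shape[1]
    print(f"atlas: {atlas_df.shape[0]} genes x {atlas_df.shape[1]} tissues, "
          f"{sum(len(v) for v in atlas_truth.marker_map.values())} planted markers")
    print(f"synovium cohort: {counts.shape[0]} genes x {n} samples "
          f"({syn_spec.n_per_group[0]}L/{syn_spec.n_per_group[1]}M/{syn_spec.n_per_group[2]}F), "
          f"{len(truth.de_class_map)} planted differential genes")
    print(f"blood cohort: {b_counts.shape[1]} samples, "
          f"{len(b_truth.de_class_map)} planted differential genes")
    print(f"inputs written to {OUT}/")


if __name__ == "__main__":
    main()
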