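"""Six-month follow-up: regenerate follow-up histology with a planted
treatment response, then measure the pathotype-shift / ΔDAS28 linear
relationship and the shift-direction x ACPA contingency.

Writes results/followup_shift.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tripathotype.histology import (
    classify,
    contingency_by_acpa,
    inflammation_ordinal,
    read_histology_csv,
    shift_vs_response,
)
from tripathotype.io import read_sample_table_csv
from tripathotype.synthetic import cohort_pathotype_calls, generate_followup

DATA = Path("results/data")
OUT = Path("results")
SEED = 0


def main() -> None:
    baseline = read_histology_csv(DATA / "histology.csv")
    clinical = read_sample_table_csv(DATA / "synovium_clinical.csv")
    followup, delta = generate_followup(baseline, response_strength=1.0, seed=SEED)

    base_calls = cohort_pathotype_calls(baseline)
    fup_calls = cohort_pathotype_calls(followup)
    res = shift_vs_response(base_calls, fup_calls, delta.tolist())
    print(f"pathotype shift vs ΔDAS28-ESR: Pearson r = {res.r:.2f} "
          f"(p = {res.p:.2g}, n = {res.n} graded pairs)")
    print("positive r: biopsies that moved to a less inflammatory pathotype "
          "showed larger DAS28 improvement, as planted")

    rows = []
    for b, f in zip(base_calls, fup_calls):
        if b.label == "ungraded" or f.label == "ungraded":
            shift = np.nan
        else:
            shift = inflammation_ordinal(b.label) - inflammation_ordinal(f.label)
        rows.append({"sample_id": b.sample_id, "baseline": b.label,
                     "followup": f.label, "shift": shift,
                     "delta_das28": delta[b.sample_id]})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "followup_shift.csv", index=False)

    graded = table.dropna(subset=["shift"]).set_index("sample_id")
    acpa = clinical.loc[graded.index, "ACPA_status"]
    less_inflamed = graded["shift"] > 0
    cont = [
        [int((less_inflamed & (acpa == "pos")).sum()),
         int((~less_inflamed & (acpa == "pos")).sum())],
        [int((less_inflamed & (acpa == "neg")).sum()),
         int((~less_inflamed & (acpa == "neg")).sum())],
    ]
    p = contingency_by_acpa(cont)
    print(f"shift-direction x ACPA Fisher exact p = {p:.2f} "
          f"(ACPA was not coupled to response in this cohort, so a "
          f"non-significant p is the planted expectation)")


if __name__ == "__main__":
    main()
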