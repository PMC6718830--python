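"""Histological pathotype classification of synovial biopsies.

Biopsies are scored semiquantitatively (0-4) by immunohistochemistry for
T cells (CD3), B cells (CD20), lining and sublining macrophages
(CD68L/CD68SL) and plasma cells (CD138); CD20+ B-cell aggregates are
graded 0-3. Three pathotypes are recognised:

* lympho-myeloid (L): grade 2-3 CD20+ aggregates with CD20 >= 2,
  or CD138 > 2;
* diffuse-myeloid (M): CD68SL >= 2 with CD138 <= 2 and (CD20 <= 1 or
  CD3 >= 1), and not lympho-myeloid;
* pauci-immune fibroid (F): CD68SL < 2 and CD3, CD20, CD138 all < 1.

Rules are evaluated with precedence L > M > F; score combinations firing
no rule are reported as ``ungraded`` and excluded from ordinal analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PATHOTYPES = ("lymphoid", "myeloid", "fibroid")

#: inflammation ordering used for pathotype-shift analyses
_ORDINAL = {"fibroid": 0, "myeloid": 1, "lymphoid": 2}

_SCORE_FIELDS = ("CD3", "CD20", "CD68L", "CD68SL", "CD138")


class HistologyError(ValueError):
    """Invalid histology scores or degenerate shift analysis input."""


@dataclass(frozen=True)
class HistologySample:
    """Semiquantitative IHC scores for one biopsy.

    All marker scores are integers 0-4; the CD20+ aggregate grade is 0-3
    (0 meaning no aggregates scored).
    """

    sample_id: str
    CD3: int
    CD20: int
    CD68L: int
    CD68SL: int
    CD138: int
    cd20_aggregate_grade: int

    def __post_init__(self) -> None:
        for field in _SCORE_FIELDS:
            v = getattr(self, field)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
                raise HistologyError(
                    f"{self.sample_id}: {field}={v!r} outside integer range 0-4"
                )
        g = self.cd20_aggregate_grade
        if not (isinstance(g, (int, np.integer)) and 0 <= g <= 3):
            raise HistologyError(
                f"{self.sample_id}: cd20_aggregate_grade={g!r} outside integer range 0-3"
            )


@dataclass(frozen=True)
class PathotypeCall:
    sample_id: str
    label: str  # lymphoid | myeloid | fibroid | ungraded
    fired_rule: str


def classify(h: HistologySample) -> PathotypeCall:
    """Apply the pathotype rules to one biopsy, precedence L > M > F."""
    # L: grade 2-3 CD20+ aggregates (with CD20 >= 2), or CD138 > 2 alone
    if h.cd20_aggregate_grade >= 2 and h.CD20 >= 2:
        return PathotypeCall(h.sample_id, "lymphoid", "L: grade 2-3 CD20+ aggregates, CD20>=2")
    if h.CD138 > 2:
        return PathotypeCall(h.sample_id, "lymphoid", "L: CD138>2")
    # M: sublining macrophage rich, B-cell poor (or T-cell containing)
    if h.CD68SL >= 2 and h.CD138 <= 2 and (h.CD20 <= 1 or h.CD3 >= 1):
        return PathotypeCall(h.sample_id, "myeloid", "M: CD68SL>=2, CD138<=2, CD20<=1 or CD3>=1")
    # F: paucity of immune infiltrate
    if h.CD68SL < 2 and h.CD3 < 1 and h.CD20 < 1 and h.CD138 < 1:
        return PathotypeCall(h.sample_id, "fibroid", "F: CD68SL<2 and CD3,CD20,CD138<1")
    return PathotypeCall(h.sample_id, "ungraded", "no rule fired")


def classify_all(samples: Iterable[HistologySample]) -> list[PathotypeCall]:
    return [classify(h) for h in samples]


def inflammation_ordinal(label: str) -> int:
    """Map a pathotype to its inflammation ordinal (fibroid 0 < myeloid 1 < lymphoid 2)."""
    try:
        return _ORDINAL[label]
    except KeyError:
        raise HistologyError(
            f"no inflammation ordinal for label {label!r}; ungraded samples are "
            "excluded from shift analysis"
        ) from None


@dataclass(frozen=True)
class ShiftResult:
    r: float
    p: float
    n: int
    degenerate: bool = False


def pathotype_shift(baseline: PathotypeCall, followup: PathotypeCall) -> int:
    """Ordinal shift, positive when the biopsy became less inflammatory."""
    return inflammation_ordinal(baseline.label) - inflammation_ordinal(followup.label)


def shift_vs_response(
    baseline: Sequence[PathotypeCall],
    followup: Sequence[PathotypeCall],
    delta_das28: Sequence[float],
) -> ShiftResult:
    """Pearson correlation of pathotype shift against change in DAS28.

    Shift = ordinal(baseline) - ordinal(6 months); ΔDAS28 = baseline - 6
    months, so positive values mean clinical improvement on both axes.
    Pairs ungraded at either timepoint are dropped. A zero-variance shift
    or response vector yields a degenerate (NaN) result rather than an
    exception.
    """
    base_by_id = {c.sample_id: c for c in baseline}
    fup_by_id = {c.sample_id: c for c in followup}
    if set(base_by_id) != set(fup_by_id):
        raise HistologyError("baseline and follow-up sample ids do not match")
    if len(baseline) != len(delta_das28):
        raise HistologyError("delta_das28 length does not match sample count")
    deltas = dict(zip((c.sample_id for c in baseline), delta_das28))

    shifts, resp = [], []
    for sid, b in base_by_id.items():
        f = fup_by_id[sid]
        d = deltas[sid]
        if b.label == "ungraded" or f.label == "ungraded" or not np.isfinite(d):
            continue
        shifts.append(pathotype_shift(b, f))
        resp.append(float(d))
    if len(shifts) < 3:
        raise HistologyError(
            f"insufficient data: {len(shifts)} complete graded pairs (need >=3)"
        )
    shifts_a = np.asarray(shifts, dtype=float)
    resp_a = np.asarray(resp, dtype=float)
    if np.ptp(shifts_a) == 0 or np.ptp(resp_a) == 0:
        return ShiftResult(r=float("nan"), p=float("nan"), n=len(shifts), degenerate=True)
    r, p = stats.pearsonr(shifts_a, resp_a)
    return ShiftResult(r=float(r), p=float(p), n=len(shifts))


def contingency_by_acpa(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 shift-direction x ACPA-status table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise HistologyError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise HistologyError("negative cell counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise HistologyError("empty margin in 2x2 table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# CSV I/O

HISTOLOGY_COLUMNS = ["sample_id", *_SCORE_FIELDS, "cd20_aggregate_grade"]


def read_histology_csv(path) -> list[HistologySample]:
    df = pd.read_csv(path)
    missing = set(HISTOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise HistologyError(f"histology CSV missing columns: {sorted(missing)}")
    return [
        HistologySample(
            sample_id=str(row.sample_id),
            CD3=int(row.CD3),
            CD20=int(row.CD20),
            CD68L=int(row.CD68L),
            CD68SL=int(row.CD68SL),
            CD138=int(row.CD138),
            cd20_aggregate_grade=int(row.cd20_aggregate_grade),
        )
        for row in df.itertuples(index=False)
    ]


def write_histology_csv(samples: Sequence[HistologySample], path, calls=None) -> None:
    rows = []
    for h in samples:
        d = {c: getattr(h, c) for c in HISTOLOGY_COLUMNS}
        rows.append(d)
    df = pd.DataFrame(rows, columns=HISTOLOGY_COLUMNS)
    if calls is not None:
        labels = {c.sample_id: c.label for c in calls}
        df["pathotype"] = [labels[h.sample_id] for h in samples]
    df.to_csv(path, index=False)
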