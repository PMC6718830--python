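"""Polar "three-way volcano" projection of three-group DE results.

Per-gene group summaries (L, M, F) — mean Z scores or mean log2 folds —
are reduced to the plane exactly as RGB color space maps to hue and
saturation:

    x = sqrt(3)/2 * (M - F)
    y = L - (M + F) / 2
    theta = atan2(y, x),   r = sqrt(x^2 + y^2)

so the lymphoid axis points to 90 deg, myeloid to 330 deg (-30) and
fibroid to 210 deg, 120 deg apart. The vertical axis of the cylindrical
3D variant is -log10 of the three-group likelihood-ratio p value.
Adding a constant to all three group means leaves (x, y) unchanged, so
only relative up/down regulation determines a gene's angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AXIS_ANGLES = {"L": 90.0, "M": 330.0, "F": 210.0}

COLOR_HEX = {
    "blue": "#0000FF",
    "red": "#FF0000",
    "green": "#00B050",
    "purple": "#A000A0",
    "yellow": "#FFC000",
    "cyan": "#00B0F0",
    "gray": "#808080",
}

P_FLOOR = 1e-300  # underflow clip before -log10; caps z_height at 300


class PolarError(ValueError):
    pass


@dataclass(frozen=True)
class PolarGene:
    gene_id: str
    L: float
    M: float
    F: float
    x: float
    y: float
    theta_deg: float
    r: float
    z_height: float
    color_class: str


def project_xy(L, M, F):
    """Vectorized planar coordinates; accepts scalars or arrays."""
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    F = np.asarray(F, dtype=float)
    x = math.sqrt(3.0) / 2.0 * (M - F)
    y = L - 0.5 * (M + F)
    return x, y


def theta_r(x, y):
    """Angle in degrees on [0, 360) and radius; theta at the origin is 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    theta = np.where(r == 0, 0.0, theta)
    return theta, r


def z_height(lrt_p):
    p = np.asarray(lrt_p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise PolarError("lrt_p outside [0, 1]")
    return -np.log10(np.clip(p, P_FLOOR, 1.0))


def project(gene_id: str, L: float, M: float, F: float, lrt_p: float,
            color_class: str = "gray") -> PolarGene:
    """Project one gene's (L, M, F) summary onto the polar plane."""
    for name, v in (("L", L), ("M", M), ("F", F)):
        if not np.isfinite(v):
            raise PolarError(f"non-finite group summary {name}={v!r} for {gene_id}")
    if not (np.isfinite(lrt_p) and 0.0 <= lrt_p <= 1.0):
        raise PolarError(f"invalid lrt_p={lrt_p!r} for {gene_id}")
    x, y = project_xy(L, M, F)
    theta, r = theta_r(x, y)
    return PolarGene(
        gene_id=gene_id, L=float(L), M=float(M), F=float(F),
        x=float(x), y=float(y), theta_deg=float(theta), r=float(r),
        z_height=float(z_height(lrt_p)), color_class=color_class,
    )


@dataclass
class PolarPayload:
    genes: pd.DataFrame
    radial_mode: str
    q_threshold: float
    axis_angles: dict = field(default_factory=lambda: dict(AXIS_ANGLES))
    meta: dict = field(default_factory=dict)


def build_payload(de_table: pd.DataFrame, radial_mode: str = "zscore",
                  q_threshold: float = 0.05) -> PolarPayload:
    """Project a full DE table (one row per gene) onto the polar plane.

    ``radial_mode='zscore'`` uses the per-group mean Z columns (z_L, z_M,
    z_F); ``'fold'`` uses centered log2 group means instead, which
    rescales r. The fold-change angles are not in general identical to
    the Z-score angles (they coincide only when folds are proportional
    to centered Z differences); the payload therefore records the median
    absolute angular discrepancy between the two modes rather than
    asserting their equality.
    """
    if de_table.empty:
        raise PolarError("empty DE table")
    if radial_mode not in ("zscore", "fold"):
        raise PolarError(f"unknown radial_mode {radial_mode!r}")

    z = {g: de_table[f"z_{g}"].to_numpy(dtype=float) for g in ("L", "M", "F")}
    if radial_mode == "zscore":
        L, M, F = z["L"], z["M"], z["F"]
    else:
        lg = {g: np.log2(de_table[f"mean_{g}"].to_numpy(dtype=float) + 0.5)
              for g in ("L", "M", "F")}
        center = (lg["L"] + lg["M"] + lg["F"]) / 3.0
        L, M, F = lg["L"] - center, lg["M"] - center, lg["F"] - center

    x, y = project_xy(L, M, F)
    theta, r = theta_r(x, y)
    lrt_p = de_table["lrt_p"].to_numpy(dtype=float)
    zh = z_height(np.where(np.isfinite(lrt_p), lrt_p, 1.0))

    genes = pd.DataFrame({
        "gene_id": de_table.index.astype(str),
        "L": L, "M": M, "F": F,
        "x": x, "y": y, "theta_deg": theta, "r": r,
        "z_height": zh,
        "color_class": de_table["color_class"].to_numpy(),
    }).set_index("gene_id")

    # empirical angular discrepancy between radial modes (reported, not asserted)
    xz, yz = project_xy(z["L"], z["M"], z["F"])
    theta_z, r_z = theta_r(xz, yz)
    both = (r > 0) & (r_z > 0)
    if both.any():
        d = np.abs(((theta[both] - theta_z[both]) + 180.0) % 360.0 - 180.0)
        theta_disc = float(np.median(d))
    else:
        theta_disc = 0.0
    return PolarPayload(
        genes=genes, radial_mode=radial_mode, q_threshold=q_threshold,
        meta={"median_theta_discrepancy_vs_zscore_deg": theta_disc,
              "n_significant": int((de_table["color_class"] != "gray").sum())},
    )


def _points(payload: PolarPayload) -> list[dict]:
    recs = []
    for gid, row in payload.genes.iterrows():
        recs.append({
            "gene_id": str(gid),
            "x": float(row["x"]), "y": float(row["y"]),
            "theta_deg": float(row["theta_deg"]), "r": float(row["r"]),
            "z_height": float(row["z_height"]),
            "color_class": str(row["color_class"]),
            "color_hex": COLOR_HEX[str(row["color_class"])],
        })
    return recs


def polar_2d_payload(payload: PolarPayload) -> dict:
    """JSON-serializable 2D polar plot structure (no plotting library needed)."""
    return {
        "kind": "polar_2d",
        "axes": [{"label": k, "angle_deg": v} for k, v in payload.axis_angles.items()],
        "radial_mode": payload.radial_mode,
        "points": _points(payload),
        "meta": payload.meta,
    }


def cylinder_3d_payload(payload: PolarPayload) -> dict:
    """JSON-serializable cylindrical 3D volcano structure; the vertical
    axis is -log10 LRT p."""
    out = polar_2d_payload(payload)
    out["kind"] = "cylinder_3d"
    out["z_axis"] = {"label": "-log10 LRT p", "max": 300.0}
    return out
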