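"""Joint-space width (JSW) and narrowing (JSN) from frontal-plane contours.

JSW is the vertical distance from the central point of a femoral condyle
surface down to the tibial plateau, per compartment; JSN is the percentage
JSW loss between a baseline and a follow-up radiograph.  Contours are
programmatic polylines in the (z, y) image plane (z mediolateral, y
vertical, mm); a synthetic generator produces paired baseline/follow-up
contours with a prescribed true narrowing and additive point noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import AnatomicMeasurements


@dataclass(frozen=True)
class JointContours:
    """Frontal-plane femoral and tibial contours with per-compartment ROIs."""

    femoral: np.ndarray  # (n, 2) columns (z, y), mm
    tibial: np.ndarray  # (m, 2)
    roi: dict  # compartment -> (z_lo, z_hi)


@dataclass(frozen=True)
class JSWRecord:
    jsw_medial: float
    jsw_lateral: float
    timepoint: str = "baseline"

    def __post_init__(self) -> None:
        if self.jsw_medial <= 0 or self.jsw_lateral <= 0:
            raise ValueError("JSW must be positive")

    def jsw(self, compartment: str) -> float:
        return self.jsw_medial if compartment == "medial" else self.jsw_lateral


def _interp_contour(contour: np.ndarray, z: float) -> float:
    zs, ys = contour[:, 0], contour[:, 1]
    order = np.argsort(zs)
    zs, ys = zs[order], ys[order]
    if not zs[0] <= z <= zs[-1]:
        raise ValueError(f"projection at z = {z:.2f} mm misses the contour")
    return float(np.interp(z, zs, ys))


def measure_jsw(
    contours: JointContours, compartment: str, mode: str = "midpoint"
) -> float:
    """JSW (mm) for one compartment.

    ``mode='midpoint'`` takes the femoral point at the ROI z-midpoint (the
    default reading of 'central point of the condyle surface');
    ``mode='lowest'`` takes the lowest femoral point within the ROI.  The
    value is the vertical drop to the tibial contour at the same z.
    """
    z_lo, z_hi = contours.roi[compartment]
    if z_hi <= z_lo:
        raise ValueError("empty compartment ROI")
    if mode == "midpoint":
        z = 0.5 * (z_lo + z_hi)
    elif mode == "lowest":
        fem = contours.femoral
        sel = (fem[:, 0] >= z_lo) & (fem[:, 0] <= z_hi)
        if not sel.any():
            raise ValueError("no femoral contour points inside the ROI")
        z = float(fem[sel][np.argmin(fem[sel, 1]), 0])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _interp_contour(contours.femoral, z) - _interp_contour(contours.tibial, z)


def compute_jsn(baseline: JSWRecord, followup: JSWRecord) -> dict:
    """Percentage JSW loss per compartment (negative = widening)."""
    return {
        c: 100.0 * (baseline.jsw(c) - followup.jsw(c)) / baseline.jsw(c)
        for c in ("medial", "lateral")
    }


def generate_contours(
    subject_meas: AnatomicMeasurements,
    jsn_target: "float | dict",
    noise: float = 0.0,
    seed: int = 0,
    point_spacing: float = 0.5,
) -> tuple[JointContours, JointContours]:
    """Synthetic baseline/follow-up contour pair for one knee.

    Circular condyle arcs above a flat plateau; the true JSW at each ROI
    midpoint equals the subject's joint-space measurement at baseline and
    JS x (1 - jsn/100) at follow-up.  Gaussian noise of the given standard
    deviation (mm) is added to every contour point.
    """
    if isinstance(jsn_target, dict):
        jsn = jsn_target
    else:
        jsn = {"medial": float(jsn_target), "lateral": float(jsn_target)}
    for v in jsn.values():
        if v >= 100:
            raise ValueError("JSN target must be below 100%")
    rng = np.random.default_rng(seed)
    centers = {"medial": 25.0, "lateral": 75.0}
    half_width = 18.0
    radius = 45.0
    z = np.arange(0.0, 100.0 + point_spacing / 2, point_spacing)

    def knee(jsw_by_comp):
        fem_y = np.full_like(z, np.nan)
        for comp, zc in centers.items():
            sel = np.abs(z - zc) <= half_width
            dz = z[sel] - zc
            fem_y[sel] = jsw_by_comp[comp] + radius - np.sqrt(radius**2 - dz**2)
        valid = ~np.isnan(fem_y)
        fem = np.stack([z[valid], fem_y[valid]], axis=1)
        tib = np.stack([z, np.zeros_like(z)], axis=1)
        fem = fem + np.stack(
            [np.zeros(len(fem)), rng.normal(0, noise, len(fem))], axis=1
        )
        tib = tib + np.stack(
            [np.zeros(len(tib)), rng.normal(0, noise, len(tib))], axis=1
        )
        roi = {c: (zc - half_width, zc + half_width) for c, zc in centers.items()}
        return JointContours(fem, tib, roi)

    base_jsw = {
        "medial": subject_meas.js_medial,
        "lateral": subject_meas.js_lateral,
    }
    follow_jsw = {c: base_jsw[c] * (1.0 - jsn[c] / 100.0) for c in base_jsw}
    return knee(base_jsw), knee(follow_jsw)
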