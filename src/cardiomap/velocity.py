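"""Conduction-velocity vector fields from activation maps.

At each valid pixel a second-order polynomial surface

    T(x, y) ≈ a·x² + b·y² + c·xy + d·x + e·y + f

is fitted by ordinary least squares to the activation times in a local
window, in window-centered physical coordinates (x, y in μm, T in ms), so
the local gradient ∇T at the pixel is simply (d, e).  The conduction
velocity then follows from inverting the gradient of the travel-time field:

    v = ∇T / |∇T|²,   hence   |v| = 1 / |∇T|,

pointing in the direction of propagation.  Pixels whose fit is
rank-deficient, whose residual exceeds a goodness-of-fit bound, or whose
gradient magnitude falls below a floor (a wavefront collision or
breakthrough site, where the travel-time gradient genuinely vanishes) are
marked invalid.

Vectors are summarized in fixed-size square ROIs (default 16×16 pixels) by
the arithmetic mean speed and the circular mean angle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import ActivationMap
from .imaging_io import pixel_coords

logger = logging.getLogger("cardiomap")

#: default gradient floor in ms/μm below which a gradient is treated as a
#: local extremum / breakthrough rather than a propagating front
GRADIENT_FLOOR = 1e-6

#: default residual bound as a fraction of the window's activation-time span
RESIDUAL_FRACTION = 0.10


@dataclass
class SurfaceFit:
    """Quadratic-surface fit in window-centered physical coordinates."""

    coefficients: np.ndarray  # (a, b, c, d, e, f)
    residual_rms_ms: float
    n_points: int
    half_width: int
    valid: bool = True

    @property
    def gradient(self) -> tuple[float, float]:
        """∇T at the window center, (d, e), in ms/μm."""
        return float(self.coefficients[3]), float(self.coefficients[4])


@dataclass
class VelocityField:
    """Per-pixel conduction-velocity vectors (μm/ms) with validity."""

    vx: np.ndarray
    vy: np.ndarray
    validity: np.ndarray
    pixel_size_um: float
    residual_rms_ms: np.ndarray | None = None

    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def angle_deg(self) -> np.ndarray:
        """Absolute vector angles, CCW degrees from +x, wrapped to [0, 360)."""
        return np.degrees(np.arctan2(self.vy, self.vx)) % 360.0


@dataclass
class ROISummary:
    """Vector statistics over one square ROI."""

    roi_id: int
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    n_vectors: int
    mean_speed: float
    speed_sd: float
    mean_angle_deg: float


def _window_design(amap: ActivationMap, row: int, col: int, half_width: int):
    """Valid window pixels as (design matrix, times); coords centered on (row, col)."""
    r0 = max(row - half_width, 0)
    r1 = min(row + half_width + 1, amap.shape[0])
    c0 = max(col - half_width, 0)
    c1 = min(col + half_width + 1, amap.shape[1])
    sub_valid = amap.validity[r0:r1, c0:c1]
    rr, cc = np.nonzero(sub_valid)
    times = amap.times_ms[r0:r1, c0:c1][rr, cc]
    # y-up physical frame: +row is -y
    dx = (cc + c0 - col) * amap.pixel_size_um
    dy = (row - (rr + r0)) * amap.pixel_size_um
    design = np.column_stack([dx**2, dy**2, dx * dy, dx, dy, np.ones_like(dx, dtype=float)])
    return design, times


def fit_local_surface(
    amap: ActivationMap, row: int, col: int, half_width: int = 2
) -> SurfaceFit:
    """Least-squares quadratic surface over the local window around a pixel.

    Requires a valid center pixel and at least 6 valid window pixels in
    general position (the model has 6 coefficients); otherwise, or when the
    design is rank-deficient, an invalid fit is returned.
    """
    if not (0 <= row < amap.shape[0] and 0 <= col < amap.shape[1]):
        raise ValueError(f"center ({row}, {col}) outside map of shape {amap.shape}")
    bad = SurfaceFit(np.full(6, np.nan), float("nan"), 0, half_width, valid=False)
    if not amap.validity[row, col]:
        return bad
    design, times = _window_design(amap, row, col, half_width)
    if len(times) < 6:
        return bad
    coef, _, rank, _ = np.linalg.lstsq(design, times, rcond=None)
    if rank < 6:
        return bad
    resid = times - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    return SurfaceFit(coef, rms, len(times), half_width)


def velocity_from_gradient(
    tx: float, ty: float, gradient_floor: float = GRADIENT_FLOOR
) -> tuple[float, float]:
    """Invert a travel-time gradient (ms/μm) into a velocity vector (μm/ms).

    v = (Tx, Ty) / (Tx² + Ty²); returns (NaN, NaN) when |∇T| falls below the
    floor — the signature of a local extremum or breakthrough site, not a
    propagating wavefront.
    """
    if not (np.isfinite(tx) and np.isfinite(ty)):
        return (float("nan"), float("nan"))
    g2 = tx * tx + ty * ty
    if np.sqrt(g2) < gradient_floor:
        return (float("nan"), float("nan"))
    return (tx / g2, ty / g2)


def velocity_field(
    amap: ActivationMap,
    half_width: int = 2,
    max_residual_ms: float | None = None,
    gradient_floor: float = GRADIENT_FLOOR,
) -> VelocityField:
    """Estimate the conduction-velocity vector at every valid pixel.

    ``max_residual_ms`` bounds the surface-fit residual RMS; when None it
    defaults per window to ``RESIDUAL_FRACTION`` of that window's
    activation-time span, so poorly modelled neighbourhoods (wave collisions,
    detection outliers) are excluded rather than inverted into spurious
    vectors.
    """
    shape = amap.shape
    vx = np.full(shape, np.nan)
    vy = np.full(shape, np.nan)
    resid = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for r, c in zip(*np.nonzero(amap.validity)):
        fit = fit_local_surface(amap, r, c, half_width)
        if not fit.valid:
            continue
        design, times = _window_design(amap, r, c, half_width)
        span = float(times.max() - times.min())
        bound = max_residual_ms if max_residual_ms is not None else RESIDUAL_FRACTION * span
        if fit.residual_rms_ms > bound:
            continue
        v = velocity_from_gradient(*fit.gradient, gradient_floor=gradient_floor)
        if np.isfinite(v[0]):
            vx[r, c], vy[r, c] = v
            resid[r, c] = fit.residual_rms_ms
            valid[r, c] = True
    if not valid.any():
        logger.warning("velocity_field: no valid vectors")
    return VelocityField(vx, vy, valid, amap.pixel_size_um, resid)


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Circular mean of angles in degrees, wrapped to [0, 360)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360.0)


def roi_summaries(
    field: VelocityField, roi_size: int = 16, origin: tuple[int, int] | None = None
) -> list[ROISummary]:
    """Tile the valid region with square ROIs and summarize vectors per ROI.

    The default 16×16-pixel tiling matches ROIs covering ≈35×35 μm² at the
    native magnification.  Tiling is anchored at the bounding box of the
    valid pixels (or an explicit ``origin``); ROIs are clipped at the map
    edge and partially valid ROIs are summarized over their valid pixels.
    ROIs without any valid vector are reported with ``n_vectors = 0`` and
    NaN statistics.
    """
    if roi_size < 2:
        raise ValueError("roi_size must be at least 2")
    rr, cc = np.nonzero(field.validity)
    if len(rr) == 0:
        return []
    if origin is None:
        origin = (int(rr.min()), int(cc.min()))
    r_end, c_end = int(rr.max()) + 1, int(cc.max()) + 1
    speed = field.speed()
    angle = field.angle_deg()
    out: list[ROISummary] = []
    roi_id = 0
    for r0 in range(origin[0], r_end, roi_size):
        for c0 in range(origin[1], c_end, roi_size):
            r1 = min(r0 + roi_size, field.validity.shape[0])
            c1 = min(c0 + roi_size, field.validity.shape[1])
            sel = field.validity[r0:r1, c0:c1]
            n = int(sel.sum())
            if n == 0:
                out.append(
                    ROISummary(roi_id, r0, r1, c0, c1, 0, float("nan"), float("nan"), float("nan"))
                )
            else:
                sp = speed[r0:r1, c0:c1][sel]
                an = angle[r0:r1, c0:c1][sel]
                sd = float(np.std(sp, ddof=1)) if n > 1 else float("nan")
                out.append(
                    ROISummary(
                        roi_id, r0, r1, c0, c1, n,
                        float(np.mean(sp)), sd, circular_mean_deg(an),
                    )
                )
            roi_id += 1
    return out


def roi_table(summaries: list[ROISummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def field_table(field: VelocityField) -> pd.DataFrame:
    """Tidy per-pixel vector table (valid pixels only)."""
    X, Y = pixel_coords(field.validity.shape, field.pixel_size_um)
    rr, cc = np.nonzero(field.validity)
    resid = (
        field.residual_rms_ms[rr, cc]
        if field.residual_rms_ms is not None
        else np.full(len(rr), np.nan)
    )
    return pd.DataFrame(
        {
            "row": rr,
            "col": cc,
            "x_um": X[rr, cc],
            "y_um": Y[rr, cc],
            "vx": field.vx[rr, cc],
            "vy": field.vy[rr, cc],
            "speed": field.speed()[rr, cc],
            "angle_deg": field.angle_deg()[rr, cc],
            "residual_rms": resid,
        }
    )
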