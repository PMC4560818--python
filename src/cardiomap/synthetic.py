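"""Synthetic excitation-wave movies with known ground truth.

Generates kinematic activation-time fields T(x, y) (planar, radial, and a
two-region field with per-region speed and anisotropy), renders them into
noisy voltage-dye movies with a prescribed action-potential template and dye
polarity, and fabricates mask pairs and nuclei tables for the morphometry
stage.  Every downstream stage of the pipeline can therefore be tested by
parameter recovery against analytic truth.

The waves are purely kinematic: T is prescribed, the true conduction-velocity
field is its analytic gradient inverted, v = ∇T / |∇T|².  No
reaction–diffusion electrophysiology is simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging_io import FluorescenceMovie, pixel_coords, write_mask, write_movie

SCENARIOS = ("planar", "radial", "two_region")
TEMPLATES = ("linear_ramp", "sigmoid")


@dataclass
class ApTemplate:
    """Action-potential waveform template.

    The unit waveform is 0 before onset, rises over ``upstroke_ms`` and then
    holds a plateau (no repolarization within the analysis window, so the
    half-amplitude crossing is unique).  Both shapes cross 50% of amplitude
    exactly ``upstroke_ms / 2`` after onset: the linear ramp trivially, the
    sigmoid because it is a symmetric truncated logistic.
    """

    name: str = "linear_ramp"
    upstroke_ms: float = 1.0
    plateau_ms: float = 50.0
    amplitude: float = 100.0

    def __post_init__(self):
        if self.name not in TEMPLATES:
            raise ValueError(f"unknown template {self.name!r}; expected one of {TEMPLATES}")
        if self.upstroke_ms <= 0 or self.plateau_ms < 0 or self.amplitude <= 0:
            raise ValueError("upstroke_ms, amplitude must be > 0 and plateau_ms >= 0")

    @property
    def duration_ms(self) -> float:
        return self.upstroke_ms + self.plateau_ms

    def unit_waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate the unit-amplitude waveform at times relative to onset."""
        t = np.asarray(t_ms, dtype=float)
        u = self.upstroke_ms
        if self.name == "linear_ramp":
            return np.clip(t / u, 0.0, 1.0)
        # truncated logistic, rescaled to hit 0 and 1 exactly at the ends
        tau = u / 8.0
        s = 1.0 / (1.0 + np.exp(-np.clip((t - u / 2.0) / tau, -500, 500)))
        s0 = 1.0 / (1.0 + np.exp(4.0))
        out = (s - s0) / (1.0 - 2.0 * s0)
        return np.clip(np.where(t < 0, 0.0, np.where(t > u, 1.0, out)), 0.0, 1.0)


@dataclass
class WaveSpec:
    """Parameters of one synthetic scenario.

    Defaults mirror the acquisition they emulate: 2,000 frames/s recordings of
    embryonic zebrafish hearts where a 16×16-pixel ROI covers ≈35×35 μm²
    (pixel size ≈ 2.2 μm), with a negative-going dye signal.
    """

    grid_shape: tuple[int, int] = (64, 64)
    pixel_size_um: float = 2.2
    frame_rate_hz: float = 2000.0
    scenario: str = "planar"
    direction_deg: float = 0.0
    speed_um_per_ms: float = 10.0
    # two_region parameters: region 0 is left of boundary_col, region 1 right
    region_speeds: tuple[float, float] = (8.0, 2.0)
    region_anisotropy: tuple[float, float] = (1.0, 1.0)
    boundary_col: int | None = None
    undulation_deg: float = 0.0
    undulation_period_um: float = 50.0
    ap_template: ApTemplate = field(default_factory=ApTemplate)
    polarity: str = "negative"
    baseline: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if tuple(self.grid_shape) < (8, 8) or len(self.grid_shape) != 2:
            raise ValueError("grid_shape must be at least (8, 8)")
        if not (0.0 <= self.direction_deg < 360.0):
            raise ValueError("direction_deg must lie in [0, 360)")
        if self.speed_um_per_ms <= 0 or any(s <= 0 for s in self.region_speeds):
            raise ValueError("speeds must be positive")
        if any(a < 1 for a in self.region_anisotropy):
            raise ValueError("anisotropy ratios must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0.0 <= self.undulation_deg < 90.0):
            raise ValueError("undulation_deg must lie in [0, 90)")
        if self.boundary_col is None:
            self.boundary_col = self.grid_shape[1] // 2
        if self.scenario == "two_region" and not (0 < self.boundary_col < self.grid_shape[1]):
            raise ValueError("boundary_col must split the grid into two non-empty regions")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d


@dataclass
class GroundTruth:
    """Analytic activation-time and velocity fields for a scenario.

    Wherever the true gradient is nonzero, speed × |∇T| = 1 holds by
    construction.  ``unit_vector`` is the principal propagation direction
    (for the radial scenario, where no single direction exists, it is the
    nominal +x axis).
    """

    activation_ms: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    validity: np.ndarray
    unit_vector: np.ndarray
    pixel_size_um: float

    def speed(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)


def make_activation_field(spec: WaveSpec) -> GroundTruth:
    """Build the ground-truth activation field T(x, y) and its velocity field.

    planar
        T = (p · d̂) / speed, offset so min T = 0; velocity is ``speed · d̂``
        everywhere.
    radial
        T = |p − center| / speed from the grid center; velocity points
        radially outward with magnitude ``speed`` (undefined at the center).
    two_region
        Propagation along +x with per-region slowness 1/speed, continuous
        across the boundary column.  A transverse sinusoidal wavefront
        undulation (max deviation ``undulation_deg / anisotropy`` per region,
        amplitude ramping to zero at the boundary so T stays continuous)
        models isotropic regions as multidirectional and anisotropic regions
        as nearly linear.  With the default ``undulation_deg = 0`` the field
        is exactly piecewise planar.
    """
    X, Y = pixel_coords(spec.grid_shape, spec.pixel_size_um)
    valid = np.ones(spec.grid_shape, dtype=bool)

    if spec.scenario == "planar":
        th = np.deg2rad(spec.direction_deg)
        d = np.array([np.cos(th), np.sin(th)])
        proj = X * d[0] + Y * d[1]
        T = (proj - proj.min()) / spec.speed_um_per_ms
        vx = np.full(spec.grid_shape, spec.speed_um_per_ms * d[0])
        vy = np.full(spec.grid_shape, spec.speed_um_per_ms * d[1])
        return GroundTruth(T, vx, vy, valid, d, spec.pixel_size_um)

    if spec.scenario == "radial":
        cx = (spec.grid_shape[1] - 1) / 2.0 * spec.pixel_size_um
        cy = (spec.grid_shape[0] - 1) / 2.0 * spec.pixel_size_um
        rx, ry = X - cx, Y - cy
        r = np.hypot(rx, ry)
        T = r / spec.speed_um_per_ms
        with np.errstate(invalid="ignore", divide="ignore"):
            vx = spec.speed_um_per_ms * rx / r
            vy = spec.speed_um_per_ms * ry / r
        center = r == 0
        vx[center] = 0.0
        vy[center] = 0.0
        valid &= ~center
        return GroundTruth(T, vx, vy, valid, np.array([1.0, 0.0]), spec.pixel_size_um)

    # two_region
    s0, s1 = spec.region_speeds
    xb = spec.boundary_col * spec.pixel_size_um
    xmax = (spec.grid_shape[1] - 1) * spec.pixel_size_um
    left = X < xb
    slowness = np.where(left, 1.0 / s0, 1.0 / s1)
    B = np.where(left, X / s0, xb / s0 + (X - xb) / s1)

    k = 2.0 * np.pi / spec.undulation_period_um
    if spec.undulation_deg == 0.0:
        A = np.zeros_like(X)
        dA = np.zeros_like(X)
    else:
        # full undulation amplitude per region: transverse gradient tan(φ)·slowness
        phi = np.deg2rad(spec.undulation_deg) / np.asarray(spec.region_anisotropy)
        A_full = np.tan(phi) / (np.array([s0, s1]) * k)
        # amplitude ramps linearly from 0 at the boundary to A_full at each edge
        span_l = max(xb, spec.pixel_size_um)
        span_r = max(xmax - xb, spec.pixel_size_um)
        A = np.where(left, A_full[0] * (xb - X) / span_l, A_full[1] * (X - xb) / span_r)
        dA = np.where(left, -A_full[0] / span_l, A_full[1] / span_r)

    T = B + A * np.sin(k * Y)
    Tx = slowness + dA * np.sin(k * Y)
    Ty = A * k * np.cos(k * Y)
    g2 = Tx**2 + Ty**2
    vx = Tx / g2
    vy = Ty / g2
    return GroundTruth(T, vx, vy, valid, np.array([1.0, 0.0]), spec.pixel_size_um)


def render_movie(
    truth: GroundTruth, spec: WaveSpec, duration_ms: float | None = None
) -> FluorescenceMovie:
    """Render a ground-truth activation field into a voltage-dye movie.

    Each pixel trace is ``baseline ± amplitude · AP(t − T(x, y)) + noise``
    with sign set by the dye polarity (negative: fluorescence drops on
    depolarization) and i.i.d. Gaussian noise of sd ``noise_sd`` drawn from
    ``spec.seed``.  The movie must cover every upstroke:
    ``duration ≥ max(T) + template duration``.
    """
    tpl = spec.ap_template
    t_max = float(truth.activation_ms.max())
    needed = t_max + tpl.duration_ms
    if duration_ms is None:
        duration_ms = needed + 2.0 / spec.frame_rate_hz * 1e3
    if duration_ms < t_max + tpl.upstroke_ms:
        raise ValueError(
            f"duration {duration_ms:.3f} ms too short: latest upstroke ends at "
            f"{t_max + tpl.upstroke_ms:.3f} ms"
        )
    n_frames = int(np.ceil(duration_ms * spec.frame_rate_hz / 1e3)) + 1
    times = np.arange(n_frames) / spec.frame_rate_hz * 1e3

    ap = tpl.unit_waveform(times[:, None, None] - truth.activation_ms[None]) * tpl.amplitude
    sign = -1.0 if spec.polarity == "negative" else 1.0
    frames = spec.baseline + sign * ap
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        frames = frames + rng.normal(0.0, spec.noise_sd, size=frames.shape)
    return FluorescenceMovie(frames, spec.frame_rate_hz, spec.pixel_size_um, spec.polarity)


def simulate(spec: WaveSpec) -> tuple[GroundTruth, FluorescenceMovie]:
    """Convenience: ground truth plus rendered movie for one spec."""
    truth = make_activation_field(spec)
    return truth, render_movie(truth, spec)


def two_region_study_spec(seed: int = 0) -> WaveSpec:
    """The fixed study conditions for the two-region comparison.

    A fast isotropic region (8 μm/ms, multidirectional: full 15° wavefront
    undulation) abuts a slow anisotropic region (2 μm/ms, anisotropy ratio 3,
    hence only 5° of deviation), imaged at SNR 10 (amplitude 100, noise sd
    10).  This is the kinematic analogue of the outer-curvature /
    inner-curvature contrast the pipeline must resolve.
    """
    return WaveSpec(
        grid_shape=(64, 96),
        scenario="two_region",
        region_speeds=(8.0, 2.0),
        region_anisotropy=(1.0, 3.0),
        undulation_deg=15.0,
        undulation_period_um=50.0,
        noise_sd=10.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# morphometry fixtures


def make_heart_masks(
    target_fraction: float, shape: tuple[int, int] = (64, 64), seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Build a (reporter_mask, ventricle_mask) pair with a prescribed area fraction.

    The ventricle is a filled ellipse; the reporter territory is the connected
    blob of ventricle pixels nearest a seeded anchor point, sized so that
    |reporter| / |ventricle| matches ``target_fraction`` to within one pixel's
    worth of area.  reporter ⊆ ventricle always.
    """
    if not (0.0 <= target_fraction <= 1.0):
        raise ValueError("target_fraction must lie in [0, 1]")
    rows, cols = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    ventricle = ((rows - cy) / (0.42 * shape[0])) ** 2 + (
        (cols - cx) / (0.42 * shape[1])
    ) ** 2 <= 1.0
    n = int(ventricle.sum())
    if n == 0:
        raise ValueError("ventricle mask is empty; use a larger shape")
    k = int(round(target_fraction * n))

    rng = np.random.default_rng(seed)
    vr, vc = np.nonzero(ventricle)
    anchor = rng.integers(len(vr))
    d2 = (vr - vr[anchor]) ** 2 + (vc - vc[anchor]) ** 2
    order = np.lexsort((vc, vr, d2))  # deterministic tie-break
    reporter = np.zeros(shape, dtype=bool)
    reporter[vr[order[:k]], vc[order[:k]]] = True
    return reporter, ventricle


def make_accrual_counts(n_converted: int, n_new: int, seed: int = 0) -> pd.DataFrame:
    """Fabricate a nuclei table with the requested converted/new totals.

    Returns a shuffled DataFrame with columns ``nucleus_id`` and ``converted``
    (True for photoconverted nuclei present at the early timepoint, False for
    cardiomyocytes added afterwards).
    """
    if n_converted < 0 or n_new < 0:
        raise ValueError("counts must be non-negative")
    if n_converted + n_new == 0:
        raise ValueError("at least one nucleus is required")
    converted = np.concatenate(
        [np.ones(n_converted, dtype=bool), np.zeros(n_new, dtype=bool)]
    )
    rng = np.random.default_rng(seed)
    converted = converted[rng.permutation(len(converted))]
    return pd.DataFrame(
        {"nucleus_id": np.arange(1, len(converted) + 1), "converted": converted}
    )


# ---------------------------------------------------------------------------
# on-disk products


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    """Write the T map as float32 TIFF and the true vectors as CSV."""
    out_dir = Path(out_dir)
    tifffile.imwrite(out_dir / "truth_activation.tif", truth.activation_ms.astype(np.float32))
    X, Y = pixel_coords(truth.activation_ms.shape, truth.pixel_size_um)
    rows, cols = np.indices(truth.activation_ms.shape)
    pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "time_ms": truth.activation_ms.ravel(),
            "vx": truth.vx.ravel(),
            "vy": truth.vy.ravel(),
            "valid": truth.validity.ravel().astype(int),
        }
    ).to_csv(out_dir / "truth_velocity.csv", index=False)


def write_simulation(spec: WaveSpec, out_dir) -> dict:
    """Simulate a spec and write movie + sidecar + ground truth to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth, movie = simulate(spec)
    write_movie(movie, out_dir / "movie.tif", extra_metadata={"seed": spec.seed, "wave_spec": spec.to_dict()})
    write_ground_truth(truth, out_dir)
    return {"movie": "movie.tif", "truth_activation": "truth_activation.tif", "truth_velocity": "truth_velocity.csv"}
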