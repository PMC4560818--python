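"""Vector angles relative to the heart's principal direction, polar
histograms, circular variability, and group comparisons.

The geometric reference is a unit vector pointing from the inner curvature
of the atrium (the region that typically activates first) towards the
outflow tract (which activates last) — the principal direction of
propagation.  Velocity-vector angles are measured counterclockwise from
this unit vector, binned into 22.5°-wide intervals over [0°, 360°), and
presented as frequency polar plots whose radial coordinate is the
percentage of vectors per bin.  Regional multidirectionality is quantified
as the angle standard deviation in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("cardiomap")

DEFAULT_BIN_WIDTH_DEG = 22.5


@dataclass
class PrincipalDirection:
    """Geometric reference vector between two landmarks (physical μm)."""

    origin: np.ndarray
    target: np.ndarray
    unit_vector: np.ndarray

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.unit_vector[1], self.unit_vector[0])) % 360.0)


@dataclass
class AngleSet:
    """Angles of velocity vectors relative to the unit vector, in [0, 360)."""

    angles_deg: np.ndarray

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=float) % 360.0

    def __len__(self) -> int:
        return len(self.angles_deg)


@dataclass
class PolarHistogram:
    """Angular frequency histogram; radial coordinate is percent of vectors."""

    bin_edges_deg: np.ndarray
    freq_percent: np.ndarray
    counts: np.ndarray
    n_total: int

    @property
    def n_bins(self) -> int:
        return len(self.freq_percent)


def principal_direction(origin, target) -> PrincipalDirection:
    """Unit vector from the atrial inner-curvature landmark to the outflow tract."""
    origin = np.asarray(origin, dtype=float)
    target = np.asarray(target, dtype=float)
    delta = target - origin
    norm = float(np.linalg.norm(delta))
    if norm == 0.0:
        raise ValueError("origin and target landmarks coincide")
    return PrincipalDirection(origin, target, delta / norm)


def landmarks_from_activation(amap) -> tuple[np.ndarray, np.ndarray]:
    """Convenience landmarks: earliest- and latest-activating valid pixels.

    Returns (origin_xy, target_xy) in physical μm.  Offered as a fallback
    only; user-supplied landmarks always take precedence.
    """
    from .imaging_io import pixel_coords

    if not amap.validity.any():
        raise ValueError("activation map has no valid pixels")
    X, Y = pixel_coords(amap.shape, amap.pixel_size_um)
    t = np.where(amap.validity, amap.times_ms, np.nan)
    i0 = np.unravel_index(np.nanargmin(t), t.shape)
    i1 = np.unravel_index(np.nanargmax(t), t.shape)
    return np.array([X[i0], Y[i0]]), np.array([X[i1], Y[i1]])


def relative_angles(velocity_field, direction: PrincipalDirection) -> AngleSet:
    """CCW angles from the unit vector to each valid velocity vector."""
    sel = velocity_field.validity
    if not sel.any():
        raise ValueError("velocity field has no valid vectors")
    ang = np.degrees(np.arctan2(velocity_field.vy[sel], velocity_field.vx[sel]))
    return AngleSet((ang - direction.angle_deg) % 360.0)


def polar_histogram(angles: AngleSet, bin_width_deg: float = DEFAULT_BIN_WIDTH_DEG) -> PolarHistogram:
    """Frequency polar histogram over half-open bins [k·w, (k+1)·w).

    ``bin_width_deg`` must divide 360 evenly (the default 22.5° yields
    exactly 16 bins).  An angle exactly on an edge goes to the higher bin;
    360° wraps to 0°.  Percentages sum to 100 for any non-empty input.
    """
    a = np.asarray(angles.angles_deg if isinstance(angles, AngleSet) else angles, dtype=float)
    if a.size == 0:
        raise ValueError("empty angle set")
    n_bins_f = 360.0 / bin_width_deg
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(f"bin width {bin_width_deg} does not divide 360 evenly")
    idx = np.floor((a % 360.0) / bin_width_deg).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guards float roundoff at the top edge
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_width_deg
    return PolarHistogram(edges, 100.0 * counts / a.size, counts, int(a.size))


def circular_mean_deg(angles_deg) -> float:
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360.0)


def angle_variability(angles, method: str = "circular") -> float:
    """Angle standard deviation in degrees.

    ``circular`` (default): with R the mean resultant length of the unit
    vectors at the angles, s.d. = sqrt(−2 ln R) converted to degrees — the
    standard dispersion measure for wrapped data, equal to the arithmetic
    s.d. in the small-dispersion limit.  R = 0 (perfectly balanced angles)
    has no defined s.d. and returns NaN.

    ``arithmetic``: sample s.d. of the deviations from the circular mean,
    wrapped to (−180, 180] — provided for sensitivity analysis.
    """
    a = np.asarray(angles.angles_deg if isinstance(angles, AngleSet) else angles, dtype=float)
    if a.size < 2:
        raise ValueError("angle variability requires at least 2 angles")
    if method == "circular":
        rad = np.deg2rad(a)
        mu = np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))
        # resultant length via deviations from the circular mean: identical to
        # |mean(exp(iθ))| but exact (R = 1) for zero-dispersion input
        R = float(np.mean(np.cos(rad - mu)))
        if R <= 1e-12:
            logger.warning("angle_variability: zero resultant length, s.d. undefined")
            return float("nan")
        R = min(R, 1.0)
        return float(np.degrees(np.sqrt(max(-2.0 * np.log(R), 0.0))))
    if method == "arithmetic":
        mu = circular_mean_deg(a)
        dev = (a - mu + 180.0) % 360.0 - 180.0
        return float(np.std(dev, ddof=1))
    raise ValueError(f"unknown method {method!r}; use 'circular' or 'arithmetic'")


def compare_groups(groups: dict[str, np.ndarray], test: str = "auto") -> pd.DataFrame:
    """Two-tailed unpaired t-test (2 groups) or one-way ANOVA + Tukey HSD (>2).

    Returns a tidy table with one row per test/pairwise comparison:
    columns ``test``, ``comparison``, ``statistic``, ``p_value``,
    ``degenerate`` (True when the pooled within-group variance is zero, in
    which case the p-value is not meaningful).
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    if test == "auto":
        test = "t_test" if len(arrays) == 2 else "anova_tukey"

    pooled_var = float(np.mean([np.var(a, ddof=1) for a in arrays]))
    degenerate = pooled_var == 0.0
    rows = []
    if test == "t_test":
        if len(arrays) != 2:
            raise ValueError("t_test requires exactly 2 groups")
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=True)
        if degenerate and np.allclose(arrays[0].mean(), arrays[1].mean()):
            stat, p = 0.0, 1.0  # identical constant groups: no effect
        rows.append(
            {
                "test": "t_test",
                "comparison": f"{names[0]} vs {names[1]}",
                "statistic": float(stat),
                "p_value": float(p),
                "degenerate": degenerate,
            }
        )
    elif test == "anova_tukey":
        stat, p = stats.f_oneway(*arrays)
        rows.append(
            {
                "test": "anova",
                "comparison": " vs ".join(names),
                "statistic": float(stat),
                "p_value": float(p),
                "degenerate": degenerate,
            }
        )
        if len(arrays) > 2 and not degenerate:
            from itertools import combinations

            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            values = np.concatenate(arrays)
            labels = np.concatenate([[k] * len(groups[k]) for k in names])
            res = pairwise_tukeyhsd(values, labels)
            pairs = list(combinations(res.groupsunique, 2))
            for (g1, g2), meandiff, p_adj in zip(pairs, res.meandiffs, res.pvalues):
                rows.append(
                    {
                        "test": "tukey",
                        "comparison": f"{g1} vs {g2}",
                        "statistic": float(meandiff),
                        "p_value": float(p_adj),
                        "degenerate": False,
                    }
                )
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame(rows)
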