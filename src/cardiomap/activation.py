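"""Local activation-time maps from normalized voltage-dye movies.

The local activation time of a pixel is the time at which its action
potential first reaches 50% of its amplitude during the depolarization
phase.  On the normalized (min 0, max 1) trace this is the first upward
crossing of 0.5 that belongs to a contiguous rising segment running from
below a lower gate (default 0.25) to above an upper gate (default 0.75);
the gates reject isolated noise blips that graze the half-amplitude level.
The crossing time is linearly interpolated between the bracketing frames,
with frame 0 at time 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .imaging_io import NormalizedMovie, pixel_coords

logger = logging.getLogger("cardiomap")


@dataclass
class ActivationMap:
    """Per-pixel local activation times T(x, y) in ms plus a validity mask.

    Invalid pixels (no qualifying upstroke, masked out, or insufficient
    dynamic range upstream) carry NaN in ``times_ms``.
    """

    times_ms: np.ndarray
    validity: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.times_ms.shape


def detect_activation_time(
    trace: np.ndarray,
    frame_rate_hz: float,
    low_gate: float = 0.25,
    high_gate: float = 0.75,
    level: float = 0.5,
) -> float:
    """Time (ms) of the first qualifying 50%-amplitude upward crossing.

    A crossing of ``level`` between frames i and i+1 qualifies if, walking
    backward from i, the trace drops below ``low_gate`` before ever exceeding
    ``high_gate``, and, walking forward from i+1, it rises above ``high_gate``
    before ever dropping below ``low_gate`` — i.e. the crossing sits inside
    one contiguous depolarization upstroke.  Returns NaN when no crossing
    qualifies (the pixel is reported invalid, never an exception).
    """
    t = np.asarray(trace, dtype=float)
    if t.size < 2 or not np.all(np.isfinite(t)):
        return float("nan")
    candidates = np.nonzero((t[:-1] < level) & (t[1:] >= level))[0]
    for i in candidates:
        ok = False
        for j in range(i, -1, -1):
            if t[j] > high_gate:
                break
            if t[j] < low_gate:
                ok = True
                break
        if not ok:
            continue
        ok = False
        for j in range(i + 1, t.size):
            if t[j] < low_gate:
                break
            if t[j] > high_gate:
                ok = True
                break
        if not ok:
            continue
        frac = (level - t[i]) / (t[i + 1] - t[i])
        return float((i + frac) / frame_rate_hz * 1e3)
    return float("nan")


def activation_map(
    movie: NormalizedMovie, low_gate: float = 0.25, high_gate: float = 0.75
) -> ActivationMap:
    """Apply the 50%-amplitude criterion to every valid pixel of a movie."""
    shape = movie.frame_shape
    times = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for r, c in zip(*np.nonzero(movie.validity)):
        t = detect_activation_time(movie.frames[:, r, c], movie.frame_rate_hz, low_gate, high_gate)
        if np.isfinite(t):
            times[r, c] = t
            valid[r, c] = True
    if not valid.any():
        logger.warning("activation_map: no pixel produced a qualifying upstroke")
    return ActivationMap(times, valid, movie.frame_rate_hz, movie.pixel_size_um)


def write_activation_map(amap: ActivationMap, tif_path, csv_path) -> None:
    """Export as 32-bit float TIFF (NaN at invalid pixels) and a tidy CSV."""
    tifffile.imwrite(Path(tif_path), amap.times_ms.astype(np.float32))
    X, Y = pixel_coords(amap.shape, amap.pixel_size_um)
    rr, cc = np.nonzero(amap.validity)
    pd.DataFrame(
        {
            "row": rr,
            "col": cc,
            "x_um": X[rr, cc],
            "y_um": Y[rr, cc],
            "time_ms": amap.times_ms[rr, cc],
        }
    ).to_csv(Path(csv_path), index=False)


def load_activation_map(tif_path, frame_rate_hz: float, pixel_size_um: float) -> ActivationMap:
    times = np.asarray(tifffile.imread(Path(tif_path)), dtype=float)
    return ActivationMap(times, np.isfinite(times), frame_rate_hz, pixel_size_um)
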