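"""Movie and mask I/O, trace normalization, and coordinate conventions.

All frame arrays are indexed ``[frame, row, col]``.  Physical coordinates use
a y-up frame: ``x = col * pixel_size`` increases rightward and
``y = (n_rows - 1 - row) * pixel_size`` increases upward, so vector angles are
standard counterclockwise degrees.

Voltage-sensitive dyes such as di-8-ANEPPS *decrease* in fluorescence on
depolarization; :func:`normalize_pixels` applies the polarity convention so
every downstream stage sees depolarization-positive traces in [0, 1].
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("cardiomap")

POLARITIES = ("negative", "positive")

#: Ranges at or below this raw-intensity value are treated as zero amplitude.
_RANGE_EPS = 1e-12


def pixel_coords(shape: tuple[int, int], pixel_size_um: float):
    """Return (X, Y) physical coordinate arrays in μm for a pixel grid.

    X increases with column; Y increases upward (decreasing row).
    """
    rows, cols = np.indices(shape)
    x = cols * pixel_size_um
    y = (shape[0] - 1 - rows) * pixel_size_um
    return x.astype(float), y.astype(float)


@dataclass
class FluorescenceMovie:
    """Time-ordered fluorescence frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (T, R, C)
        Pixel intensities in arbitrary units, acquisition order.
    frame_rate_hz : float
        Acquisition rate in frames per second.
    pixel_size_um : float
        Physical pixel size in μm.
    polarity : {"negative", "positive"}
        "negative" means fluorescence decreases on depolarization
        (di-8-ANEPPS convention).
    mask : ndarray of bool, optional
        Tissue/ROI mask; pixels outside are excluded downstream.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    polarity: str = "negative"
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (T, R, C), got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("movie must contain at least 2 frames")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}, got {self.polarity!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise ValueError("mask shape must equal frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_ms(self) -> float:
        return (self.n_frames - 1) / self.frame_rate_hz * 1e3

    def times_ms(self) -> np.ndarray:
        """Frame timestamps in ms; frame 0 is time 0."""
        return np.arange(self.n_frames) / self.frame_rate_hz * 1e3


@dataclass
class NormalizedMovie:
    """Per-pixel min–max normalized, depolarization-positive movie.

    At valid pixels each trace spans exactly [0, 1]; pixels with insufficient
    dynamic range (or outside the mask) are flagged in ``validity`` and their
    traces are NaN — never silently zeroed.
    """

    frames: np.ndarray
    validity: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: FluorescenceMovie, path, extra_metadata: dict | None = None) -> Path:
    """Write a movie as a multi-page grayscale float32 TIFF plus JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_size_um": movie.pixel_size_um,
        "polarity": movie.polarity,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def load_movie(
    path,
    frame_rate_hz: float | None = None,
    pixel_size_um: float | None = None,
    polarity: str | None = None,
) -> FluorescenceMovie:
    """Load a multi-page grayscale TIFF movie.

    A JSON sidecar (same stem, ``.json`` suffix) written by :func:`write_movie`
    overrides the keyword metadata when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # inconsistent page shapes land here
        raise ValueError(f"could not read {path} as a TIFF stack: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError("movie must have at least 2 frames (got a single page)")
    if frames.ndim != 3:
        raise ValueError(f"expected grayscale pages (T, R, C); got shape {frames.shape}")

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frame_rate_hz = meta.get("frame_rate_hz", frame_rate_hz)
        pixel_size_um = meta.get("pixel_size_um", pixel_size_um)
        polarity = meta.get("polarity", polarity)
    if frame_rate_hz is None or pixel_size_um is None or polarity is None:
        raise ValueError(
            "frame_rate_hz, pixel_size_um and polarity must be supplied "
            "(no sidecar metadata found)"
        )
    return FluorescenceMovie(frames, frame_rate_hz, pixel_size_um, polarity)


def write_mask(mask: np.ndarray, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool).astype(np.uint8) * 255))
    return path


def load_mask(path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path))) > 0


def robust_noise_sd(movie: FluorescenceMovie) -> float:
    """Robust per-movie noise estimate in raw intensity units.

    Uses the median absolute deviation of the per-pixel first temporal
    difference, scaled to be consistent with a Gaussian sd (the difference of
    two independent samples has sd σ√2), then takes the median over pixels.
    """
    d = np.diff(movie.frames, axis=0)
    mad = np.median(np.abs(d - np.median(d, axis=0)), axis=0)
    per_pixel_sd = 1.4826 * mad / np.sqrt(2.0)
    return float(np.median(per_pixel_sd))


def normalize_pixels(movie: FluorescenceMovie, min_range: float | None = None) -> NormalizedMovie:
    """Rescale each pixel trace to [0, 1], depolarization-positive.

    Negative-polarity traces are sign-flipped first.  Pixels whose raw
    intensity range falls below ``min_range`` (default: 5× the robust noise
    estimate from :func:`robust_noise_sd`) are flagged invalid; constant
    traces are always invalid.
    """
    if min_range is None:
        min_range = 5.0 * robust_noise_sd(movie)
    signed = -movie.frames if movie.polarity == "negative" else movie.frames
    lo = signed.min(axis=0)
    hi = signed.max(axis=0)
    rng = hi - lo
    valid = (rng >= min_range) & (rng > _RANGE_EPS)
    if movie.mask is not None:
        valid &= movie.mask
    with np.errstate(invalid="ignore", divide="ignore"):
        frames = (signed - lo[None]) / rng[None]
    frames[:, ~valid] = np.nan
    if not valid.any():
        logger.warning("normalize_pixels: no valid pixels (all below min_range or masked)")
    return NormalizedMovie(frames, valid, movie.frame_rate_hz, movie.pixel_size_um)


def smooth_temporal(movie: FluorescenceMovie, width: int) -> FluorescenceMovie:
    """Optional odd-width moving-average temporal filter (off by default)."""
    if width % 2 != 1 or width < 1:
        raise ValueError("filter width must be a positive odd integer")
    if width == 1:
        return movie
    from scipy.ndimage import uniform_filter1d

    frames = uniform_filter1d(movie.frames, size=width, axis=0, mode="nearest")
    return dataclasses.replace(movie, frames=frames)


def apply_mask(obj, mask: np.ndarray):
    """Restrict a movie or map to a binary mask.

    Works on any object carrying either a ``mask`` attribute
    (:class:`FluorescenceMovie`) or a ``validity`` array (normalized movies,
    activation maps, velocity fields); returns a copy with the mask folded in.
    """
    mask = np.asarray(mask, dtype=bool)
    if isinstance(obj, FluorescenceMovie):
        if mask.shape != obj.frame_shape:
            raise ValueError("mask shape must equal frame shape")
        combined = mask if obj.mask is None else (mask & obj.mask)
        if not combined.any():
            logger.warning("apply_mask: mask excludes every pixel")
        return dataclasses.replace(obj, mask=combined)
    if hasattr(obj, "validity"):
        if mask.shape != obj.validity.shape:
            raise ValueError("mask shape must equal frame shape")
        new = dataclasses.replace(obj, validity=obj.validity & mask)
        if not new.validity.any():
            logger.warning("apply_mask: mask excludes every valid pixel")
        return new
    raise TypeError(f"cannot apply mask to {type(obj).__name__}")
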