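"""Heart-field morphometry: reporter-area fractions and photoconversion accrual.

Two readouts of how the first (FHF) and second (SHF) heart fields partition
the embryonic ventricle:

* the fraction of the ventricular area (myosin-positive mask) covered by a
  FHF reporter (e.g. drl:EGFP) — :func:`fhf_fraction`;
* the percentage of cardiomyocytes newly added to the ventricle after
  photoconversion of a nuclear KikGR reporter, counted from nuclei labelled
  converted (present at the early timepoint) versus non-converted (added
  later) — :func:`accrual_percentage`.

Segmentation of the raw confocal data into binary masks and nuclei tables is
upstream of this module; masks and count tables are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import compare_groups  # group stats (t-test / ANOVA+Tukey) reused

__all__ = [
    "MaskPair",
    "AccrualCounts",
    "fhf_fraction",
    "mask_diagnostics",
    "accrual_percentage",
    "counts_from_table",
    "compare_groups",
]


@dataclass
class MaskPair:
    """Reporter-positive and ventricle (myosin-positive) binary masks."""

    reporter: np.ndarray
    ventricle: np.ndarray

    def __post_init__(self):
        self.reporter = np.asarray(self.reporter, dtype=bool)
        self.ventricle = np.asarray(self.ventricle, dtype=bool)
        if self.reporter.shape != self.ventricle.shape:
            raise ValueError("reporter and ventricle masks must have the same shape")
        if not self.ventricle.any():
            raise ValueError("ventricle mask is empty")


@dataclass
class AccrualCounts:
    """Nuclei counts: photoconverted vs newly added (non-converted)."""

    n_converted: int
    n_new: int

    def __post_init__(self):
        if self.n_converted < 0 or self.n_new < 0:
            raise ValueError("counts must be non-negative")
        if self.n_converted + self.n_new == 0:
            raise ValueError("at least one nucleus is required")


def fhf_fraction(masks: MaskPair) -> float:
    """Reporter-labelled fraction of the ventricular area, in [0, 1].

    Counts |reporter ∩ ventricle| / |ventricle|; reporter pixels outside the
    ventricle do not enter the fraction (see :func:`mask_diagnostics`).
    """
    inside = int(np.count_nonzero(masks.reporter & masks.ventricle))
    return inside / int(np.count_nonzero(masks.ventricle))


def mask_diagnostics(masks: MaskPair, pixel_size_um: float = 1.0) -> dict:
    """Pixel counts, areas (pixel count × pixel_size²) and the fraction."""
    n_v = int(np.count_nonzero(masks.ventricle))
    n_in = int(np.count_nonzero(masks.reporter & masks.ventricle))
    n_out = int(np.count_nonzero(masks.reporter & ~masks.ventricle))
    return {
        "n_ventricle": n_v,
        "n_reporter_inside": n_in,
        "n_reporter_outside": n_out,
        "ventricle_area_um2": n_v * pixel_size_um**2,
        "reporter_area_um2": n_in * pixel_size_um**2,
        "fraction": n_in / n_v,
    }


def accrual_percentage(counts: AccrualCounts) -> float:
    """Percentage of newly added cardiomyocytes: 100 · n_new / (n_new + n_converted)."""
    return 100.0 * counts.n_new / (counts.n_new + counts.n_converted)


def counts_from_table(table: pd.DataFrame) -> AccrualCounts:
    """Build counts from a nuclei table with a boolean/0-1 ``converted`` column."""
    if "converted" not in table.columns:
        raise ValueError("nuclei table must have a 'converted' column")
    conv = table["converted"].astype(bool)
    return AccrualCounts(int(conv.sum()), int((~conv).sum()))
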