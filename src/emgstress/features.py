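"""The 17 statistical time features (STFs) of a signal window.

These are the classic time-domain descriptors of the vibration-analysis
literature, applied to (normalized) EMG windows: location (mode, mean,
median), spread (range, variance, standard deviation), amplitude statistics
(RMS, square-mean-root) and their dimensionless shape/peak ratios (shape,
crest, impulse and latitude factors), plus RMS-normalized central moments of
orders 3–6 (skewness, kurtosis, 5th and 6th moments).

Conventions (all deliberate, see the methods note):

* every averaged quantity uses the population 1/N convention;
* range is max - min (non-negative);
* the peak value in crest/impulse/latitude factors is ``max |x|``;
* the square-mean-root averages the square roots of |x| (normalized EMG has
  negative samples);
* the central moments of order 3-6 are normalized by powers of the RMS, not
  of the standard deviation — skewness here equals the conventional moment
  skewness times (std/rms)^3, and so on for higher orders;
* the grouped (binned) mode interpolates within the modal histogram class:
  ``mode = L + c * d_minus / (d_minus + d_plus)`` with d_minus/d_plus the
  absolute count differences to the left/right neighbour classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Segment

#: Column order of the feature table (fixed; selection tie-breaks rely on it).
FEATURE_NAMES = (
    "mode",
    "mean",
    "range",
    "variance",
    "std",
    "impulse_factor",
    "smr",
    "sf_smr",
    "rms",
    "sf_rms",
    "crest_factor",
    "latitude_factor",
    "skewness",
    "kurtosis",
    "moment5",
    "moment6",
    "median",
)

META_COLUMNS = ("subject_id", "segment_index", "scenario", "label")


class FeatureError(ValueError):
    """Raised when a window is degenerate (e.g. all-zero: RMS = 0)."""


@dataclass(frozen=True)
class ModeBinning:
    """Histogram policy for the grouped mode.

    The default bin count is Sturges' rule, ceil(1 + log2 N), over
    [min, max]; ties between modal classes break to the leftmost.
    """

    bin_count: int | None = None

    def bins_for(self, n: int) -> int:
        if self.bin_count is not None:
            if self.bin_count < 1:
                raise ValueError("bin_count must be >= 1")
            return self.bin_count
        return max(int(math.ceil(1.0 + math.log2(n))), 1)


def grouped_mode(x: Sequence[float] | np.ndarray, binning: ModeBinning = ModeBinning()) -> float:
    """Grouped (binned) mode with within-class interpolation.

    mode = L + c * d-/(d- + d+), where L is the lower limit and c the width
    of the modal class and d-/d+ are the absolute count differences to the
    left/right neighbour classes (a missing neighbour counts 0). When both
    differences vanish the modal-class midpoint is returned; a constant
    sample degenerates to that constant.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return lo
    nbins = binning.bins_for(x.size)
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    i = int(np.argmax(counts))  # argmax takes the leftmost maximal class
    left = counts[i - 1] if i > 0 else 0
    right = counts[i + 1] if i < nbins - 1 else 0
    d_minus = abs(float(counts[i]) - float(left))
    d_plus = abs(float(counts[i]) - float(right))
    L = float(edges[i])
    c = float(edges[i + 1] - edges[i])
    if d_minus + d_plus == 0.0:
        return L + c / 2.0
    return L + c * d_minus / (d_minus + d_plus)


def extract_stf(
    seg: Segment | Sequence[float] | np.ndarray,
    binning: ModeBinning = ModeBinning(),
) -> dict[str, float]:
    """Compute the 17 STFs of a window; returns {feature name: value}.

    Accepts a Segment or a bare sample array. Raises FeatureError for
    all-zero windows, where the RMS- and SMR-normalized ratios are undefined.
    """
    x = seg.samples if isinstance(seg, Segment) else np.asarray(seg, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")

    mean = float(np.mean(x))
    centered = x - mean
    variance = float(np.mean(centered**2))
    std = math.sqrt(variance)
    rms = float(np.sqrt(np.mean(x**2)))
    abs_mean = float(np.mean(np.abs(x)))
    smr = float(np.mean(np.sqrt(np.abs(x)))) ** 2
    peak = float(np.max(np.abs(x)))

    if rms == 0.0 or smr == 0.0 or abs_mean == 0.0:
        raise FeatureError(
            "all-zero window: RMS/SMR-normalized features are undefined"
        )

    return {
        "mode": grouped_mode(x, binning),
        "mean": mean,
        "range": float(np.max(x) - np.min(x)),
        "variance": variance,
        "std": std,
        "impulse_factor": peak / abs_mean,
        "smr": smr,
        "sf_smr": smr / abs_mean,
        "rms": rms,
        "sf_rms": rms / abs_mean,
        "crest_factor": peak / rms,
        "latitude_factor": peak / smr,
        "skewness": float(np.mean(centered**3)) / rms**3,
        "kurtosis": float(np.mean(centered**4)) / rms**4,
        "moment5": float(np.mean(centered**5)) / rms**5,
        "moment6": float(np.mean(centered**6)) / rms**6,
        "median": float(np.median(x)),
    }


def build_feature_table(
    segments: Iterable[Segment],
    binning: ModeBinning = ModeBinning(),
) -> pd.DataFrame:
    """One row per segment: subject/scenario/label metadata + the 17 STFs."""
    segments = list(segments)
    if not segments:
        raise ValueError("need at least one segment")
    per_subject_index: dict[str, int] = {}
    rows = []
    for seg in segments:
        idx = per_subject_index.get(seg.subject_id, 0)
        per_subject_index[seg.subject_id] = idx + 1
        row: dict[str, object] = {
            "subject_id": seg.subject_id,
            "segment_index": idx,
            "scenario": seg.scenario,
            "label": seg.label,
        }
        row.update(extract_stf(seg, binning))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in list(META_COLUMNS) + list(FEATURE_NAMES) if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing feature-table columns {missing}")
    return table
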