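"""Rest-baseline z-normalization of EMG segments.

Raw EMG amplitudes are not comparable across subjects, so every segment of
a subject is rescaled with that subject's rest-period statistics:
``x_norm = (x - mu) / sigma`` with mu the rest mean and sigma the rest
population (1/N) standard deviation. After this, the rest segment has mean 0
and std 1 exactly, while stress segments keep a variance proportional to
their raw variance ratio against rest — which is exactly the quantity the
feature-selection step finds discriminative.

``mode="self"`` (each segment normalized by its own statistics) is also
available; note it forces unit variance on every segment and thereby erases
the variance/std contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

import numpy as np

from .io import Segment

NormalizationMode = Literal["rest_baseline", "self"]


@dataclass(frozen=True)
class NormalizationParams:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def segment_stats(seg: Segment) -> NormalizationParams:
    """Mean and population (1/N) standard deviation of a segment."""
    x = seg.samples
    if x.size < 2:
        raise ValueError("need at least 2 samples to estimate a baseline")
    sigma = float(np.std(x))  # population convention, ddof=0
    if sigma == 0.0:
        raise ValueError("constant segment: zero-variance baseline")
    return NormalizationParams(mu=float(np.mean(x)), sigma=sigma)


def baseline_stats(rest_segment: Segment) -> NormalizationParams:
    """Normalization parameters from a subject's rest (no-stress) segment."""
    if rest_segment.scenario != "rest":
        raise ValueError(
            f"baseline must come from the rest period, got {rest_segment.scenario!r}"
        )
    return segment_stats(rest_segment)


def normalize(seg: Segment, params: NormalizationParams) -> Segment:
    """Replace every sample x by (x - mu) / sigma; metadata preserved."""
    return replace(seg, samples=(seg.samples - params.mu) / params.sigma)


def normalize_segments(
    segments: Iterable[Segment],
    mode: NormalizationMode = "rest_baseline",
) -> list[Segment]:
    """Normalize a cohort's segments, per subject.

    rest_baseline: all of a subject's segments share that subject's rest
    statistics. self: each segment is normalized by its own statistics.
    """
    segments = list(segments)
    if mode == "self":
        return [normalize(s, segment_stats(s)) for s in segments]
    if mode != "rest_baseline":
        raise ValueError(f"unknown normalization mode {mode!r}")
    params: dict[str, NormalizationParams] = {}
    for seg in segments:
        if seg.scenario == "rest":
            if seg.subject_id in params:
                raise ValueError(
                    f"subject {seg.subject_id}: multiple rest segments"
                )
            params[seg.subject_id] = baseline_stats(seg)
    out = []
    for seg in segments:
        if seg.subject_id not in params:
            raise ValueError(f"subject {seg.subject_id}: no rest segment to use as baseline")
        out.append(normalize(seg, params[seg.subject_id]))
    return out
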