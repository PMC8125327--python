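"""Recording / annotation I/O, segmentation, and window truncation.

A :class:`Recording` is one subject's single-channel surface-EMG amplitude
series. The driving protocol annotates it with scenario intervals (rest,
city, highway); segmentation cuts one fixed-length window from the start of
each interval and assigns the binary stress label: rest is the no-stress
condition (NSC), city and highway are stress conditions (SC).

File formats are deliberately plain text:

* recording CSV — comment header ``# subject_id=<id> fs=<Hz>``, then an
  ``amplitude`` column, one sample per line;
* annotation CSV — columns ``scenario,start_s,end_s`` with 0-based,
  half-open ``[start_s, end_s)`` intervals in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

SCENARIOS = ("rest", "city", "highway")
NSC = "NSC"
SC = "SC"

DEFAULT_FS = 15.5  # Hz; effective EMG sampling rate of the drivedb recordings


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent scenario annotations."""


@dataclass(frozen=True)
class Recording:
    """Single-subject raw EMG amplitude series."""

    subject_id: str
    fs: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class ScenarioAnnotation:
    """Ordered, non-overlapping scenario intervals over a recording."""

    intervals: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        ivals = tuple((str(s), float(a), float(b)) for s, a, b in self.intervals)
        prev_end = -math.inf
        for scenario, start_s, end_s in ivals:
            if scenario not in SCENARIOS:
                raise AnnotationError(f"unknown scenario {scenario!r}")
            if end_s <= start_s:
                raise AnnotationError(
                    f"interval {scenario} has end_s={end_s} <= start_s={start_s}"
                )
            if start_s < prev_end:
                raise AnnotationError("intervals overlap or are out of order")
            prev_end = end_s
        object.__setattr__(self, "intervals", ivals)

    def count(self, scenario: str) -> int:
        return sum(1 for s, _, _ in self.intervals if s == scenario)


@dataclass(frozen=True)
class Segment:
    """One fixed-length scenario window with its binary stress label."""

    subject_id: str
    scenario: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def label(self) -> str:
        # rest is the no-stress condition; city and highway are stress conditions
        return NSC if self.scenario == "rest" else SC

    @property
    def duration_min(self) -> float:
        return self.samples.size / self.fs / 60.0


def n_samples(minutes: float, fs: float) -> int:
    """Window length in samples: round-half-up of minutes*60*fs."""
    return int(math.floor(minutes * 60.0 * fs + 0.5))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# subject_id={rec.subject_id} fs={rec.fs!r}\n")
        fh.write("amplitude\n")
        np.savetxt(fh, rec.samples, fmt="%.12g")


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# subject_id=... fs=...' header")
        fields = dict(
            item.split("=", 1) for item in header.lstrip("# ").split() if "=" in item
        )
        try:
            subject_id = fields["subject_id"]
            fs = float(fields["fs"])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}: malformed header {header!r}") from exc
        column = fh.readline().strip()
        if column != "amplitude":
            raise ValueError(f"{path}: expected 'amplitude' column, got {column!r}")
        try:
            samples = np.loadtxt(fh, dtype=float, ndmin=1)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric amplitude value") from exc
    return Recording(subject_id=subject_id, fs=fs, samples=samples)


def write_annotations(ann: ScenarioAnnotation, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("scenario,start_s,end_s\n")
        for scenario, start_s, end_s in ann.intervals:
            fh.write(f"{scenario},{start_s!r},{end_s!r}\n")


def read_annotations(path: str | Path) -> ScenarioAnnotation:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if header != "scenario,start_s,end_s":
            raise ValueError(f"{path}: unexpected annotation header {header!r}")
        intervals = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            scenario, start_s, end_s = line.split(",")
            intervals.append((scenario, float(start_s), float(end_s)))
    return ScenarioAnnotation(intervals=tuple(intervals))


def read_wfdb_recording(record_path: str | Path, channel: str = "EMG") -> Recording:
    """Optionally read a Physionet drivedb waveform record.

    Requires the ``wfdb`` package (``pip install wfdb``); it is not a core
    dependency because the pipeline is fully exercisable on synthetic cohorts.
    """
    try:
        import wfdb  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading Physionet waveform records requires the optional 'wfdb' "
            "package; install it with `pip install wfdb`"
        ) from exc
    record_path = str(record_path)
    record = wfdb.rdrecord(record_path)  # pragma: no cover - optional dependency
    names = list(record.sig_name)  # pragma: no cover
    if channel not in names:  # pragma: no cover
        raise ValueError(f"channel {channel!r} not in {names}")
    idx = names.index(channel)  # pragma: no cover
    return Recording(  # pragma: no cover
        subject_id=Path(record_path).name,
        fs=float(record.fs),
        samples=np.asarray(record.p_signal[:, idx], dtype=float),
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def extract_segments(
    rec: Recording,
    ann: ScenarioAnnotation,
    window_minutes: float = 5.0,
) -> list[Segment]:
    """Cut one ``window_minutes`` window from the start of each scenario interval.

    The default protocol has exactly five intervals (1 rest + 2 city +
    2 highway), so each recording yields five segments: one NSC and four SC.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    counts = {s: ann.count(s) for s in SCENARIOS}
    if counts != {"rest": 1, "city": 2, "highway": 2}:
        raise AnnotationError(
            f"expected 1 rest + 2 city + 2 highway intervals, got {counts}"
        )
    n_win = n_samples(window_minutes, rec.fs)
    segments: list[Segment] = []
    for scenario, start_s, end_s in ann.intervals:
        if (end_s - start_s) / 60.0 < window_minutes - 1e-9:
            raise AnnotationError(
                f"{scenario} interval [{start_s}, {end_s}) is shorter than "
                f"the {window_minutes}-min window"
            )
        start = n_samples(start_s / 60.0, rec.fs)
        if start + n_win > rec.samples.size:
            raise AnnotationError(
                f"{scenario} interval extends past the end of the recording"
            )
        segments.append(
            Segment(
                subject_id=rec.subject_id,
                scenario=scenario,
                samples=rec.samples[start : start + n_win].copy(),
                fs=rec.fs,
            )
        )
    return segments


def truncate_segment(seg: Segment, window_minutes: float) -> Segment:
    """Keep the first ``window_minutes`` of a segment (metadata preserved)."""
    n_win = n_samples(window_minutes, seg.fs)
    if n_win > seg.samples.size:
        raise ValueError(
            f"cannot truncate to {window_minutes} min: segment holds only "
            f"{seg.duration_min:.3f} min"
        )
    return replace(seg, samples=seg.samples[:n_win].copy())
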