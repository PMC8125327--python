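"""End-to-end study orchestration.

Pipeline: cohort (synthetic or from disk) -> scenario segmentation ->
rest-baseline normalization -> 17 statistical time features -> Kruskal-Wallis
ranking and selection -> kernel-SVM cross-validation over a window-length
grid, plus an SVM-vs-MLP comparison. Produces three tables: the per-feature
p-values, the kernels x window-lengths accuracy matrix, and the classifier
comparison (accuracy, AUC).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify, features, io, preprocess, selection, synthetic

log = logging.getLogger("emgstress")


@dataclass(frozen=True)
class StudyConfig:
    # cohort source: either a directory of recording/annotation CSVs ...
    cohort_dir: str | None = None
    # ... or the synthetic generator
    n_subjects: int = 10
    variance_multiplier_city: float = 2.0
    variance_multiplier_highway: float = 3.0
    burst_rate: float = 0.5
    burst_amplitude_gain: float = 2.0
    fs: float = io.DEFAULT_FS
    # analysis
    window_lengths: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    kernels: tuple[str, ...] = classify.KERNEL_NAMES
    normalization: str = "rest_baseline"
    alpha: float = 0.01
    top_k: int = 2
    exclude: tuple[str, ...] = ("median", "smr")
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.window_lengths or any(
            not (0 < L <= 5) for L in self.window_lengths
        ):
            raise ValueError("window lengths must lie in (0, 5] minutes")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        unknown = set(self.kernels) - set(classify.KERNEL_NAMES)
        if unknown:
            raise ValueError(f"unknown kernels {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("window_lengths", "kernels", "exclude"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class StudyReport:
    pvalues: pd.DataFrame  # feature, H, p_value (ascending p)
    accuracy_matrix: pd.DataFrame  # rows kernels, columns window lengths, %
    comparison: pd.DataFrame  # SVM (best kernel) vs MLP: accuracy %, AUC
    selected: tuple[str, ...]
    best_kernel: str
    best_report: classify.CVReport  # best kernel at the longest window
    config: StudyConfig

    def equals(self, other: "StudyReport") -> bool:
        return (
            self.pvalues.equals(other.pvalues)
            and self.accuracy_matrix.equals(other.accuracy_matrix)
            and self.comparison.equals(other.comparison)
            and self.selected == other.selected
            and self.best_kernel == other.best_kernel
        )


def load_cohort(directory: str | Path) -> list[tuple[io.Recording, io.ScenarioAnnotation]]:
    """Read every ``<stem>.csv`` / ``<stem>.annotations.csv`` pair in a directory."""
    directory = Path(directory)
    cohort = []
    for rec_path in sorted(directory.glob("*.csv")):
        if rec_path.name.endswith(".annotations.csv"):
            continue
        ann_path = rec_path.parent / (rec_path.stem + ".annotations.csv")
        if not ann_path.exists():
            raise FileNotFoundError(f"missing annotations for {rec_path}")
        cohort.append((io.read_recording(rec_path), io.read_annotations(ann_path)))
    if not cohort:
        raise FileNotFoundError(f"no recordings found in {directory}")
    return cohort


def save_cohort(
    cohort: Sequence[tuple[io.Recording, io.ScenarioAnnotation]],
    directory: str | Path,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec, ann in cohort:
        io.write_recording(rec, directory / f"{rec.subject_id}.csv")
        io.write_annotations(ann, directory / f"{rec.subject_id}.annotations.csv")


def _synthetic_cohort(cfg: StudyConfig):
    model = synthetic.StressModel(
        variance_multiplier_city=cfg.variance_multiplier_city,
        variance_multiplier_highway=cfg.variance_multiplier_highway,
        burst_amplitude_gain=cfg.burst_amplitude_gain,
    )
    return synthetic.generate_cohort(
        n_subjects=cfg.n_subjects,
        model=model,
        seed=cfg.seed,
        fs=cfg.fs,
        burst_rate=cfg.burst_rate,
    )


def feature_table_for_length(
    cohort: Sequence[tuple[io.Recording, io.ScenarioAnnotation]],
    window_minutes: float,
    normalization: str = "rest_baseline",
) -> pd.DataFrame:
    """Segment at 5 min, truncate to the target length, normalize, extract.

    The normalization baseline is recomputed from the truncated rest segment,
    so the rest window has exactly unit variance at every study length.
    """
    segments = []
    for rec, ann in cohort:
        for seg in io.extract_segments(rec, ann, window_minutes=5.0):
            segments.append(io.truncate_segment(seg, window_minutes))
    normalized = preprocess.normalize_segments(segments, mode=normalization)  # type: ignore[arg-type]
    return features.build_feature_table(normalized)


def _xy(table: pd.DataFrame, selected: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(selected)].to_numpy(dtype=float)
    y = (table["label"] == io.SC).to_numpy(dtype=int)
    return X, y


def run_study(cfg: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the full study; optionally persist all intermediate artifacts."""
    t0 = time.perf_counter()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if cfg.cohort_dir is not None:
        cohort = load_cohort(cfg.cohort_dir)
    else:
        cohort = _synthetic_cohort(cfg)
        if out is not None:
            save_cohort(cohort, out / "cohort")
    log.info("cohort ready: %d recordings (%.2fs)", len(cohort), time.perf_counter() - t0)

    tables = {
        L: feature_table_for_length(cohort, L, cfg.normalization)
        for L in cfg.window_lengths
    }
    if out is not None:
        for L, table in tables.items():
            features.write_feature_table(table, out / f"features_{L:g}min.csv")
    log.info("feature tables built (%.2fs)", time.perf_counter() - t0)

    # select once, on the longest window studied
    L_max = max(cfg.window_lengths)
    ranked = selection.rank_features(tables[L_max], grouping="two_class")
    sel = selection.select_features(
        ranked, alpha=cfg.alpha, top_k=cfg.top_k, exclude=cfg.exclude
    )
    pvalues = pd.DataFrame(
        [{"feature": r.feature_name, "H": r.H, "p_value": r.p_value} for r in sel.ranked]
    )
    if out is not None:
        selection.save_selection(sel, out / "selection.json")
        pvalues.to_csv(out / "pvalues.csv", index=False)
    log.info("selected features %s (%.2fs)", sel.selected, time.perf_counter() - t0)

    cv = classify.CVConfig(k=cfg.folds, seed=cfg.seed)
    specs = classify.kernel_grid(P=len(sel.selected))
    acc = pd.DataFrame(
        index=list(cfg.kernels),
        columns=[f"{L:g}min" for L in cfg.window_lengths],
        dtype=float,
    )
    reports: dict[tuple[str, float], classify.CVReport] = {}
    for L in cfg.window_lengths:
        X, y = _xy(tables[L], sel.selected)
        for name in cfg.kernels:
            report = classify.crossvalidate(
                lambda name=name: classify.SVMStressClassifier(specs[name]), X, y, cv
            )
            reports[(name, L)] = report
            acc.loc[name, f"{L:g}min"] = report.accuracy
    best_kernel = acc[f"{L_max:g}min"].idxmax()
    best_report = reports[(best_kernel, L_max)]
    log.info("accuracy matrix done, best kernel %s (%.2fs)", best_kernel, time.perf_counter() - t0)

    X, y = _xy(tables[L_max], sel.selected)
    mlp_report = classify.crossvalidate(
        lambda: classify.MLPStressClassifier(hidden=10, seed=cfg.seed), X, y, cv
    )
    comparison = pd.DataFrame(
        [
            {
                "classifier": f"SVM ({best_kernel})",
                "accuracy": best_report.accuracy,
                "auc": best_report.auc,
            },
            {"classifier": "MLP", "accuracy": mlp_report.accuracy, "auc": mlp_report.auc},
        ]
    )

    if out is not None:
        acc.rename_axis("kernel").to_csv(out / "accuracy_matrix.csv")
        comparison.to_csv(out / "comparison.csv", index=False)
        payload = {
            "config": asdict(cfg),
            "selected": list(sel.selected),
            "best_kernel": str(best_kernel),
            "best": {
                "accuracy": best_report.accuracy,
                "sensitivity": best_report.sensitivity,
                "specificity": best_report.specificity,
                "auc": best_report.auc,
                "folds": [asdict(f) for f in best_report.folds],
            },
            "mlp": {"accuracy": mlp_report.accuracy, "auc": mlp_report.auc},
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2) + "\n")
    log.info("study complete (%.2fs)", time.perf_counter() - t0)

    return StudyReport(
        pvalues=pvalues,
        accuracy_matrix=acc,
        comparison=comparison,
        selected=sel.selected,
        best_kernel=str(best_kernel),
        best_report=best_report,
        config=cfg,
    )


def compare_classifiers(cfg: StudyConfig) -> pd.DataFrame:
    """SVM (best kernel at the longest window) vs the MLP: accuracy %, AUC."""
    return run_study(cfg).comparison
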