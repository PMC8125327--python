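"""Kruskal-Wallis feature ranking and selection.

Each feature column is tested for distributional differences between
condition groups — either the binary no-stress/stress (NSC vs SC) grouping
or the three driving scenarios — with the rank-based Kruskal-Wallis H test
(tie-corrected, chi-square p-value). Physiological features are rarely
Gaussian, which is why a rank test is used instead of ANOVA. Features are
ranked by ascending p-value; selection keeps the top-k below a significance
threshold (default 0.01), minus an explicit exclusion list for features
vetoed on distribution-overlap grounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES

Grouping = Literal["two_class", "three_scenario"]


class SelectionError(ValueError):
    """Raised when no feature satisfies the selection threshold."""


@dataclass(frozen=True)
class KWResult:
    feature_name: str
    H: float
    p_value: float
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class SelectionResult:
    ranked: tuple[KWResult, ...]  # ascending p; ties keep feature-table order
    selected: tuple[str, ...]
    alpha: float
    grouping: str = "two_class"
    excluded: tuple[str, ...] = field(default_factory=tuple)


def _quantize_significant(x: np.ndarray, digits: int) -> np.ndarray:
    """Round to `digits` significant digits so 1-ulp noise forms exact ties.

    Feature columns can contain values that are equal by construction (e.g.
    the variance of a rest segment normalized by its own statistics is
    exactly 1) but differ in the last floating-point bit; without this,
    the tie correction would rank such columns arbitrarily.
    """
    out = np.array(x, dtype=float)
    nz = out != 0
    mag = 10.0 ** (digits - 1 - np.floor(np.log10(np.abs(out[nz]))))
    out[nz] = np.round(out[nz] * mag) / mag
    return out


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    feature_name: str = "",
    tie_sig_digits: int | None = 12,
) -> KWResult:
    """Tie-corrected Kruskal-Wallis H and chi-square p for >= 2 groups.

    Observations are treated as tied when equal to `tie_sig_digits`
    significant digits (None disables), making the tie correction robust to
    last-bit floating-point noise. A degenerate input where every
    observation is identical has all midranks equal: H = 0 and p = 1 by
    convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if tie_sig_digits is not None:
        arrays = [_quantize_significant(a, tie_sig_digits) for a in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return KWResult(
        feature_name=feature_name,
        H=float(h),
        p_value=float(p),
        group_sizes=tuple(a.size for a in arrays),
    )


def _groups_for(table: pd.DataFrame, grouping: Grouping) -> list[pd.DataFrame]:
    if grouping == "two_class":
        keys, column = ["NSC", "SC"], "label"
    elif grouping == "three_scenario":
        keys, column = ["rest", "city", "highway"], "scenario"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    groups = [table[table[column] == k] for k in keys]
    empty = [k for k, g in zip(keys, groups) if g.empty]
    if empty:
        raise ValueError(f"empty group(s) {empty} under {grouping} grouping")
    return groups


def rank_features(table: pd.DataFrame, grouping: Grouping = "two_class") -> SelectionResult:
    """One Kruskal-Wallis test per feature column, ranked by ascending p.

    Exact p ties keep the feature-table column order (a deterministic,
    documented tie-break; variance and std precede rms in that order).
    """
    groups = _groups_for(table, grouping)
    results = [
        kruskal_wallis([g[name].to_numpy() for g in groups], feature_name=name)
        for name in FEATURE_NAMES
    ]
    ranked = sorted(results, key=lambda r: r.p_value)  # stable: ties keep order
    return SelectionResult(
        ranked=tuple(ranked), selected=(), alpha=float("nan"), grouping=grouping
    )


def select_features(
    result: SelectionResult,
    alpha: float = 0.01,
    top_k: int = 2,
    exclude: Iterable[str] = (),
) -> SelectionResult:
    """Keep the top_k smallest-p features with p < alpha, minus exclusions.

    The exclusion list encodes judgement-call vetoes (features whose group
    distributions visibly overlap despite a small p, e.g. median and SMR in
    the original study); it is configuration, not inference.
    """
    exclude = tuple(exclude)
    passing = [
        r.feature_name
        for r in result.ranked
        if r.p_value < alpha and r.feature_name not in exclude
    ]
    if not passing:
        raise SelectionError(f"no feature passes alpha={alpha} after exclusions")
    return SelectionResult(
        ranked=result.ranked,
        selected=tuple(passing[:top_k]),
        alpha=alpha,
        grouping=result.grouping,
        excluded=exclude,
    )


def save_selection(result: SelectionResult, path: str | Path) -> None:
    payload = {
        "grouping": result.grouping,
        "alpha": result.alpha,
        "excluded": list(result.excluded),
        "selected": list(result.selected),
        "ranked": [
            {
                "feature": r.feature_name,
                "H": r.H,
                "p_value": r.p_value,
                "group_sizes": list(r.group_sizes),
            }
            for r in result.ranked
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_selection(path: str | Path) -> SelectionResult:
    payload = json.loads(Path(path).read_text())
    ranked = tuple(
        KWResult(
            feature_name=r["feature"],
            H=float(r["H"]),
            p_value=float(r["p_value"]),
            group_sizes=tuple(r["group_sizes"]),
        )
        for r in payload["ranked"]
    )
    return SelectionResult(
        ranked=ranked,
        selected=tuple(payload["selected"]),
        alpha=float(payload["alpha"]),
        grouping=payload["grouping"],
        excluded=tuple(payload["excluded"]),
    )
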