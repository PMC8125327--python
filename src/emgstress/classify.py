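"""Kernel-SVM stress classifiers, an MLP comparator, and cross-validation.

The binary task: label a 5-min EMG window as stress (SC, positive class) or
no-stress (NSC). Six kernel configurations are compared — linear, quadratic,
cubic (inhomogeneous polynomials ``(1 + u.v)^d``) and three Gaussian
bandwidth presets derived from the predictor count P (fine ``sqrt(P)/4``,
medium ``sqrt(P)``, coarse ``4 sqrt(P)``). Features are standardized to the
training fold's statistics before kernel evaluation.

The SVM dual problem is solved by scikit-learn's SMO solver; the contract is
the KKT-satisfying solution, not a particular solver trajectory. The MLP
comparator is a 2-10-2 network with bipolar-sigmoid (tanh) hidden units
trained by damped Gauss-Newton (Levenberg-Marquardt) least squares — small
enough (52 parameters) that the exact Jacobian is formed directly.

Metrics follow the usual screening conventions: sensitivity is the true
positive rate on stress windows, specificity the true negative rate on rest
windows, accuracy the mean of per-fold accuracies, and AUC the rank
(trapezoidal) area under the ROC of the pooled decision values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

NSC_LABEL = 0
SC_LABEL = 1  # stress is the positive class

KernelFamily = Literal["linear", "quadratic", "cubic", "gaussian"]

KERNEL_NAMES = (
    "linear",
    "quadratic",
    "cubic",
    "fine_gaussian",
    "medium_gaussian",
    "coarse_gaussian",
)


class DegenerateDataError(ValueError):
    """Raised when the two classes occupy identical points in feature space."""


@dataclass(frozen=True)
class KernelSpec:
    family: KernelFamily
    P: int = 2
    scale: float | None = None  # gaussian only

    def __post_init__(self) -> None:
        if self.family not in ("linear", "quadratic", "cubic", "gaussian"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.P < 1:
            raise ValueError("P (number of predictors) must be >= 1")
        if self.family == "gaussian":
            if self.scale is None or self.scale <= 0:
                raise ValueError("gaussian kernel needs a positive scale")


def gaussian_scale(
    preset: Literal["fine", "medium", "coarse"],
    P: int,
    convention: Literal["sqrt", "literal"] = "sqrt",
) -> float:
    """Bandwidth preset from the predictor count P.

    The default "sqrt" convention gives sqrt(P)/4, sqrt(P), 4*sqrt(P) for
    fine/medium/coarse; "literal" gives P/4, P, 4P.
    """
    base = math.sqrt(P) if convention == "sqrt" else float(P)
    factor = {"fine": 0.25, "medium": 1.0, "coarse": 4.0}[preset]
    return base * factor


def kernel_grid(
    P: int = 2, convention: Literal["sqrt", "literal"] = "sqrt"
) -> dict[str, KernelSpec]:
    """The six named kernel configurations under study, keyed by name."""
    return {
        "linear": KernelSpec("linear", P=P),
        "quadratic": KernelSpec("quadratic", P=P),
        "cubic": KernelSpec("cubic", P=P),
        "fine_gaussian": KernelSpec("gaussian", P=P, scale=gaussian_scale("fine", P, convention)),
        "medium_gaussian": KernelSpec("gaussian", P=P, scale=gaussian_scale("medium", P, convention)),
        "coarse_gaussian": KernelSpec("gaussian", P=P, scale=gaussian_scale("coarse", P, convention)),
    }


def make_kernel(spec: KernelSpec) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Gram-matrix function K(U, V) for the given kernel specification."""
    if spec.family == "linear":
        return lambda U, V: np.asarray(U) @ np.asarray(V).T
    if spec.family == "quadratic":
        return lambda U, V: (1.0 + np.asarray(U) @ np.asarray(V).T) ** 2
    if spec.family == "cubic":
        return lambda U, V: (1.0 + np.asarray(U) @ np.asarray(V).T) ** 3
    scale = float(spec.scale)  # type: ignore[arg-type]

    def gaussian(U: np.ndarray, V: np.ndarray) -> np.ndarray:
        U, V = np.asarray(U, dtype=float), np.asarray(V, dtype=float)
        sq = (
            np.sum(U**2, axis=1)[:, None]
            + np.sum(V**2, axis=1)[None, :]
            - 2.0 * U @ V.T
        )
        return np.exp(-np.maximum(sq, 0.0) / scale**2)

    return gaussian


def _validate_binary(y: np.ndarray) -> None:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need samples of both classes (NSC and SC)")
    if not set(classes).issubset({NSC_LABEL, SC_LABEL}):
        raise ValueError(f"labels must be 0 (NSC) or 1 (SC), got {classes}")


class _Standardizer:
    """Column-wise z-scoring fit on the training fold; zero-spread guard."""

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu_) / self.sd_


class SVMStressClassifier:
    """Soft-margin kernel SVM with fold-local feature standardization."""

    def __init__(
        self,
        spec: KernelSpec,
        box_constraint: float = 1.0,
        standardize: bool = True,
    ) -> None:
        if box_constraint <= 0:
            raise ValueError("box_constraint must be positive")
        self.spec = spec
        self.box_constraint = box_constraint
        self.standardize = standardize

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMStressClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        _validate_binary(y)
        _check_not_degenerate(X, y)
        self.scaler_ = _Standardizer().fit(X) if self.standardize else None
        Xs = self.scaler_.transform(X) if self.scaler_ else X
        # tight solver tolerance so the dual solution meets the KKT
        # conditions well inside 1e-4 on the margin values; the iteration cap
        # only bites on unlearnable (label-noise) data where the margin
        # geometry is meaningless anyway
        self.svc_ = SVC(
            C=self.box_constraint,
            kernel=make_kernel(self.spec),
            tol=1e-6,
            max_iter=100_000,
        )
        with warnings.catch_warnings():
            # the cap is only reached on label-noise data, where an early
            # stop is the intended behaviour, not a defect to report
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.svc_.fit(Xs, y)
        self.X_train_ = Xs
        return self

    # exposed solution pieces (support set, dual coefficients, bias)
    @property
    def support_(self) -> np.ndarray:
        return self.svc_.support_

    @property
    def dual_coef_(self) -> np.ndarray:
        return self.svc_.dual_coef_

    @property
    def intercept_(self) -> float:
        return float(self.svc_.intercept_[0])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler_.transform(np.asarray(X, dtype=float)) if self.scaler_ else np.asarray(X, dtype=float)
        return self.svc_.decision_function(Xs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler_.transform(np.asarray(X, dtype=float)) if self.scaler_ else np.asarray(X, dtype=float)
        return self.svc_.predict(Xs)


def _check_not_degenerate(X: np.ndarray, y: np.ndarray) -> None:
    """Reject data where both classes occupy exactly the same point set."""
    rows0 = {tuple(row) for row in X[y == NSC_LABEL]}
    rows1 = {tuple(row) for row in X[y == SC_LABEL]}
    if rows0 == rows1:
        raise DegenerateDataError(
            "the two classes consist of identical feature vectors; "
            "no separating geometry exists"
        )


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    box_constraint: float = 1.0,
    standardize: bool = True,
) -> SVMStressClassifier:
    """Fit one SVM on all provided samples (see crossvalidate for CV)."""
    return SVMStressClassifier(spec, box_constraint, standardize).fit(X, y)


# ---------------------------------------------------------------------------
# MLP comparator: 2-10-2 tanh network, Levenberg-Marquardt least squares
# ---------------------------------------------------------------------------


class MLPStressClassifier:
    """Small feed-forward net trained by damped Gauss-Newton least squares.

    Architecture: P inputs -> `hidden` tanh units -> 2 linear outputs, one
    per class, fit to +/-1 one-hot targets; prediction is the argmax and the
    decision value is out(SC) - out(NSC). The Levenberg-Marquardt damping
    factor starts at `lambda_init` and is divided/multiplied by 10 on
    accepted/rejected steps. Fully deterministic given the seed.
    """

    def __init__(
        self,
        hidden: int = 10,
        seed: int = 0,
        max_epochs: int = 200,
        lambda_init: float = 1e-3,
        standardize: bool = True,
    ) -> None:
        if hidden < 1:
            raise ValueError("hidden must be >= 1")
        self.hidden = hidden
        self.seed = seed
        self.max_epochs = max_epochs
        self.lambda_init = lambda_init
        self.standardize = standardize

    # parameter packing order: W1 (H x D), b1 (H), W2 (2 x H), b2 (2)
    def _unpack(self, theta: np.ndarray, d: int):
        h = self.hidden
        i = 0
        W1 = theta[i : i + h * d].reshape(h, d); i += h * d
        b1 = theta[i : i + h]; i += h
        W2 = theta[i : i + 2 * h].reshape(2, h); i += 2 * h
        b2 = theta[i : i + 2]
        return W1, b1, W2, b2

    def _forward(self, theta: np.ndarray, X: np.ndarray):
        W1, b1, W2, b2 = self._unpack(theta, X.shape[1])
        Hact = np.tanh(X @ W1.T + b1)  # (N, H)
        O = Hact @ W2.T + b2  # (N, 2)
        return Hact, O

    def _jacobian(self, theta: np.ndarray, X: np.ndarray, Hact: np.ndarray) -> np.ndarray:
        n, d = X.shape
        h = self.hidden
        W1, b1, W2, b2 = self._unpack(theta, d)
        G = 1.0 - Hact**2  # tanh'(a), (N, H)
        # residual index (n, k) flattened row-major over k
        JW1 = np.einsum("kj,nj,ni->nkji", W2, G, X).reshape(n * 2, h * d)
        Jb1 = np.einsum("kj,nj->nkj", W2, G).reshape(n * 2, h)
        JW2 = np.zeros((n, 2, 2, h))
        JW2[:, [0, 1], [0, 1], :] = Hact[:, None, :]
        JW2 = JW2.reshape(n * 2, 2 * h)
        Jb2 = np.tile(np.eye(2), (n, 1))
        return np.hstack([JW1, Jb1, JW2, Jb2])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPStressClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        _validate_binary(y)
        self.scaler_ = _Standardizer().fit(X) if self.standardize else None
        Xs = self.scaler_.transform(X) if self.scaler_ else X
        n, d = Xs.shape
        T = np.full((n, 2), -1.0)
        T[np.arange(n), y] = 1.0

        rng = np.random.default_rng(self.seed)
        nparams = self.hidden * d + self.hidden + 2 * self.hidden + 2
        theta = rng.normal(0.0, 0.5, size=nparams)

        lam = self.lambda_init
        Hact, O = self._forward(theta, Xs)
        r = (O - T).reshape(-1)
        sse = float(r @ r)
        for _ in range(self.max_epochs):
            J = self._jacobian(theta, Xs, Hact)
            g = J.T @ r
            if float(np.linalg.norm(g)) < 1e-10:
                break
            JtJ = J.T @ J
            accepted = False
            for _try in range(12):
                try:
                    step = np.linalg.solve(JtJ + lam * np.eye(nparams), g)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                theta_new = theta - step
                Hact_new, O_new = self._forward(theta_new, Xs)
                r_new = (O_new - T).reshape(-1)
                sse_new = float(r_new @ r_new)
                if sse_new < sse:
                    theta, Hact, r, sse = theta_new, Hact_new, r_new, sse_new
                    lam = max(lam / 10.0, 1e-12)
                    accepted = True
                    break
                lam *= 10.0
            if not accepted or sse < 1e-12:
                break
        self.theta_ = theta
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaler_.transform(np.asarray(X, dtype=float)) if self.scaler_ else np.asarray(X, dtype=float)
        _, O = self._forward(self.theta_, Xs)
        return O[:, SC_LABEL] - O[:, NSC_LABEL]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


def train_mlp(
    X: np.ndarray, y: np.ndarray, hidden: int = 10, seed: int = 0
) -> MLPStressClassifier:
    return MLPStressClassifier(hidden=hidden, seed=seed).fit(X, y)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class FoldResult:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.tn + self.fp + self.fn)


@dataclass(frozen=True)
class CVReport:
    """Aggregate k-fold metrics; percentages on the 0-100 scale."""

    folds: tuple[FoldResult, ...]
    accuracy: float  # mean of per-fold accuracies, %
    sensitivity: float  # pooled TP/(TP+FN) on the stress class, %
    specificity: float  # pooled TN/(TN+FP) on the rest class, %
    auc: float  # pooled decision values, rank/trapezoidal ROC area
    n: int

    @property
    def pooled(self) -> FoldResult:
        return FoldResult(
            tp=sum(f.tp for f in self.folds),
            fn=sum(f.fn for f in self.folds),
            tn=sum(f.tn for f in self.folds),
            fp=sum(f.fp for f in self.folds),
        )


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Accuracy / sensitivity / specificity (in %) from confusion counts."""
    total = tp + fn + tn + fp
    return {
        "accuracy": 100.0 * (tp + tn) / total,
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
    }


def crossvalidate(
    build: Callable[[], object],
    X: np.ndarray,
    y: np.ndarray,
    cv: CVConfig = CVConfig(),
) -> CVReport:
    """Stratified k-fold CV of any classifier with fit/predict/decision_function.

    Each sample is validated exactly once; fold accuracies are averaged, the
    confusion counts are pooled for sensitivity/specificity, and the AUC is
    computed on the pooled decision values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _validate_binary(y)
    class_counts = np.bincount(y, minlength=2)
    if cv.stratified and cv.k > int(class_counts.min()):
        raise ValueError(
            f"k={cv.k} exceeds the smallest class count {int(class_counts.min())}"
        )
    splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    folds: list[FoldResult] = []
    pooled_scores = np.empty_like(y, dtype=float)
    for train_idx, test_idx in splitter.split(X, y):
        model = build()
        model.fit(X[train_idx], y[train_idx])  # type: ignore[attr-defined]
        pred = model.predict(X[test_idx])  # type: ignore[attr-defined]
        pooled_scores[test_idx] = model.decision_function(X[test_idx])  # type: ignore[attr-defined]
        yt = y[test_idx]
        folds.append(
            FoldResult(
                tp=int(np.sum((pred == SC_LABEL) & (yt == SC_LABEL))),
                fn=int(np.sum((pred == NSC_LABEL) & (yt == SC_LABEL))),
                tn=int(np.sum((pred == NSC_LABEL) & (yt == NSC_LABEL))),
                fp=int(np.sum((pred == SC_LABEL) & (yt == NSC_LABEL))),
            )
        )
    pooled = FoldResult(
        tp=sum(f.tp for f in folds),
        fn=sum(f.fn for f in folds),
        tn=sum(f.tn for f in folds),
        fp=sum(f.fp for f in folds),
    )
    metrics = confusion_metrics(pooled.tp, pooled.fn, pooled.tn, pooled.fp)
    return CVReport(
        folds=tuple(folds),
        accuracy=100.0 * float(np.mean([f.accuracy for f in folds])),
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        auc=float(roc_auc_score(y, pooled_scores)),
        n=int(y.size),
    )
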