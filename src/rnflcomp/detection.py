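"""Normative limits, run-length detection and diagnostic evaluation.

An eye is flagged as glaucomatous when a sufficiently long run of
consecutive points on the scan circle falls below the one-sided 95%
lower normative limit built from healthy reference eyes.  The run
length L is an integer score; sweeping L gives the ROC curve.  AUROC is
the Mann–Whitney probability that a random glaucomatous eye outscores a
random healthy one (ties counted one half), which equals the
trapezoidal area under the operating points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.utils.validation import check_is_fitted

from .exceptions import ContractError
from .profiles import Cohort, profile_columns

__all__ = [
    "NormativeLimits",
    "fit_normative_limits",
    "detection_score",
    "detection_scores",
    "RunLengthDetector",
    "RocResult",
    "roc",
    "PerformanceReport",
    "performance_at",
    "al_subgroup",
    "relative_auroc_gain",
    "group_mean_profile",
    "mean_absolute_compensation",
]

POSITIVE_LABEL = "glaucoma"


@dataclass
class NormativeLimits:
    """Per-point one-sided lower normative bound (µm)."""

    lower_bound: np.ndarray
    method: str
    reference_n: int

    @property
    def P(self) -> int:
        return self.lower_bound.size


def fit_normative_limits(
    profiles: np.ndarray, method: str = "empirical_p5", percentile: float = 5.0
) -> NormativeLimits:
    """Lower normative limit from healthy reference profiles.

    ``empirical_p5``: per-point linearly interpolated order statistic at
    the given percentile (default 5 → one-sided 95% limit); needs at
    least 20 reference profiles.  ``gaussian_1645``: mean − 1.645·SD.
    """
    Y = np.asarray(profiles, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ContractError("need a (n, P) matrix with n >= 2 reference profiles")
    n = Y.shape[0]
    if method == "empirical_p5":
        if n < 20:
            raise ContractError(
                f"empirical percentile limit needs >= 20 reference profiles "
                f"(got {n}); use method='gaussian_1645'"
            )
        bound = np.percentile(Y, percentile, axis=0, method="linear")
    elif method == "gaussian_1645":
        z = 1.6448536269514722  # one-sided 95% normal quantile
        bound = Y.mean(axis=0) - z * Y.std(axis=0, ddof=1)
    else:
        raise ContractError(f"unknown method {method!r}")
    return NormativeLimits(
        lower_bound=np.clip(bound, 0.0, None), method=method, reference_n=n
    )


def detection_score(values: np.ndarray, limits: NormativeLimits) -> int:
    """Longest circular run of consecutive points strictly below the limit."""
    values = np.asarray(values, dtype=float)
    if values.size != limits.P:
        raise ContractError(f"profile length {values.size} != limits P={limits.P}")
    below = values < limits.lower_bound
    return _max_circular_run(below)


def _max_circular_run(below: np.ndarray) -> int:
    P = below.size
    if below.all():
        return P
    if not below.any():
        return 0
    # doubling the sequence turns circular runs into linear ones
    b = np.concatenate([below, below]).astype(np.int8)
    edges = np.diff(np.concatenate([[0], b, [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return int(min(int((ends - starts).max()), P))


def detection_scores(Y: np.ndarray, limits: NormativeLimits) -> np.ndarray:
    """Run-length scores for each row of a (n, P) matrix."""
    Y = np.asarray(Y, dtype=float)
    return np.array([detection_score(row, limits) for row in Y], dtype=int)


class RunLengthDetector(BaseEstimator, ClassifierMixin):
    """Classifier: normative limits + run-length score + threshold.

    ``fit(X, y)`` builds the limits from the rows labeled normal (or all
    rows when y is None); ``decision_function`` returns the integer run
    length; ``predict`` flags glaucoma at ``score >= threshold``.
    X may be a plain (n, P) array or a DataFrame with p-columns.
    """

    def __init__(
        self, method: str = "empirical_p5", threshold: int = 1, percentile: float = 5.0
    ):
        self.method = method
        self.threshold = threshold
        self.percentile = percentile

    @staticmethod
    def _matrix(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            P = sum(1 for c in X.columns if c.startswith("p") and c[1:].isdigit())
            if P:
                return X[profile_columns(P)].to_numpy(dtype=float)
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def fit(self, X, y=None) -> "RunLengthDetector":
        Y = self._matrix(X)
        if y is not None:
            y = np.asarray(y)
            Y = Y[y != POSITIVE_LABEL]
        self.limits_ = fit_normative_limits(Y, self.method, self.percentile)
        self.classes_ = np.array(["normal", POSITIVE_LABEL])
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "limits_")
        return detection_scores(self._matrix(X), self.limits_)

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return np.where(scores >= self.threshold, POSITIVE_LABEL, "normal")


# ---------------------------------------------------------------------------
# ROC and threshold metrics
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Operating points (score >= threshold ⇒ glaucoma) and AUROC."""

    thresholds: np.ndarray
    sensitivity: np.ndarray       # true-positive rate per operating point
    one_minus_specificity: np.ndarray
    auroc: float


def _check_two_classes(labels) -> np.ndarray:
    y = np.asarray(labels)
    pos = y == POSITIVE_LABEL
    if pos.all() or not pos.any():
        raise ContractError("ROC needs both classes present")
    return pos


def roc(scores, labels) -> RocResult:
    """ROC over all distinct score thresholds, AUROC by trapezoid rule."""
    y = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s)
    return RocResult(
        thresholds=thr,
        sensitivity=tpr,
        one_minus_specificity=fpr,
        auroc=float(_trapezoid_auc(fpr, tpr)),
    )


@dataclass
class PerformanceReport:
    """Confusion counts and derived metrics at one threshold."""

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float = field(init=False)
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)

    def __post_init__(self):
        def ratio(num, den):
            return num / den if den > 0 else float("nan")

        n = self.tp + self.fp + self.tn + self.fn
        self.accuracy = ratio(self.tp + self.tn, n)
        self.sensitivity = ratio(self.tp, self.tp + self.fn)
        self.specificity = ratio(self.tn, self.tn + self.fp)
        self.ppv = ratio(self.tp, self.tp + self.fp)
        self.npv = ratio(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def performance_at(scores, labels, threshold: float) -> PerformanceReport:
    """Accuracy/sens/spec/PPV/NPV classifying glaucoma at score >= threshold."""
    pos = _check_two_classes(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    return PerformanceReport(
        threshold=threshold,
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


# ---------------------------------------------------------------------------
# subgroups and summaries
# ---------------------------------------------------------------------------

def al_subgroup(cohort: Cohort, fraction: float) -> Cohort:
    """The ⌈fraction·n⌉ eyes with the longest axial length.

    Ties in axial length break by eye_id so the subgroup is
    deterministic; both labels are retained.
    """
    if not 0.0 < fraction <= 1.0:
        raise ContractError("fraction must lie in (0, 1]")
    k = ceil(fraction * len(cohort))
    order = cohort.frame.sort_values(
        ["axial_length", "eye_id"], ascending=[False, True], kind="mergesort"
    )
    return Cohort(order.head(k).reset_index(drop=True), P=cohort.P)


def relative_auroc_gain(auroc_before: float, auroc_after: float) -> float:
    """Percent change 100·(after − before)/before."""
    for v in (auroc_before, auroc_after):
        if not 0.0 < v <= 1.0:
            raise ContractError("AUROC values must lie in (0, 1]")
    return 100.0 * (auroc_after - auroc_before) / auroc_before


def group_mean_profile(profiles: np.ndarray) -> np.ndarray:
    """Pointwise mean profile of a (n, P) matrix."""
    Y = np.asarray(profiles, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 1:
        raise ContractError("need a non-empty (n, P) matrix")
    return Y.mean(axis=0)


def mean_absolute_compensation(original: np.ndarray, compensated: np.ndarray) -> float:
    """Mean |compensated − original| over all eyes and points (µm)."""
    a = np.asarray(original, dtype=float)
    b = np.asarray(compensated, dtype=float)
    if a.shape != b.shape:
        raise ContractError("shape mismatch between original and compensated")
    return float(np.mean(np.abs(b - a)))
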