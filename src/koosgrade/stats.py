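"""Evaluation metrics, agreement coefficients, the corrected resampled
paired t-test, and stratified k-fold splitting for ordinal Koos grades.

Metric definitions (4 ordinal classes, labels 1..4):

* accuracy       = n_match / n_total
* MA-MAE         = (1/n) * sum_j (1/n_j) * sum_{x in T_j} |D(x)|, the
  macro average over classes represented in the ground truth of the
  mean absolute ordinal error within each class,
* weighted F1    = sum_j (n_j / n_total) * F1_j with one-vs-rest
  per-class F1 and weights proportional to the true class support.

The corrected resampled paired t-test accounts for the overlap of
cross-validation training sets by inflating the variance term:
``t = dbar / sqrt((1/k + n2/n1) * s_d^2)`` with k folds and test/train
size ratio n2/n1; the p-value uses k - 1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, ParameterError

GRADES = (1, 2, 3, 4)


def _as_grade_arrays(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=int).ravel()
    yp = np.asarray(y_pred, dtype=int).ravel()
    if yt.size == 0 or yt.size != yp.size:
        raise DegenerateInputError("inputs must be nonempty and of equal length")
    return yt, yp


def accuracy(y_true, y_pred) -> float:
    """Fraction of correctly classified samples."""
    yt, yp = _as_grade_arrays(y_true, y_pred)
    return float((yt == yp).mean())


def ma_mae(y_true, y_pred, classes=GRADES) -> float:
    """Macro-averaged mean absolute ordinal error.

    Averages the within-class mean |true - predicted| over the classes
    present in the ground truth; absent classes are excluded from the
    outer average.
    """
    yt, yp = _as_grade_arrays(y_true, y_pred)
    if not set(yt) <= set(classes):
        raise ParameterError("y_true contains labels outside the class set")
    present = [c for c in classes if (yt == c).any()]
    per_class = [np.abs(yt[yt == c] - yp[yt == c]).mean() for c in present]
    return float(np.mean(per_class))


def weighted_f1(y_true, y_pred) -> float:
    """Support-weighted average of per-class one-vs-rest F1 scores.

    A class with zero precision + recall contributes F1 = 0; classes
    absent from the ground truth carry zero weight.
    """
    yt, yp = _as_grade_arrays(y_true, y_pred)
    total = 0.0
    for c in np.unique(yt):
        support = (yt == c).sum()
        tp = ((yt == c) & (yp == c)).sum()
        predicted = (yp == c).sum()
        precision = tp / predicted if predicted else 0.0
        recall = tp / support
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        total += support / yt.size * f1
    return float(total)


@dataclass
class ConfusionMatrix:
    """4x4 confusion counts; rows = true grade, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4) or (self.counts < 0).any():
            raise ParameterError("counts must be a nonnegative 4x4 grid")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def to_frame(self):
        import pandas as pd

        labels = [f"grade {g}" for g in GRADES]
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Confusion counts over the four Koos grades."""
    yt, yp = _as_grade_arrays(y_true, y_pred)
    if not (set(yt) | set(yp)) <= set(GRADES):
        raise ParameterError("grades must lie in 1..4")
    counts = np.zeros((4, 4), dtype=int)
    for t, p in zip(yt, yp):
        counts[t - 1, p - 1] += 1
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    """Accuracy, weighted F1 and MA-MAE with the confusion matrix."""

    accuracy: float
    weighted_f1: float
    ma_mae: float
    confusion: ConfusionMatrix
    per_fold: dict[str, list[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "weighted_f1": self.weighted_f1,
            "ma_mae": self.ma_mae,
            "confusion": self.confusion.counts.tolist(),
        }
        if self.per_fold:
            d["per_fold"] = self.per_fold
        return d


def metrics_report(y_true, y_pred) -> MetricsReport:
    return MetricsReport(
        accuracy=accuracy(y_true, y_pred),
        weighted_f1=weighted_f1(y_true, y_pred),
        ma_mae=ma_mae(y_true, y_pred),
        confusion=confusion(y_true, y_pred),
    )


# ---------------------------------------------------------------------------
# Agreement coefficients


def fleiss_kappa(ratings) -> float:
    """Fleiss' generalized kappa for a cases x raters grade table.

    Category proportions are pooled over all ratings; agreement of 1
    means all raters identical on all cases.  Raises on degenerate
    tables where the expected agreement is 1 (a single category used).
    """
    r = np.asarray(ratings, dtype=int)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise DegenerateInputError("need >= 2 cases and >= 2 raters")
    n_cases, n_raters = r.shape
    cats = np.unique(r)
    counts = np.stack([(r == c).sum(axis=1) for c in cats], axis=1)  # cases x cats
    p_j = counts.sum(axis=0) / (n_cases * n_raters)
    p_i = ((counts**2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = p_i.mean()
    p_e = float((p_j**2).sum())
    if p_e >= 1.0 - 1e-15:
        raise DegenerateInputError("all ratings in one category: kappa undefined")
    return float((p_bar - p_e) / (1.0 - p_e))


def weighted_kappa_quadratic(r1, r2, classes=GRADES) -> float:
    """Cohen's kappa with quadratic (Fleiss-Cohen) weights.

    Weights w_ij = 1 - (i - j)^2 / (k - 1)^2 over k ordered categories;
    the expected matrix is the outer product of the two raters'
    marginals.  A IV-rated-as-II error is penalised 4x more than a
    IV-rated-as-III error ((2^2)/(1^2) on the disagreement scale).
    """
    a, b = _as_grade_arrays(r1, r2)
    if a.size < 2:
        raise DegenerateInputError("need at least two paired ratings")
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[idx[x], idx[y]] += 1
    obs /= a.size
    marg_a, marg_b = obs.sum(axis=1), obs.sum(axis=0)
    expected = np.outer(marg_a, marg_b)
    i, j = np.indices((k, k))
    penalty = (i - j) ** 2 / (k - 1) ** 2  # 1 - w_ij
    denom = (penalty * expected).sum()
    if denom <= 1e-15:
        raise DegenerateInputError("zero expected disagreement: kappa undefined")
    return float(1.0 - (penalty * obs).sum() / denom)


# ---------------------------------------------------------------------------
# Corrected resampled paired t-test


@dataclass
class PairedDiffs:
    """Per-fold metric differences between two methods.

    ``test_train_ratio`` is n2/n1, the ratio of test-set to training-set
    samples in each fold.  For k-fold cross-validation the test fold
    holds 1/k of the data, giving (1/k)/(1 - 1/k); some authors invert
    the ratio (e.g. 0.8/0.2 = 4 for 5 folds), which is supported by
    passing it explicitly.
    """

    diffs: np.ndarray
    test_train_ratio: float

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=float).ravel()
        if self.diffs.size < 2:
            raise ParameterError("need k >= 2 paired differences")
        if self.test_train_ratio < 0:
            raise ParameterError("test/train ratio must be >= 0")

    @property
    def k(self) -> int:
        return self.diffs.size


def cv_test_train_ratio(k: int, paper_convention: bool = False) -> float:
    """n2/n1 for k-fold CV: test/train = (1/k)/(1-1/k); the inverted
    train/test reading (k - 1) is available via *paper_convention*."""
    if paper_convention:
        return float(k - 1)
    return (1.0 / k) / (1.0 - 1.0 / k)


def corrected_ttest(pd_: PairedDiffs) -> tuple[float, float]:
    """Corrected resampled paired t-test.

    Returns (t, two-sided p) with ``t = dbar / sqrt((1/k + n2/n1) * s^2)``
    where s^2 is the unbiased sample variance of the differences and the
    p-value uses Student's t with k - 1 degrees of freedom.  At ratio 0
    this reduces to the classical paired t statistic.  All-zero
    differences (a method compared with itself) return (0, 1).
    """
    d = pd_.diffs
    k = pd_.k
    dbar = float(d.mean())
    var = float(d.var(ddof=1))
    if var == 0.0:
        if dbar == 0.0:
            return 0.0, 1.0
        raise DegenerateInputError("zero variance with nonzero mean difference")
    t = dbar / np.sqrt((1.0 / k + pd_.test_train_ratio) * var)
    p = 2.0 * sps.t.sf(abs(t), df=k - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Stratified k-fold


def stratified_kfold(grades, k: int, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment by seeded shuffle + round-robin dealing.

    Cases of each grade are shuffled and dealt to folds in a single
    round-robin pass whose position carries over between grades, so both
    the per-grade counts and the total fold sizes differ by at most one
    across folds (308 cases over 5 folds gives a largest fold of 62).
    Returns the fold index (0..k-1) per case.
    """
    y = np.asarray(grades).ravel()
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > y.size:
        raise ParameterError("k exceeds the number of cases")
    rng = np.random.default_rng(seed)
    folds = np.full(y.size, -1, dtype=int)
    pos = 0
    for g in np.unique(y):
        idx = np.flatnonzero(y == g)
        rng.shuffle(idx)
        for case in idx:
            folds[case] = pos % k
            pos += 1
    return folds
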