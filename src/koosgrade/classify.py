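"""Koos-grade classifiers: Random Forest, volume-threshold baseline,
importance-driven backward feature elimination, and the casting-vote
ensemble.

The Random Forest operates on the 9 handcrafted geometric predictors
(volume, distances, contact area).  The baseline reduces grading to
three ordered tumor-volume cutoffs t1 <= t2 <= t3, chosen exhaustively
to maximise the weighted F1 score of the induced monotone rule
``grade(v) = 1 + #{t <= v}``.  The ensemble pools six grade votes
(three Random-Forest votes — one per input modality — which carry a
casting vote, plus three externally supplied network votes) and picks
the plurality grade, breaking ties first by caster votes, then by the
lowest ordinal grade.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import DegenerateInputError, DegenerateTrainingError, ParameterError
from .features import FeatureTable
from .stats import stratified_kfold, weighted_f1

GRADES = (1, 2, 3, 4)


@dataclass(frozen=True)
class RFConfig:
    """Random-Forest settings.

    Defaults follow the grading pipeline's published configuration:
    100,000 trees, maximum depth 5, minimum 2 samples per leaf,
    scikit-learn defaults otherwise.  ``class_weighting`` (off by
    default) weights classes inversely to their frequency, mirroring
    the weighted cross-entropy used by the neural branch.  Tree counts
    beyond a few hundred change desk-scale results negligibly, so tests
    and examples run with ``n_trees=500``.
    """

    n_trees: int = 100_000
    max_depth: int = 5
    min_samples_leaf: int = 2
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1 or self.min_samples_leaf < 1:
            raise ParameterError("n_trees, max_depth, min_samples_leaf must be >= 1")


@dataclass
class GradeModel:
    """A fitted Random Forest exposing grade prediction and importances."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...]
    config: RFConfig

    def predict(self, features: pd.DataFrame | pd.Series) -> np.ndarray:
        if isinstance(features, pd.Series):
            features = features.to_frame().T
        X = features[list(self.feature_names)].to_numpy(dtype=float)
        return self.estimator.predict(X).astype(int)

    def feature_importances(self) -> pd.Series:
        imp = pd.Series(self.estimator.feature_importances_, index=self.feature_names)
        return imp


def fit_rf(table: FeatureTable, cfg: RFConfig = RFConfig()) -> GradeModel:
    """Fit the Random-Forest grade classifier on a labelled feature table."""
    if table.grades is None:
        raise DegenerateTrainingError("feature table carries no grades")
    y = table.grades.to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training labels contain a single grade")
    X = table.features.to_numpy(dtype=float)
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        min_samples_leaf=cfg.min_samples_leaf,
        class_weight="balanced" if cfg.class_weighting else None,
        random_state=cfg.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    return GradeModel(est, tuple(table.features.columns), cfg)


# ---------------------------------------------------------------------------
# Volume-threshold baseline


@dataclass(frozen=True)
class Thresholds:
    """Three ordered tumor-volume cutoffs (mm^3) and the training F1."""

    cuts: tuple[float, float, float]
    weighted_f1: float = float("nan")

    def __post_init__(self) -> None:
        c = self.cuts
        if not (np.isfinite(c).all() and c[0] <= c[1] <= c[2] and c[0] > 0):
            raise ParameterError("cuts must be finite, positive and ordered")


def predict_baseline(volume, thresholds: Thresholds):
    """Grade = 1 + number of cutoffs <= volume (monotone in volume)."""
    v = np.asarray(volume, dtype=float)
    grade = 1 + (np.asarray(thresholds.cuts)[:, None] <= v.ravel()).sum(axis=0)
    return int(grade[0]) if v.ndim == 0 else grade.reshape(v.shape)


def _candidate_cuts(volumes: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted volumes, plus finite
    boundary sentinels that let any grade band be empty."""
    distinct = np.unique(volumes)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    lo = distinct[0]  # cut <= all volumes: grade-1 band empty
    hi = distinct[-1] + 1.0  # cut > all volumes: grade-4 band empty
    return np.concatenate([[lo], mids, [hi]])


def _f1_from_confusion(conf: np.ndarray) -> np.ndarray:
    """Weighted F1 for a stack of 4x4 confusion matrices (..., true, pred)."""
    support = conf.sum(axis=-1)
    predicted = conf.sum(axis=-2)
    tp = np.diagonal(conf, axis1=-2, axis2=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(predicted > 0, tp / np.maximum(predicted, 1), 0.0)
        recall = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    total = support.sum(axis=-1, keepdims=True)
    return (support * f1).sum(axis=-1) / total[..., 0]


def fit_volume_baseline(volumes, grades) -> Thresholds:
    """Learn the three volume cutoffs maximising training weighted F1.

    Exhaustive search over all ordered triples of candidate cuts
    (midpoints between consecutive distinct sorted volumes plus boundary
    sentinels); ties resolve to the lexicographically first triple.
    """
    v = np.asarray(volumes, dtype=float)
    y = np.asarray(grades, dtype=int)
    if v.size != y.size or v.size == 0:
        raise ParameterError("volumes and grades must be equal-length, nonempty")
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("need at least two distinct grades")
    if len(np.unique(v)) < 2:
        raise DegenerateTrainingError("all volumes identical")
    cuts = _candidate_cuts(v)
    m = len(cuts)
    # S[g, i] = number of cases of true grade g with cut_i <= volume
    passed = cuts[:, None] <= v[None, :]  # (m, n)
    S = np.stack([(passed & (y == g)).sum(axis=1) for g in GRADES]).T  # (m, 4)
    n_g = np.array([(y == g).sum() for g in GRADES])
    best = (-1.0, None)
    # chunk over the top cut k; vectorise over (i, j) with i <= j <= k
    for k in range(m):
        i_idx, j_idx = np.triu_indices(k + 1)
        conf = np.zeros((len(i_idx), 4, 4))
        conf[:, :, 3] = S[k]  # predicted IV: volume >= cut_k
        conf[:, :, 2] = S[j_idx] - S[k]
        conf[:, :, 1] = S[i_idx] - S[j_idx]
        conf[:, :, 0] = n_g - S[i_idx]
        f1 = _f1_from_confusion(conf)
        b = int(np.argmax(f1))
        if f1[b] > best[0] + 1e-15:
            best = (float(f1[b]), (float(cuts[i_idx[b]]), float(cuts[j_idx[b]]), float(cuts[k])))
    return Thresholds(best[1], weighted_f1=best[0])


def fit_volume_baseline_bruteforce(volumes, grades) -> Thresholds:
    """Plain-loop exhaustive search over the same candidate triples.

    Independent of the vectorised path; intended as a cross-check on
    small inputs (O(m^3 n)).
    """
    v = np.asarray(volumes, dtype=float)
    y = np.asarray(grades, dtype=int)
    cuts = _candidate_cuts(v)
    best = (-1.0, None)
    for triple in combinations_with_replacement(cuts, 3):
        pred = 1 + (np.asarray(triple)[:, None] <= v).sum(axis=0)
        f1 = weighted_f1(y, pred)
        if f1 > best[0] + 1e-15:
            best = (f1, tuple(float(t) for t in triple))
    return Thresholds(best[1], weighted_f1=best[0])


# ---------------------------------------------------------------------------
# Backward feature elimination


def backward_select_features(
    table: FeatureTable,
    cfg: RFConfig = RFConfig(n_trees=500),
    val_fraction: float = 0.2,
    seed: int = 0,
) -> list[str]:
    """Importance-driven backward elimination of predictors.

    A seeded stratified split holds out ``val_fraction`` of the cases;
    the loop fits a forest on the current predictor set, records the
    validation accuracy, and drops the lowest-importance predictor,
    down to a single predictor.  The predictor set with maximal
    recorded validation accuracy is returned (earliest maximum — i.e.
    the largest such set — on ties).
    """
    if table.grades is None:
        raise DegenerateTrainingError("feature table carries no grades")
    if not 0 < val_fraction < 1:
        raise ParameterError("val_fraction must be in (0, 1)")
    y = table.grades.to_numpy(dtype=int)
    k = max(2, round(1.0 / val_fraction))
    folds = stratified_kfold(y, k=k, seed=seed)
    val = folds == 0
    current = list(table.features.columns)
    history: list[tuple[float, list[str]]] = []
    while current:
        sub_train = FeatureTable(
            table.features.loc[~val, current], table.grades[~val]
        )
        model = fit_rf(sub_train, cfg)
        pred = model.predict(table.features.loc[val, current])
        acc = float((pred == y[val]).mean())
        history.append((acc, current.copy()))
        if len(current) == 1:
            break
        drop = model.feature_importances().idxmin()
        current.remove(drop)
    best_acc = max(acc for acc, _ in history)
    for acc, names in history:  # earliest maximum
        if acc == best_acc:
            return names
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Casting-vote ensemble


@dataclass(frozen=True)
class Vote:
    grade: int
    is_caster: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ParameterError(f"grade must be in 1..4, got {self.grade}")


@dataclass
class VotePanel:
    """Grade votes feeding the ensemble; the canonical panel has six
    votes of which the three Random-Forest votes are casters."""

    votes: list[Vote] = field(default_factory=list)

    def add(self, grade: int, is_caster: bool = False, source: str = "") -> None:
        self.votes.append(Vote(int(grade), is_caster, source))


def ensemble_vote(panel: VotePanel) -> int:
    """Plurality grade with the casting-vote tie-break cascade.

    The grade with strictly most votes wins; grades tied for most votes
    are ranked by caster votes; a residual tie resolves to the lowest
    ordinal grade.  The result is invariant to vote order.
    """
    if not panel.votes:
        raise DegenerateInputError("empty vote panel")
    counts = Counter(v.grade for v in panel.votes)
    top = max(counts.values())
    tied = sorted(g for g, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    caster_counts = Counter(v.grade for v in panel.votes if v.is_caster and v.grade in tied)
    top_casters = max((caster_counts.get(g, 0) for g in tied), default=0)
    tied = [g for g in tied if caster_counts.get(g, 0) == top_casters]
    return min(tied)
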