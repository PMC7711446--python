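"""Threshold classification and statistical evaluation of entropy features.

One scalar feature per record (its entropy value) is turned into a binary
classifier by a cut-off read from the ROC curve at the point nearest
(FPR, TPR) = (0, 1).  Performance is summarised as sensitivity,
specificity, accuracy and the Matthews correlation coefficient; group
differences are tested with the two-sided Wilcoxon rank-sum
(Mann-Whitney) test; generalisation is probed with a bootstrap
leave-one-out scheme that repeatedly holds out one record per class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import SlopEnParams, slope_entropy
from .errors import ParameterError
from .preprocessing import Epoch
from .records import MoodState

__all__ = [
    "ScoredSample",
    "RocCurve",
    "ConfusionCounts",
    "ClassPairResult",
    "roc_curve",
    "threshold_nearest_01",
    "classify",
    "confusion_counts",
    "classification_metrics",
    "rank_sum_test",
    "loo_bootstrap",
    "evaluate_pair",
    "gamma_grid_search",
]

#: Largest pooled sample size for which the rank-sum p-value is computed
#: by exhaustive enumeration of group assignments.
EXACT_RANKSUM_LIMIT = 12


@dataclass(frozen=True)
class ScoredSample:
    """One record's feature value with its class label."""

    source_id: str
    state: MoodState
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", MoodState(self.state))
        if not math.isfinite(self.score):
            raise ParameterError(f"score for {self.source_id!r} is not finite")


@dataclass
class RocCurve:
    """ROC sweep with an explicit score orientation.

    ``high_score_positive`` means a sample is called positive when its
    score is >= the threshold; ``low_score_positive`` flips the comparison.
    The orientation is auto-detected as the direction with AUC >= 0.5.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    orientation: str
    auc: float


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class ClassPairResult:
    """Classification summary for one ordered class pair; the first class
    of the pair plays the role of 'positive'."""

    pair: tuple[MoodState, MoodState]
    se: float
    sp: float
    acc: float
    mcc: float
    p_value: float
    threshold: float
    orientation: str
    n_per_class: tuple[int, int]
    counts: ConfusionCounts = field(repr=False, default=None)  # type: ignore[assignment]


def _split_scores(samples: Iterable[ScoredSample], positive: MoodState,
                  negative: MoodState | None = None):
    pos, neg = [], []
    for s in samples:
        if s.state == positive:
            pos.append(s.score)
        elif negative is None or s.state == negative:
            neg.append(s.score)
    return np.asarray(pos, float), np.asarray(neg, float)


def _auc_high(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC of the 'high score -> positive' direction via the rank statistic."""
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def roc_curve(samples: Iterable[ScoredSample], positive: MoodState,
              negative: MoodState | None = None) -> RocCurve:
    """ROC curve over all distinct score thresholds plus an endpoint
    sentinel, oriented automatically (ties favour high_score_positive)."""
    samples = list(samples)
    positive = MoodState(positive)
    pos, neg = _split_scores(samples, positive, negative)
    if pos.size == 0 or neg.size == 0:
        raise ParameterError("roc_curve requires both classes to be present")
    auc_high = _auc_high(pos, neg)
    if auc_high >= 0.5:
        orientation, auc = "high_score_positive", auc_high
        thresholds = np.concatenate(([np.inf], np.unique(np.concatenate([pos, neg]))[::-1]))
        tpr = np.array([np.mean(pos >= t) for t in thresholds])
        fpr = np.array([np.mean(neg >= t) for t in thresholds])
    else:
        orientation, auc = "low_score_positive", 1.0 - auc_high
        thresholds = np.concatenate(([-np.inf], np.unique(np.concatenate([pos, neg]))))
        tpr = np.array([np.mean(pos <= t) for t in thresholds])
        fpr = np.array([np.mean(neg <= t) for t in thresholds])
    return RocCurve(thresholds, tpr, fpr, orientation, auc)


def threshold_nearest_01(curve: RocCurve) -> float:
    """Threshold of the ROC point nearest (0, 1) in Euclidean distance.

    Ties prefer the higher TPR, then the lower threshold.  The returned
    threshold is a sample score (the least extreme score still classified
    positive at the chosen point).
    """
    d2 = curve.fpr ** 2 + (1.0 - curve.tpr) ** 2
    order = sorted(range(len(d2)),
                   key=lambda i: (d2[i], -curve.tpr[i], curve.thresholds[i]))
    return float(curve.thresholds[order[0]])


def classify(scores: Iterable[float], threshold: float, orientation: str) -> np.ndarray:
    """Predicted positivity of each score under the threshold convention."""
    scores = np.asarray(list(scores), float)
    if orientation == "high_score_positive":
        return scores >= threshold
    if orientation == "low_score_positive":
        return scores <= threshold
    raise ParameterError(f"unknown orientation {orientation!r}")


def confusion_counts(samples: Iterable[ScoredSample], positive: MoodState,
                     threshold: float, orientation: str,
                     negative: MoodState | None = None) -> ConfusionCounts:
    pos, neg = _split_scores(samples, MoodState(positive), negative)
    pred_pos = classify(pos, threshold, orientation)
    pred_neg = classify(neg, threshold, orientation)
    return ConfusionCounts(tp=int(pred_pos.sum()), fn=int((~pred_pos).sum()),
                           fp=int(pred_neg.sum()), tn=int((~pred_neg).sum()))


def classification_metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, MCC) of a confusion matrix.

    Se = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total and
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); whenever a
    factor of the MCC denominator is zero the coefficient is defined as 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ParameterError("confusion matrix is empty")
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return float(se), float(sp), float(acc), float(mcc)


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n, n_a) group assignments.

    Ties are handled with midranks; 'as or more extreme' is measured by the
    distance of the rank-sum statistic from its permutation mean.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, na = pooled.size, a.size
    observed = ranks[:na].sum()
    mean = na * (n + 1) / 2
    dev = abs(observed - mean)
    hits = total = 0
    for combo in itertools.combinations(range(n), na):
        total += 1
        if abs(ranks[list(combo)].sum() - mean) >= dev - 1e-9:
            hits += 1
    return hits / total


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value for unpaired
    groups: exact enumeration when n_a + n_b <= 12, tie-corrected normal
    approximation otherwise."""
    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("rank_sum_test requires two non-empty groups")
    if a.size + b.size <= EXACT_RANKSUM_LIMIT:
        return float(_exact_rank_sum_p(a, b))
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


def evaluate_pair(samples: Iterable[ScoredSample],
                  pair: tuple[MoodState, MoodState]) -> ClassPairResult:
    """Full single-pair evaluation: ROC threshold at the nearest-(0,1)
    point, confusion metrics and the rank-sum p-value."""
    pos_state, neg_state = MoodState(pair[0]), MoodState(pair[1])
    samples = [s for s in samples if s.state in (pos_state, neg_state)]
    curve = roc_curve(samples, pos_state, neg_state)
    threshold = threshold_nearest_01(curve)
    counts = confusion_counts(samples, pos_state, threshold, curve.orientation,
                              neg_state)
    se, sp, acc, mcc = classification_metrics(counts)
    a, b = _split_scores(samples, pos_state, neg_state)
    p = rank_sum_test(a, b)
    return ClassPairResult(pair=(pos_state, neg_state), se=se, sp=sp, acc=acc,
                           mcc=mcc, p_value=p, threshold=threshold,
                           orientation=curve.orientation,
                           n_per_class=(a.size, b.size), counts=counts)


def loo_bootstrap(samples: Iterable[ScoredSample],
                  pair: tuple[MoodState, MoodState],
                  n_realisations: int = 1000,
                  seed: int = 0) -> tuple[float, float]:
    """Bootstrap leave-one-out accuracy: mean and SD over realisations.

    Each realisation removes one record per class uniformly at random
    (with replacement across realisations), re-derives the ROC threshold
    on the remainder, and classifies the two held-out records, giving a
    realisation accuracy in {0, 0.5, 1}.
    """
    if n_realisations < 1:
        raise ParameterError("n_realisations must be >= 1")
    pos_state, neg_state = MoodState(pair[0]), MoodState(pair[1])
    pos = [s for s in samples if s.state == pos_state]
    neg = [s for s in samples if s.state == neg_state]
    if len(pos) < 2 or len(neg) < 2:
        raise ParameterError("loo_bootstrap requires >= 2 samples per class")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    accs = np.empty(n_realisations)
    for i in range(n_realisations):
        ip = int(rng.integers(len(pos)))
        ineg = int(rng.integers(len(neg)))
        train = pos[:ip] + pos[ip + 1:] + neg[:ineg] + neg[ineg + 1:]
        curve = roc_curve(train, pos_state, neg_state)
        thr = threshold_nearest_01(curve)
        hit_pos = bool(classify([pos[ip].score], thr, curve.orientation)[0])
        hit_neg = not bool(classify([neg[ineg].score], thr, curve.orientation)[0])
        accs[i] = (hit_pos + hit_neg) / 2.0
    return float(accs.mean()), float(accs.std())


def gamma_grid_search(epochs: Iterable[Epoch],
                      pair: tuple[MoodState, MoodState],
                      m: int, delta: float,
                      grid: Sequence[float]) -> pd.DataFrame:
    """One full single-pair evaluation per gamma value of the grid.

    Returns a table ordered by gamma with columns gamma, m, delta, se, sp,
    acc, mcc, p_value, threshold, n_a, n_b.
    """
    grid = list(grid)
    if not grid:
        raise ParameterError("gamma grid must be non-empty")
    bad = [g for g in grid if not g > delta]
    if bad:
        raise ParameterError(f"grid values {bad} violate gamma > delta ({delta})")
    epochs = list(epochs)
    rows = []
    for gamma in sorted(grid):
        params = SlopEnParams(m=m, gamma=gamma, delta=delta)
        scored = [ScoredSample(e.source_id, e.state, slope_entropy(e.values, params).value)
                  for e in epochs]
        res = evaluate_pair(scored, pair)
        rows.append({"gamma": gamma, "m": m, "delta": delta, "se": res.se,
                     "sp": res.sp, "acc": res.acc, "mcc": res.mcc,
                     "p_value": res.p_value, "threshold": res.threshold,
                     "n_a": res.n_per_class[0], "n_b": res.n_per_class[1]})
    return pd.DataFrame(rows)
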