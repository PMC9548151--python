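"""Evaluation metrics: ROC-AUC, average precision, specificity at fixed
sensitivity, pooled-score compatibility analysis, score histograms.

ROC-AUC equals the Mann-Whitney U statistic normalised by n_pos * n_neg
with ties counted one half; average precision is the step-wise summary of
the precision-recall curve.  Both delegate to scikit-learn, which uses
exactly those conventions; the test suite cross-checks them against
independent brute-force implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass(frozen=True)
class ScoreSet:
    """Parallel prediction scores in [0,1] and binary labels."""

    scores: np.ndarray
    labels: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if s.shape != y.shape or s.ndim != 1:
            raise ValueError("scores and labels must be matching 1-D arrays")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((1 - self.labels).sum())

    def require_both_classes(self) -> None:
        if self.n_pos == 0 or self.n_neg == 0:
            raise ValueError("both classes must be present")


@dataclass(frozen=True)
class EvalResult:
    """Metric bundle for one score set."""

    auc: float
    average_precision: float
    specificity_at_sensitivity: float
    sensitivity_level: float
    threshold: float
    n_pos: int
    n_neg: int


def roc_auc(score_set: ScoreSet) -> float:
    """Area under the ROC curve (ties counted half)."""
    score_set.require_both_classes()
    return float(roc_auc_score(score_set.labels, score_set.scores))


def average_precision(score_set: ScoreSet) -> float:
    """Step-wise average precision: sum of (delta recall) x precision."""
    score_set.require_both_classes()
    return float(average_precision_score(score_set.labels, score_set.scores))


def specificity_at_sensitivity(
    score_set: ScoreSet, sensitivity: float = 0.95
) -> tuple[float, float]:
    """Specificity at the most permissive threshold keeping >= the target
    sensitivity.

    A variant is called pathogenic when score >= threshold.  The threshold
    is the largest observed score for which sensitivity (fraction of
    positives called) is at least ``sensitivity``; specificity is the
    fraction of negatives strictly below it.  Only observed scores are used
    as candidate thresholds (no interpolation).
    """
    score_set.require_both_classes()
    s, y = score_set.scores, score_set.labels
    pos = s[y == 1]
    neg = s[y == 0]
    candidates = np.unique(s)[::-1]  # descending
    for t in candidates:
        sens = np.mean(pos >= t)
        if sens >= sensitivity:
            spec = float(np.mean(neg < t))
            return spec, float(t)
    # unreachable: the minimum score always yields sensitivity 1
    t = candidates[-1]
    return float(np.mean(neg < t)), float(t)


def evaluate(score_set: ScoreSet, sensitivity: float = 0.95) -> EvalResult:
    spec, thr = specificity_at_sensitivity(score_set, sensitivity)
    return EvalResult(
        auc=roc_auc(score_set),
        average_precision=average_precision(score_set),
        specificity_at_sensitivity=spec,
        sensitivity_level=sensitivity,
        threshold=thr,
        n_pos=score_set.n_pos,
        n_neg=score_set.n_neg,
    )


@dataclass(frozen=True)
class PooledAucResult:
    pooled_auc: float
    auc_a: float
    auc_b: float
    sample_n: int


def pooled_auc(
    set_a: ScoreSet, set_b: ScoreSet, sample_n: int, seed: int = 0
) -> PooledAucResult:
    """Compatibility analysis: AUC of equal-size samples pooled across sets.

    If two score sets are compatible (similar scores convey similar
    pathogenicity probability), the pooled AUC is close to both individual
    AUCs.
    """
    if sample_n > min(len(set_a.scores), len(set_b.scores)):
        raise ValueError("sample_n exceeds the size of a score set")
    rng = np.random.default_rng(seed)
    ia = rng.choice(len(set_a.scores), size=sample_n, replace=False)
    ib = rng.choice(len(set_b.scores), size=sample_n, replace=False)
    pooled = ScoreSet(
        scores=np.concatenate([set_a.scores[ia], set_b.scores[ib]]),
        labels=np.concatenate([set_a.labels[ia], set_b.labels[ib]]),
        source="pooled",
    )
    return PooledAucResult(
        pooled_auc=roc_auc(pooled),
        auc_a=roc_auc(set_a),
        auc_b=roc_auc(set_b),
        sample_n=sample_n,
    )


@dataclass(frozen=True)
class ScoreHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    low_high_ratio: float  # lowest-bin mass over highest-bin mass


def score_histogram(scores: np.ndarray, n_bins: int = 10) -> ScoreHistogram:
    """Equal-width histogram over [0,1] with the extreme-bin mass ratio."""
    s = np.asarray(scores, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0,1]")
    counts, edges = np.histogram(s, bins=n_bins, range=(0.0, 1.0))
    hi = counts[-1]
    ratio = float(counts[0] / hi) if hi > 0 else float("inf")
    return ScoreHistogram(bin_edges=edges, counts=counts, low_high_ratio=ratio)
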