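"""Evaluation metrics against independent brute-force implementations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flankrnn.metrics import (
    ScoreSet,
    average_precision,
    evaluate,
    pooled_auc,
    roc_auc,
    score_histogram,
    specificity_at_sensitivity,
)

# ---------------------------------------------------------------------------
# brute-force references
# ---------------------------------------------------------------------------

def bf_auc(scores, labels):
    """Pair counting: correctly ordered positive-negative pairs, ties half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def bf_ap(scores, labels):
    """Step-wise AP over descending unique thresholds."""
    total_pos = labels.sum()
    ap, prev_recall = 0.0, 0.0
    for t in np.unique(scores)[::-1]:
        called = scores >= t
        precision = labels[called].sum() / called.sum()
        recall = labels[called].sum() / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def bf_spec_at_sens(scores, labels, sensitivity):
    """Exhaustive threshold sweep over observed scores."""
    pos, neg = scores[labels == 1], scores[labels == 0]
    best = None
    for t in np.unique(scores)[::-1]:
        if np.mean(pos >= t) >= sensitivity:
            best = (float(np.mean(neg < t)), float(t))
            break
    return best


def random_instance(rng, n_max=30, tie_prone=False):
    while True:
        n = int(rng.integers(4, n_max + 1))
        labels = rng.integers(0, 2, n)
        if 0 < labels.sum() < n:
            break
    scores = rng.random(n)
    if tie_prone:
        scores = np.round(scores, 1)
    return scores, labels


# ---------------------------------------------------------------------------
# examples
# ---------------------------------------------------------------------------

class TestRocAuc:
    def test_perfect_separation_is_one(self):
        s = ScoreSet(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert roc_auc(s) == 1.0

    def test_all_ties_is_half(self):
        s = ScoreSet(np.full(10, 0.5), np.array([1] * 5 + [0] * 5))
        assert roc_auc(s) == 0.5

    def test_three_of_four_pairs_ordered(self):
        s = ScoreSet(np.array([0.9, 0.8, 0.3, 0.2]), np.array([1, 0, 1, 0]))
        assert roc_auc(s) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(ScoreSet(np.array([0.1, 0.2]), np.array([1, 1])))


class TestAveragePrecision:
    def test_perfect_ranking_is_one(self):
        s = ScoreSet(np.array([0.9, 0.8, 0.2, 0.1, 0.05]), np.array([1, 1, 0, 0, 0]))
        assert average_precision(s) == 1.0

    def test_hand_computed_three_point_case(self):
        s = ScoreSet(np.array([0.9, 0.8, 0.3]), np.array([1, 0, 1]))
        assert average_precision(s) == pytest.approx(5 / 6)

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(0)
        n = 20_000
        labels = (rng.random(n) < 0.3).astype(int)
        s = ScoreSet(rng.random(n), labels)
        assert average_precision(s) == pytest.approx(0.3, abs=0.02)


class TestSpecificityAtSensitivity:
    def test_perfect_separation_full_specificity(self):
        s = ScoreSet(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        spec, thr = specificity_at_sensitivity(s)
        assert spec == 1.0 and thr == 0.8

    def test_all_equal_scores_zero_specificity(self):
        s = ScoreSet(np.full(8, 0.4), np.array([1] * 4 + [0] * 4))
        spec, _ = specificity_at_sensitivity(s)
        assert spec == 0.0

    def test_19_of_20_positives_case(self):
        scores = np.array([0.9] * 19 + [0.1] + [0.5] * 10)
        labels = np.array([1] * 20 + [0] * 10)
        spec, thr = specificity_at_sensitivity(ScoreSet(scores, labels), 0.95)
        assert thr == 0.9 and spec == 1.0

    def test_non_increasing_in_requested_sensitivity(self):
        rng = np.random.default_rng(1)
        scores, labels = random_instance(rng)
        s = ScoreSet(scores, labels)
        specs = [specificity_at_sensitivity(s, lv)[0]
                 for lv in (0.5, 0.7, 0.9, 0.95, 1.0)]
        assert all(a >= b for a, b in zip(specs, specs[1:]))


class TestBruteForceAgreement:
    def test_all_metrics_match_brute_force_on_200_random_instances(self):
        rng = np.random.default_rng(123)
        for k in range(200):
            scores, labels = random_instance(rng, tie_prone=k % 3 == 0)
            s = ScoreSet(scores, labels)
            assert abs(roc_auc(s) - bf_auc(scores, labels)) < 1e-12
            assert abs(average_precision(s) - bf_ap(scores, labels)) < 1e-12
            got = specificity_at_sensitivity(s, 0.95)
            assert got == pytest.approx(bf_spec_at_sens(scores, labels, 0.95))


class TestMetricProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_auc_complement_identity(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_instance(rng)
        a = roc_auc(ScoreSet(scores, labels))
        b = roc_auc(ScoreSet(1 - scores, labels))
        assert a + b == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores, labels = random_instance(rng)
        a = roc_auc(ScoreSet(scores, labels))
        transformed = 1 / (1 + np.exp(-(3 * scores + 1)))  # strictly monotone
        b = roc_auc(ScoreSet(transformed, labels))
        assert a == pytest.approx(b, abs=1e-12)


class TestPooledAuc:
    def _make_set(self, rng, n, shift=2.2, sigma=1.05):
        labels = rng.integers(0, 2, n)
        z = shift * labels + rng.normal(0, sigma, n)
        return ScoreSet(1 / (1 + np.exp(-z + shift / 2)), labels)

    def test_identical_sets_pool_to_their_own_auc(self):
        rng = np.random.default_rng(2)
        s = self._make_set(rng, 400)
        r = pooled_auc(s, s, sample_n=400, seed=0)
        assert r.pooled_auc == pytest.approx(r.auc_a)

    def test_shared_boundary_perfect_sets_pool_to_one(self):
        a = ScoreSet(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        b = ScoreSet(np.array([0.99, 0.7, 0.3, 0.05]), np.array([1, 1, 0, 0]))
        r = pooled_auc(a, b, sample_n=4, seed=0)
        assert r.pooled_auc == 1.0

    def test_compatible_sets_pool_within_002_of_both(self):
        rng = np.random.default_rng(3)
        a = self._make_set(rng, 3000)
        b = self._make_set(rng, 3000)
        r = pooled_auc(a, b, sample_n=828, seed=1)
        # oracle: direct AUC on the explicitly pooled sample
        assert abs(r.pooled_auc - r.auc_a) < 0.02
        assert abs(r.pooled_auc - r.auc_b) < 0.02

    def test_oversized_sample_rejected(self):
        a = ScoreSet(np.array([0.9, 0.1]), np.array([1, 0]))
        with pytest.raises(ValueError):
            pooled_auc(a, a, sample_n=3, seed=0)


class TestScoreHistogram:
    def test_all_zero_scores_in_first_bin(self):
        h = score_histogram(np.zeros(50), n_bins=10)
        assert h.counts[0] == 50 and h.counts[1:].sum() == 0

    def test_uniform_scores_near_equal_bins(self):
        rng = np.random.default_rng(4)
        h = score_histogram(rng.random(100_000), n_bins=10)
        assert np.all(np.abs(h.counts - 10_000) < 500)

    def test_four_to_one_extreme_mixture_ratio(self):
        rng = np.random.default_rng(5)
        low = rng.uniform(0, 0.05, 8000)
        high = rng.uniform(0.95, 1.0, 2000)
        h = score_histogram(np.concatenate([low, high]), n_bins=10)
        assert h.low_high_ratio == pytest.approx(4.0, rel=0.05)

    def test_eval_bundle_fields_in_unit_interval(self):
        rng = np.random.default_rng(6)
        scores, labels = random_instance(rng)
        e = evaluate(ScoreSet(scores, labels))
        for v in (e.auc, e.average_precision, e.specificity_at_sensitivity):
            assert 0.0 <= v <= 1.0
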