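"""Metric oracles (brute-force concordance, exact Shapley enumeration),
bootstrap behavior, and the cohort frequency-deviation statistic."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepsiswatch.ehr import Episode, Observation
from sepsiswatch.evaluation import (
    MetricError,
    auprc,
    auroc,
    bootstrap_ci,
    brier,
    confusion_at,
    indicator_frequency_deviation,
    shapley_attributions,
    youden,
    youden_optimal_threshold,
)


def _bruteforce_auroc(scores, labels):
    """Exhaustive pairwise concordance with ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = np.round(rng.uniform(0, 1, 12), 2)  # rounding forces ties
            labels = np.array([0] * 6 + [1] * 6)
            rng.shuffle(labels)
            assert auroc(scores, labels) == pytest.approx(
                _bruteforce_auroc(scores, labels), abs=1e-12
            )

    def test_single_class_errors(self):
        with pytest.raises(MetricError):
            auroc([0.1, 0.9], [1, 1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, width=32), min_size=4, max_size=30))
    def test_mann_whitney_identity(self, scores):
        """AUROC equals the rank-sum transform for arbitrary scores."""
        labels = np.tile([0, 1], len(scores) // 2 + 1)[: len(scores)]
        if labels.sum() in (0, len(labels)):
            return
        from scipy.stats import rankdata

        r = rankdata(scores)
        n1 = labels.sum()
        n0 = len(labels) - n1
        u = r[np.asarray(labels) == 1].sum() - n1 * (n1 + 1) / 2
        assert auroc(scores, labels) == pytest.approx(u / (n0 * n1), abs=1e-12)


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_single_positive_ranked_first(self):
        scores = [0.9] + [0.1] * 9
        labels = [1] + [0] * 9
        assert auprc(scores, labels) == 1.0

    def test_random_scores_near_prevalence(self):
        rng = np.random.default_rng(1)
        n, pi = 4000, 0.25
        labels = (rng.uniform(size=n) < pi).astype(int)
        scores = rng.uniform(size=n)
        assert auprc(scores, labels) == pytest.approx(pi, abs=0.04)

    def test_no_positives_errors(self):
        with pytest.raises(MetricError):
            auprc([0.5, 0.6], [0, 0])


class TestConfusion:
    def test_threshold_zero_full_sensitivity(self):
        s, p, _ = confusion_at([0.2, 0.8], [1, 0], 0.0)
        assert s == 1.0

    def test_threshold_above_max(self):
        s, p, _ = confusion_at([0.2, 0.8], [1, 0], 0.9)
        assert s == 0.0 and p == 1.0

    def test_hand_counts(self):
        """TP=88 FN=12 TN=84 FP=16 → (0.88, 0.84, 0.86)."""
        scores = [0.9] * 88 + [0.1] * 12 + [0.1] * 84 + [0.9] * 16
        labels = [1] * 100 + [0] * 100
        s, p, a = confusion_at(scores, labels, 0.5)
        assert (s, p, a) == (0.88, 0.84, 0.86)

    def test_boundary_score_counts_positive(self):
        s, _, _ = confusion_at([0.5], [1], 0.5)
        assert s == 1.0


class TestYouden:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [(0.818, 0.828, 0.646), (0.777, 0.785, 0.562), (0.807, 0.816, 0.623), (1.0, 1.0, 1.0)],
    )
    def test_reported_operating_points(self, sens, spec, expected):
        assert round(youden(sens, spec), 3) == expected

    def test_consistency_with_confusion(self):
        """J recomputed from the table's own sensitivity/specificity
        reproduces the stored J exactly."""
        rng = np.random.default_rng(2)
        scores = rng.uniform(0, 1, 200)
        labels = rng.integers(0, 2, 200)
        thr = youden_optimal_threshold(scores, labels)
        s, p, _ = confusion_at(scores, labels, thr)
        assert youden(s, p) == s + p - 1.0


class TestBrier:
    def test_perfect_confident(self):
        assert brier([0.0, 1.0], [0, 1]) == 0.0

    def test_all_half(self):
        assert brier([0.5] * 4, [0, 1, 0, 1]) == 0.25

    def test_hand_arithmetic(self):
        scores = [0.9, 0.2, 0.6, 0.4]
        labels = [1, 0, 0, 1]
        expected = np.mean([(0.9 - 1) ** 2, 0.2**2, 0.6**2, (0.4 - 1) ** 2])
        assert brier(scores, labels) == pytest.approx(expected, abs=1e-12)


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        fn = lambda s, l: 0.75
        point, lo, hi = bootstrap_ci(fn, np.zeros(20), np.tile([0, 1], 10), b=200, seed=0)
        assert point == lo == hi == 0.75

    def test_same_seed_identical(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        a = bootstrap_ci(auroc, scores, labels, b=300, seed=5)
        b = bootstrap_ci(auroc, scores, labels, b=300, seed=5)
        assert a == b

    def test_interval_brackets_point(self):
        rng = np.random.default_rng(4)
        labels = np.tile([0, 1], 40)
        scores = rng.uniform(0, 1, 80) + 0.4 * labels
        point, lo, hi = bootstrap_ci(auroc, scores, labels, b=500, seed=1)
        assert lo <= point <= hi

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(auroc, np.zeros(4), np.array([0, 1, 0, 1]), b=50)


class TestShapley:
    def test_constant_model_all_zero(self):
        f = lambda X: np.full(len(X), 0.3)
        rep = shapley_attributions(f, np.zeros((3, 4)), np.ones((5, 4)))
        np.testing.assert_allclose(rep.phi, 0.0, atol=1e-12)

    def test_stump_matches_exhaustive_enumeration(self):
        """Single-split stump: exact attributions equal an independently
        written subset-enumeration Shapley formula."""
        f = lambda X: np.where(X[:, 0] > 0, 2.0, 0.0)
        bg = np.array([[-1.0, 5.0], [1.0, -3.0], [-1.0, 2.0], [1.0, 7.0]])
        x = np.array([[1.0, 0.0]])
        rep = shapley_attributions(f, x, bg, ["x0", "x1"])

        # independent oracle: phi_i = sum_S w(S) [v(S+i) - v(S)]
        from itertools import combinations
        from math import factorial

        def v(subset):
            data = bg.copy()
            for j in subset:
                data[:, j] = x[0, j]
            return float(np.mean(f(data)))

        m = 2
        expected = []
        for j in range(m):
            others = [k for k in range(m) if k != j]
            tot = 0.0
            for size in range(m):
                for sub in combinations(others, size):
                    w = factorial(len(sub)) * factorial(m - len(sub) - 1) / factorial(m)
                    tot += w * (v(sub + (j,)) - v(sub))
            expected.append(tot)
        np.testing.assert_allclose(rep.phi[0], expected, atol=1e-12)
        assert rep.local_accuracy_error() < 1e-12

    def test_duplicated_features_symmetric(self):
        f = lambda X: X[:, 0] + X[:, 1]
        rng = np.random.default_rng(5)
        bg = rng.normal(0, 1, (10, 2))
        x = rng.normal(0, 1, (5, 2))
        x[:, 1] = x[:, 0]
        bg[:, 1] = bg[:, 0]
        rep = shapley_attributions(f, x, bg)
        np.testing.assert_allclose(rep.mean_abs[0], rep.mean_abs[1], atol=1e-10)

    def test_permutation_path_local_accuracy(self):
        rng = np.random.default_rng(6)
        w = rng.normal(0, 1, 15)
        f = lambda X: X @ w
        bg = rng.normal(0, 1, (12, 15))
        x = rng.normal(0, 1, (3, 15))
        rep = shapley_attributions(f, x, bg, n_permutations=20, seed=0)
        assert rep.local_accuracy_error() < 1e-10

    def test_tree_model_local_accuracy(self):
        """Exact local accuracy on a real boosted model's probabilities."""
        from sepsiswatch.models import BoostedConfig, train_boosted

        rng = np.random.default_rng(7)
        n = 120
        y = rng.integers(0, 2, n)
        x = rng.normal(0, 1, (n, 5))
        x[:, 0] += y
        model, _ = train_boosted(
            x, y, BoostedConfig(learning_rates=(0.1,), max_depths=(3,), n_rounds_max=30)
        )
        f = lambda data: model.predict_proba(data)[:, 1]
        rep = shapley_attributions(f, x[:3], x[:30], [f"f{j}" for j in range(5)])
        assert rep.local_accuracy_error() < 1e-6
        assert rep.ranking()[0] == "f0"


class TestFrequencyDeviation:
    def _cohort(self, counts_by_var, n_ep=2, window=2.0):
        eps = []
        for i in range(n_ep):
            obs = []
            for var, per_ep in counts_by_var.items():
                obs.extend(
                    Observation(window * (k + 1) / (per_ep + 1), var, 1.0)
                    for k in range(per_ep)
                )
            eps.append(
                Episode(f"e{i}", 2.0, "male", 12.0, "control",
                        anchor_time_h=24.0, observations=obs)
            )
        return eps

    def test_identical_cohorts_zero(self):
        a = self._cohort({"HR": 2})
        table = indicator_frequency_deviation(a, a, (2.0,))
        assert (table.values == 0).all()

    def test_direct_counting(self):
        a = self._cohort({"HR": 2})
        b = self._cohort({"HR": 1})
        table = indicator_frequency_deviation(a, b, (2.0,))
        assert table.loc["HR", "2h"] == pytest.approx(1.0)

    def test_antisymmetric(self):
        rngA = self._cohort({"HR": 3, "LAC": 1})
        rngB = self._cohort({"HR": 1, "LAC": 2})
        t_ab = indicator_frequency_deviation(rngA, rngB, (2.0, 6.0))
        t_ba = indicator_frequency_deviation(rngB, rngA, (2.0, 6.0))
        np.testing.assert_allclose(t_ab.values, -t_ba.values)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            indicator_frequency_deviation([], self._cohort({"HR": 1}))
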