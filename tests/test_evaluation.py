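"""Stratified splits, classification metrics, the repeated-evaluation
protocol, and the gated paired comparison."""

import numpy as np
import pytest
from scipy import stats

from adafnn import (
    compare_configurations,
    one_vs_rest_auc,
    repeated_evaluation,
    stratified_split,
    weighted_f1,
)
from adafnn.evaluation import leakage_overlap


def brute_force_weighted_f1(y_true, y_pred):
    total = 0.0
    n = len(y_true)
    for c in range(3):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        n_pred = sum(1 for p in y_pred if p == c)
        n_true = sum(1 for t in y_true if t == c)
        prec = tp / n_pred if n_pred else 0.0
        rec = tp / n_true if n_true else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        total += (n_true / n) * f1
    return total


def brute_force_ovr_auc(y_true, probs):
    aucs = []
    for c in range(3):
        pos = [p for p, t in zip(probs[:, c], y_true) if t == c]
        neg = [p for p, t in zip(probs[:, c], y_true) if t != c]
        if not pos or not neg:
            continue
        wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
                   for a in pos for b in neg)
        aucs.append(wins / (len(pos) * len(neg)))
    return float(np.mean(aucs))


class TestStratifiedSplit:
    def test_per_class_rounding(self):
        labels = np.repeat([0, 1, 2], [20, 10, 10])
        tr, te = stratified_split(labels, 0.7, 0)
        counts = np.bincount(labels[tr], minlength=3)
        np.testing.assert_array_equal(counts, [14, 7, 7])

    def test_disjoint_and_exhaustive(self, rng):
        labels = rng.integers(0, 3, size=100)
        tr, te = stratified_split(labels, 0.7, 5)
        assert np.intersect1d(tr, te).size == 0
        assert np.union1d(tr, te).size == 100

    def test_full_fraction_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 0, 1, 1, 2, 2]), 1.0, 0)

    def test_seed_determinism_and_variation(self):
        labels = np.repeat([0, 1, 2], [30, 20, 12])
        tr1, _ = stratified_split(labels, 0.7, 3)
        tr2, _ = stratified_split(labels, 0.7, 3)
        tr3, _ = stratified_split(labels, 0.7, 4)
        np.testing.assert_array_equal(tr1, tr2)
        assert not np.array_equal(tr1, tr3)
        # same class proportions regardless of seed
        assert np.bincount(labels[tr1]).tolist() == np.bincount(labels[tr3]).tolist()

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 0, 1, 1, 2]), 0.7, 0)


class TestWeightedF1:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        assert weighted_f1(y, y) == pytest.approx(1.0)

    def test_degenerate_all_majority_predictor(self):
        y_true = np.array([0, 1, 2] * 4)
        y_pred = np.zeros(12, dtype=int)
        # F1 for class 0: precision 1/3, recall 1 -> 0.5; others 0
        assert weighted_f1(y_true, y_pred) == pytest.approx(1 / 6)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            n = rng.integers(5, 40)
            yt = rng.integers(0, 3, size=n)
            yp = rng.integers(0, 3, size=n)
            assert weighted_f1(yt, yp) == pytest.approx(
                brute_force_weighted_f1(yt, yp), abs=1e-12
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_f1(np.array([]), np.array([]))


class TestOneVsRestAuc:
    def test_perfectly_ordered_probabilities(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        probs = np.eye(3)[y] * 0.8 + 0.1
        probs /= probs.sum(axis=1, keepdims=True)
        assert one_vs_rest_auc(y, probs) == pytest.approx(1.0)

    def test_label_independent_probabilities_near_half(self):
        rng = np.random.default_rng(0)
        n = 3000
        y = rng.integers(0, 3, size=n)
        probs = rng.dirichlet(np.ones(3), size=n)
        assert abs(one_vs_rest_auc(y, probs) - 0.5) < 0.03

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(30):
            n = 50
            y = rng.integers(0, 3, size=n)
            if len(np.unique(y)) < 3:
                continue
            probs = rng.dirichlet(np.ones(3), size=n)
            assert one_vs_rest_auc(y, probs) == pytest.approx(
                brute_force_ovr_auc(y, probs), abs=1e-12
            )

    def test_absent_class_skipped_with_warning(self):
        y = np.array([0, 0, 1, 1])
        probs = np.full((4, 3), 1 / 3)
        with pytest.warns(UserWarning):
            val = one_vs_rest_auc(y, probs)
        assert val == pytest.approx(0.5)


class _MajorityModel:
    """Always predicts the training-set majority class."""

    def __init__(self, label):
        self.label = label

    def predict(self, ts):
        probs = np.zeros((ts.n, 3))
        probs[:, self.label] = 0.9
        probs += 0.1 / 3
        probs /= probs.sum(axis=1, keepdims=True)
        return np.full(ts.n, self.label), probs


class TestRepeatedEvaluation:
    def _majority_fit(self, train_set, seed):
        return _MajorityModel(int(np.bincount(train_set.labels).argmax()))

    def test_single_run_has_nan_sd(self, tiny_trials):
        ts, _ = tiny_trials
        res = repeated_evaluation(ts, fit=self._majority_fit, n_runs=1,
                                  base_seed=0)
        assert np.isnan(res.summary["accuracy_sd"])

    def test_majority_model_accuracy_matches_prevalence(self):
        # stratification preserves prevalence: a majority-class dummy scores
        # ~120/222 on every 70/30 split of 120/60/42-imbalanced data
        from adafnn.synthetic import SyntheticSpec, generate_trials
        ts, _ = generate_trials(SyntheticSpec(J=16, F=1,
                                              informative_channels=(0,)))
        res = repeated_evaluation(ts, fit=self._majority_fit, n_runs=20,
                                  base_seed=0)
        assert res.summary["accuracy_mean"] == pytest.approx(120 / 222, abs=0.02)

    def test_no_leakage_and_determinism(self, tiny_trials):
        ts, _ = tiny_trials
        r1 = repeated_evaluation(ts, fit=self._majority_fit, n_runs=10,
                                 base_seed=3)
        r2 = repeated_evaluation(ts, fit=self._majority_fit, n_runs=10,
                                 base_seed=3)
        assert leakage_overlap(r1) == 0
        assert r1.summary == r2.summary

    def test_summary_within_per_run_range(self, tiny_trials):
        ts, _ = tiny_trials
        res = repeated_evaluation(ts, fit=self._majority_fit, n_runs=10,
                                  base_seed=1)
        accs = res.per_run["accuracy"]
        assert accs.min() <= res.summary["accuracy_mean"] <= accs.max()
        assert res.summary["accuracy_sd"] >= 0


class TestCompareConfigurations:
    def test_constant_shift_on_normal_data_rejected_by_paired_t(self, rng):
        a = rng.normal(0.6, 0.05, size=100)
        b = a + 0.05
        res = compare_configurations(a, b)
        assert res.test_used == "paired_t"
        assert res.p_value < 1e-10
        assert res.significant

    def test_identical_vectors_fail_to_reject(self, rng):
        a = rng.normal(0.6, 0.05, size=100)
        res = compare_configurations(a, a)
        assert res.test_used == "degenerate"
        assert not res.significant

    def test_heavy_tailed_contamination_takes_wilcoxon_branch(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.6, 0.05, size=100)
        b = a + stats.cauchy.rvs(scale=0.05, size=100,
                                 random_state=np.random.default_rng(43))
        res = compare_configurations(a, b)
        assert res.test_used == "wilcoxon_signed_rank"

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_configurations(np.ones(10), np.ones(9))


class TestGroupedSplit:
    def test_groups_never_straddle_the_split(self, rng):
        from adafnn.evaluation import grouped_split
        groups = np.repeat(np.arange(12), 6)
        labels = rng.integers(0, 3, size=72)
        tr, te = grouped_split(labels, groups, 0.7, seed=1)
        assert set(groups[tr]).isdisjoint(set(groups[te]))
        assert np.union1d(tr, te).size == 72
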