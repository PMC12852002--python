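"""AUC, metric panel, DeLong test, confidence intervals, subject splits."""

import numpy as np
import pytest
from scipy import stats

from oracles import auc_brute, auc_vectorized
from pcgstack import (auc_ci, binary_metrics, delong_test, roc_auc,
                      subject_stratified_split)
from pcgstack.errors import InvalidInputError


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([-1, -1, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), y) == 0.0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(10, 40)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # with ties
            labels = rng.choice([-1, 1], size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert np.isclose(roc_auc(scores, labels),
                              auc_brute(scores, labels), atol=1e-12)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(2000)
        labels = rng.choice([-1, 1], size=2000)
        assert abs(roc_auc(scores, labels) - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestBinaryMetrics:
    def test_hand_confusion_matrix(self):
        # TP=3 FP=1 FN=1 TN=5 at threshold 0.5
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.2, 0.1, 0.1])
        labels = np.array([1, 1, 1, -1, 1, -1, -1, -1, -1, -1])
        m = binary_metrics(scores, labels)
        assert np.isclose(m.sensitivity, 0.75)
        assert np.isclose(m.specificity, 5 / 6)
        assert np.isclose(m.precision, 0.75)
        assert np.isclose(m.accuracy, 0.8)
        assert np.isclose(m.f1, 0.75)

    def test_all_correct_gives_ones(self):
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array([1, 1, -1, -1])
        m = binary_metrics(scores, labels)
        for v in (m.auc, m.accuracy, m.sensitivity, m.specificity,
                  m.precision, m.f1):
            assert v == 1.0

    def test_f1_identity_on_random_confusions(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = 60
            scores = rng.random(n)
            labels = rng.choice([-1, 1], size=n)
            if len(np.unique(labels)) < 2:
                continue
            m = binary_metrics(scores, labels)
            if m.precision + m.sensitivity > 0:
                assert np.isclose(
                    m.f1, 2 * m.precision * m.sensitivity
                    / (m.precision + m.sensitivity))

    def test_no_predicted_positives_flagged(self):
        m = binary_metrics(np.array([0.1, 0.2, 0.3]), np.array([1, -1, -1]))
        assert m.precision == 0.0 and not m.precision_defined


class TestDeLong:
    def _correlated_scores(self, rng, n=50, informative=(1.0, 1.0)):
        y = np.repeat([-1, 1], n // 2)
        base = rng.normal(size=n)
        a = base * informative[0] + rng.normal(size=n) * 0.5 + (y == 1) * 1.0
        b = base * informative[1] + rng.normal(size=n) * 0.5 + (y == 1) * 1.0
        return a, b, y

    def test_identical_scores_give_p_one(self):
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        y = np.array([-1, 1, -1, 1, 1, -1])
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b, y = self._correlated_scores(rng, informative=(1.0, 0.2))
        z1, p1 = delong_test(a, b, y)
        z2, p2 = delong_test(b, a, y)
        assert np.isclose(z1, -z2) and np.isclose(p1, p2)

    def test_matches_paired_bootstrap_oracle(self):
        """DeLong p within 0.03 of a 10,000-rep paired-bootstrap p at n=50."""
        rng = np.random.default_rng(4)
        a, b, y = self._correlated_scores(rng, informative=(1.0, 0.4))
        _, p_delong = delong_test(a, b, y)
        reps = 10_000
        n = len(y)
        deltas = np.empty(reps)
        boot_rng = np.random.default_rng(5)
        for r in range(reps):
            idx = boot_rng.integers(0, n, size=n)
            yy = y[idx]
            if len(np.unique(yy)) < 2:
                deltas[r] = 0.0
                continue
            deltas[r] = auc_vectorized(a[idx], yy) - auc_vectorized(b[idx], yy)
        # two-sided bootstrap p: how often the resampled difference crosses 0
        p_boot = 2 * min((deltas <= 0).mean(), (deltas >= 0).mean())
        p_boot = min(p_boot, 1.0)
        assert abs(p_delong - p_boot) < 0.03

    def test_null_p_values_approximately_uniform(self):
        """Under the null (equally informative correlated scores) the DeLong
        p-value distribution is near-uniform (KS < 0.1 over 500 sims)."""
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(500):
            a, b, y = self._correlated_scores(rng, n=60)
            _, p = delong_test(a, b, y)
            pvals.append(p)
        ks = stats.ks_1samp(pvals, stats.uniform.cdf).statistic
        assert ks < 0.1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            delong_test(np.zeros(5), np.zeros(6), np.array([1, -1, 1, -1, 1]))


class TestAucCI:
    def test_separable_data_upper_bound_clipped_to_one(self):
        y = np.array([-1, -1, 1, 1])
        lo, hi = auc_ci(np.array([0.1, 0.2, 0.8, 0.9]), y)
        assert hi == 1.0

    def test_interval_contains_point_auc(self):
        rng = np.random.default_rng(7)
        y = np.repeat([-1, 1], 30)
        s = rng.normal(size=60) + (y == 1) * 0.8
        lo, hi = auc_ci(s, y)
        a = roc_auc(s, y)
        assert lo <= a <= hi

    def test_coverage_near_nominal(self):
        """95% CI coverage on binormal data with true AUC 0.8, n=100."""
        mu = np.sqrt(2) * stats.norm.ppf(0.8)  # binormal model: AUC = 0.8
        rng = np.random.default_rng(8)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = np.repeat([-1, 1], 50)
            s = rng.normal(size=100) + (y == 1) * mu
            lo, hi = auc_ci(s, y)
            hits += lo <= 0.8 <= hi
        assert abs(hits / n_sim - 0.95) <= 0.025


class TestSubjectSplit:
    def _ids(self, n_per_class, segs=3):
        subs, labels = [], []
        for cls in (-1, 1):
            for s in range(n_per_class):
                sid = f"c{cls}_{s}"
                subs += [sid] * segs
                labels += [cls] * segs
        return np.array(subs), np.array(labels)

    def test_no_subject_in_both_partitions(self):
        subs, labels = self._ids(15)
        plan = subject_stratified_split(subs, labels, seed=0)
        assert not (plan.train_subjects & plan.test_subjects)

    def test_stratified_subject_counts(self):
        subs, labels = self._ids(20)
        plan = subject_stratified_split(subs, labels, ratio=0.7, seed=1)
        for cls in (-1, 1):
            train_c = sum(1 for s in plan.train_subjects
                          if s.startswith(f"c{cls}_"))
            assert train_c == 14

    def test_deterministic_given_seed(self):
        subs, labels = self._ids(10)
        p1 = subject_stratified_split(subs, labels, seed=5)
        p2 = subject_stratified_split(subs, labels, seed=5)
        assert p1.train_subjects == p2.train_subjects

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InvalidInputError):
            subject_stratified_split(np.array(["a", "b"]), np.array([-1, 1]))

    def test_conflicting_subject_labels_rejected(self):
        with pytest.raises(InvalidInputError):
            subject_stratified_split(np.array(["a", "a", "b", "c"]),
                                     np.array([-1, 1, -1, 1]))
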