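"""Metric implementations against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graymap.evaluation import (
    compute_binary_metrics,
    compute_multiclass_metrics,
    discordance_rate,
    icc,
    median_consensus,
    stratified_folds,
)

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def kappa_oracle(cm):
    """Cohen's kappa straight from marginal expected agreement."""
    cm = np.asarray(cm, float)
    n = cm.sum()
    po = np.trace(cm) / n
    pe = (cm.sum(1) * cm.sum(0)).sum() / n**2
    return (po - pe) / (1 - pe) if pe < 1 else 0.0


def mcc_oracle(cm):
    """Generalized multiclass MCC from the confusion matrix definition."""
    cm = np.asarray(cm, float)
    t = cm.sum(1)
    p = cm.sum(0)
    n = cm.sum()
    c = np.trace(cm)
    num = c * n - t @ p
    den = np.sqrt(n**2 - p @ p) * np.sqrt(n**2 - t @ t)
    return num / den if den else 0.0


def auc_oracle(y, s):
    """All-pairs comparison with tie halving, O(n^2)."""
    pos = s[np.asarray(y) == 1]
    neg = s[np.asarray(y) == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def icc_oracle(x):
    """ICC(2,1) from two-way ANOVA sums of squares."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ms_r = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
    ss_e = ((x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True) + grand) ** 2).sum()
    ms_e = ss_e / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


# ---------------------------------------------------------------------------
# multiclass metrics
# ---------------------------------------------------------------------------


class TestMulticlassMetrics:
    def test_perfect_diagonal(self):
        rep = compute_multiclass_metrics(np.diag([10, 12, 8]))
        assert rep["accuracy"] == 1.0
        assert rep["kappa"] == pytest.approx(1.0)
        assert rep["mcc"] == pytest.approx(1.0)
        assert rep["f1_macro"] == pytest.approx(1.0)

    def test_random_cm_matches_oracles(self, rng):
        for _ in range(30):
            cm = rng.integers(0, 10, size=(3, 3))
            if cm.sum() == 0 or (cm.sum(1) > 0).sum() < 2:
                continue
            rep = compute_multiclass_metrics(cm)
            assert rep["kappa"] == pytest.approx(kappa_oracle(cm), abs=1e-12)
            assert rep["mcc"] == pytest.approx(mcc_oracle(cm), abs=1e-12)
            assert rep["accuracy"] == pytest.approx(np.trace(cm) / cm.sum(), abs=1e-12)

    def test_count_conserved_under_permutation(self, rng):
        cm = rng.integers(1, 8, size=(3, 3))
        perm = [2, 0, 1]
        cm_p = cm[:, perm]
        assert cm.sum() == cm_p.sum()
        r1 = compute_multiclass_metrics(cm)
        r2 = compute_multiclass_metrics(cm_p)
        assert r1["accuracy"] == pytest.approx(np.trace(cm) / cm.sum())
        assert r2["accuracy"] == pytest.approx(np.trace(cm_p) / cm_p.sum())

    def test_single_class_flagged(self):
        cm = np.zeros((3, 3), dtype=int)
        cm[1, 1] = 5
        cm[1, 2] = 3
        rep = compute_multiclass_metrics(cm)
        assert rep["kappa"] == 0.0 and rep["mcc"] == 0.0
        assert rep.flags

    def test_diagonal_iff_all_ones(self, rng):
        """kappa = mcc = accuracy = 1 exactly when the matrix is diagonal."""
        diag = np.diag([4, 5, 6])
        rep = compute_multiclass_metrics(diag)
        assert rep["kappa"] == rep["mcc"] == rep["accuracy"] == 1.0
        off = diag.copy()
        off[0, 1] = 1
        rep2 = compute_multiclass_metrics(off)
        assert rep2["accuracy"] < 1 and rep2["kappa"] < 1 and rep2["mcc"] < 1


# ---------------------------------------------------------------------------
# binary metrics
# ---------------------------------------------------------------------------


class TestBinaryMetrics:
    def _cohort_counts_metrics(self):
        """Counts consistent with a 228-case cohort: TP=89 FP=7 FN=11 TN=121."""
        y = np.array([1] * 89 + [1] * 11 + [0] * 7 + [0] * 121)
        s = np.array([0.9] * 89 + [0.1] * 11 + [0.9] * 7 + [0.1] * 121)
        return compute_binary_metrics(y, s)

    def test_f1_from_precision_recall(self):
        rep = self._cohort_counts_metrics()
        assert rep["precision"] == pytest.approx(0.927, abs=5e-4)
        assert rep["recall"] == pytest.approx(0.89, abs=5e-4)
        assert rep["f1"] == pytest.approx(0.908, abs=5e-4)

    def test_jaccard(self):
        assert self._cohort_counts_metrics()["jaccard"] == pytest.approx(0.832, abs=5e-4)

    def test_accuracy_specificity(self):
        rep = self._cohort_counts_metrics()
        assert rep["accuracy"] == pytest.approx(0.921, abs=5e-4)
        assert rep["specificity"] == pytest.approx(0.945, abs=5e-4)

    def test_auc_matches_pairwise_oracle(self, rng):
        y = rng.integers(0, 2, size=200)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=200)
        s = np.round(rng.random(200), 2)  # rounding forces ties
        rep = compute_binary_metrics(y, s)
        assert rep["auc"] == pytest.approx(auc_oracle(y, s), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = np.array([0, 1] * 50)
        s = rng.random(100)
        a1 = compute_binary_metrics(y, s)["auc"]
        a2 = compute_binary_metrics(y, np.exp(3 * s) + 7)["auc"]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_one_class_truth_flagged(self):
        rep = compute_binary_metrics([1, 1, 1], [0.2, 0.6, 0.9])
        assert np.isnan(rep["auc"])
        assert rep.flags


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


class TestICC:
    def test_identical_raters(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3)) + 0  # identical columns
        val, (lo, hi) = icc(x)
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_null_simulation_near_zero(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=(200, 3))
        val, _ = icc(x)
        assert abs(val) < 0.1

    def test_matches_anova_oracle(self):
        x = np.array(
            [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]],
            dtype=float,
        )
        val, _ = icc(x)
        assert val == pytest.approx(icc_oracle(x), abs=1e-9)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(5)
        subject = rng.normal(size=(40, 1))
        x = subject + rng.normal(scale=0.5, size=(40, 3))
        val, (lo, hi) = icc(x)
        assert lo <= val <= hi

    def test_degenerate_constant_matrix(self):
        val, ci = icc(np.full((6, 3), 2.0))
        assert val == 1.0

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc(np.zeros((3, 3)))


# ---------------------------------------------------------------------------
# discordance, consensus, folds
# ---------------------------------------------------------------------------


class TestDiscordance:
    @pytest.mark.parametrize(
        "d,n,expected", [(13, 228, 5.70), (18, 228, 7.89), (0, 100, 0.00), (1, 800, 0.13)]
    )
    def test_printed_style_rounding(self, d, n, expected):
        assert discordance_rate(d, n) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            discordance_rate(1, 0)
        with pytest.raises(ValueError):
            discordance_rate(5, 3)


def test_median_consensus_ordinal():
    scores = np.array([[1, 2, 2], [0, 3, 1], [3, 3, 2]])
    np.testing.assert_array_equal(median_consensus(scores), [2, 1, 3])


class TestStratifiedFolds:
    def test_sizes_differ_by_at_most_one(self, rng):
        labels = rng.integers(0, 6, size=97)
        folds = stratified_folds(labels, n_folds=5, seed=1)
        sizes = np.bincount(folds, minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_within_class_balance(self, rng):
        labels = np.repeat(np.arange(3), 25)
        folds = stratified_folds(labels, n_folds=5, seed=2)
        for c in range(3):
            sizes = np.bincount(folds[labels == c], minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_deterministic_given_seed(self, rng):
        labels = rng.integers(0, 4, size=60)
        np.testing.assert_array_equal(
            stratified_folds(labels, seed=7), stratified_folds(labels, seed=7)
        )


# ---------------------------------------------------------------------------
# property test: oracle equivalence on random small confusion matrices
# ---------------------------------------------------------------------------


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 12), min_size=9, max_size=9))
def test_metric_oracle_equivalence_property(cells):
    cm = np.array(cells).reshape(3, 3)
    if cm.sum() == 0 or (cm.sum(1) > 0).sum() < 2 or (cm.sum(0) > 0).sum() < 2:
        return
    rep = compute_multiclass_metrics(cm)
    assert rep["kappa"] == pytest.approx(kappa_oracle(cm), abs=1e-9)
    assert rep["mcc"] == pytest.approx(mcc_oracle(cm), abs=1e-9)
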