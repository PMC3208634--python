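"""Confusion metrics, ROC/AUC, correlated-AUC test, 5x2 CV, group stats."""

import numpy as np
import pandas as pd
import pytest

from sdinet import evaluation as ev
from sdinet._util import round_half_away


def pair_count_auc(scores, labels):
    """Brute-force Mann-Whitney oracle: P(case > control) + 1/2 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return (wins + 0.5 * ties) / (cases.size * controls.size)


class TestConfusionMetrics:
    def test_perfect(self):
        m = ev.confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 100.0, 100.0)

    def test_balanced_accuracy_is_mean_of_sn_sp(self):
        y = np.r_[np.ones(40), np.zeros(60)]
        pred = y.copy()
        pred[:11] = 0  # SN 72.5
        pred[40 + 47:] = 1  # SP ~78.3
        m = ev.confusion_metrics(y, pred)
        assert m.accuracy == pytest.approx((m.sensitivity + m.specificity) / 2)

    def test_all_positive_predictor(self):
        m = ev.confusion_metrics([0, 1, 0, 1], [1, 1, 1, 1])
        assert (m.sensitivity, m.specificity, m.accuracy) == (100.0, 0.0, 50.0)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ev.UndefinedMetricError):
            ev.confusion_metrics([1, 1], [0, 1])

    def test_percentages_recomputable_from_counts(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        pred = rng.integers(0, 2, 200)
        m = ev.confusion_metrics(y, pred)
        assert m.sensitivity == pytest.approx(100 * m.tp / (m.tp + m.fn), abs=0.1)
        assert m.specificity == pytest.approx(100 * m.tn / (m.tn + m.fp), abs=0.1)


class TestRocAuc:
    def test_perfect_separation(self):
        roc = ev.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_null_large_n(self):
        rng = np.random.default_rng(1)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert ev.roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_six_by_six_pair_counting(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.55, 0.3, 0.85, 0.65, 0.5, 0.4, 0.3, 0.2]
        labels = [1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        roc = ev.roc_auc(scores, labels)
        assert roc.auc == pytest.approx(pair_count_auc(scores, labels))

    def test_constant_scores_warn(self):
        with pytest.warns(UserWarning):
            roc = ev.roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_curve_monotone_with_unit_endpoints(self):
        rng = np.random.default_rng(2)
        roc = ev.roc_auc(rng.random(100), rng.integers(0, 2, 100))
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], 300)  # heavy ties
        labels = rng.integers(0, 2, 300)
        assert ev.roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores)
        )


class TestCompareAuc:
    def test_identical_scores(self):
        rng = np.random.default_rng(4)
        s = rng.random(100)
        y = rng.integers(0, 2, 100)
        z, p = ev.compare_auc(ev.roc_auc(s, y), ev.roc_auc(s, y), paired=True)
        assert (z, p) == (0.0, 1.0)

    def test_r_zero_reduces_to_unpaired(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 200)
        r1 = ev.roc_auc(rng.random(200) + 0.3 * y, y)
        r2 = ev.roc_auc(rng.random(200) + 0.1 * y, y)
        z_un, _ = ev.compare_auc(r1, r2, paired=False)
        se1 = ev.hanley_se(r1.auc, r1.n_cases, r1.n_controls)
        se2 = ev.hanley_se(r2.auc, r2.n_cases, r2.n_controls)
        assert z_un == pytest.approx((r1.auc - r2.auc) / np.hypot(se1, se2))

    def test_mismatched_samples_refused(self):
        rng = np.random.default_rng(6)
        y1 = np.r_[np.ones(10), np.zeros(10)].astype(int)
        y2 = np.r_[np.ones(12), np.zeros(8)].astype(int)
        r1 = ev.roc_auc(rng.random(20), y1)
        r2 = ev.roc_auc(rng.random(20), y2)
        with pytest.raises(ValueError):
            ev.compare_auc(r1, r2, paired=True)

    def test_power_for_auc_gap(self):
        # two classifiers with a true AUC gap ~0.12 at n=400: the paired test
        # should reject at the 5% level in well over half of replicates
        rng = np.random.default_rng(7)
        rejections = 0
        n = 400
        for _ in range(200):
            y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
            good = y * 1.1 + rng.normal(size=n)  # AUC ~ 0.78
            weak = y * 0.45 + 0.4 * good + rng.normal(size=n)  # correlated, AUC ~ 0.66
            z, p = ev.compare_auc(ev.roc_auc(good, y), ev.roc_auc(weak, y))
            rejections += int(p < 0.05)
        assert rejections / 200 > 0.5


def _mean_difference_trainer(X_train, y_train, seed):
    # deterministic linear scorer: mean difference direction
    mu1 = X_train[y_train == 1].mean().to_numpy()
    mu0 = X_train[y_train == 0].mean().to_numpy()
    w = mu1 - mu0

    def score(X_test):
        raw = X_test.to_numpy() @ w
        lo, hi = raw.min(), raw.max()
        return (raw - lo) / (hi - lo) if hi > lo else np.full(len(raw), 0.5)

    return score


@pytest.fixture(scope="module")
def cv_report():
    rng = np.random.default_rng(8)
    X = pd.DataFrame(rng.random((80, 4)), columns=list("abcd"))
    y = (X["a"] + 0.3 * rng.random(80) > 0.6).astype(int)
    return ev.five_by_two_cv(X, y, _mean_difference_trainer, seed=3)


class TestFiveByTwoCv:
    _trainer = staticmethod(_mean_difference_trainer)

    def test_ten_folds_with_partition_property(self, cv_report):
        assert len(cv_report.folds) == 10
        assert [f.fold_id for f in cv_report.folds] == [
            f"{r}{t}" for r in range(1, 6) for t in "ab"
        ]
        # each repeat's halves are disjoint and cover the sample
        for rep in range(5):
            half = cv_report.partitions[rep]
            assert 0 < half.sum() < half.size

    def test_averages_equal_fold_means(self, cv_report):
        assert cv_report.avg_sensitivity == pytest.approx(
            np.mean([f.sensitivity for f in cv_report.folds])
        )
        assert cv_report.avg_accuracy == pytest.approx(
            np.mean([f.accuracy for f in cv_report.folds])
        )

    def test_stratification_preserves_prevalence(self, cv_report):
        y = cv_report.labels
        for rep in range(5):
            half = cv_report.partitions[rep]
            assert abs(y[half].mean() - y[~half].mean()) < 0.1

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.random((60, 3)), columns=list("abc"))
        y = (X["a"] > 0.5).astype(int)
        r1 = ev.five_by_two_cv(X, y, self._trainer, seed=11)
        r2 = ev.five_by_two_cv(X, y, self._trainer, seed=11)
        np.testing.assert_array_equal(r1.partitions, r2.partitions)
        np.testing.assert_array_equal(r1.scores, r2.scores)


class TestFoldHomogeneity:
    def test_identical_folds(self):
        folds = [ev.confusion_metrics([1, 1, 0, 0], [1, 0, 0, 0], str(i))
                 for i in range(5)]
        chi2, p = ev.fold_homogeneity_chi2(folds)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_three_folds(self):
        # correct/total: 30/40, 20/40, 25/40; pooled rate 75/120 = 0.625
        folds = [
            ev.FoldMetrics(str(i), tp=c, fn=40 - c, tn=0, fp=0, sensitivity=0,
                           specificity=0, accuracy=0, raw_accuracy=0)
            for i, c in enumerate((30, 20, 25))
        ]
        chi2, p = ev.fold_homogeneity_chi2(folds)
        e_c, e_w = 40 * 0.625, 40 * 0.375
        expected = sum(
            (c - e_c) ** 2 / e_c + ((40 - c) - e_w) ** 2 / e_w for c in (30, 20, 25)
        )
        assert chi2 == pytest.approx(expected)

    def test_deviant_fold_detected(self):
        folds = [ev.confusion_metrics([1] * 50 + [0] * 50,
                                      [1] * 45 + [0] * 5 + [0] * 45 + [1] * 5, str(i))
                 for i in range(4)]
        folds.append(ev.confusion_metrics([1] * 50 + [0] * 50,
                                          [0] * 50 + [1] * 50, "deviant"))
        chi2, p = ev.fold_homogeneity_chi2(folds)
        assert p < 0.05


class TestGroupCompare:
    def test_identical_groups(self):
        rng = np.random.default_rng(10)
        half = pd.DataFrame(
            {"cont": rng.normal(50, 5, 100), "flag": rng.integers(0, 2, 100)}
        )
        table = pd.concat([half, half], ignore_index=True)
        groups = np.r_[np.zeros(100), np.ones(100)]
        out = table_p = ev.group_compare(table, groups)
        p_flag = out.loc[out.variable == "flag", "p"].item()
        p_cont = table_p.loc[table_p.variable == "cont", "p"].item()
        assert p_flag == pytest.approx(1.0)
        assert p_cont >= 0.99

    def test_shifted_normal_uses_t_test(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame({"x": np.r_[rng.normal(0, 1, 200), rng.normal(1, 1, 200)]})
        groups = np.r_[np.zeros(200), np.ones(200)]
        out = ev.group_compare(table, groups)
        assert out.test.item() == "t-test"
        assert out.p.item() < 0.001

    def test_zero_variance_skipped(self):
        table = pd.DataFrame({"x": np.ones(40)})
        out = ev.group_compare(table, np.r_[np.zeros(20), np.ones(20)])
        assert out.test.item() == "skipped"


class TestCorrelate:
    def test_identity(self):
        x = np.arange(10.0)
        r, _ = ev.correlate(x, x, method="pearson")
        assert r == pytest.approx(1.0)

    def test_independent_null(self):
        rng = np.random.default_rng(12)
        r, _ = ev.correlate(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.05

    def test_spearman_hand_ranked(self):
        # d = (-1, 1, -1, 1, 0); rho = 1 - 6*4 / (5*24) = 0.8
        r, _ = ev.correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], method="spearman")
        assert r == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ev.UndefinedMetricError):
            ev.correlate([1, 1, 1, 1], [1, 2, 3, 4])


class TestChiSquare:
    def test_yates_matches_closed_form(self):
        # n * (|ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b, c, d = 12, 7, 5, 14
        n = a + b + c + d
        closed = (
            n * (max(0.0, abs(a * d - b * c) - n / 2)) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        chi2, _ = ev.yates_chi2([[a, b], [c, d]])
        assert chi2 == pytest.approx(closed)

    def test_fisher_option(self):
        _, p = ev.yates_chi2([[2, 8], [8, 2]], correction="fisher")
        from scipy.stats import fisher_exact

        assert p == pytest.approx(fisher_exact([[2, 8], [8, 2]])[1])


def test_round_half_away():
    assert round_half_away(74.84, 1) == 74.8
    assert round_half_away(75.45, 1) == 75.5  # half rounds away, not to even
    assert round_half_away(-0.25, 1) == -0.3
    assert round_half_away(0.0173351, 3) == 0.017
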