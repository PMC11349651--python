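"""Cohort statistics: 2x2 operating characteristics, ROC/AUC against a
brute-force pairwise oracle, normality-gated group comparisons, and
logistic regression."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capscore import (
    ConfusionTable,
    DegenerateDataError,
    ValidationError,
    auc_mann_whitney,
    compare_categorical,
    compare_continuous,
    compare_groups,
    confusion_metrics,
    evaluate_score,
    fit_logistic,
    generate_cohort,
    default_params,
    ppv_npv_at_prevalence,
    roc_analysis,
)

from conftest import make_subject


def brute_force_auc(scores, labels):
    """Independent oracle: count positive-over-negative wins, ties as 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_published_counts_give_published_metrics(self):
        m = confusion_metrics(ConfusionTable(tp=25, fp=4, tn=16, fn=3))
        assert m.sensitivity == Fraction(25, 28)
        assert m.specificity == Fraction(16, 20)
        assert m.ppv == Fraction(25, 29)
        assert m.npv == Fraction(16, 19)
        pct = m.as_percentages()
        assert pct["specificity"] == 80.0
        assert pct["ppv"] == 86.2
        assert pct["npv"] == 84.2

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionTable(tp=10, fp=0, tn=10, fn=0))
        assert m.sensitivity == m.specificity == m.ppv == m.npv == 1
        assert m.lr_positive is None  # 1 - specificity = 0
        assert m.lr_negative == 0

    def test_zero_denominators_are_undefined_not_zero(self):
        # no reference positives and no negative predictions
        m = confusion_metrics(ConfusionTable(tp=0, fp=5, tn=0, fn=0))
        assert m.sensitivity is None and m.npv is None
        assert m.specificity == 0 and m.ppv == 0

    def test_likelihood_ratio_identities(self):
        m = confusion_metrics(ConfusionTable(tp=25, fp=4, tn=16, fn=3))
        assert m.lr_positive == m.sensitivity / (1 - m.specificity)
        assert m.lr_negative == (1 - m.sensitivity) / m.specificity

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_label_swap_duality(self, cells):
        tp, fp, tn, fn = cells
        if tp + fp + tn + fn == 0:
            return
        m = confusion_metrics(ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn))
        swapped = confusion_metrics(ConfusionTable(tp=tn, fp=fn, tn=tp, fn=fp))
        assert m.sensitivity == swapped.specificity
        assert m.ppv == swapped.npv

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionTable(tp=-1, fp=0, tn=1, fn=0)


class TestPrevalence:
    def test_ppv_increases_npv_decreases_with_prevalence(self):
        prevalences = np.linspace(0.05, 0.95, 19)
        ppvs, npvs = zip(
            *(ppv_npv_at_prevalence(25 / 28, 0.80, p) for p in prevalences)
        )
        assert all(a < b for a, b in zip(ppvs, ppvs[1:]))
        assert all(a > b for a, b in zip(npvs, npvs[1:]))


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([0, 1, 2, 3], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_all_ties(self):
        assert roc_analysis([2, 2, 2, 2], [0, 1, 0, 1]).auc == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(2, 21, size=2)
        # integer scores force ties
        scores = np.concatenate([rng.integers(0, 6, n1), rng.integers(0, 6, n0)])
        labels = np.array([1] * n1 + [0] * n0)
        r = roc_analysis(scores, labels)
        assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_label_swap_maps_auc_to_complement(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = (rng.random(30) < 0.5).astype(int)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_curve_is_step_function_with_matching_area(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=40) + np.repeat([1.0, 0.0], 20)
        labels = np.repeat([1, 0], 20)
        r = roc_analysis(scores, labels)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)
        assert np.trapezoid(r.tpr, r.fpr) == pytest.approx(r.auc, abs=1e-12)

    @pytest.mark.parametrize("method", ["delong", "hanley_mcneil"])
    def test_ci_contains_auc(self, method):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=60) + np.repeat([0.8, 0.0], 30)
        labels = np.repeat([1, 0], 30)
        r = roc_analysis(scores, labels, ci_method=method)
        lo, hi = r.auc_ci_95
        assert 0.0 <= lo <= r.auc <= hi <= 1.0
        assert r.method == method

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_analysis([1.0, 2.0], [1, 1])


class TestGroupComparisons:
    def test_normal_groups_use_t_test(self):
        rng = np.random.default_rng(0)
        c = compare_continuous(rng.normal(0, 1, 60), rng.normal(1, 1, 60))
        assert c.test == "t"
        assert c.p_value < 0.01

    def test_skewed_groups_fall_back_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        c = compare_continuous(rng.exponential(1.0, 120), rng.exponential(1.0, 120))
        assert c.test == "mann_whitney"

    def test_all_identical_values_degenerate(self):
        with pytest.raises(DegenerateDataError):
            compare_continuous([3.0] * 10, [3.0] * 10)

    def test_published_mmse_difference_detected_in_most_replicates(self):
        """Normal draws at the published group means/SDs (24.50 (2.52) n=30
        vs 26.85 (3.71) n=22) should usually reach p < 0.05."""
        rng = np.random.default_rng(42)
        hits = sum(
            compare_continuous(
                rng.normal(24.50, 2.52, 30), rng.normal(26.85, 3.71, 22)
            ).p_value
            < 0.05
            for _ in range(100)
        )
        assert hits >= 60

    def test_identical_categorical_groups_give_p_one(self):
        a = ["f", "m"] * 10
        c = compare_categorical(a, list(a))
        assert c.test == "chi_square"
        assert c.statistic == pytest.approx(0.0)
        assert c.p_value == pytest.approx(1.0)

    def test_single_category_is_uninformative(self):
        c = compare_categorical(["f"] * 8, ["f"] * 5)
        assert c.p_value == 1.0

    def test_compare_groups_on_synthetic_cohort(self):
        cohort = generate_cohort(default_params(400, 400), seed=2)
        npi = compare_groups(cohort, "npiq_total")
        assert npi.p_value < 1e-6  # 2.73 vs 1.18 separates easily at n=400
        sex = compare_groups(cohort, "sex")
        assert sex.test == "chi_square"
        with pytest.raises(ValidationError):
            compare_groups(cohort, "shoe_size")


class TestLogistic:
    @staticmethod
    def grid_best_loglik(X, y, center, half_width=0.3, step=0.01):
        """Oracle: best log-likelihood over a 0.01-step coefficient grid
        around ``center`` (any grid point lower-bounds the true optimum)."""
        axes = [np.arange(c - half_width, c + half_width + step / 2, step) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        B = np.stack([g.ravel() for g in grids])  # (k, m)
        eta = X @ B
        ll = (y[:, None] * eta - np.log1p(np.exp(eta))).sum(axis=0)
        return float(ll.max())

    def test_irls_beats_coefficient_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            X = rng.normal(size=(50, 2))
            p = 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 0] - 0.5 * X[:, 1])))
            y = (rng.random(50) < p).astype(float)
            fit = fit_logistic(X, y)
            assert fit.converged
            design = np.column_stack([np.ones(50), X])
            best = self.grid_best_loglik(design, y, fit.params)
            assert fit.log_likelihood >= best - 1e-10

    def test_null_feature_has_near_zero_coefficient(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(2000, 1))
        y = (rng.random(2000) < 0.5).astype(float)
        fit = fit_logistic(X, y)
        assert fit.converged
        assert abs(fit.params[1]) < 0.15
        assert fit.p_values[1] > 0.001

    def test_matches_independent_solver(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(9)
        X = rng.normal(size=(200, 2))
        p = 1 / (1 + np.exp(-(0.5 + X[:, 0])))
        y = (rng.random(200) < p).astype(float)
        fit = fit_logistic(X, y)
        sk = LogisticRegression(C=1e10, tol=1e-10).fit(X, y)
        assert fit.params[0] == pytest.approx(sk.intercept_[0], abs=1e-4)
        assert fit.params[1:] == pytest.approx(sk.coef_[0], abs=1e-4)

    def test_perfect_separation_flagged(self):
        X = np.linspace(-1, 1, 20)[:, None]
        y = (X[:, 0] > 0).astype(float)
        fit = fit_logistic(X, y)
        assert fit.separation and not fit.converged

    def test_constant_feature_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(np.ones((20, 1)), np.tile([0.0, 1.0], 10))

    def test_npiq_is_the_independent_predictor_in_synthetic_cohorts(self):
        """In cohorts generated with the published group parameters, NPI-Q
        total drives amyloid status far more than the other covariates."""
        hits = 0
        for seed in range(5):
            cohort = generate_cohort(default_params(150, 150), seed=seed)
            rows = np.array(
                [
                    (
                        s.npiq.total_score,
                        s.hachinski,
                        s.age,
                        1 if s.amyloid_status_reference == "positive" else 0,
                    )
                    for s in cohort
                ],
                dtype=float,
            )
            fit = fit_logistic(rows[:, :3], rows[:, 3], feature_names=["npi", "hach", "age"])
            if fit.converged and fit.p_values[1] < 0.05 and min(fit.p_values[2:]) > fit.p_values[1]:
                hits += 1
        assert hits >= 4


class TestEvaluateScore:
    def test_fixture_reproduces_published_counts(self, fixture_cohort):
        ev = evaluate_score(fixture_cohort, "caps", threshold=3)
        assert ev.confusion.as_tuple() == (25, 4, 16, 3)
        assert ev.n_scored == 48 and ev.n_excluded == 0

    def test_unscoreable_subjects_dropped_and_counted(self, fixture_cohort):
        cohort = list(fixture_cohort) + [
            make_subject({}, n_visits=1, id="one-visit"),
            make_subject({}, reference="unknown", id="no-label"),
        ]
        ev = evaluate_score(cohort, "caps")
        assert ev.n_excluded == 2
        assert {sid for sid, _ in ev.exclusions} == {"one-visit", "no-label"}
        assert ev.confusion.n == 48

    def test_single_class_cohort_has_defined_counts_but_no_roc(self):
        cohort = [
            make_subject({"depression": 2}, rapid=True, fazekas=0, id=f"s{i}")
            for i in range(5)
        ]
        ev = evaluate_score(cohort, "caps")
        assert ev.metrics.sensitivity == 1
        assert ev.metrics.specificity is None
        assert ev.roc is None

    def test_caps_mt_rescues_high_atrophy_false_negatives(self, fixture_cohort):
        plain = evaluate_score(fixture_cohort, "caps")
        mt = evaluate_score(fixture_cohort, "caps_mt")
        assert mt.confusion.fn < plain.confusion.fn
        assert mt.roc.auc > plain.roc.auc

    def test_no_scoreable_subjects_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_score([make_subject({}, n_visits=1)], "caps")
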