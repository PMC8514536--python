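"""Metrics against independent oracles: brute-force AUC, hand-computed
regression examples, closed-form bootstrap and point-biserial limits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fundusroar.evaluation import (
    auc,
    baseline_mae,
    bootstrap_ci,
    error_reduction,
    evaluate_classification,
    evaluate_regression,
    kde_summary,
    patient_level_scores,
    point_biserial,
    regression_metrics,
)


def auc_pair_counting(labels, scores):
    """Independent oracle: fraction of positive-negative pairs ranked
    concordantly, ties counted half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = concordant = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1
        if p > n:
            concordant += 1
        elif p == n:
            concordant += 0.5
    return concordant / total


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        y = [0.1, 0.5, 0.9]
        mae, r2, r = regression_metrics(y, y)
        assert mae == 0.0
        assert r2 == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([0.2, 0.4, 0.6, 0.8])
        _, r2, _ = regression_metrics(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_worked_example(self):
        """Hand computation: SS_res = 0.03, SS_tot = 0.20."""
        mae, r2, _ = regression_metrics([0.2, 0.4, 0.6, 0.8], [0.3, 0.4, 0.5, 0.9])
        assert mae == pytest.approx(0.075)
        assert r2 == pytest.approx(0.85)

    def test_zero_variance_truth_raises(self):
        with pytest.raises(ValueError):
            regression_metrics([0.5, 0.5], [0.1, 0.9])

    def test_r_squared_equals_r2_for_least_squares_fit(self):
        """On a least-squares linear fit, Pearson r^2 equals R^2 exactly."""
        rng = np.random.default_rng(0)
        y = rng.random(200)
        noise = rng.normal(0, 0.3, 200)
        x = y + noise
        a, b = np.polyfit(y, x, 1)  # predict x from y? fit y_pred = a*y + b
        y_pred = a * y + b
        # R^2 of predicting x by the fitted line, against Pearson r of (x, fit)
        _, r2, r = regression_metrics(x, y_pred)
        assert r2 == pytest.approx(r**2, abs=1e-10)


class TestBaselineAndErrorReduction:
    def test_constant_labels(self):
        assert baseline_mae([0.3, 0.3, 0.3]) == 0.0

    def test_two_point_case(self):
        assert baseline_mae([0.0, 1.0]) == pytest.approx(0.5)

    def test_matches_brute_force_on_cohort_labels(self):
        from fundusroar.cohort import GeneratorConfig, sample_cohort

        y = sample_cohort(GeneratorConfig(n_patients=300, seed=13))["vcdr_true"].to_numpy()
        mean = y.mean()
        brute = sum(abs(v - mean) for v in y) / len(y)
        assert baseline_mae(y) == pytest.approx(brute)

    @pytest.mark.parametrize(
        "model,base,expected", [(0.079, 0.19, 58), (0.19, 0.19, 0), (0.0, 0.19, 100)]
    )
    def test_error_reduction(self, model, base, expected):
        assert error_reduction(model, base) == expected

    def test_zero_baseline_raises(self):
        with pytest.raises(ValueError):
            error_reduction(0.1, 0.0)


class TestPatientAggregation:
    def test_max_of_patient_scores(self):
        agg = patient_level_scores([0.2, 0.9], [7, 7], [1, 1])
        assert len(agg) == 1 and agg["score"].iloc[0] == 0.9

    def test_single_image_patients_unchanged(self):
        agg = patient_level_scores([0.3, 0.7], [1, 2])
        assert sorted(agg["score"]) == [0.3, 0.7]

    def test_permutation_invariant_within_patient(self):
        rng = np.random.default_rng(0)
        scores = rng.random(12)
        pids = [1, 1, 1, 2, 2, 2, 3, 3, 3, 4, 4, 4]
        a = patient_level_scores(scores, pids)
        perm = rng.permutation(12)
        b = patient_level_scores(scores[perm], np.array(pids)[perm])
        pd.testing.assert_frame_equal(
            a.sort_values("patient_id").reset_index(drop=True),
            b.sort_values("patient_id").reset_index(drop=True),
        )

    def test_patient_auc_with_one_image_each_equals_image_auc(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        agg = patient_level_scores(scores, np.arange(30), labels)
        assert auc(agg["label"], agg["score"]) == pytest.approx(auc(labels, scores))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 1], [0.1, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_small_worked_example(self):
        assert auc([0, 0, 1, 1], [0.1, 0.6, 0.4, 0.8]) == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.2, 0.4])

    def test_matches_pair_counting_oracle_exhaustively(self):
        """Seeded battery over all n <= 12, with ties forced by rounding."""
        rng = np.random.default_rng(99)
        for n in range(2, 13):
            for _ in range(20):
                labels = rng.integers(0, 2, n)
                if labels.min() == labels.max():
                    labels[0] = 1 - labels[0]
                scores = np.round(rng.random(n), 1)
                assert auc(labels, scores) == pytest.approx(
                    auc_pair_counting(labels, scores), abs=1e-12
                )


class TestPointBiserial:
    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(0)
        b = rng.integers(0, 2, 1000)
        x = rng.normal(size=1000)
        assert abs(point_biserial(b, x)) < 0.1

    def test_median_split_closed_form(self):
        """Thresholding a normal at its median gives r -> sqrt(2/pi) ~ 0.798."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=200_000)
        b = (x > np.median(x)).astype(int)
        assert point_biserial(b, x) == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_constant_binary_raises(self):
        with pytest.raises(ValueError):
            point_biserial([1, 1, 1], [0.1, 0.2, 0.3])


class TestBootstrap:
    def test_constant_data_zero_width(self):
        data = pd.DataFrame({"patient_id": range(20), "x": 3.0})
        point, lo, hi, _ = bootstrap_ci(lambda d: d["x"].mean(), data, iterations=100, seed=0)
        assert point == lo == hi == 3.0

    def test_ci_contains_point_for_the_mean(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame({"patient_id": range(100), "x": rng.normal(size=100)})
        point, lo, hi, _ = bootstrap_ci(lambda d: d["x"].mean(), data, iterations=500, seed=1)
        assert lo <= point <= hi

    def test_normal_mean_halfwidth_matches_closed_form(self):
        """For 200 standard-normal draws the 95% CI of the mean has
        half-width ~1.96/sqrt(200)."""
        rng = np.random.default_rng(3)
        data = pd.DataFrame({"patient_id": range(200), "x": rng.standard_normal(200)})
        _, lo, hi, _ = bootstrap_ci(lambda d: d["x"].mean(), data, iterations=3000, seed=3)
        half = (hi - lo) / 2
        expected = 1.96 / np.sqrt(200)
        assert abs(half - expected) / expected < 0.20

    def test_single_iteration_degenerate_interval(self):
        data = pd.DataFrame({"patient_id": range(10), "x": np.arange(10.0)})
        _, lo, hi, _ = bootstrap_ci(lambda d: d["x"].mean(), data, iterations=1, seed=0)
        assert lo == hi

    def test_degenerate_resamples_are_redrawn(self):
        data = pd.DataFrame({"patient_id": [0, 1], "label": [0, 1], "s": [0.2, 0.8]})
        point, lo, hi, redraws = bootstrap_ci(
            lambda d: auc(d["label"], d["s"]), data, iterations=50, seed=0
        )
        assert redraws > 0
        assert point == 1.0

    def test_resampling_unit_is_patient(self):
        """All images of a drawn patient enter the resample together."""
        data = pd.DataFrame({"patient_id": [0, 0, 1, 1], "x": [1.0, 1.0, 2.0, 2.0]})

        def check(d):
            counts = d.groupby("patient_id").size()
            assert (counts % 2 == 0).all()
            return d["x"].mean()

        bootstrap_ci(check, data, iterations=20, seed=0)


class TestReports:
    def test_regression_report_consistency(self):
        rng = np.random.default_rng(5)
        y = rng.random(120) * 0.6 + 0.2
        pred = np.clip(y + rng.normal(0, 0.05, 120), 0, 1)
        pids = np.repeat(np.arange(40), 3)
        rep = evaluate_regression(y, pred, pids, iterations=400, seed=5)
        assert rep.mae.ci_low <= rep.mae.point <= rep.mae.ci_high
        assert rep.r2.ci_low <= rep.r2.point <= rep.r2.ci_high
        assert rep.n_patients == 40 and rep.n_images == 120
        assert rep.error_reduction_pct == error_reduction(rep.mae.point, rep.baseline_mae)

    def test_classification_report_consistency(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = np.clip(labels * 0.4 + rng.random(100) * 0.6, 0, 1)
        pids = np.repeat(np.arange(50), 2)
        rep = evaluate_classification(labels, scores, pids, iterations=400, seed=6)
        assert 0.0 <= rep.auc.ci_low <= rep.auc.point <= rep.auc.ci_high <= 1.0


class TestKdeSummary:
    def _data(self, n=200, noise=0.05):
        rng = np.random.default_rng(7)
        y = rng.random(n)
        return y, y + rng.normal(0, noise, n)

    def test_density_integrates_to_one(self):
        y, p = self._data()
        out = kde_summary(y, p)
        dx = out["x"][1] - out["x"][0]
        dy = out["y"][1] - out["y"][0]
        assert out["density"].sum() * dx * dy == pytest.approx(1.0, abs=0.01)

    def test_swap_transposes_density(self):
        y, p = self._data()
        a = kde_summary(y, p)
        b = kde_summary(p, y)
        assert np.allclose(a["density"], b["density"].T, atol=1e-12)

    def test_near_perfect_predictions_concentrate_on_diagonal(self):
        rng = np.random.default_rng(8)
        y = rng.random(300)
        p = y + rng.normal(0, 1e-3, 300)
        out = kde_summary(y, p)
        xx, yy = np.meshgrid(out["x"], out["y"])
        bw = np.sqrt(np.diag(np.atleast_2d(np.cov(np.vstack([p, y]))))).max() * out["bandwidth_factor"]
        near = np.abs(xx - yy) < 2 * bw
        dx = out["x"][1] - out["x"][0]
        mass_near = out["density"][near].sum() * dx * dx
        assert mass_near >= 0.9

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            kde_summary(np.full(20, 0.5), np.linspace(0, 1, 20))
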