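"""Tests of dichotomization, logistic fitting, Monte Carlo cross-validated
model comparison, and the benchmark classification rule."""

import numpy as np
import pandas as pd
import pytest

from polconn.compare import (
    ComparisonResult,
    ModelSpec,
    assemble_features,
    compare_to_benchmark,
    dichotomize,
    fit_logistic,
    monte_carlo_cv,
)
from polconn.synthetic import generate_cohort, generate_score_matrix


class TestDichotomize:
    def test_default_cohort_counts(self, cohort174):
        labels = dichotomize(cohort174)
        # 24+52+49 liberal, 36+9+4 conservative
        assert (labels == 0).sum() == 125
        assert (labels == 1).sum() == 49

    @pytest.mark.parametrize("ideology,expected", [(3, 0), (4, 1), (1, 0), (6, 1)])
    def test_category_boundaries(self, cohort174, ideology, expected):
        cohort = cohort174.copy()
        cohort["conservatism"] = ideology
        assert (dichotomize(cohort) == expected).all()

    def test_out_of_range_rejected(self, cohort174):
        bad = cohort174.copy()
        bad.loc[0, "conservatism"] = 0
        with pytest.raises(ValueError):
            dichotomize(bad)


def _table(X, names=None):
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


class TestFitLogistic:
    def test_separating_predictor_gives_training_auc_one(self):
        X = _table(np.linspace(-2, 2, 40)[:, None])
        y = (X["x0"] > 0).astype(int)
        fit = fit_logistic(X, y, ("x0",))
        p = fit.predict_proba(X)
        assert fit.separation_flagged
        order = np.argsort(p)
        assert (np.sort(y.to_numpy()[order][20:]) == 1).all()

    def test_intercept_only_predicts_prevalence(self, rng):
        X = _table(np.zeros((100, 1)) + rng.normal(0, 1e-9, (100, 1)))
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(X, y, ("x0",))
        np.testing.assert_allclose(fit.predict_proba(X), 0.3, atol=0.01)

    def test_coefficient_recovery(self, rng):
        # ML consistency: logistic data with beta = (1, -0.5), n = 5000
        n = 5000
        X = rng.standard_normal((n, 2))
        eta = 1.0 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic(_table(X), y, ("x0", "x1"))
        np.testing.assert_allclose(fit.coef, [1.0, -0.5], atol=0.1)

    def test_single_class_rejected(self, rng):
        X = _table(rng.standard_normal((20, 1)))
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(X, np.zeros(20), ("x0",))

    def test_duplicated_predictor_same_probabilities(self, rng):
        n = 300
        X = rng.standard_normal((n, 2))
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        base = fit_logistic(_table(X), y, ("x0", "x1"))
        dup = _table(np.column_stack([X, X[:, 0]]), ["x0", "x1", "x2"])
        both = fit_logistic(dup, y, ("x0", "x1", "x2"))
        # the duplicated column is non-identified, which routes the fit
        # through the regularized fallback; probabilities agree approximately
        np.testing.assert_allclose(
            base.predict_proba(_table(X)), both.predict_proba(dup), atol=0.05
        )


class TestMonteCarloCV:
    def test_separating_feature_gives_auc_one(self, rng):
        n = 80
        x = np.r_[rng.uniform(1, 2, 40), rng.uniform(-2, -1, 40)]
        y = pd.Series(np.r_[np.ones(40), np.zeros(40)].astype(int))
        feats = _table(x[:, None])
        res = monte_carlo_cv([ModelSpec("m", ("x0",))], feats, y,
                             n_samples=50, seed=0)
        assert res.summary.loc["m", "mean_auc"] == pytest.approx(1.0)

    def test_null_features_give_chance_auc(self, rng):
        # a single dataset realization carries a shared spurious association
        # across its splits, so chance level is assessed as the median over
        # replicate null datasets
        n = 174
        means = []
        for rep in range(5):
            feats = _table(rng.standard_normal((n, 3)))
            y = pd.Series((rng.uniform(size=n) < 0.3).astype(int))
            res = monte_carlo_cv([ModelSpec("null", ("x0", "x1", "x2"))],
                                 feats, y, n_samples=40, seed=rep)
            means.append(res.summary.loc["null", "mean_auc"])
        assert 0.45 <= np.median(means) <= 0.55

    def test_nested_noise_model_within_one_sd(self, rng):
        n = 200
        signal = rng.standard_normal(n)
        y = pd.Series((rng.uniform(size=n) < 1 / (1 + np.exp(-signal))).astype(int))
        feats = _table(np.column_stack([signal, rng.standard_normal(n)]),
                       ["sig", "noise"])
        res = monte_carlo_cv(
            [ModelSpec("small", ("sig",)), ModelSpec("big", ("sig", "noise"))],
            feats, y, n_samples=200, seed=2,
        )
        s = res.summary
        assert abs(s.loc["small", "mean_auc"] - s.loc["big", "mean_auc"]) < s[
            "sd_auc"
        ].max()

    def test_splits_shared_across_models(self, rng):
        # two specs naming the same predictor must give identical AUC vectors
        n = 120
        x = rng.standard_normal(n)
        y = pd.Series((rng.uniform(size=n) < 1 / (1 + np.exp(-x))).astype(int))
        feats = _table(np.column_stack([x, x]), ["a", "b"])
        res = monte_carlo_cv(
            [ModelSpec("ma", ("a",)), ModelSpec("mb", ("b",))],
            feats, y, n_samples=30, seed=3,
        )
        np.testing.assert_allclose(res.auc["ma"], res.auc["mb"])

    def test_unknown_predictor_rejected(self, rng):
        feats = _table(rng.standard_normal((30, 1)))
        y = pd.Series(np.r_[np.ones(15), np.zeros(15)].astype(int))
        with pytest.raises(ValueError, match="unknown predictors"):
            monte_carlo_cv([ModelSpec("m", ("nope",))], feats, y, n_samples=1)


class TestBenchmarkClassification:
    def _result(self, auc_by_model):
        n = 100
        auc = pd.DataFrame(auc_by_model)
        acc = auc.copy()
        return ComparisonResult(auc=auc, accuracy=acc)

    def test_identical_model_indistinguishable(self, rng):
        a = rng.uniform(0.6, 0.8, 100)
        res = self._result({"parent_conservatism": a, "same": a})
        cls = compare_to_benchmark(res)
        assert cls["same"] == "indistinguishable"

    def test_perfect_model_above_chance_benchmark(self, rng):
        res = self._result(
            {
                "parent_conservatism": rng.uniform(0.45, 0.55, 100),
                "perfect": np.ones(100),
            }
        )
        cls = compare_to_benchmark(res)
        assert cls["perfect"] == "above"
        assert cls["parent_conservatism"] == "indistinguishable"

    def test_below_classification(self, rng):
        res = self._result(
            {
                "parent_conservatism": rng.uniform(0.7, 0.8, 100),
                "weak": rng.uniform(0.4, 0.5, 100),
            }
        )
        assert compare_to_benchmark(res)["weak"] == "below"

    def test_missing_benchmark_rejected(self, rng):
        res = self._result({"m": rng.uniform(0, 1, 100)})
        with pytest.raises(ValueError, match="benchmark"):
            compare_to_benchmark(res)


class TestEndToEndComparison:
    def test_planted_task_score_lifts_combined_model(self, cohort174):
        # one task carries signal; parents carry partial signal via the
        # cohort copula; the combined model should classify above survey-only
        sm = generate_score_matrix(cohort174, {"empathy": 0.75}, seed=5)
        feats = assemble_features(sm, cohort174)
        labels = dichotomize(cohort174)
        specs = [
            ModelSpec("parent_conservatism",
                      ("mother_conservatism", "father_conservatism")),
            ModelSpec("combined", ("empathy", "mother_conservatism",
                                   "father_conservatism")),
        ]
        res = monte_carlo_cv(specs, feats, labels.loc[feats.index],
                             n_samples=200, seed=6)
        s = res.summary
        assert s.loc["combined", "mean_auc"] > s.loc[
            "parent_conservatism", "mean_auc"
        ]
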