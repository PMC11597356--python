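import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarnest.feature_selection import SelectorSpec
from qsarnest.features import FeatureMatrix
from qsarnest.learners import LearnerSpec, fit
from qsarnest.validation import (
    MetricSet,
    ccc,
    nested_cv,
    partial_dependence,
    permutation_importance,
    r_squared,
    replicate_mean_sd,
    replicate_nested_cv,
    rmse,
    round_half_up,
    rp_squared,
    y_randomize,
)


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2, 3, 4])
        assert r_squared(y, y) == 1.0
        assert ccc(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0

    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2, 3])
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_worked_r2_example(self):
        assert r_squared([1, 2, 3], [1.1, 2.0, 2.9]) == pytest.approx(0.99)

    def test_worked_ccc_shift_example(self):
        # perfect correlation with unit shift: 2*(2/3) / (2/3 + 2/3 + 1)
        assert ccc([1, 2, 3], [2, 3, 4]) == pytest.approx(4 / 7)

    def test_ccc_negative_for_anticorrelated(self):
        y = np.array([1.0, 2, 3, 4])
        yhat = -y + 5  # matching means, perfect anticorrelation
        s_xy = np.mean((y - y.mean()) * (yhat - yhat.mean()))
        expected = 2 * s_xy / (y.var() + yhat.var())
        assert ccc(y, yhat) == pytest.approx(expected)
        assert ccc(y, yhat) < 0

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            ccc([1, 1, 1], [1, 1, 1])

    def test_rmse_cases(self):
        assert rmse([0.0, 0.0], [1.0, -1.0]) == pytest.approx(1.0)
        assert rmse([1.0, 2.0], [1.5, 2.5]) == pytest.approx(0.5)

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_ccc_bounded_by_pearson(self, seed):
        # Lin's inequality: |CCC| <= |r|
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        y = rng.standard_normal(n)
        yhat = rng.standard_normal(n)
        if y.std() == 0 or yhat.std() == 0:
            return
        r = np.corrcoef(y, yhat)[0, 1]
        assert abs(ccc(y, yhat)) <= abs(r) + 1e-12

    def test_metric_set_recomputable(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(50)
        yhat = y + 0.3 * rng.standard_normal(50)
        m = MetricSet.from_predictions(y, yhat)
        assert m == MetricSet(r2=r_squared(y, yhat), ccc=ccc(y, yhat), rmse=rmse(y, yhat))


class TestRpSquared:
    @pytest.mark.parametrize(
        "r2,rr2,expected",
        [(0.701, -0.220, 0.803), (0.719, -0.113, 0.773), (0.754, -0.056, 0.781)],
    )
    def test_published_reconstructions(self, r2, rr2, expected):
        assert rp_squared(r2, rr2) == pytest.approx(expected, abs=0.002)

    def test_degenerate_and_undefined(self):
        assert rp_squared(0.5, 0.5) == 0.0
        assert math.isnan(rp_squared(0.3, 0.6))


class TestReplicateAggregation:
    def test_model4_ccc_replicates(self):
        mean, sd = replicate_mean_sd([0.857, 0.853, 0.857, 0.843, 0.845])
        assert (mean, sd) == (0.851, 0.007)

    def test_model20_ccc_replicates(self):
        mean, _ = replicate_mean_sd([0.856, 0.870, 0.868, 0.872, 0.877])
        assert mean == 0.869

    def test_identical_replicates_zero_sd(self):
        assert replicate_mean_sd([0.8, 0.8, 0.8]) == (0.8, 0.0)

    def test_half_up_rounding(self):
        assert round_half_up(0.8505, 3) == 0.851
        assert round_half_up(0.0785, 2) == 0.08


@pytest.fixture(scope="module")
def noiseless_linear():
    rng = np.random.default_rng(4)
    X = FeatureMatrix(rng.standard_normal((80, 4)), ["a", "b", "c", "d"], "continuous")
    y = 2 * X.values[:, 0] - X.values[:, 1]
    return X, y


class TestNestedCV:
    def test_model_class_containing_truth_is_recovered(self, noiseless_linear):
        X, y = noiseless_linear
        res = nested_cv(
            X, y, SelectorSpec("none"), LearnerSpec(name="linear"),
            outer_folds=5, inner_folds=3, seed=0, preprocess=False,
        )
        assert res.metrics.r2 >= 0.999

    def test_null_response_scores_at_chance(self):
        rng = np.random.default_rng(8)
        X = FeatureMatrix(rng.standard_normal((200, 10)), [f"f{j}" for j in range(10)], "continuous")
        y = rng.standard_normal(200)
        res = nested_cv(
            X, y, SelectorSpec("top_mi", {"k": 3}), LearnerSpec(name="linear"),
            outer_folds=5, inner_folds=3, seed=1, preprocess=False,
        )
        assert res.metrics.r2 <= 0.1

    def test_every_compound_predicted_once(self, noiseless_linear):
        X, y = noiseless_linear
        res = nested_cv(
            X, y, SelectorSpec("none"), LearnerSpec(name="linear"),
            outer_folds=4, inner_folds=3, seed=2, preprocess=False,
        )
        covered = np.concatenate([d.test_indices for d in res.fold_details])
        assert sorted(covered) == list(range(X.n))
        assert np.isfinite(res.oof_predictions).all()

    def test_metrics_recomputable_from_oof(self, noiseless_linear):
        X, y = noiseless_linear
        res = nested_cv(
            X, y, SelectorSpec("none"), LearnerSpec(name="linear"),
            outer_folds=4, inner_folds=3, seed=3, preprocess=False,
        )
        assert res.metrics == MetricSet.from_predictions(y, res.oof_predictions)

    def test_seeded_determinism(self, noiseless_linear):
        X, y = noiseless_linear
        kwargs = dict(outer_folds=4, inner_folds=3, preprocess=False)
        a = nested_cv(X, y, SelectorSpec("top_mi", {"k": 2}), LearnerSpec(name="linear"), seed=7, **kwargs)
        b = nested_cv(X, y, SelectorSpec("top_mi", {"k": 2}), LearnerSpec(name="linear"), seed=7, **kwargs)
        assert np.array_equal(a.oof_predictions, b.oof_predictions)

    def test_replicates_aggregate(self, noiseless_linear):
        X, y = noiseless_linear
        summary = replicate_nested_cv(
            X, y, SelectorSpec("none"), LearnerSpec(name="linear"),
            seeds=[0, 1, 2], outer_folds=4, inner_folds=3, preprocess=False,
        )
        assert len(summary.metric_sets) == 3
        mean, sd = summary.mean_sd["r2"]
        vals = [m.r2 for m in summary.metric_sets]
        assert mean == round_half_up(float(np.mean(vals)))
        assert sd == round_half_up(float(np.std(vals, ddof=1)))


class TestYRandomization:
    def test_permuted_response_destroys_signal(self, noiseless_linear):
        X, y = noiseless_linear
        genuine = nested_cv(
            X, y, SelectorSpec("none"), LearnerSpec(name="linear"),
            outer_folds=4, inner_folds=3, seed=0, preprocess=False,
        )
        result = y_randomize(
            X, y, SelectorSpec("none"), LearnerSpec(name="linear"), genuine.metrics,
            n_perm=3, seed=1, outer_folds=4, inner_folds=3, preprocess=False,
        )
        assert result.rr2_mean <= 0.05
        assert result.rp2 == pytest.approx(
            rp_squared(genuine.metrics.r2, result.rr2_mean)
        )

    def test_single_permutation_mean_is_that_run(self, noiseless_linear):
        X, y = noiseless_linear
        genuine = MetricSet(r2=0.9, ccc=0.9, rmse=0.3)
        result = y_randomize(
            X, y, SelectorSpec("none"), LearnerSpec(name="linear"), genuine,
            n_perm=1, seed=5, outer_folds=4, inner_folds=3, preprocess=False,
        )
        assert result.rr2_mean == result.metric_sets[0].r2

    def test_seeded_rerun_identical(self, noiseless_linear):
        X, y = noiseless_linear
        genuine = MetricSet(r2=0.9, ccc=0.9, rmse=0.3)
        kwargs = dict(n_perm=2, seed=6, outer_folds=4, inner_folds=3, preprocess=False)
        a = y_randomize(X, y, SelectorSpec("none"), LearnerSpec(name="linear"), genuine, **kwargs)
        b = y_randomize(X, y, SelectorSpec("none"), LearnerSpec(name="linear"), genuine, **kwargs)
        assert a.rr2_mean == b.rr2_mean


class TestInterpretation:
    @pytest.fixture(scope="class")
    def single_feature_truth(self):
        rng = np.random.default_rng(9)
        X = FeatureMatrix(rng.standard_normal((150, 4)), ["sig", "n1", "n2", "n3"], "continuous")
        y = 2.0 * X.values[:, 0] + 0.1 * rng.standard_normal(150)
        model = fit(LearnerSpec(name="linear"), X, y)
        return model, X, y

    def test_truth_feature_ranks_first_null_feature_near_zero(self, single_feature_truth):
        model, X, y = single_feature_truth
        imp = permutation_importance(model, X, y, n_repeats=5, seed=0)
        assert max(imp, key=imp.get) == "sig"
        assert imp["n1"] < 0.05

    def test_zero_repeats_rejected(self, single_feature_truth):
        model, X, y = single_feature_truth
        with pytest.raises(ValueError):
            permutation_importance(model, X, y, n_repeats=0)

    def test_linear_pd_has_model_slope(self):
        rng = np.random.default_rng(12)
        X = FeatureMatrix(rng.standard_normal((100, 3)), ["sig", "n1", "n2"], "continuous")
        y = 2.0 * X.values[:, 0]  # noiseless: the fitted slope is exactly 2
        model = fit(LearnerSpec(name="linear"), X, y)
        grid, means = partial_dependence(model, X, "sig", grid_size=10)
        slopes = np.diff(means) / np.diff(grid)
        assert np.allclose(slopes, 2.0, atol=1e-6)

    def test_binary_feature_two_point_grid(self):
        rng = np.random.default_rng(10)
        values = np.column_stack([rng.integers(0, 2, 80), rng.standard_normal(80)]).astype(float)
        X = FeatureMatrix(values, ["bit", "cont"], "continuous")
        y = values[:, 0] + 0.1 * rng.standard_normal(80)
        model = fit(LearnerSpec(name="linear"), X, y)
        grid, _ = partial_dependence(model, X, "bit")
        assert len(grid) == 2

    def test_monotone_truth_monotone_pd(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 4, 200)
        X = FeatureMatrix(np.column_stack([x, rng.standard_normal(200)]), ["x", "n"], "continuous")
        y = np.sqrt(x) + 0.05 * rng.standard_normal(200)
        model = fit(LearnerSpec(name="gbm", params={"n_estimators": 80}), X, y)
        _, means = partial_dependence(model, X, "x", grid_size=8)
        assert np.all(np.diff(means) >= -0.02)
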