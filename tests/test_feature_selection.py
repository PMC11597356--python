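import numpy as np
import pytest

from qsarnest.feature_selection import (
    boruta_select,
    cmim_select,
    ga_select,
    jmim_select,
    mutual_information,
)
from qsarnest.features import FeatureMatrix
from qsarnest.learners import LearnerSpec
from qsarnest.synthetic_data import SyntheticSpec, gen_features, gen_regression_problem


class TestMutualInformation:
    def test_identity_is_log_bins(self):
        x = np.random.default_rng(0).standard_normal(5000)
        assert mutual_information(x, x, n_bins=10) == pytest.approx(np.log(10), abs=1e-9)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(1)
        mi = mutual_information(rng.standard_normal(5000), rng.standard_normal(5000))
        assert mi < 0.02

    def test_constant_vector_zero(self):
        assert mutual_information(np.ones(100), np.arange(100.0)) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(500)
        y = x + rng.standard_normal(500)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))


def _redundancy_problem(seed=0, n=600):
    """x2 is an exact copy of x1; x3 independently informative; 3 noise columns."""
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x3 = rng.standard_normal(n)
    noise = rng.standard_normal((n, 3))
    y = x1 + 0.8 * x3 + 0.3 * rng.standard_normal(n)
    fm = FeatureMatrix(
        np.column_stack([x1, x1.copy(), x3, noise]),
        ["x1", "x2", "x3", "n1", "n2", "n3"],
        "continuous",
    )
    return fm, y


class TestCmimJmim:
    def test_informative_feature_selected_first(self, independent_problem):
        X, y, truth, _ = independent_problem
        assert cmim_select(X, y, k=1).selected[0] in truth
        assert jmim_select(X, y, k=1).selected[0] in truth

    def test_copy_feature_deprioritized(self):
        fm, y = _redundancy_problem()
        for select in (cmim_select, jmim_select):
            result = select(fm, y, k=3)
            # x1 (or its copy) first, then the independently informative x3
            assert result.selected[0] in ("x1", "x2")
            assert result.selected[1] == "x3"
            other_copy = "x2" if result.selected[0] == "x1" else "x1"
            assert other_copy not in result.selected[:3] or result.selected[2] != other_copy

    def test_cmim_conditional_score_of_copy_is_zero(self):
        fm, y = _redundancy_problem()
        result = cmim_select(fm, y, k=fm.p)
        # once x1 is in, the copy's min conditional MI collapses to ~0
        copy_name = "x2" if result.selected[0] == "x1" else "x1"
        assert result.scores[copy_name] < 0.05

    def test_jmim_recovers_xor_interaction(self):
        rng = np.random.default_rng(7)
        n = 1000
        b1, b2 = rng.integers(0, 2, (2, n))
        noise = rng.integers(0, 2, (n, 4))
        y = (b1 ^ b2).astype(float)
        fm = FeatureMatrix(
            np.column_stack([b1, b2, noise]).astype(float),
            ["b1", "b2", "n1", "n2", "n3", "n4"],
            "binary",
        )
        # marginally both parents are uninformative (MI ~ 0) ...
        assert mutual_information(b1.astype(float), y) < 0.01
        assert mutual_information(b2.astype(float), y) < 0.01
        # ... but once b1 is in S, b2 attains the max joint MI and is picked
        result = jmim_select(fm, y, k=2, initial=["b1"])
        assert result.selected == ("b1", "b2")
        assert result.scores["b2"] > 0.5  # joint MI close to H(y) ~ log 2

    def test_k_zero_empty_and_k_p_full(self):
        fm, y = _redundancy_problem()
        assert cmim_select(fm, y, k=0).selected == ()
        assert set(jmim_select(fm, y, k=fm.p).selected) == set(fm.feature_names)

    def test_first_pick_is_argmax_marginal_mi(self):
        fm, y = _redundancy_problem(seed=3)
        marginal = [mutual_information(fm.values[:, j], y) for j in range(fm.p)]
        best = fm.feature_names[int(np.argmax(marginal))]
        assert cmim_select(fm, y, k=2).selected[0] == best
        assert jmim_select(fm, y, k=2).selected[0] == best


class TestBoruta:
    def test_planted_features_confirmed(self, independent_problem):
        X, y, truth, _ = independent_problem
        result = boruta_select(X, y, seed=1)
        assert set(truth) <= set(result.selected)
        assert len(set(result.selected) - set(truth)) <= 1

    def test_pure_noise_confirms_nothing(self):
        spec = SyntheticSpec(
            n=300, p=50, k_informative=0, noise_sd=1.0, r_star2=None, block_corr=0.0, seed=21
        )
        X = gen_features(spec)
        y = np.random.default_rng(22).normal(6, 1.5, 300)
        assert boruta_select(X, y, seed=2).selected == ()

    def test_seeded_determinism(self, independent_problem):
        X, y, _, _ = independent_problem
        a = boruta_select(X, y, max_iter=15, seed=9)
        b = boruta_select(X, y, max_iter=15, seed=9)
        assert a.selected == b.selected and a.scores == b.scores

    def test_max_iter_one_reproducible(self, independent_problem):
        X, y, _, _ = independent_problem
        a = boruta_select(X, y, max_iter=1, seed=3)
        assert a.params["n_confirmed"] + a.params["n_rejected"] + a.params["n_tentative"] == X.p

    def test_non_finite_rejected(self, independent_problem):
        X, y, _, _ = independent_problem
        bad = X.values.copy()
        bad[0, 0] = np.nan
        fm = FeatureMatrix(np.nan_to_num(bad), X.feature_names, "continuous")
        fm.values[0, 0] = np.inf
        with pytest.raises(ValueError):
            boruta_select(fm, y)


class TestGeneticAlgorithm:
    @pytest.fixture(scope="class")
    def small_problem(self):
        spec = SyntheticSpec(
            n=120, p=12, k_informative=3, beta=(1, 1, 1), noise_sd=0.5, r_star2=None,
            block_corr=0.0, seed=13,
        )
        return gen_regression_problem(spec)

    def test_informative_subset_beats_noise_subset(self, small_problem):
        from qsarnest.feature_selection import _cv_rmse

        X, y, truth, _ = small_problem
        spec = LearnerSpec(name="linear")
        idx_true = [X.feature_names.index(t) for t in truth]
        idx_noise = [j for j in range(X.p) if X.feature_names[j] not in truth][:3]
        fit_true = _cv_rmse(X.values[:, idx_true], y, spec, folds=5, seed=0)
        fit_noise = _cv_rmse(X.values[:, idx_noise], y, spec, folds=5, seed=0)
        assert fit_true < fit_noise

    def test_finds_informative_features(self, small_problem):
        X, y, truth, _ = small_problem
        result = ga_select(
            X, y, LearnerSpec(name="linear"), pop_size=20, generations=10, seed=4
        )
        assert set(truth) <= set(result.selected)

    def test_best_fitness_monotone_under_elitism(self, small_problem):
        X, y, _, _ = small_problem
        result = ga_select(
            X, y, LearnerSpec(name="linear"), pop_size=12, generations=8, seed=5
        )
        history = result.params["fitness_history"]
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_seeded_determinism(self, small_problem):
        X, y, _, _ = small_problem
        kwargs = dict(pop_size=10, generations=4, seed=6)
        a = ga_select(X, y, LearnerSpec(name="linear"), **kwargs)
        b = ga_select(X, y, LearnerSpec(name="linear"), **kwargs)
        assert a.selected == b.selected

    def test_zero_generations_returns_initial_best(self, small_problem):
        X, y, _, _ = small_problem
        result = ga_select(X, y, LearnerSpec(name="linear"), pop_size=10, generations=0, seed=7)
        assert len(result.selected) >= 1
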