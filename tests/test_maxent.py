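import numpy as np
import pytest
from scipy.stats import spearmanr

from sharksdm import (
    EnvStack,
    build_features,
    cumulative_output,
    cumulative_scores,
    fit_maxent,
    presences_to_cells,
    raw_distribution,
    sample_background,
    synth_sightings,
    synth_truth,
    training_gain,
)
from sharksdm.maxent import FeatureExpansion, FeatureMeta

from conftest import make_grid


def _single_feature_fe(col, presence_rows):
    col = np.asarray(col, float)
    n = len(col)
    cells = np.column_stack([np.arange(n), np.zeros(n, int)])
    return FeatureExpansion(
        design=col[:, None],
        feature_meta=[FeatureMeta("linear", ("v",))],
        presence_rows=np.asarray(presence_rows, int),
        cells=cells,
        variables=("v",),
    )


class TestSampleBackground:
    def test_all_cells_when_under_cap(self, tiny_stack):
        cells = sample_background(tiny_stack, max_points=10000, seed=0)
        assert len(cells) == (~tiny_stack.mask).sum()

    def test_cap_binds(self):
        g = make_grid(np.zeros((150, 150)))
        stack = EnvStack("July", {"depth": g.like(np.random.default_rng(0).normal(size=g.shape))})
        cells = sample_background(stack, max_points=10000, seed=1)
        assert len(cells) == 10000
        assert len(np.unique(cells, axis=0)) == 10000

    def test_deterministic_and_presences_unioned(self):
        g = make_grid(np.zeros((150, 150)))
        stack = EnvStack("July", {"depth": g})
        presence = np.array([[0, 0], [149, 149]])
        a = sample_background(stack, 5000, seed=3, presence_cells=presence)
        b = sample_background(stack, 5000, seed=3, presence_cells=presence)
        assert np.array_equal(a, b)
        flat = {tuple(c) for c in a}
        assert (0, 0) in flat and (149, 149) in flat


class TestBuildFeatures:
    def test_linear_only_single_variable(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        fe = build_features(tiny_stack, cells, cells[:1], classes=("linear",))
        assert fe.n_features == 3  # depth, chl_a, sst
        assert all(m.cls == "linear" for m in fe.feature_meta)
        assert fe.design.min() >= 0 and fe.design.max() <= 1

    def test_lqp_counts(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        fe = build_features(
            tiny_stack, cells, cells[:1], classes=("linear", "quadratic", "product")
        )
        assert fe.n_features == 3 + 3 + 3  # 3 linear, 3 quadratic, C(3,2) products

    def test_constant_variable_dropped_with_warning(self):
        g = make_grid(np.linspace(0, 1, 16).reshape(4, 4))
        flat = make_grid(np.full((4, 4), 2.0))
        stack = EnvStack("July", {"depth": g, "sst": flat})
        cells = stack.unmasked_cells()
        with pytest.warns(UserWarning, match="sst"):
            fe = build_features(stack, cells, cells[:1], classes=("linear",))
        assert fe.variables == ("depth",)

    def test_knot_count_cap(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        fe = build_features(
            tiny_stack, cells, cells[:1], classes=("threshold",), knots_per_variable=5
        )
        per_var = {v: 0 for v in fe.variables}
        for m in fe.feature_meta:
            per_var[m.variables[0]] += 1
        assert all(c <= 5 for c in per_var.values())


class TestFitMaxent:
    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        fe = _single_feature_fe(rng.random(50), [0, 1, 2])
        fit = fit_maxent(fe, beta=1e6)
        assert np.all(fit.lambdas == 0)
        assert np.allclose(fit.raw, 1.0 / 50)
        assert fit.training_gain == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_oracle(self):
        # binary feature: 15 of 20 presences have f=1, half of background does
        col = np.zeros(200)
        col[:100] = 1.0
        presence = np.concatenate([np.zeros(15, int), np.full(5, 150)])
        fe = _single_feature_fe(col, presence)
        fit = fit_maxent(fe, beta=0.0, max_iter=5000, tol=1e-10)
        grid = np.linspace(-3, 3, 600001)
        fbar = 15 / 20
        ll = fbar * grid - np.logaddexp(np.log(100) + grid, np.log(100))
        assert fit.lambdas[0] == pytest.approx(grid[np.argmax(ll)], abs=1e-3)

    def test_penalty_monotonicity(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        presence = cells[::7]
        fe = build_features(tiny_stack, cells, presence)
        g0 = fit_maxent(fe, beta=0.0).training_gain
        g1 = fit_maxent(fe, beta=1.0).training_gain
        assert g0 >= g1

    def test_deterministic_bit_identical(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        fe = build_features(tiny_stack, cells, cells[::9])
        a = fit_maxent(fe, beta=1.0)
        b = fit_maxent(fe, beta=1.0)
        assert np.array_equal(a.lambdas, b.lambdas)

    def test_n_params_non_increasing_in_beta(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        fe = build_features(tiny_stack, cells, cells[::5])
        n_params = [fit_maxent(fe, beta=b).n_params for b in (0.5, 1, 2, 4, 8)]
        assert all(a >= b for a, b in zip(n_params, n_params[1:]))

    def test_non_finite_design_rejected(self):
        fe = _single_feature_fe([0.0, np.nan, 1.0], [0])
        with pytest.raises(ValueError, match="non-finite"):
            fit_maxent(fe)


class TestRawDistribution:
    def test_zero_lambdas_uniform(self):
        fe = _single_feature_fe(np.linspace(0, 1, 30), [0, 1])
        fit = fit_maxent(fe, beta=1e9)
        raw = raw_distribution(fit, fe)
        assert np.allclose(raw, 1 / 30)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        col = rng.random(40)
        fe = _single_feature_fe(col, [0, 3, 5])
        fit = fit_maxent(fe, beta=0.5)
        shifted = _single_feature_fe(col + 0.7, [0, 3, 5])  # adds 0.7*lambda to eta
        assert np.allclose(raw_distribution(fit, fe), raw_distribution(fit, shifted))

    def test_matches_exp_normalize_oracle(self):
        rng = np.random.default_rng(2)
        col = rng.random(10)
        fe = _single_feature_fe(col, [0])
        fit = fit_maxent(fe, beta=1.0)
        eta = col * fit.lambdas[0]
        oracle = np.exp(eta) / np.exp(eta).sum()
        assert np.allclose(raw_distribution(fit, fe), oracle, atol=1e-12)

    def test_raw_sums_to_one(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        fe = build_features(tiny_stack, cells, cells[::11])
        fit = fit_maxent(fe, beta=1.0)
        assert fit.raw.sum() == pytest.approx(1.0, abs=1e-9)


class TestCumulativeOutput:
    def test_three_cell_example(self):
        assert np.allclose(cumulative_scores([0.5, 0.3, 0.2]), [100.0, 50.0, 20.0])

    def test_uniform_all_100(self):
        for n in (1, 4, 17):
            assert np.allclose(cumulative_scores(np.full(n, 1.0 / n)), 100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_cumsum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.random(60)
        raw[rng.integers(0, 60, 10)] = raw[0]  # inject ties
        raw /= raw.sum()
        cum = cumulative_scores(raw)
        oracle = np.array([100.0 * raw[raw <= r].sum() for r in raw])
        assert np.allclose(cum, oracle, atol=1e-9)
        assert cum.max() == pytest.approx(100.0)

    def test_painted_onto_grid(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        raw = np.full(len(cells), 1.0 / len(cells))
        smap = cumulative_output(raw, cells, tiny_stack.template)
        assert np.allclose(smap.cumulative.values[~smap.cumulative.mask], 100.0)


class TestTrainingGain:
    def test_zero_lambda_zero_gain(self):
        fe = _single_feature_fe(np.linspace(0, 1, 25), [0, 1, 2])
        fit = fit_maxent(fe, beta=1e9)
        assert training_gain(fit, fe) == pytest.approx(0.0, abs=1e-12)

    def test_separating_feature_gain_limit(self):
        # presences all in the f=1 group of 25 cells out of 100
        col = np.zeros(100)
        col[:25] = 1.0
        fe = _single_feature_fe(col, np.arange(10))
        fit = fit_maxent(fe, beta=0.0, max_iter=2000)
        limit = np.log(100 / 25)
        assert fit.training_gain <= limit + 1e-9
        assert fit.training_gain == pytest.approx(limit, abs=0.01)

    def test_matches_likelihood_oracle(self):
        rng = np.random.default_rng(6)
        col = rng.random(10)
        presence = np.array([1, 1, 4])
        fe = _single_feature_fe(col, presence)
        fit = fit_maxent(fe, beta=0.7)
        raw = raw_distribution(fit, fe)
        oracle = np.mean(np.log(raw[presence])) + np.log(10)
        assert training_gain(fit, fe) == pytest.approx(oracle, abs=1e-10)


class TestParameterRecovery:
    def test_two_feature_truth_recovered(self):
        # truth from two smooth linear effects; 500 presences; fitted
        # cumulative map should rank-correlate > 0.9 with the true raw surface
        rng = np.random.default_rng(21)
        shape = (30, 30)
        v1 = make_grid(np.linspace(0, 1, shape[1])[None, :] * np.ones(shape))
        v2 = make_grid(rng.normal(size=shape).cumsum(axis=0) / 10.0)
        stack = EnvStack("July", {"depth": v1, "sst": v2})
        truth = synth_truth(stack, {"depth": 3.0, "sst": 2.0})
        table = synth_sightings(truth, 500, "July", seed=21)
        assign = presences_to_cells(table, stack.template)
        cells = stack.unmasked_cells()
        fe = build_features(stack, cells, assign.cells, classes=("linear",))
        fit = fit_maxent(fe, beta=0.5)
        cum = cumulative_scores(fit.raw)
        truth_vals = truth.values[cells[:, 0], cells[:, 1]]
        rho = spearmanr(cum, truth_vals).statistic
        assert rho > 0.9
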