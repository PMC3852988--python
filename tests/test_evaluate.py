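import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from sharksdm import (
    DEFAULT_BETA_GRID,
    aicc,
    classify_auc,
    fit_maxent,
    fit_replicates,
    jackknife_gain,
    percent_contribution,
    permutation_importance,
    roc_auc,
    select_regularization,
    standardized_likelihood,
)
from sharksdm.maxent import FeatureExpansion, FeatureMeta


class TestStandardizedLikelihood:
    def test_uniform(self):
        raw = np.full(20, 1 / 20)
        assert standardized_likelihood(raw, [0, 3, 7]) == pytest.approx(3 * np.log(1 / 20))

    def test_direct_product(self):
        raw = np.array([0.5, 0.3, 0.2])
        ll = standardized_likelihood(raw, [0, 0, 2])
        assert ll == pytest.approx(np.log(0.5 * 0.5 * 0.2))

    def test_unvisited_zero_cell_no_effect(self):
        raw = np.array([0.5, 0.3, 0.2])
        raw_aug = np.array([0.5, 0.3, 0.2, 0.0])
        assert standardized_likelihood(raw, [0, 2]) == pytest.approx(
            standardized_likelihood(raw_aug, [0, 2])
        )

    def test_presence_on_zero_cell_is_neg_inf(self):
        assert standardized_likelihood(np.array([1.0, 0.0]), [1]) == -np.inf


class TestAicc:
    def test_k_zero(self):
        assert aicc(-5.0, 0, 10).aicc == pytest.approx(10.0)

    def test_closed_form(self):
        rec = aicc(-10.0, 2, 10)
        assert rec.aicc == pytest.approx(4 + 20 + 12 / 7)

    def test_undefined_guard(self):
        rec = aicc(-10.0, 9, 10)
        assert not rec.defined and rec.aicc is None


class TestSelectRegularization:
    def test_default_grid_has_nine_candidates(self):
        assert DEFAULT_BETA_GRID == (1, 3, 5, 7, 9, 11, 13, 15, 17)

    def test_single_candidate(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        sel = select_regularization(tiny_stack, cells[::6], beta_grid=(2.0,), seed=0)
        assert sel.best_beta == 2.0
        assert len(sel.table) == 1

    def test_tie_breaks_to_smaller_beta(self, tiny_stack):
        # huge betas shrink everything to zero -> identical AICc records
        cells = tiny_stack.unmasked_cells()
        sel = select_regularization(tiny_stack, cells[::6], beta_grid=(500.0, 900.0), seed=0)
        assert sel.best_beta == 500.0

    def test_all_undefined_raises(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        # 2 presences cannot support any nonzero-parameter model's AICc
        with pytest.raises(ValueError, match="AICc undefined"):
            select_regularization(tiny_stack, cells[:2], beta_grid=(0.001,), seed=0)


class TestRocAuc:
    def test_three_quarters_concordant(self):
        r = roc_auc([0.9, 0.4], [0.5, 0.1])
        assert r.auc == pytest.approx(0.75)

    def test_identical_distributions(self):
        r = roc_auc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.auc == pytest.approx(0.5)

    def test_max_ss_threshold_sweep(self):
        r = roc_auc([0.8, 0.6], [0.7, 0.2, 0.1])
        assert r.max_ss_threshold == pytest.approx(0.6)
        i = np.where(r.thresholds == 0.6)[0][0]
        assert r.sensitivity[i] == pytest.approx(1.0)
        assert r.specificity[i] == pytest.approx(2 / 3)

    def test_threshold_tie_goes_lower(self):
        # two thresholds reach the same sens+spec; the lower one is returned
        r = roc_auc([1.0, 2.0], [0.0])
        assert r.max_ss_threshold == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60)
    @given(
        p=st.lists(st.integers(0, 10), min_size=1, max_size=100),
        b=st.lists(st.integers(0, 10), min_size=1, max_size=100),
    )
    def test_matches_pairwise_concordance_oracle(self, p, b):
        p, b = np.array(p, float), np.array(b, float)
        auc = roc_auc(p, b).auc
        wins = sum((pi > bi) + 0.5 * (pi == bi) for pi in p for bi in b)
        assert auc == pytest.approx(wins / (len(p) * len(b)), abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(0)
        p = rng.normal(1, 1, 50)
        b = rng.normal(0, 1, 80)
        y = np.concatenate([np.ones(50), np.zeros(80)])
        assert roc_auc(p, b).auc == pytest.approx(
            roc_auc_score(y, np.concatenate([p, b])), abs=1e-12
        )


class TestClassifyAuc:
    @pytest.mark.parametrize(
        "auc,label",
        [
            (0.796, "better than random"),
            (0.5, "no discrimination"),
            (0.3, "worse than random"),
            (1.0, "perfect discrimination"),
        ],
    )
    def test_bins(self, auc, label):
        assert classify_auc(auc) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_auc(1.2)


class TestFitReplicates:
    def test_loo_fold_count_and_determinism(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        presence = cells[::80][:4]
        a = fit_replicates(tiny_stack, presence, beta=1.0, mode="crossvalidation",
                           replicates=100, seed=5)
        b = fit_replicates(tiny_stack, presence, beta=1.0, mode="crossvalidation",
                           replicates=100, seed=5)
        assert len(a.auc) == 4  # leave-one-out when n < replicates
        assert np.array_equal(a.auc, b.auc)

    def test_replicate_cap(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        ens = fit_replicates(tiny_stack, cells[::40], beta=2.0, mode="bootstrap",
                             replicates=1000, seed=1)
        assert len(ens.auc) == 100

    def test_single_replicate_sd_map_zero(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        ens = fit_replicates(tiny_stack, cells[::40], beta=2.0, mode="bootstrap",
                             replicates=1, seed=1)
        sd = ens.suitability.replicate_sd
        assert np.allclose(sd.values[~sd.mask], 0.0)

    def test_subsampling_split_sizes(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        presence = cells[::30]
        ens = fit_replicates(tiny_stack, presence, beta=2.0, mode="subsampling",
                             replicates=3, test_fraction=0.25, seed=2)
        assert len(ens.auc) == 3

    def test_invalid_mode_and_fraction(self, tiny_stack):
        cells = tiny_stack.unmasked_cells()
        with pytest.raises(ValueError, match="mode"):
            fit_replicates(tiny_stack, cells[::40], 1.0, mode="jackknife")
        with pytest.raises(ValueError, match="test_fraction"):
            fit_replicates(tiny_stack, cells[::40], 1.0, mode="subsampling",
                           test_fraction=1.5)


def _informative_fe(n_extra_vars=2, seed=0, n=300):
    """One strongly informative binary variable plus noise variables."""
    rng = np.random.default_rng(seed)
    cols = [np.r_[np.ones(n // 2), np.zeros(n - n // 2)]]
    names = ["depth"]
    meta = [FeatureMeta("linear", ("depth",))]
    pool = ["sst", "chl_a", "slope", "aspect"]
    for k in range(n_extra_vars):
        cols.append(rng.random(n))
        names.append(pool[k])
        meta.append(FeatureMeta("linear", (pool[k],)))
    presence = rng.integers(0, n // 2, 40)  # all in the f=1 half
    cells = np.column_stack([np.arange(n), np.zeros(n, int)])
    return FeatureExpansion(np.column_stack(cols), meta, presence, cells, tuple(names))


class TestImportance:
    def test_single_variable_contribution_is_100(self):
        fe = _informative_fe(n_extra_vars=0)
        fit = fit_maxent(fe, beta=1.0)
        pc = percent_contribution(fit, fe)
        assert pc["depth"] == pytest.approx(100.0)

    def test_duplicated_variable_conserves_total(self):
        fe = _informative_fe(n_extra_vars=0)
        design = np.column_stack([fe.design[:, 0], fe.design[:, 0]])
        meta = [FeatureMeta("linear", ("depth",)), FeatureMeta("linear", ("sst",))]
        fe2 = FeatureExpansion(design, meta, fe.presence_rows, fe.cells, ("depth", "sst"))
        fit = fit_maxent(fe2, beta=1.0)
        pc = percent_contribution(fit, fe2)
        assert pc.sum() == pytest.approx(100.0, abs=0.01)

    def test_inactive_variable_zero_contribution(self):
        fe = _informative_fe(n_extra_vars=2, seed=3)
        fit = fit_maxent(fe, beta=4.0)
        lam_by_var = {
            v: fit.lambdas[[j for j, m in enumerate(fe.feature_meta) if m.variables == (v,)]]
            for v in fe.variables
        }
        pc = percent_contribution(fit, fe)
        for v, lams in lam_by_var.items():
            if np.all(lams == 0):
                assert pc[v] == pytest.approx(0.0, abs=1e-12)

    def test_permutation_importance_sums_to_100(self):
        fe = _informative_fe(n_extra_vars=2, seed=1)
        fit = fit_maxent(fe, beta=0.5)
        pi = permutation_importance(fit, fe, seed=1)
        assert pi.sum() == pytest.approx(100.0, abs=0.01)

    def test_sole_informative_variable_dominates(self):
        fe = _informative_fe(n_extra_vars=2, seed=2)
        fit = fit_maxent(fe, beta=2.0)
        pi = permutation_importance(fit, fe, seed=2)
        assert pi["depth"] == pytest.approx(100.0, abs=1e-9)

    def test_absent_variable_zero_importance(self):
        fe = _informative_fe(n_extra_vars=1, seed=4)
        fit = fit_maxent(fe, beta=8.0)
        cols = [j for j, m in enumerate(fe.feature_meta) if m.variables == ("sst",)]
        if np.all(fit.lambdas[cols] == 0):
            pi = permutation_importance(fit, fe, seed=4)
            assert pi["sst"] == pytest.approx(0.0, abs=1e-12)


class TestJackknife:
    def test_single_variable(self):
        fe = _informative_fe(n_extra_vars=0)
        jk = jackknife_gain(fe, beta=1.0)
        assert jk.loc["depth", "gain_alone"] == pytest.approx(jk.attrs["full_gain"], abs=1e-6)
        assert np.isnan(jk.loc["depth", "gain_without"])

    def test_noise_variable_barely_matters(self):
        fe = _informative_fe(n_extra_vars=1, seed=5)
        jk = jackknife_gain(fe, beta=1.0)
        full = jk.attrs["full_gain"]
        assert jk.loc["sst", "gain_without"] == pytest.approx(full, rel=0.05)

    def test_gain_alone_bounded_by_full(self):
        fe = _informative_fe(n_extra_vars=2, seed=6)
        jk = jackknife_gain(fe, beta=1.0)
        full = jk.attrs["full_gain"]
        assert (jk["gain_alone"] <= full + 1e-6).all()
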