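"""Information criteria, classification skill, cross-validation, Moran's I,
mixed-model R², and multi-iteration ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import koalasdm as k
from koalasdm.selection import _lag_pairs, morans_i

from conftest import FreeSpec, simulated_design


class TestInformationCriteria:
    def test_aicc_closed_form(self):
        assert k.aicc(-100, 3, 50) == pytest.approx(206.5217, abs=1e-4)

    def test_aicc_approaches_aic_for_large_n(self):
        aic = -2 * (-100) + 2 * 3
        assert abs(k.aicc(-100, 3, 10**6) - aic) < 1e-4

    def test_aicc_small_sample_guard(self):
        with pytest.raises(ValueError):
            k.aicc(-100, 3, 4)

    def test_bic_closed_form(self):
        assert k.bic(-100, 3, 50) == pytest.approx(211.7360, abs=1e-4)

    def test_bic_zero_parameters(self):
        assert k.bic(-50, 0, 10) == pytest.approx(100.0)

    def test_bic_penalty_monotone_in_k(self):
        assert k.bic(-100, 5, 50) > k.bic(-100, 3, 50)

    def test_weights_two_unit_delta(self):
        w = k.info_weights([0.0, 2.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_weights_single_model(self):
        assert k.info_weights([123.4]) == pytest.approx([1.0])

    def test_weights_symmetry(self):
        assert np.allclose(k.info_weights([7.0] * 5), 0.2)

    def test_weights_reject_nonfinite(self):
        with pytest.raises(ValueError):
            k.info_weights([1.0, np.inf])

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=1, max_size=12),
        st.floats(min_value=-1e6, max_value=1e6),
    )
    def test_weights_normalize_and_shift_invariant(self, values, shift):
        w = k.info_weights(values)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, k.info_weights(np.asarray(values) + shift), atol=1e-9)


class TestPctDeviance:
    def _fit(self, dev):
        f = k.FitResult(
            name="m", params=pd.Series({"intercept": 0.0}), bse=pd.Series({"intercept": 1.0}),
            loglik=-dev / 2, deviance=dev, sigma2_alpha=0.0, n_obs=10, k=1,
            fitted=np.array([]), converged=True,
        )
        return f

    def test_identity_is_zero(self):
        assert k.pct_deviance(self._fit(100.0), self._fit(100.0)) == 0.0

    def test_half_deviance(self):
        assert k.pct_deviance(self._fit(50.0), self._fit(100.0)) == pytest.approx(50.0)

    def test_saturated_limit(self):
        assert k.pct_deviance(self._fit(0.0), self._fit(100.0)) == pytest.approx(100.0)

    def test_zero_null_deviance_errors(self):
        with pytest.raises(ValueError):
            k.pct_deviance(self._fit(0.0), self._fit(0.0))


class TestCohensKappa:
    def test_perfect_agreement(self):
        y = np.array([1, 1, 0, 0])
        assert k.cohens_kappa(y, y.astype(float)) == pytest.approx(1.0)

    def test_hand_computed_confusion_table(self):
        # TP=40, TN=40, FP=10, FN=10: p_o=0.8, p_e=0.5, kappa=0.6
        y = np.r_[np.ones(40), np.zeros(40), np.zeros(10), np.ones(10)]
        p = np.r_[np.ones(40), np.zeros(40), np.ones(10), np.zeros(10)]
        assert k.cohens_kappa(y, p) == pytest.approx(0.6, abs=1e-12)

    def test_chance_level_predictions(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 10_000)
        p = rng.random(10_000)  # independent of y, matching 0.5 marginal
        assert abs(k.cohens_kappa(y, p)) < 0.05

    def test_degenerate_marginals_nan(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = k.cohens_kappa(np.ones(5), np.ones(5))
        assert np.isnan(out)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = rng.integers(0, 2, 50)
            p = rng.random(50)
            w = rng.choice([0.1, 1.0], 50)
            kap = k.cohens_kappa(y, p, w)
            assert -1.0 <= kap <= 1.0


class TestCrossValidate:
    def test_strong_signal_low_error(self):
        d, _ = simulated_design(n=600, beta=(6.0,), seed=3)
        mean, sd = k.cross_validate(d, FreeSpec("m", ("x0",)), n_folds=5, seed=1,
                                    use_random_effect=False)
        assert mean < 0.15

    def test_constant_half_probability_error(self):
        rng = np.random.default_rng(4)
        d = pd.DataFrame(
            {"response": rng.integers(0, 2, 400), "weight": 1.0, "offset": 0.0}
        )
        mean, _ = k.cross_validate(d, FreeSpec("null", ()), n_folds=5, seed=1,
                                   use_random_effect=False)
        assert mean == pytest.approx(0.5, abs=0.05)

    def test_every_row_held_out_once(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.random.default_rng(5).integers(0, 2, 100)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=1)
        seen = np.concatenate([test for _, test in skf.split(np.zeros(100), y)])
        assert sorted(seen) == list(range(100))

    def test_too_few_folds_rejected(self):
        d, _ = simulated_design(n=50, beta=(1.0,), seed=6)
        with pytest.raises(ValueError):
            k.cross_validate(d, FreeSpec("m", ("x0",)), n_folds=1, seed=0)


class TestMoransI:
    def test_checkerboard_is_minus_one(self):
        vals = np.array([1.0, -1.0, -1.0, 1.0])
        ii, jj = _lag_pairs(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]), 1)
        I, _, _ = morans_i(vals, ii, jj)
        assert I == pytest.approx(-1.0, abs=1e-12)

    def test_iid_values_near_null_expectation(self):
        n_side = 30
        rng = np.random.default_rng(7)
        vals = rng.normal(size=n_side * n_side)
        rows, cols = np.divmod(np.arange(n_side * n_side), n_side)
        cg = k.morans_correlogram(vals, rows, cols, n_lags=1)
        n = n_side * n_side
        ii, jj = _lag_pairs(rows, cols, 1)
        _, e_i, var_i = morans_i(vals, ii, jj)
        assert abs(cg["I"].iloc[0] - e_i) < 3 * np.sqrt(var_i)

    def test_bonferroni_threshold(self):
        # smooth field: strong positive autocorrelation at lag 1
        g = k.make_landscape(20, 20, 0.9, seed=8)
        vals = g.predictors["elevation"].to_numpy()
        rows = g.predictors["row"].to_numpy()
        cols = g.predictors["col"].to_numpy()
        cg = k.morans_correlogram(vals, rows, cols, n_lags=5, alpha=0.05)
        assert bool(cg.loc[0, "significant"])
        assert (cg["significant"] == (cg["p"] < 0.01)).all()

    def test_zero_variance_rejected(self):
        rows, cols = np.divmod(np.arange(16), 4)
        with pytest.raises(ValueError):
            k.morans_correlogram(np.ones(16), rows, cols)

    def test_minimum_cells(self):
        with pytest.raises(ValueError):
            k.morans_correlogram(np.arange(4.0), np.zeros(4), np.arange(4))


class TestR2Nakagawa:
    def _fit(self, linpred, sigma2):
        return k.FitResult(
            name="m", params=pd.Series({"intercept": 0.0}), bse=pd.Series({"intercept": 1.0}),
            loglik=0.0, deviance=0.0, sigma2_alpha=sigma2, n_obs=len(linpred), k=1,
            fitted=np.array([]), converged=True, linpred_fixed=np.asarray(linpred),
        )

    def test_null_model_zero(self):
        r2m, r2c = k.r2_nakagawa(self._fit(np.zeros(100), 0.0))
        assert r2m == 0.0 and r2c == 0.0

    def test_no_random_effect_equalizes(self):
        lp = np.random.default_rng(9).normal(size=200)
        r2m, r2c = k.r2_nakagawa(self._fit(lp, 0.0))
        assert r2m == pytest.approx(r2c)

    def test_unit_variances_closed_form(self):
        rng = np.random.default_rng(10)
        lp = rng.normal(size=200_000)
        lp = (lp - lp.mean()) / lp.std()  # variance exactly 1
        r2m, _ = k.r2_nakagawa(self._fit(lp, 1.0))
        assert r2m == pytest.approx(100.0 / (2 + np.pi**2 / 3), abs=1e-6)


@pytest.fixture(scope="module")
def ranked(grid, occurrence, specs):
    designs = k.build_design_iterations(occurrence, grid, n_iterations=2, ratio=5)
    return k.rank_models(designs, specs, n_folds=0)


class TestRankModels:
    def test_waicc_sums_to_one_per_iteration(self, ranked):
        sums = ranked.per_iteration.groupby("iteration")["waicc"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_ranks_are_permutations(self, ranked):
        for _, sub in ranked.per_iteration.groupby("iteration"):
            assert sorted(sub["rank"]) == list(range(1, len(sub) + 1))

    def test_single_iteration_median_is_rank(self, grid, occurrence, specs):
        designs = k.build_design_iterations(occurrence, grid, n_iterations=1, ratio=5)
        res = k.rank_models(designs, specs, n_folds=0)
        merged = res.table.merge(res.per_iteration, on="model")
        assert (merged["median_rank"] == merged["rank"]).all()

    def test_invariant_to_model_ordering(self, grid, occurrence, specs, ranked):
        designs = k.build_design_iterations(occurrence, grid, n_iterations=2, ratio=5)
        res2 = k.rank_models(designs, list(reversed(specs)), n_folds=0)
        a = ranked.table.sort_values("model").reset_index(drop=True)
        b = res2.table.sort_values("model").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, atol=1e-10)

    def test_null_model_explains_nothing(self, ranked):
        null_rows = ranked.per_iteration[ranked.per_iteration["model"] == "null"]
        assert np.allclose(null_rows["pct_deviance"], 0.0)
        assert np.allclose(null_rows["r2m"], 0.0, atol=1e-8)


class TestResidualAutocorrelation:
    def test_glmm_residuals_less_autocorrelated_than_glm(self, grid, specs):
        """Block random intercepts soak up the spatial signal the GLM leaves
        in its residuals."""
        truth = k.TrueModel(
            coefficients={"temp_range": -0.8, "elevation": 0.005},
            intercept=-0.5, re_sd=1.0, block_size=4,
        )
        spec = specs[8]  # elevation only: misspecified, leaves structure
        wins = 0
        n_reps = 10
        for rep in range(n_reps):
            _, presence = k.simulate_occupancy(grid, truth, seed=500 + rep)
            d = grid.predictors.copy().reset_index()
            d["response"] = presence
            d["weight"] = 1.0
            d["offset"] = 0.0
            glm = k.fit_glm(d, spec)
            glmm = k.fit_glmm(d, spec, block_size=4)
            r_glm = k.pearson_residuals(glm, d)
            r_glmm = k.pearson_residuals(glmm, d)
            rows = d["row"].to_numpy()
            cols = d["col"].to_numpy()
            i_glm = k.morans_correlogram(r_glm, rows, cols, n_lags=1)["I"].iloc[0]
            i_glmm = k.morans_correlogram(r_glmm, rows, cols, n_lags=1)["I"].iloc[0]
            wins += abs(i_glmm) < abs(i_glm)
        assert wins >= 0.9 * n_reps
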