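"""Weighted binomial GLM/GLMM core: IRLS, Laplace marginal likelihood,
prediction contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import koalasdm as k
from koalasdm.glmm import (
    _design_matrix,
    _laplace_loglik,
    _pirls,
    marginal_loglik_quadrature,
)

from conftest import FreeSpec, simulated_design

NULL = FreeSpec("null", ())


class TestFitGlm:
    def test_intercept_only_closed_form(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        w = rng.choice([0.1, 1.0, 3.0], 200)
        d = pd.DataFrame({"response": y, "weight": w, "offset": 0.0})
        fit = k.fit_glm(d, NULL)
        assert fit.params["intercept"] == pytest.approx(
            logit(np.sum(w * y) / np.sum(w)), abs=1e-7
        )

    def test_all_same_response_flags_separation(self):
        d = pd.DataFrame({"response": np.ones(20, dtype=int), "weight": 1.0, "offset": 0.0})
        fit = k.fit_glm(d, NULL)
        assert not fit.converged
        assert "possible_separation" in fit.flags

    def test_coefficient_recovery_within_3_se(self):
        d, _ = simulated_design(n=5000, beta=(0.5, -1.0), seed=1)
        fit = k.fit_glm(d, FreeSpec("m", ("x0", "x1")))
        for name, true in (("x0", 0.5), ("x1", -1.0)):
            assert abs(fit.params[name] - true) <= 3 * fit.bse[name]

    def test_agrees_with_statsmodels_weighted_offset_glm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        d, _ = simulated_design(n=800, beta=(0.7,), seed=3, offset_sd=0.3,
                                weights=rng.choice([0.1, 1.0], 800))
        fit = k.fit_glm(d, FreeSpec("m", ("x0",)))
        ref = sm.GLM(
            d["response"].to_numpy(dtype=float),
            sm.add_constant(d["x0"].to_numpy()),
            family=sm.families.Binomial(),
            var_weights=d["weight"].to_numpy(),
            offset=d["offset"].to_numpy(),
        ).fit()
        assert np.allclose(fit.params.values, ref.params, atol=1e-7)
        assert np.allclose(fit.bse.values, ref.bse, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_rank_deficiency_names_columns(self):
        d, _ = simulated_design(n=100, beta=(0.5, 0.5), seed=2)
        d["x1"] = d["x0"]
        with pytest.raises(ValueError, match="x1"):
            k.fit_glm(d, FreeSpec("m", ("x0", "x1")))

    def test_duplicated_row_equals_doubled_weight(self):
        d, _ = simulated_design(n=120, beta=(0.6,), seed=5)
        dup = pd.concat([d, d.iloc[[0]]], ignore_index=True)
        dw = d.copy()
        dw.loc[0, "weight"] = 2.0
        f1 = k.fit_glm(dup, FreeSpec("m", ("x0",)))
        f2 = k.fit_glm(dw, FreeSpec("m", ("x0",)))
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)
        assert np.allclose(f1.params.values, f2.params.values, atol=1e-8)

    def test_nested_deviance_monotone(self, design, specs):
        null_fit = k.fit_glm(design, next(s for s in specs if s.is_null))
        for spec in specs[:3]:
            fit = k.fit_glm(design, spec)
            assert fit.deviance <= null_fit.deviance + 1e-6


class TestFitGlmm:
    def test_matches_glm_when_no_random_variation(self):
        d, blocks = simulated_design(n=1500, beta=(0.5,), seed=8, re_sd=0.0, n_blocks=50)
        glm = k.fit_glm(d, FreeSpec("m", ("x0",)))
        glmm = k.fit_glmm(d, FreeSpec("m", ("x0",)), blocks=blocks)
        assert glmm.loglik == pytest.approx(glm.loglik, abs=1e-4)
        assert glmm.sigma2_alpha < 1e-3

    def test_profile_at_zero_variance_equals_glm(self):
        """The GLM is the σ→0 limit of the Laplace marginal likelihood."""
        for seed in range(5):
            d, blocks = simulated_design(n=300, beta=(0.4,), seed=seed, n_blocks=10)
            spec = FreeSpec("m", ("x0",))
            glm = k.fit_glm(d, spec)
            X, _ = _design_matrix(d, spec)
            y = d["response"].to_numpy(dtype=float)
            w = d["weight"].to_numpy(dtype=float)
            off = d["offset"].to_numpy(dtype=float)
            nb = blocks.max() + 1
            sigma2 = 1e-12
            beta, u, *_ = _pirls(X, y, w, off, blocks, nb, sigma2,
                                 glm.params.values.copy(), np.zeros(nb))
            ll = _laplace_loglik(X, y, w, off, blocks, nb, sigma2, beta, u)
            assert ll == pytest.approx(glm.loglik, abs=1e-6)

    def test_variance_recovery_band(self):
        """σ̂² lands in [0.5, 2.0] for true σ²=1 in ≥90% of 20 replicates."""
        hits = 0
        spec = FreeSpec("m", ("x0",))
        for rep in range(20):
            d, blocks = simulated_design(
                n=400 * 25, beta=(0.5,), seed=100 + rep, re_sd=1.0, n_blocks=400
            )
            fit = k.fit_glmm(d, spec, blocks=blocks)
            hits += 0.5 <= fit.sigma2_alpha <= 2.0
        assert hits >= 18

    def test_laplace_agrees_with_adaptive_quadrature(self):
        d, blocks = simulated_design(n=1200, beta=(0.7,), seed=9, re_sd=0.8, n_blocks=2)
        spec = FreeSpec("m", ("x0",))
        fit = k.fit_glmm(d, spec, blocks=blocks)
        X, _ = _design_matrix(d, spec)
        gh = marginal_loglik_quadrature(
            X,
            d["response"].to_numpy(dtype=float),
            d["weight"].to_numpy(dtype=float),
            d["offset"].to_numpy(dtype=float),
            blocks,
            2,
            max(fit.sigma2_alpha, 1e-12),
            fit.params.values,
            n_quad=21,
        )
        assert fit.loglik == pytest.approx(gh, abs=1e-3)

    def test_single_block_warns_but_fits(self):
        d, _ = simulated_design(n=200, beta=(0.5,), seed=11)
        with pytest.warns(UserWarning, match="single"):
            fit = k.fit_glmm(d, FreeSpec("m", ("x0",)), blocks=np.zeros(200, dtype=int))
        assert np.isfinite(fit.loglik)

    def test_k_counts_variance_component(self, design, specs):
        glm = k.fit_glm(design, specs[8])
        glmm = k.fit_glmm(design, specs[8])
        assert glmm.k == glm.k + 1


class TestPredictProb:
    def _fit(self, params, centering=None):
        names = list(params)
        return k.FitResult(
            name="m",
            params=pd.Series(params),
            bse=pd.Series({n: 1.0 for n in names}),
            loglik=0.0,
            deviance=0.0,
            sigma2_alpha=0.0,
            n_obs=1,
            k=len(names),
            fitted=np.array([]),
            converged=True,
            centering=centering or {},
            offset_mean=0.0,
        )

    def test_null_gives_half(self):
        fit = self._fit({"intercept": 0.0})
        p = k.predict_prob(fit, pd.DataFrame(index=range(3)), offset=0.0)
        assert np.allclose(p, 0.5)

    def test_logit_closed_form(self):
        fit = self._fit({"intercept": 0.0, "x": 1.0})
        p = k.predict_prob(fit, pd.DataFrame({"x": [0.5]}), offset=0.0)
        assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-0.5)), abs=1e-4)

    def test_offset_shifts_logit_exactly(self, design, specs):
        fit = k.fit_glm(design, specs[8])
        base = k.predict_prob(fit, design, offset=0.0, already_centered=True)
        shifted = k.predict_prob(fit, design, offset=1.5, already_centered=True)
        assert np.allclose(logit(shifted) - logit(base), 1.5, atol=1e-8)

    def test_missing_predictor_errors(self):
        fit = self._fit({"intercept": 0.0, "x": 1.0})
        with pytest.raises(ValueError, match="x"):
            k.predict_prob(fit, pd.DataFrame({"y": [1.0]}))

    def test_training_centering_reapplied(self):
        fit = self._fit({"intercept": 0.0, "x": 2.0}, centering={"x": 10.0})
        p = k.predict_prob(fit, pd.DataFrame({"x": [10.0]}), offset=0.0)
        assert p[0] == pytest.approx(0.5)
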