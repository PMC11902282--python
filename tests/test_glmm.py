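"""GLMM design, likelihood, fitting and prediction tests.

The quadrature likelihood is checked against brute-force numerical
integration; the fitting path against the plain-logistic limit and a
local-maximum property; predictions against closed-form cases.
"""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logsumexp

from conftest import simulate_glmm
from isoscreen.glmm import (
    ModelSpec,
    _group_loglik,
    aicc,
    build_design,
    eb_modes,
    fit_glmm,
    predict_ss,
)


class TestModelSpec:
    def test_formula_roundtrip(self):
        spec = ModelSpec.from_formula(
            "system ~ crop + cn_ratio + c_pct + d15n + crop:d15n + crop:cn_ratio"
            " + (1 | company)"
        )
        assert spec.response == "system"
        assert spec.grouping == "company"
        assert ("crop",) in spec.fixed_terms
        assert ("crop", "d15n") in spec.fixed_terms
        assert ModelSpec.from_formula(spec.formula()) == spec

    def test_star_expansion(self):
        spec = ModelSpec.from_formula("y ~ a*b")
        assert set(spec.fixed_terms) == {("a",), ("b",), ("a", "b")}

    def test_hierarchy_enforced(self):
        with pytest.raises(ValueError, match="hierarchy"):
            ModelSpec(response="y", fixed_terms=(("a",), ("a", "b")))


class TestBuildDesign:
    def test_final_model_column_count(self, default_table):
        # 7-level crop, 3 continuous mains, 2 crop-by-continuous
        # interactions: 1 + 6 + 3 + 6 + 6 = 22 columns
        spec = ModelSpec.from_formula(
            "system ~ crop + cn_ratio + c_pct + d15n + crop:d15n + crop:cn_ratio"
            " + (1 | company)"
        )
        d = build_design(spec, default_table)
        assert d.X.shape[1] == 22
        assert d.colnames[0] == "Intercept"

    def test_intercept_only(self, default_table):
        d = build_design(
            ModelSpec(response="system", fixed_terms=(), grouping="company"),
            default_table,
        )
        assert d.X.shape[1] == 1
        np.testing.assert_array_equal(d.X[:, 0], 1.0)

    def test_two_crop_toy_table_matches_hand_coding(self):
        df = pd.DataFrame(
            {
                "y": [0, 1, 0, 1],
                "crop": ["a", "a", "b", "b"],
                "x": [1.0, 2.0, 3.0, 4.0],
                "g": ["u", "u", "v", "v"],
            }
        )
        spec = ModelSpec.from_formula("y ~ crop + x + crop:x + (1|g)")
        d = build_design(spec, df)
        assert d.colnames == ["Intercept", "crop[b]", "x", "crop[b]:x"]
        xc = df["x"] - df["x"].mean()
        hand = np.column_stack(
            [np.ones(4), [0, 0, 1, 1], xc, [0, 0, 1, 1] * xc]
        )
        np.testing.assert_allclose(d.X, hand)
        # natural-scale transform undoes the centering
        beta_c = np.array([0.5, -0.2, 1.0, 0.4])
        eta = d.X @ beta_c
        nat = np.column_stack([np.ones(4), [0, 0, 1, 1], df["x"], [0, 0, 1, 1] * df["x"]])
        np.testing.assert_allclose(nat @ (d.natural_transform @ beta_c), eta)

    def test_unseen_level_raises(self, default_table):
        spec = ModelSpec.from_formula("system ~ crop + (1|company)")
        d = build_design(spec, default_table)
        bad = default_table.head(3).copy()
        bad.loc[bad.index[0], "crop"] = "durian"
        with pytest.raises(ValueError, match="durian"):
            build_design(spec, bad, template=d)


class TestLikelihood:
    def test_adaptive_quadrature_matches_dense_grid(self):
        # toy data, <= 5 groups: brute-force integration over a dense b
        # grid agrees with the adaptive rule within 1e-4 per group
        df = simulate_glmm(seed=12, n_groups=4, per_group=5, sigma_b=1.0)
        d = build_design(ModelSpec.from_formula("y ~ x + (1|g)"), df)
        theta = np.array([0.2, 0.8, np.log(1.3)])
        z, w = np.polynomial.hermite.hermgauss(11)
        ll = _group_loglik(theta, d.y, d.X, d.group_idx, 4, z, np.log(w))
        bg = np.linspace(-12, 12, 10_001)
        eta = d.X @ theta[:2]
        sigma = np.exp(theta[-1])
        for gi in range(4):
            m = d.group_idx == gi
            lp = (
                d.y[m][:, None] * (eta[m][:, None] + bg)
                - np.logaddexp(0, eta[m][:, None] + bg)
            ).sum(axis=0)
            lp += -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * (bg / sigma) ** 2
            brute = logsumexp(lp) + np.log(bg[1] - bg[0])
            assert abs(ll[gi] - brute) < 1e-4

    def test_sigma_zero_limit_matches_plain_logistic(self):
        df = simulate_glmm(seed=3, n_groups=40, per_group=20, sigma_b=0.0)
        d = build_design(ModelSpec.from_formula("y ~ x + (1|g)"), df)
        fit = fit_glmm(d)
        assert fit.converged
        ref = sm.Logit(d.y, sm.add_constant(df["x"].to_numpy())).fit(disp=0)
        se = np.asarray(ref.bse)
        assert np.all(np.abs(fit.beta.to_numpy() - np.asarray(ref.params)) < 3 * se)

    def test_quadrature_count_stability(self, model_table):
        spec = ModelSpec.from_formula("system ~ d15n + (1|company)")
        f11 = fit_glmm(build_design(spec, model_table), n_quad=11)
        f25 = fit_glmm(build_design(spec, model_table), n_quad=25)
        diff = np.abs(f11.beta.to_numpy() - f25.beta.to_numpy())
        assert np.all(diff < f11.se().to_numpy()[:-1])

    def test_estimate_is_local_maximum(self, model_fit):
        d = model_fit.design
        z, w = np.polynomial.hermite.hermgauss(11)
        logw = np.log(w)
        theta_hat = np.concatenate(
            [model_fit.beta_centred, [np.log(model_fit.sigma_b)]]
        )
        ll_hat = _group_loglik(
            theta_hat, d.y, d.X, d.group_idx, d.n_groups, z, logw
        ).sum()
        rng = np.random.default_rng(1)
        for _ in range(50):
            pert = theta_hat + rng.normal(0, 0.05, len(theta_hat))
            ll = _group_loglik(pert, d.y, d.X, d.group_idx, d.n_groups, z, logw).sum()
            assert ll <= ll_hat + 1e-8

    def test_one_observation_per_group_still_fits(self):
        df = simulate_glmm(seed=4, n_groups=80, per_group=1, sigma_b=0.5)
        fit = fit_glmm(build_design(ModelSpec.from_formula("y ~ x + (1|g)"), df))
        assert fit.converged
        assert np.isfinite(fit.loglik)


class TestRecovery:
    def test_model_mode_parameter_recovery(self, model_fit):
        # generator truth: intercept -3.2, d15n slope 0.8, sigma_b 1.5
        se = model_fit.se()
        assert abs(model_fit.beta["Intercept"] - (-3.2)) < 3 * se["Intercept"]
        assert abs(model_fit.beta["d15n"] - 0.8) < 3 * se["d15n"]
        assert abs(model_fit.sigma_b - 1.5) < 3 * se["sigma_b"]

    def test_eb_modes_track_simulated_effects(self):
        rng = np.random.default_rng(5)
        n_groups, per_group = 60, 25
        g = np.repeat(np.arange(n_groups), per_group)
        x = rng.normal(0, 1, n_groups * per_group)
        b = rng.normal(0, 1.2, n_groups)
        y = (rng.random(len(x)) < expit(0.2 + 0.7 * x + b[g])).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "g": [f"g{i:03d}" for i in g]})
        fit = fit_glmm(build_design(ModelSpec.from_formula("y ~ x + (1|g)"), df))
        re = eb_modes(fit)
        assert np.corrcoef(re.modes, b)[0, 1] > 0.5

    def test_eb_modes_shrink_to_zero_without_signal(self):
        # all groups identical: the prior dominates, modes near zero
        df = simulate_glmm(seed=6, n_groups=20, per_group=10, sigma_b=0.0)
        fit = fit_glmm(build_design(ModelSpec.from_formula("y ~ x + (1|g)"), df))
        re = eb_modes(fit)
        assert np.max(np.abs(re.modes)) < 0.5


class TestPredictSS:
    def test_logit_inverse_at_zero(self):
        df = pd.DataFrame(
            {"y": [0, 1] * 10, "x": [0.0] * 20, "g": ["a", "b"] * 10}
        )
        from conftest import make_fit

        fit = make_fit(df, "y ~ x + (1|g)", beta_natural=[0.0, 1.0], sigma_b=1.0)
        probs = predict_ss(fit, df)
        np.testing.assert_allclose(probs, 0.5)

    def test_monotone_in_positive_slope_covariate(self, model_fit, model_table):
        nd = model_table.head(1).copy()
        grid = pd.concat([nd] * 50, ignore_index=True)
        grid["d15n"] = np.linspace(-5, 15, 50)
        probs = predict_ss(model_fit, grid)
        assert model_fit.beta["d15n"] > 0
        assert np.all(np.diff(probs) >= 0)

    def test_unseen_company_falls_back_to_zero(self, model_fit, model_table):
        nd = model_table.head(2).copy()
        nd["company"] = "C999"
        with pytest.warns(RuntimeWarning, match="C999"):
            probs = predict_ss(model_fit, nd, mode="at_eb_mode")
        np.testing.assert_allclose(probs, predict_ss(model_fit, nd, mode="at_zero"))


class TestAICc:
    def test_direct_formula_value(self, model_fit):
        import dataclasses

        fake = dataclasses.replace(model_fit, loglik=-100.0)
        fake.design = model_fit.design
        # k = 2 fixed + 1 variance = 3 -> use formula directly
        k, n = fake.k_params, fake.n_obs
        assert aicc(fake) == pytest.approx(200 + 2 * k + 2 * k * (k + 1) / (n - k - 1))

    def test_hand_value(self, model_fit):
        import dataclasses

        # loglik -100, k = 3, n = 100: 200 + 6 + 24/96 = 206.25 by hand
        fake = dataclasses.replace(model_fit, loglik=-100.0, n_obs=100)
        assert fake.k_params == 3
        assert aicc(fake) == pytest.approx(206.25)

    def test_undefined_for_tiny_n(self, model_fit):
        import dataclasses

        small = dataclasses.replace(model_fit, n_obs=3)
        with pytest.raises(ValueError, match="undefined"):
            aicc(small)
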