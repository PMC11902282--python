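"""Effect profiles, FNR computation, bootstrap thresholds, cutoffs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from conftest import make_fit
from isoscreen.marginal import predict_pa
from isoscreen.thresholds import (
    effect_profile,
    fnr,
    invert_cutoff,
    select_threshold,
)


def _crop_frame(n=300, seed=0, slope=0.8):
    rng = np.random.default_rng(seed)
    d15n = rng.normal(4, 3, n)
    cn = rng.normal(37, 8, n)
    eta = -3.0 + slope * d15n
    y = np.where(rng.random(n) < expit(eta), "organic", "conventional")
    return pd.DataFrame(
        {
            "system": y,
            "d15n": d15n,
            "cn_ratio": cn,
            "crop": "raspberry",
            "company": [f"c{i % 10}" for i in range(n)],
        }
    )


class TestFNR:
    def test_boundary_thresholds(self):
        probs = np.array([0.2, 0.6, 0.9, 0.4])
        y = np.array(["organic", "conventional", "organic", "organic"])
        assert fnr(probs, y, 0.0) == 0.0
        assert fnr(probs, y, 1.0 + 1e-9) == 1.0

    def test_ten_point_hand_count(self):
        probs = np.array([0.05, 0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95])
        y = np.array([0, 1, 0, 1, 1, 0, 1, 1, 0, 1])
        # organics below 0.5: probs 0.15, 0.35, 0.45 -> 3 of 6
        assert fnr(probs, y, 0.5) == pytest.approx(3 / 6)

    def test_no_organics_is_undefined(self):
        with pytest.raises(ValueError):
            fnr([0.1, 0.9], [0, 0], 0.5)

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_monotone_in_threshold(self, t1, t2):
        probs = np.linspace(0.01, 0.99, 40)
        y = np.tile([0, 1], 20)
        lo, hi = sorted((t1, t2))
        assert fnr(probs, y, lo) <= fnr(probs, y, hi)


class TestSelectThreshold:
    def test_separated_classes_give_achievable_zero_fnr(self):
        probs = np.concatenate([np.linspace(0.05, 0.3, 40), np.linspace(0.6, 0.95, 40)])
        y = np.array([0] * 40 + [1] * 40)
        dec = select_threshold(probs, y, replicates=500, seed=1)
        assert dec.achievable
        assert 0.3 < dec.threshold <= 0.6
        assert dec.fnr_point == 0.0
        assert dec.accuracy == 1.0

    def test_deterministic_given_seed(self, model_fit, model_table):
        pa = predict_pa(model_fit, model_table)
        a = select_threshold(pa, model_table["system"], replicates=300, seed=9)
        b = select_threshold(pa, model_table["system"], replicates=300, seed=9)
        assert a.threshold == b.threshold
        assert a.fnr_upper95 == b.fnr_upper95

    def test_tighter_target_never_raises_threshold(self, model_fit, model_table):
        pa = predict_pa(model_fit, model_table)
        y = model_table["system"]
        t1 = select_threshold(pa, y, target=0.01, replicates=500, seed=3).threshold
        t2 = select_threshold(pa, y, target=0.005, replicates=500, seed=3).threshold
        assert t2 <= t1

    def test_replicate_floor(self):
        with pytest.raises(ValueError, match="100"):
            select_threshold([0.1, 0.9], [0, 1], replicates=50)

    def test_upper_bound_brackets_point_estimate(self, model_fit, model_table):
        pa = predict_pa(model_fit, model_table)
        dec = select_threshold(pa, model_table["system"], replicates=500, seed=5)
        assert 0.0 <= dec.fnr_point <= dec.fnr_upper95 <= 1.0
        assert dec.achievable == (dec.fnr_upper95 < dec.target)

    def test_accuracy_never_beats_best_possible(self, model_fit, model_table):
        pa = predict_pa(model_fit, model_table)
        y = (model_table["system"] == "organic").to_numpy()
        dec = select_threshold(pa, model_table["system"], replicates=300, seed=7)
        best_acc = max(
            np.mean((pa >= t) == y) for t in np.concatenate([[0.0], np.unique(pa)])
        )
        assert dec.accuracy <= best_acc + 1e-12


class TestEffectProfile:
    def test_flat_when_coefficient_is_zero(self):
        df = _crop_frame()
        fit = make_fit(
            df, "system ~ d15n + cn_ratio + (1|company)",
            beta_natural={"Intercept": -3.0, "d15n": 0.8}, sigma_b=1.0,
        )
        prof = effect_profile(fit, "raspberry", "cn_ratio", df)
        assert prof.table["prob"].std() < 1e-12

    def test_profile_consistent_with_predict_pa(self):
        df = _crop_frame()
        fit = make_fit(
            df, "system ~ d15n + cn_ratio + (1|company)",
            beta_natural={"Intercept": -3.0, "d15n": 0.8, "cn_ratio": -0.02},
            sigma_b=1.2,
        )
        mean_d15n = df["d15n"].mean()
        prof = effect_profile(
            fit, "raspberry", "d15n", df, grid=np.array([mean_d15n - 1e-9, mean_d15n])
        )
        nd = pd.DataFrame(
            {
                "d15n": [mean_d15n],
                "cn_ratio": [df["cn_ratio"].mean()],
                "crop": ["raspberry"],
                "company": ["c0"],
            }
        )
        assert prof.table["prob"].iloc[-1] == pytest.approx(
            predict_pa(fit, nd)[0], abs=1e-10
        )

    def test_bounds_bracket_estimate_and_extrapolation_flagged(self, model_fit, model_table):
        sub = model_table[model_table["crop"] == "raspberry"]
        lo, hi = sub["d15n"].min(), sub["d15n"].max()
        wide = np.linspace(lo - 3 * (hi - lo), hi + 3 * (hi - lo), 40)
        with pytest.warns(RuntimeWarning, match="extrapolate"):
            prof = effect_profile(model_fit, "raspberry", "d15n", model_table, grid=wide)
        t = prof.table
        assert (t["lower"] <= t["prob"]).all() and (t["prob"] <= t["upper"]).all()
        assert t["extrapolated"].any() and not t["extrapolated"].iloc[len(t) // 2]

    def test_ci_width_matches_parametric_bootstrap(self, model_fit, model_table):
        # oracle: draw coefficients from the fit covariance and recompute
        # the marginal logit at one grid point
        grid = np.array([2.0, 3.0])
        prof = effect_profile(model_fit, "raspberry", "d15n", model_table, grid=grid)
        row = prof.table.iloc[1]
        rng = np.random.default_rng(42)
        theta_hat = np.concatenate(
            [model_fit.beta_centred, [np.log(model_fit.sigma_b)]]
        )
        draws = rng.multivariate_normal(theta_hat, model_fit.vcov_internal, size=2000)
        from isoscreen.marginal import _pa_from_eta
        from isoscreen.thresholds import _design_matrix, _profile_newdata

        nd, _ = _profile_newdata(model_fit, "raspberry", "d15n", grid[1:], model_table)
        X1 = _design_matrix(model_fit, nd)
        sims = [
            logit(
                np.clip(_pa_from_eta(X1 @ th[:-1], np.exp(th[-1])), 1e-12, 1 - 1e-12)
            )[0]
            for th in draws
        ]
        boot_width = np.quantile(sims, 0.975) - np.quantile(sims, 0.025)
        delta_width = logit(row["upper"]) - logit(row["lower"])
        assert delta_width == pytest.approx(boot_width, rel=0.15)


class TestInvertCutoff:
    def test_closed_form_inversion_without_random_effect(self):
        # sigma = 0: PA prob = expit(b0 + b1 x); cutoff solves it exactly
        df = _crop_frame(seed=3)
        fit = make_fit(
            df, "system ~ d15n + (1|company)", beta_natural={"Intercept": -3.0, "d15n": 0.8}, sigma_b=0.0
        )
        cut = invert_cutoff(fit, "raspberry", "d15n", 0.25, df)
        assert cut is not None
        assert cut.direction == "below"
        assert cut.value == pytest.approx((logit(0.25) + 3.0) / 0.8, abs=1e-6)

    def test_negative_slope_flags_above(self):
        df = _crop_frame(seed=4)
        fit = make_fit(
            df, "system ~ cn_ratio + (1|company)",
            beta_natural={"Intercept": 3.0, "cn_ratio": -0.1}, sigma_b=0.5,
        )
        cut = invert_cutoff(fit, "raspberry", "cn_ratio", 0.4, df)
        assert cut is not None
        assert cut.direction == "above"

    def test_threshold_outside_range_gives_no_cutoff(self):
        df = _crop_frame(seed=5)
        fit = make_fit(
            df, "system ~ d15n + (1|company)", beta_natural={"Intercept": -3.0, "d15n": 0.8}, sigma_b=0.0
        )
        assert invert_cutoff(fit, "raspberry", "d15n", 0.99999, df) is None

    def test_bisection_agrees_with_dense_grid(self, model_fit, model_table):
        dec_threshold = 0.3
        cut = invert_cutoff(model_fit, "raspberry", "d15n", dec_threshold, model_table)
        assert cut is not None
        sub = model_table[model_table["crop"] == "raspberry"]["d15n"]
        grid = np.linspace(sub.min(), sub.max(), 10_000)
        prof = effect_profile(model_fit, "raspberry", "d15n", model_table, grid=grid)
        j = int(np.argmin(np.abs(prof.table["prob"].to_numpy() - dec_threshold)))
        assert abs(cut.value - grid[j]) <= grid[1] - grid[0]
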