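"""Goodness-of-fit, residual/influence and score-test oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from isoscreen.diagnostics import (
    hosmer_lemeshow,
    osius_rojek,
    rao_importance,
    re_normality,
    residuals_influence,
    score_test,
    stukel,
)
from isoscreen.glmm import ModelSpec


def _logistic_sim(rng, n=3000, beta=(0.2, 0.8), quadratic=0.0):
    x = rng.normal(0, 1, n)
    eta = beta[0] + beta[1] * x + quadratic * x**2
    y = (rng.random(n) < expit(eta)).astype(float)
    X = np.column_stack([np.ones(n), x])
    fit = sm.Logit(y, X).fit(disp=0)
    return fit.predict(), y, X


class TestHosmerLemeshow:
    def test_perfect_calibration_with_flat_probs(self):
        # equal fitted probabilities and a label pattern whose frequency
        # matches that probability in every bin: O = E exactly
        n = 4000
        y = np.tile([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], n // 10).astype(float)
        probs = np.full(n, 0.3)
        res = hosmer_lemeshow(probs, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_hand_built_three_bins(self):
        # bins (by sorted prob): [0.1 x 3], [0.5 x 3], [0.9 x 3]
        probs = np.array([0.1, 0.1, 0.1, 0.5, 0.5, 0.5, 0.9, 0.9, 0.9])
        y = np.array([0, 0, 1, 0, 1, 1, 1, 1, 0])
        res = hosmer_lemeshow(probs, y, bins=3)
        stat = 0.0
        for o, e, n_g, p in [(1, 0.3, 3, 0.1), (2, 1.5, 3, 0.5), (2, 2.7, 3, 0.9)]:
            stat += (o - e) ** 2 / (n_g * p * (1 - p))
        assert res.statistic == pytest.approx(stat)
        assert res.df == 1

    def test_row_order_invariance(self, rng):
        probs, y, _ = _logistic_sim(rng)
        perm = rng.permutation(len(y))
        a = hosmer_lemeshow(probs, y)
        b = hosmer_lemeshow(probs[perm], y[perm])
        assert a.statistic == pytest.approx(b.statistic)

    def test_rejects_bad_bins(self, rng):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5] * 10, [1] * 10, bins=2)


class TestOsiusRojek:
    def test_deterministic(self, rng):
        probs, y, X = _logistic_sim(rng)
        a = osius_rojek(probs, y, X)
        b = osius_rojek(probs, y, X)
        assert a.statistic == b.statistic

    def test_well_specified_large_sample_z_is_moderate(self, rng):
        probs, y, X = _logistic_sim(rng, n=8000)
        assert abs(osius_rojek(probs, y, X).statistic) < 3

    def test_power_against_gross_misspecification(self):
        # quadratic truth, linear fit: rejection should be routine
        rejections = 0
        for r in range(5):
            rng = np.random.default_rng(300 + r)
            probs, y, X = _logistic_sim(rng, n=5000, quadratic=-0.8)
            rejections += osius_rojek(probs, y, X).p < 0.05
        assert rejections >= 4


class TestStukel:
    def test_symmetry_under_label_flip(self, rng):
        probs, y, X = _logistic_sim(rng)
        a = stukel(probs, y, X)
        b = stukel(1 - probs, 1 - y, -X)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-6)

    def test_constant_eta_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stukel(np.full(50, 0.4), np.zeros(50), np.ones((50, 1)))

    def test_power_against_probit_tails(self):
        rejections = 0
        for r in range(5):
            rng = np.random.default_rng(500 + r)
            n = 40_000
            x = rng.normal(0, 2.0, n)
            y = (rng.random(n) < stats.norm.cdf(0.1 + 1.5 * x)).astype(float)
            X = np.column_stack([np.ones(n), x])
            probs = sm.Logit(y, X).fit(disp=0).predict()
            rejections += stukel(probs, y, X).p < 0.05
        assert rejections >= 4


class TestScoreTest:
    def test_single_column_agrees_with_hand_formula(self):
        # 20-row dataset: score stat for one added column via the
        # partitioned-information formula, computed by hand
        rng = np.random.default_rng(9)
        n = 20
        x = rng.normal(0, 1, n)
        znew = rng.normal(0, 1, n)
        y = (rng.random(n) < expit(0.3 + 0.7 * x)).astype(float)
        X_red = np.column_stack([np.ones(n), x])
        probs = sm.Logit(y, X_red).fit(disp=0).predict()
        X_full = np.column_stack([X_red, znew])
        stat, df = score_test(y, probs, X_full, [2])
        w = probs * (1 - probs)
        u = float(znew @ (y - probs))
        i_zz = float(znew @ (w * znew))
        i_zx = (znew * w) @ X_red
        i_xx = (X_red * w[:, None]).T @ X_red
        var = i_zz - i_zx @ np.linalg.solve(i_xx, i_zx)
        assert df == 1
        assert stat == pytest.approx(u**2 / var, rel=1e-8)

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for r in range(60):
            rng = np.random.default_rng(700 + r)
            n = 500
            x = rng.normal(0, 1, n)
            znew = rng.normal(0, 1, n)
            y = (rng.random(n) < expit(0.2 + 0.6 * x)).astype(float)
            X_red = np.column_stack([np.ones(n), x])
            probs = sm.Logit(y, X_red).fit(disp=0).predict()
            stat, _ = score_test(y, probs, np.column_stack([X_red, znew]), [2])
            pvals.append(stats.chi2.sf(stat, 1))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestResidualsInfluence:
    def test_deviance_residual_vanishes_for_certain_fit(self):
        probs = np.array([0.999999, 0.000001, 0.5])
        y = np.array([1.0, 0.0, 1.0])
        X = np.column_stack([np.ones(3), [0.1, 0.2, 0.3]])
        out = residuals_influence(probs, y, X)
        assert abs(out["deviance"].iloc[0]) < 0.01
        assert abs(out["deviance"].iloc[1]) < 0.01

    def test_pearson_squares_sum_to_pearson_statistic(self, rng):
        probs, y, X = _logistic_sim(rng, n=500)
        out = residuals_influence(probs, y, X)
        pearson_stat = float(np.sum((y - probs) ** 2 / (probs * (1 - probs))))
        assert (out["pearson"] ** 2).sum() == pytest.approx(pearson_stat)

    def test_planted_outlier_tops_influence_ranking(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < expit(0.2 + 1.2 * x)).astype(float)
        x[0], y[0] = 6.0, 0.0  # extreme covariate with flipped label
        X = np.column_stack([np.ones(n), x])
        probs = sm.Logit(y, X).fit(disp=0).predict()
        out = residuals_influence(probs, y, X)
        assert out["cook"].idxmax() == 0


class TestRENormality:
    def test_normal_modes_rarely_rejected(self):
        rejections = 0
        reps = 100
        for r in range(reps):
            rng = np.random.default_rng(900 + r)
            rejections += re_normality(rng.normal(0, 1, 99)).p < 0.05
        assert rejections / reps < 0.12

    def test_heavy_tails_detected(self):
        rejections = 0
        reps = 40
        for r in range(reps):
            rng = np.random.default_rng(1200 + r)
            rejections += re_normality(rng.standard_t(2, 99)).p < 0.05
        assert rejections / reps > 0.3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            re_normality(np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            re_normality(np.full(10, 2.5))


@pytest.fixture(scope="module")
def importance_data():
    rng = np.random.default_rng(11)
    n_groups, per_group = 30, 20
    g = np.repeat([f"c{i:02d}" for i in range(n_groups)], per_group)
    n = n_groups * per_group
    d15n = rng.normal(4, 3, n)
    d13c = rng.normal(-26, 1.4, n)
    b = dict(zip(sorted(set(g)), rng.normal(0, 1.0, n_groups)))
    eta = -2.5 + 0.6 * d15n + np.array([b[gi] for gi in g])
    y = np.where(rng.random(n) < expit(eta), "organic", "conventional")
    return pd.DataFrame(
        {"system": y, "d15n": d15n, "d13c": d13c, "company": g}
    )


class TestRaoImportance:
    def test_strong_effect_outranks_null_effect(self, importance_data):
        spec = ModelSpec.from_formula("system ~ d15n + d13c + (1|company)")
        out = rao_importance(spec, importance_data)
        ranks = {t: i for i, t in enumerate(out["term"])}
        assert ranks["d15n"] < ranks["d13c"]
        assert out.loc[out.term == "d15n", "p"].iloc[0] < 1e-4

    def test_df_counts_deleted_columns(self, importance_data):
        spec = ModelSpec.from_formula("system ~ d15n + d13c + (1|company)")
        out = rao_importance(spec, importance_data)
        assert out.loc[out.term == "d15n", "df"].iloc[0] == 1
        # company enters as fixed indicators: levels - 1 columns
        n_levels = importance_data["company"].nunique()
        assert out.loc[out.term == "company", "df"].iloc[0] == n_levels - 1

    def test_null_term_p_not_extreme(self, importance_data):
        spec = ModelSpec.from_formula("system ~ d15n + d13c + (1|company)")
        out = rao_importance(spec, importance_data)
        assert out.loc[out.term == "d13c", "p"].iloc[0] > 0.001
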