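"""FNR-controlled screening thresholds and effect profiles.

The screening rule flags a sample labelled organic as "suspect
conventional" when its population-averaged probability of being organic
falls below a crop-specific threshold.  The threshold is the highest
candidate whose false negative rate (truly organic samples flagged) stays
below the 1 % target with 95 % confidence, the confidence bound coming
from a nonparametric bootstrap of the dataset (2000 replicates).  Where
the PA probability is monotone in a single covariate, the probability
threshold is inverted into a univariate cutoff (e.g. "delta15N below
2.2 ‰ is suspect").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logit

from .glmm import FittedGLMM
from .marginal import _pa_from_eta, predict_pa

__all__ = [
    "EffectProfile",
    "ThresholdDecision",
    "CutoffResult",
    "effect_profile",
    "fnr",
    "select_threshold",
    "invert_cutoff",
]


@dataclass
class EffectProfile:
    """PA probability of being organic along one covariate, one crop.

    ``table`` columns: value, prob, lower, upper, extrapolated.  Other
    covariates are held at the crop-specific sample means in ``at``.
    """

    crop: str
    covariate: str
    table: pd.DataFrame
    at: dict[str, float]


@dataclass
class CutoffResult:
    covariate: str
    value: float
    direction: str  # "below"/"above": side on which samples are suspect


@dataclass
class ThresholdDecision:
    """Outcome of FNR-controlled threshold selection for one stratum."""

    threshold: float
    fnr_point: float
    fnr_upper95: float
    target: float
    confidence: float
    achievable: bool
    accuracy: float
    replicates: int
    crop: str | None = None
    cutoffs: list[CutoffResult] = field(default_factory=list)


def _crop_means(data: pd.DataFrame, crop: str, covariates) -> dict[str, float]:
    sub = data[data["crop"] == crop]
    if len(sub) == 0:
        raise ValueError(f"crop {crop!r} not present in the data")
    return {c: float(sub[c].mean()) for c in covariates}


def _profile_newdata(
    fit: FittedGLMM, crop: str, covariate: str, grid: np.ndarray, data: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    cont = [v for v in fit.spec.variables if v in fit.design.cont_means]
    if covariate not in cont:
        raise ValueError(f"{covariate!r} is not a continuous covariate of the model")
    at = _crop_means(data, crop, [c for c in cont if c != covariate])
    nd = pd.DataFrame({covariate: grid})
    for c, v in at.items():
        nd[c] = v
    for v in fit.spec.variables:
        if v in fit.design.factor_levels and v != "crop":
            # hold other factors at their reference level
            nd[v] = fit.design.factor_levels[v][0]
    if "crop" in fit.spec.variables:
        nd["crop"] = crop
    if fit.spec.grouping:
        nd[fit.spec.grouping] = "_pa_"  # unused by PA prediction
    return nd, at


def effect_profile(
    fit: FittedGLMM,
    crop: str,
    covariate: str,
    data: pd.DataFrame,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    level: float = 0.95,
) -> EffectProfile:
    """PA effect profile with delta-method confidence bands.

    The profile traces the population-averaged organic probability as
    ``covariate`` varies over ``grid`` (default: the crop's observed range)
    with the other continuous covariates at the crop's sample means.  The
    CI is normal-approximation on the logit scale, transformed to the
    probability scale.  Grid points beyond 1.5x the observed range
    (measured from the range midpoint) are flagged as extrapolated.
    """
    fit.require_converged()
    sub = data.loc[data["crop"] == crop, covariate].to_numpy(dtype=float)
    if len(sub) == 0:
        raise ValueError(f"crop {crop!r} not present in the data")
    lo, hi = float(sub.min()), float(sub.max())
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    nd, at = _profile_newdata(fit, crop, covariate, grid, data)
    Xc = _design_matrix(fit, nd)
    theta = np.concatenate([fit.beta_centred, [np.log(max(fit.sigma_b, 1e-8))]])

    def marg_logit(th):
        pa = _pa_from_eta(Xc @ th[:-1], np.exp(th[-1]))
        return logit(np.clip(pa, 1e-12, 1 - 1e-12))

    m = marg_logit(theta)
    p = len(theta)
    J = np.empty((len(grid), p))
    h = 1e-5 * (1 + np.abs(theta))
    for j in range(p):
        e = np.zeros(p)
        e[j] = h[j]
        J[:, j] = (marg_logit(theta + e) - marg_logit(theta - e)) / (2 * h[j])
    var = np.clip(np.einsum("ij,jk,ik->i", J, fit.vcov_internal, J), 0, None)
    from scipy.stats import norm

    zq = norm.ppf(0.5 + level / 2)
    lower = _inv_logit(m - zq * np.sqrt(var))
    upper = _inv_logit(m + zq * np.sqrt(var))
    mid, half = (lo + hi) / 2, (hi - lo) / 2
    extrap = np.abs(grid - mid) > 1.5 * half
    if extrap.any():
        warnings.warn(
            f"{int(extrap.sum())} grid points extrapolate beyond 1.5x the observed "
            f"range of {covariate} for {crop}",
            RuntimeWarning,
        )
    table = pd.DataFrame(
        {
            "value": grid,
            "prob": _inv_logit(m),
            "lower": lower,
            "upper": upper,
            "extrapolated": extrap,
        }
    )
    return EffectProfile(crop=crop, covariate=covariate, table=table, at=at)


def _inv_logit(x):
    from scipy.special import expit

    return expit(x)


def _design_matrix(fit: FittedGLMM, newdata: pd.DataFrame) -> np.ndarray:
    from .glmm import build_design

    d = build_design(fit.spec, newdata, template=fit.design, require_response=False)
    return d.X


def fnr(probs, y, threshold: float) -> float:
    """False negative rate: truly organic samples with prob < threshold."""
    probs = np.asarray(probs, dtype=float)
    y = _organic_indicator(y)
    n_org = int(y.sum())
    if n_org == 0:
        raise ValueError("no organic samples; FNR undefined")
    return float(np.sum((probs < threshold) & (y == 1)) / n_org)


def _organic_indicator(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype == object or y.dtype.kind in "US":
        return (y == "organic").astype(float)
    return y.astype(float)


def select_threshold(
    probs,
    y,
    target: float = 0.01,
    confidence: float = 0.95,
    replicates: int = 2000,
    seed: int = 0,
    strata=None,
    crop: str | None = None,
) -> ThresholdDecision:
    """Highest threshold whose bootstrap FNR bound stays under the target.

    Candidate thresholds are the sorted unique predicted probabilities plus
    0.  The dataset rows are resampled with replacement ``replicates``
    times (stratified by ``strata`` if given, by class otherwise, so both
    classes survive every replicate); for each candidate the FNR's
    one-sided upper bound is the empirical ``confidence`` quantile over
    replicates.  Returns the largest candidate whose bound is below
    ``target``; if none qualifies the decision is flagged unachievable and
    reports the best attainable bound (at threshold 0).
    """
    if replicates < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    probs = np.asarray(probs, dtype=float)
    y = _organic_indicator(y)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    if strata is None:
        strata = y
    strata = np.asarray(strata)

    candidates = np.concatenate([[0.0], np.unique(probs)])
    org_mask = y == 1
    n_rep = replicates

    # bootstrap FNR for all candidates at once: per replicate, resample
    # rows within strata, then count organics below each candidate.
    fnr_boot = np.zeros((n_rep, len(candidates)))
    stratum_idx = [np.where(strata == s)[0] for s in pd.unique(strata)]
    for r in range(n_rep):
        take = np.concatenate(
            [idx[rng.integers(0, len(idx), len(idx))] for idx in stratum_idx]
        )
        o = np.sort(probs[take[org_mask[take]]])
        if len(o) == 0:
            fnr_boot[r] = 0.0
            continue
        fnr_boot[r] = np.searchsorted(o, candidates, side="left") / len(o)
    upper = np.quantile(fnr_boot, confidence, axis=0)

    ok = upper < target
    if ok.any():
        i = int(np.max(np.where(ok)[0]))
        thr = float(candidates[i])
        achievable = True
        ub = float(upper[i])
    else:
        thr = 0.0
        achievable = False
        ub = float(upper[0])
    point = fnr(probs, y, thr)
    pred = probs >= thr
    accuracy = float(np.mean(pred == (y == 1)))
    return ThresholdDecision(
        threshold=thr,
        fnr_point=point,
        fnr_upper95=ub,
        target=target,
        confidence=confidence,
        achievable=achievable,
        accuracy=accuracy,
        replicates=replicates,
        crop=crop,
    )


def invert_cutoff(
    fit: FittedGLMM,
    crop: str,
    covariate: str,
    prob_threshold: float,
    data: pd.DataFrame,
    n_check: int = 512,
) -> CutoffResult | None:
    """Invert a probability threshold into a univariate covariate cutoff.

    Requires the crop's PA profile in ``covariate`` (other covariates at
    crop means) to be strictly monotone over the observed range and the
    threshold to be attained inside it; otherwise returns ``None`` (no
    univariate cutoff).  The root is found by bracketed bisection; the flag
    direction is "below" for an increasing profile (low values suspect)
    and "above" for a decreasing one.
    """
    fit.require_converged()
    sub = data.loc[data["crop"] == crop, covariate].to_numpy(dtype=float)
    if len(sub) == 0:
        raise ValueError(f"crop {crop!r} not present in the data")
    lo, hi = float(sub.min()), float(sub.max())
    if hi <= lo:
        return None
    grid = np.linspace(lo, hi, n_check)
    nd, _ = _profile_newdata(fit, crop, covariate, grid, data)
    Xc = _design_matrix(fit, nd)
    pa = _pa_from_eta(Xc @ fit.beta_centred, fit.sigma_b)
    diffs = np.diff(pa)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        return None
    increasing = bool(diffs[0] > 0)
    f_lo, f_hi = pa[0] - prob_threshold, pa[-1] - prob_threshold
    if f_lo * f_hi > 0:
        return None  # threshold not attained within the observed range

    def f(x):
        nd1, _ = _profile_newdata(fit, crop, covariate, np.array([x]), data)
        X1 = _design_matrix(fit, nd1)
        return float(_pa_from_eta(X1 @ fit.beta_centred, fit.sigma_b)[0] - prob_threshold)

    root = brentq(f, lo, hi, xtol=1e-8)
    return CutoffResult(
        covariate=covariate,
        value=float(root),
        direction="below" if increasing else "above",
    )
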