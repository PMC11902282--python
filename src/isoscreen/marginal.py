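"""Population-averaged (PA) quantities from a subject-specific (SS) fit.

The GLMM's coefficients are conditional on a company's random intercept
("subject-specific").  Screening rules must be company-agnostic, so the
random effect is integrated out: the PA probability at covariates x is

    E_b[ logistic(x' beta_SS + b) ],   b ~ N(0, sigma_b^2),

evaluated by Gauss-Hermite quadrature (deterministic) or Monte Carlo.
Marginal coefficients beta_PA are defined by least-squares projection of
the marginal logits onto the design — the standard marginalization
recipe — with robust SEs that propagate the fit covariance (delta method)
plus the Monte Carlo error.  Under a logit link PA slopes are attenuated
relative to SS slopes by roughly ``1/sqrt(1 + c^2 sigma_b^2)`` with
``c = 16 sqrt(3) / (15 pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.metrics import roc_curve

from .glmm import FittedGLMM

__all__ = ["MarginalModel", "predict_pa", "marginalize_coefs", "auroc"]

_QUAD_POINTS = 41


def _pa_from_eta(eta: np.ndarray, sigma: float, n_points: int = _QUAD_POINTS) -> np.ndarray:
    """Gauss-Hermite marginalization of logistic(eta + b), b ~ N(0, sigma^2)."""
    if sigma <= 0:
        return expit(eta)
    z, w = np.polynomial.hermite.hermgauss(n_points)
    w = w / np.sqrt(np.pi)
    return expit(eta[:, None] + np.sqrt(2.0) * sigma * z[None, :]) @ w


def predict_pa(
    fit: FittedGLMM,
    newdata: pd.DataFrame,
    method: str = "quadrature",
    draws: int = 5000,
    seed: int | None = None,
) -> np.ndarray:
    """Population-averaged probabilities for new samples.

    ``method='quadrature'`` (default) is deterministic; ``'monte_carlo'``
    draws ``draws`` random intercepts (refused below 100).
    """
    fit.require_converged()
    eta = fit.linear_predictor(newdata)
    if method == "quadrature":
        return _pa_from_eta(eta, fit.sigma_b)
    if method != "monte_carlo":
        raise ValueError("method must be 'quadrature' or 'monte_carlo'")
    if draws < 100:
        raise ValueError("monte_carlo needs at least 100 draws")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, fit.sigma_b, size=draws)
    return expit(eta[:, None] + b[None, :]).mean(axis=1)


@dataclass
class MarginalModel:
    """Marginalized coefficients with robust standard errors.

    ``beta_pa`` is on the natural covariate scale with the same naming as
    the source fit; ``beta_pa_centred`` matches the internal design.
    """

    fit: FittedGLMM
    beta_pa: pd.Series
    beta_pa_centred: np.ndarray
    robust_se: pd.Series
    mc_samples: int

    @property
    def attenuation(self) -> pd.Series:
        """Ratio beta_PA / beta_SS per coefficient (NaN where beta_SS ~ 0)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.beta_pa / self.fit.beta
        return r.where(self.fit.beta.abs() > 1e-8)


def _project_marginal(fit: FittedGLMM, pbar: np.ndarray) -> np.ndarray:
    X = fit.design.X
    ell = logit(np.clip(pbar, 1e-12, 1 - 1e-12))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via the QR diagonal
        _, R = np.linalg.qr(X)
        d = np.abs(np.diag(R))
        bad = [fit.design.colnames[j] for j in np.where(d < 1e-8 * d.max())[0]]
        raise ValueError(f"design is collinear in columns {bad}")
    coef, *_ = np.linalg.lstsq(X, ell, rcond=None)
    return coef


def marginalize_coefs(
    fit: FittedGLMM, draws: int = 5000, seed: int = 0
) -> MarginalModel:
    """Monte Carlo marginalization of the fitted coefficients.

    Marginal probabilities over the observed design are computed by Monte
    Carlo integration over the random-intercept distribution; beta_PA
    solves the least-squares projection of the marginal logits onto the
    design.  Robust SEs combine (i) delta-method propagation of the fit's
    covariance through the (quadrature) marginalization map and (ii) the
    Monte Carlo sampling error of the projection.
    """
    fit.require_converged()
    if draws < 1000:
        raise ValueError("need at least 1000 Monte Carlo draws")
    rng = np.random.default_rng(seed)
    X = fit.design.X
    eta = X @ fit.beta_centred
    b = rng.normal(0.0, fit.sigma_b, size=draws)
    P = expit(eta[:, None] + b[None, :])
    pbar = P.mean(axis=1)
    coef_c = _project_marginal(fit, pbar)

    # (ii) MC error: delta method through logit, projected
    var_pbar = P.var(axis=1, ddof=1) / draws
    ell_grad = 1.0 / np.clip(pbar * (1 - pbar), 1e-12, None)
    XtX_inv = np.linalg.inv(X.T @ X)
    A = XtX_inv @ X.T
    mc_cov = (A * (var_pbar * ell_grad**2)[None, :]) @ A.T

    # (i) fit-covariance propagation, using the deterministic quadrature map
    def beta_pa_of(theta):
        e = X @ theta[:-1]
        return np.linalg.lstsq(
            X, logit(np.clip(_pa_from_eta(e, np.exp(theta[-1])), 1e-12, 1 - 1e-12)),
            rcond=None,
        )[0]

    theta_hat = np.concatenate([fit.beta_centred, [np.log(max(fit.sigma_b, 1e-8))]])
    p = len(theta_hat)
    J = np.empty((X.shape[1], p))
    h = 1e-5 * (1 + np.abs(theta_hat))
    for j in range(p):
        e = np.zeros(p)
        e[j] = h[j]
        J[:, j] = (beta_pa_of(theta_hat + e) - beta_pa_of(theta_hat - e)) / (2 * h[j])
    fit_cov = J @ fit.vcov_internal @ J.T

    M = fit.design.natural_transform
    cov_nat = M @ (fit_cov + mc_cov) @ M.T
    se = np.sqrt(np.clip(np.diag(cov_nat), 0, None))
    names = fit.design.colnames
    return MarginalModel(
        fit=fit,
        beta_pa=pd.Series(M @ coef_c, index=names),
        beta_pa_centred=coef_c,
        robust_se=pd.Series(se, index=names),
        mc_samples=draws,
    )


def auroc(probs, y) -> tuple[float, pd.DataFrame]:
    """Rank-based AUROC with midrank tie handling, plus the ROC curve.

    Returns ``(auc, curve)`` where ``curve`` has columns fpr, tpr,
    threshold.  The AUC is the Mann-Whitney U statistic scaled by
    ``n1 * n0`` (probability that a random positive outranks a random
    negative, ties counted half).
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    if y.dtype == object or y.dtype.kind in "US":
        y = (y == "organic").astype(float)
    y = y.astype(float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    r = rankdata(probs, method="average")
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2
    auc = float(u / (n1 * n0))
    fpr, tpr, thr = roc_curve(y, probs)
    return auc, pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
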