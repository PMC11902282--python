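"""Goodness-of-fit and variable-importance diagnostics.

Implements the classical logistic goodness-of-fit battery applied to the
screening model — Hosmer–Lemeshow deciles-of-risk, the Osius–Rojek normal
approximation to the Pearson statistic, and Stukel's two-parameter score
test — plus residual/influence summaries, Shapiro–Wilk normality of the
empirical-Bayes company effects, and hierarchical term-deletion Rao score
tests for variable importance in the fully fixed version of the model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .glmm import Design, ModelSpec, RandomEffects, build_design

logger = logging.getLogger(__name__)

__all__ = [
    "GofResult",
    "hosmer_lemeshow",
    "osius_rojek",
    "stukel",
    "score_test",
    "residuals_influence",
    "re_normality",
    "rao_importance",
]

_PROB_EPS = 1e-10


@dataclass(frozen=True)
class GofResult:
    test: str
    statistic: float
    df: float | None
    p: float
    note: str = ""


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    return y


def hosmer_lemeshow(probs, y, bins: int = 10) -> GofResult:
    """Hosmer–Lemeshow deciles-of-risk chi-square test.

    Observations are sorted by fitted probability (ties broken by
    observation index, stable) and split into ``bins`` near-equal groups;
    the statistic sums ``(O - E)^2 / (E (1 - E/n_g))`` over groups and is
    referred to chi-square with ``bins - 2`` df.  Groups with zero expected
    count are merged into their neighbour (noted in the result).
    """
    probs = np.asarray(probs, dtype=float)
    y = _check_binary(y)
    if bins < 3:
        raise ValueError("bins must be >= 3")
    n = len(probs)
    if n < bins:
        raise ValueError("need at least one observation per bin")
    order = np.argsort(probs, kind="stable")
    groups = np.array_split(order, bins)
    note = ""
    # merge any group with zero expected count into its neighbour
    merged: list[np.ndarray] = []
    for g in groups:
        if merged and (probs[g].sum() == 0 or probs[merged[-1]].sum() == 0):
            merged[-1] = np.concatenate([merged[-1], g])
            note = "merged zero-expectation bins"
        else:
            merged.append(g)
    stat = 0.0
    for g in merged:
        n_g = len(g)
        obs = y[g].sum()
        exp = probs[g].sum()
        pbar = exp / n_g
        denom = n_g * pbar * (1 - pbar)
        if denom <= 0:
            if obs == exp:
                continue
            denom = _PROB_EPS
        stat += (obs - exp) ** 2 / denom
    df = max(len(merged) - 2, 1)
    return GofResult("hosmer-lemeshow", float(stat), float(df),
                     float(stats.chi2.sf(stat, df)), note)


def osius_rojek(probs, y, X) -> GofResult:
    """Osius–Rojek normal approximation to the Pearson chi-square.

    Treats each row as its own covariate pattern.  The Pearson statistic is
    centred at ``n - p`` (p = number of fitted parameters) and scaled using
    the residual sum of squares from the weighted regression of
    ``(1 - 2 pi) / v`` on the design with weights ``v = pi (1 - pi)``;
    two-sided p from the standard normal.
    """
    probs = np.asarray(probs, dtype=float)
    y = _check_binary(y)
    X = np.asarray(X, dtype=float)
    keep = (probs > _PROB_EPS) & (probs < 1 - _PROB_EPS)
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} degenerate fitted probabilities",
            RuntimeWarning,
        )
        probs, y, X = probs[keep], y[keep], X[keep]
    n, p = X.shape
    v = probs * (1 - probs)
    pearson = float(np.sum((y - probs) ** 2 / v))
    c = (1 - 2 * probs) / v
    sw = np.sqrt(v)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], c * sw, rcond=None)
    rss = float(np.sum(v * (c - X @ coef) ** 2))
    # A = 2 (J - sum 1/m_j) = 0 for all-singleton patterns
    z = (pearson - (n - p)) / np.sqrt(rss)
    return GofResult("osius-rojek", float(z), None, float(2 * stats.norm.sf(abs(z))))


def score_test(y, probs, X_full, new_cols) -> tuple[float, int]:
    """Rao score test for adding columns to a fitted logistic model.

    ``probs`` are fitted under the reduced model; ``X_full`` is the full
    design (reduced columns plus candidates), ``new_cols`` the indices of
    the added columns.  Returns (chi-square statistic, df).  The quadratic
    form uses the full information matrix, so nuisance-parameter
    uncertainty is accounted for.
    """
    y = _check_binary(y)
    probs = np.clip(np.asarray(probs, dtype=float), _PROB_EPS, 1 - _PROB_EPS)
    X_full = np.asarray(X_full, dtype=float)
    U = X_full.T @ (y - probs)
    w = probs * (1 - probs)
    info = (X_full * w[:, None]).T @ X_full
    stat = float(U @ np.linalg.lstsq(info, U, rcond=None)[0])
    return max(stat, 0.0), len(new_cols)


def stukel(probs, y, X) -> GofResult:
    """Stukel's generalized-logit score test (2 df).

    Augments the linear predictor ``eta = logit(pi)`` with
    ``z1 = eta^2/2 * 1[eta >= 0]`` and ``z2 = -eta^2/2 * 1[eta < 0]`` and
    score-tests the two added coefficients at the fitted model.
    """
    probs = np.clip(np.asarray(probs, dtype=float), _PROB_EPS, 1 - _PROB_EPS)
    y = _check_binary(y)
    X = np.asarray(X, dtype=float)
    eta = logit(probs)
    if np.ptp(eta) < 1e-12:
        raise ValueError("constant linear predictor; Stukel test undefined")
    z1 = 0.5 * eta**2 * (eta >= 0)
    z2 = -0.5 * eta**2 * (eta < 0)
    X_aug = np.column_stack([X, z1, z2])
    stat, df = score_test(y, probs, X_aug, [X.shape[1], X.shape[1] + 1])
    return GofResult("stukel", stat, float(df), float(stats.chi2.sf(stat, df)))


def residuals_influence(
    probs, y, X, cook_cutoff: float | None = None, leverage_cutoff: float | None = None
) -> pd.DataFrame:
    """Per-observation residual and influence table for a logistic fit.

    Columns: fitted, pearson, deviance, leverage (diagonal of the weighted
    hat matrix), cook (one-step Cook-style displacement
    ``r_p^2 h / (k (1-h)^2)``), and boolean flags at the cutoffs
    (defaults 4/n for Cook, 2k/n for leverage).
    """
    probs = np.clip(np.asarray(probs, dtype=float), _PROB_EPS, 1 - _PROB_EPS)
    y = _check_binary(y)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    w = probs * (1 - probs)
    pearson = (y - probs) / np.sqrt(w)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_sq = -2 * (y * np.log(probs) + (1 - y) * np.log1p(-probs))
    deviance = np.sign(y - probs) * np.sqrt(np.maximum(dev_sq, 0))
    Xw = X * np.sqrt(w)[:, None]
    # leverage via economical QR of the weighted design
    Q, _ = np.linalg.qr(Xw)
    leverage = np.sum(Q**2, axis=1)
    cook = pearson**2 * leverage / (k * (1 - leverage) ** 2)
    cook_cut = 4.0 / n if cook_cutoff is None else cook_cutoff
    lev_cut = 2.0 * k / n if leverage_cutoff is None else leverage_cutoff
    return pd.DataFrame(
        {
            "fitted": probs,
            "pearson": pearson,
            "deviance": deviance,
            "leverage": leverage,
            "cook": cook,
            "flag_cook": cook > cook_cut,
            "flag_leverage": leverage > lev_cut,
        }
    )


def re_normality(re: RandomEffects | np.ndarray) -> GofResult:
    """Shapiro–Wilk test of the empirical-Bayes company modes."""
    modes = re.modes if isinstance(re, RandomEffects) else np.asarray(re, dtype=float)
    if len(modes) < 3:
        raise ValueError("need at least 3 companies")
    if np.ptp(modes) < 1e-12:
        raise ValueError("company modes are constant; normality test degenerate")
    w, p = stats.shapiro(modes)
    return GofResult("shapiro-wilk", float(w), None, float(p))


# --------------------------------------------------------------------------
# fully fixed model and term-deletion importance


def _ridge_logit(X, y, alpha: float = 1e-6, max_iter: int = 200, tol: float = 1e-10):
    """IRLS logistic fit with a weak ridge penalty (not on the intercept).

    Separated factor levels (e.g. system-exclusive companies) make the
    unpenalized MLE diverge; the weak ridge keeps the fit finite while
    perturbing well-identified coefficients negligibly.
    """
    n, p = X.shape
    pen = np.full(p, alpha)
    pen[0] = 0.0  # assume column 0 is the intercept
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        grad = X.T @ (y - mu) - pen * beta
        H = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta, expit(X @ beta)


def fixed_company_table(
    table: pd.DataFrame, grouping: str = "company", min_size: int = 2
) -> pd.DataFrame:
    """Copy of the table with singleton companies pooled.

    The fully fixed model treats company as a fixed factor; companies with
    fewer than ``min_size`` observations are merged into a pooled reference
    level ("_pooled") to keep the model estimable.
    """
    out = table.copy()
    sizes = out[grouping].value_counts()
    small = set(sizes.index[sizes < min_size])
    if small:
        logger.info("pooling %d singleton companies", len(small))
        out[grouping] = out[grouping].where(~out[grouping].isin(small), "_pooled")
    return out


@dataclass(frozen=True)
class ImportanceRow:
    term: str
    statistic: float
    df: int
    p: float
    note: str = ""


def rao_importance(
    full_spec: ModelSpec,
    table: pd.DataFrame,
    min_company_size: int = 2,
    ridge: float = 1e-6,
) -> pd.DataFrame:
    """Hierarchical term-deletion Rao score tests in the fully fixed model.

    The random intercept is replaced by fixed company indicators (singleton
    companies pooled).  For each deletable variable, the variable's main
    effect and every interaction containing it are removed, the reduced
    model is refit, and the score statistic for the deleted columns is
    evaluated at the reduced fit.  Rows are sorted by statistic, matching
    the published company > delta15N > crop > C/N > C % ranking logic.
    """
    if full_spec.grouping is None:
        fixed_terms = full_spec.fixed_terms
        work = table
        group_var = None
    else:
        group_var = full_spec.grouping
        work = fixed_company_table(table, group_var, min_company_size)
        fixed_terms = full_spec.fixed_terms + ((group_var,),)
    full = ModelSpec(response=full_spec.response, fixed_terms=fixed_terms, grouping=None)
    d_full = build_design(full, work)
    variables = full.variables
    rows = []
    for var in variables:
        reduced_terms = tuple(t for t in fixed_terms if var not in t)
        deleted_cols = [
            j
            for j, t in enumerate(_term_of_column(d_full))
            if t is not None and var in t
        ]
        try:
            reduced = ModelSpec(
                response=full.response, fixed_terms=reduced_terms, grouping=None
            )
            d_red = build_design(reduced, work)
            _, probs = _ridge_logit(d_red.X, d_red.y, alpha=ridge)
            stat, df = score_test(d_full.y, probs, d_full.X, deleted_cols)
            # df = columns actually deleted (term + dependent interactions)
            df = len(deleted_cols)
            rows.append(
                ImportanceRow(var, stat, df, float(stats.chi2.sf(stat, df)))
            )
        except Exception as exc:  # noqa: BLE001 - flagged, not dropped
            rows.append(ImportanceRow(var, float("nan"), len(deleted_cols),
                                      float("nan"), note=str(exc)))
    out = pd.DataFrame([r.__dict__ for r in rows])
    return out.sort_values("statistic", ascending=False, kind="stable").reset_index(
        drop=True
    )


def _term_of_column(design: Design) -> list[tuple[str, ...] | None]:
    """Map each design column to the set of variables it involves."""
    out: list[tuple[str, ...] | None] = []
    for name in design.colnames:
        if name == "Intercept":
            out.append(None)
            continue
        vars_ = []
        for piece in name.split(":"):
            vars_.append(piece.split("[")[0])
        out.append(tuple(vars_))
    return out
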