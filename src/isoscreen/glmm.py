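"""Random-intercept logistic GLMM fit by adaptive Gauss-Hermite quadrature.

The model is a Bernoulli response (organic = 1) with logit link, fixed
covariate effects and a normally distributed per-company random intercept:

    logit P(Y_ij = 1 | b_i) = x_ij' beta + b_i,    b_i ~ N(0, sigma_b^2)

The marginal likelihood integrates each company's contribution over b_i.
That integral has no closed form under the logit link; it is approximated
per group by Gauss-Hermite quadrature with the nodes recentred at the
group's posterior mode and rescaled by the curvature there ("adaptive"
quadrature), which keeps a small number of nodes (11 by default) accurate
even for informative groups.

Maximization is quasi-Newton over (beta, log sigma_b); the log
parameterization enforces sigma_b >= 0 and near-boundary fits are flagged.
Continuous covariates are centred internally for optimizer stability and
coefficients are reported back on the natural scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = [
    "ModelSpec",
    "Design",
    "FittedGLMM",
    "RandomEffects",
    "build_design",
    "fit_glmm",
    "predict_ss",
    "eb_modes",
    "aicc",
]

_FACTOR_COLUMNS = {"crop", "system", "origin", "company"}


@dataclass(frozen=True)
class ModelSpec:
    """Symbolic model description.

    ``fixed_terms`` is a tuple of terms, each term a tuple of variable
    names: ``("d15n",)`` is a main effect, ``("crop", "d15n")`` a pairwise
    interaction.  The intercept is always included.  ``grouping`` names the
    random-intercept factor; ``grouping=None`` gives a plain logistic model.
    """

    response: str
    fixed_terms: tuple[tuple[str, ...], ...]
    grouping: str | None = "company"

    def __post_init__(self):
        # canonical order: mains first, everything lexicographic, so specs
        # compare equal regardless of how the formula was written
        object.__setattr__(
            self,
            "fixed_terms",
            tuple(sorted(self.fixed_terms, key=lambda t: (len(t), t))),
        )
        mains = {t[0] for t in self.fixed_terms if len(t) == 1}
        for t in self.fixed_terms:
            if len(t) > 2:
                raise ValueError("only main effects and pairwise interactions supported")
            if len(t) == 2 and not set(t) <= mains:
                raise ValueError(
                    f"interaction {':'.join(t)} violates hierarchy: include its main effects"
                )

    @classmethod
    def from_formula(cls, formula: str) -> "ModelSpec":
        """Parse ``response ~ a + b + a:b + (1 | group)``.

        ``a*b`` expands to ``a + b + a:b``; ``1`` denotes the (always
        implicit) intercept; at most one ``(1 | group)`` term.
        """
        if "~" not in formula:
            raise ValueError("formula must contain '~'")
        lhs, rhs = formula.split("~", 1)
        response = lhs.strip()
        if not response:
            raise ValueError("missing response")
        grouping = None
        terms: list[tuple[str, ...]] = []
        depth = 0
        part = ""
        parts = []
        for ch in rhs:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            if ch == "+" and depth == 0:
                parts.append(part)
                part = ""
            else:
                part += ch
        parts.append(part)
        for raw in parts:
            tok = raw.strip()
            if not tok or tok == "1":
                continue
            if tok.startswith("(") and tok.endswith(")"):
                inner = tok[1:-1]
                if "|" not in inner:
                    raise ValueError(f"cannot parse random term {tok!r}")
                left, grp = inner.split("|", 1)
                if left.strip() != "1":
                    raise ValueError("only random intercepts are supported")
                if grouping is not None:
                    raise ValueError("only one random-intercept term is supported")
                grouping = grp.strip()
            elif "*" in tok:
                a, b = (s.strip() for s in tok.split("*", 1))
                for t in [(a,), (b,), tuple(sorted((a, b)))]:
                    if t not in terms:
                        terms.append(t)
            elif ":" in tok:
                a, b = (s.strip() for s in tok.split(":", 1))
                t = tuple(sorted((a, b)))
                if t not in terms:
                    terms.append(t)
            else:
                if (tok,) not in terms:
                    terms.append((tok,))
        # hierarchy: silently add missing mains before validation? No --
        # the explicit contract is that callers write hierarchical formulas.
        return cls(response=response, fixed_terms=tuple(terms), grouping=grouping)

    def formula(self) -> str:
        parts = ["1"]
        parts += [":".join(t) for t in sorted(self.fixed_terms, key=lambda t: (len(t), t))]
        if self.grouping:
            parts.append(f"(1 | {self.grouping})")
        return f"{self.response} ~ " + " + ".join(parts)

    @property
    def variables(self) -> tuple[str, ...]:
        seen = []
        for t in self.fixed_terms:
            for v in t:
                if v not in seen:
                    seen.append(v)
        return tuple(seen)


@dataclass
class Design:
    """Materialized design: response, fixed-effect matrix and group index.

    ``X`` is the centred matrix used for fitting; ``natural_transform`` (M)
    maps centred coefficients back to the natural scale, ``beta_nat = M @
    beta_centred``.
    """

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    group_idx: np.ndarray | None
    group_labels: list[str] | None
    spec: ModelSpec
    factor_levels: dict[str, tuple[str, ...]]
    cont_means: dict[str, float]
    natural_transform: np.ndarray

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_groups(self) -> int:
        return 0 if self.group_labels is None else len(self.group_labels)


def _is_factor(table: pd.DataFrame, var: str) -> bool:
    s = table[var]
    return (
        var in _FACTOR_COLUMNS
        or s.dtype == object
        or isinstance(s.dtype, pd.CategoricalDtype)
        or s.dtype == bool
    )


def _response_vector(table: pd.DataFrame, response: str) -> np.ndarray:
    s = table[response]
    if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
        vals = set(s.unique())
        if not vals <= {"conventional", "organic"}:
            raise ValueError(f"cannot interpret response levels {sorted(vals)}")
        return (s == "organic").to_numpy(dtype=float)
    y = s.to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("numeric response must be binary 0/1")
    return y


def build_design(
    spec: ModelSpec,
    table: pd.DataFrame,
    template: "Design | FittedGLMM | None" = None,
    require_response: bool = True,
) -> Design:
    """Build the treatment-coded, centred design matrix for ``spec``.

    Factors use reference-level (treatment) coding against the
    alphabetically first level; interaction columns are products of the
    coded columns.  Column names are deterministic: ``Intercept``,
    ``crop[blueberry]``, ``d15n``, ``crop[blueberry]:d15n`` (factor part
    first).  If ``template`` is given (prediction mode), its factor levels
    and centering constants are reused and unseen levels raise an error.
    """
    if template is not None and not isinstance(template, Design):
        template = template.design  # FittedGLMM
    for v in spec.variables:
        if v not in table.columns:
            raise ValueError(f"column {v!r} missing from table")

    if template is None:
        factor_levels = {
            v: tuple(sorted(map(str, pd.unique(table[v].astype(str)))))
            for v in spec.variables
            if _is_factor(table, v)
        }
        cont_means = {
            v: float(np.mean(table[v].to_numpy(dtype=float)))
            for v in spec.variables
            if not _is_factor(table, v)
        }
    else:
        factor_levels = template.factor_levels
        cont_means = template.cont_means
        for v, levels in factor_levels.items():
            seen = set(map(str, pd.unique(table[v].astype(str))))
            unknown = seen - set(levels)
            if unknown:
                raise ValueError(
                    f"unseen level(s) {sorted(unknown)} for factor {v!r} at prediction time"
                )

    n = len(table)
    columns: list[np.ndarray] = [np.ones(n)]
    colnames: list[str] = ["Intercept"]
    # map variable -> list of (column name, index) for its coded columns
    coded: dict[str, list[int]] = {}

    def add_main(v: str):
        idx = []
        if v in factor_levels:
            vals = table[v].astype(str).to_numpy()
            for lev in factor_levels[v][1:]:
                columns.append((vals == lev).astype(float))
                colnames.append(f"{v}[{lev}]")
                idx.append(len(columns) - 1)
        else:
            columns.append(table[v].to_numpy(dtype=float) - cont_means[v])
            colnames.append(v)
            idx.append(len(columns) - 1)
        coded[v] = idx

    mains = [t[0] for t in spec.fixed_terms if len(t) == 1]
    for v in mains:
        add_main(v)
    for t in spec.fixed_terms:
        if len(t) != 2:
            continue
        a, b = t
        # factor part first in the column name for readability
        if a in factor_levels and b not in factor_levels:
            first, second = a, b
        elif b in factor_levels and a not in factor_levels:
            first, second = b, a
        else:
            first, second = a, b
        for i in coded[first]:
            for j in coded[second]:
                columns.append(columns[i] * columns[j])
                colnames.append(f"{colnames[i]}:{colnames[j]}")
    X = np.column_stack(columns)

    M = _natural_transform(colnames, cont_means)

    y = _response_vector(table, spec.response) if require_response else np.zeros(n)
    group_idx = group_labels = None
    if spec.grouping is not None:
        if spec.grouping not in table.columns:
            raise ValueError(f"grouping column {spec.grouping!r} missing")
        g = table[spec.grouping].astype(str)
        group_labels = sorted(g.unique())
        lut = {lab: i for i, lab in enumerate(group_labels)}
        group_idx = g.map(lut).to_numpy()

    return Design(
        y=y,
        X=X,
        colnames=colnames,
        group_idx=group_idx,
        group_labels=group_labels,
        spec=spec,
        factor_levels=factor_levels,
        cont_means=cont_means,
        natural_transform=M,
    )


def _natural_transform(colnames: list[str], cont_means: dict[str, float]) -> np.ndarray:
    """Matrix M with beta_natural = M @ beta_centred.

    Each centred column expands into natural columns: ``(c - m)`` is
    ``c - m * 1`` and ``d:(c - m)`` is ``d:c - m * d``; the correction lands
    on the parent column, which hierarchy guarantees is present.
    """
    p = len(colnames)
    pos = {name: i for i, name in enumerate(colnames)}
    M = np.eye(p)

    def parts(name):
        return name.split(":") if ":" in name else [name]

    for j, name in enumerate(colnames):
        for piece in parts(name):
            if piece in cont_means:
                m = cont_means[piece]
                rest = [q for q in parts(name) if q != piece]
                parent = ":".join(rest) if rest else "Intercept"
                M[pos[parent], j] -= m
    return M


# --------------------------------------------------------------------------
# likelihood machinery


def _posterior_modes(y, eta, gidx, ngroups, sigma, b0=None, max_iter=60, tol=1e-11):
    """Per-group mode and curvature of the conditional log-density of b.

    The joint log-density is strictly concave in b, so damped Newton with
    step-halving converges; returns (b_hat, h2) with h2 the (negative)
    second derivative at the mode.
    """
    b = np.zeros(ngroups) if b0 is None else b0.copy()
    inv_s2 = 1.0 / sigma**2

    def obj(bv):
        e = eta + bv[gidx]
        lp = y * e - np.logaddexp(0.0, e)
        return np.bincount(gidx, weights=lp, minlength=ngroups) - 0.5 * bv**2 * inv_s2

    f = obj(b)
    for _ in range(max_iter):
        mu = expit(eta + b[gidx])
        grad = np.bincount(gidx, weights=y - mu, minlength=ngroups) - b * inv_s2
        h2 = -np.bincount(gidx, weights=mu * (1 - mu), minlength=ngroups) - inv_s2
        step = grad / h2
        if np.max(np.abs(step)) < tol:
            break
        b_new = b - step
        f_new = obj(b_new)
        worse = f_new < f - 1e-12
        halvings = 0
        while worse.any() and halvings < 30:
            step = np.where(worse, step / 2, step)
            b_new = b - step
            f_new = obj(b_new)
            worse = f_new < f - 1e-12
            halvings += 1
        b, f = b_new, f_new
    mu = expit(eta + b[gidx])
    h2 = -np.bincount(gidx, weights=mu * (1 - mu), minlength=ngroups) - inv_s2
    return b, h2


def _group_loglik(theta, y, X, gidx, ngroups, z, logw, b_cache=None):
    """Per-group marginal log-likelihood via adaptive Gauss-Hermite."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    b0 = b_cache.get("b") if b_cache is not None else None
    bhat, h2 = _posterior_modes(y, eta, gidx, ngroups, sigma, b0=b0)
    if b_cache is not None:
        b_cache["b"] = bhat
    tau = 1.0 / np.sqrt(-h2)
    sqrt2 = np.sqrt(2.0)
    K = len(z)
    acc = np.empty((ngroups, K))
    log_norm_const = -0.5 * np.log(2 * np.pi) - log_sigma
    for k in range(K):
        b_k = bhat + sqrt2 * tau * z[k]
        e = eta + b_k[gidx]
        lp = y * e - np.logaddexp(0.0, e)
        s = np.bincount(gidx, weights=lp, minlength=ngroups)
        s += log_norm_const - 0.5 * (b_k / sigma) ** 2
        acc[:, k] = logw[k] + z[k] ** 2 + s
    return np.log(sqrt2 * tau) + logsumexp(acc, axis=1)


def _marginal_loglik(theta, y, X, gidx, ngroups, z, logw, b_cache=None):
    return float(np.sum(_group_loglik(theta, y, X, gidx, ngroups, z, logw, b_cache)))


@dataclass
class FittedGLMM:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Coefficients (``beta``) and their covariance are reported on the
    natural covariate scale; ``beta_centred`` is the internal
    parameterization.  ``vcov`` covers the fixed effects plus ``sigma_b``
    (delta method from the internal log-sigma parameterization).
    """

    spec: ModelSpec
    design: Design
    beta: pd.Series
    beta_centred: np.ndarray
    sigma_b: float
    vcov: pd.DataFrame
    vcov_internal: np.ndarray
    loglik: float
    n_quad: int
    converged: bool
    boundary: bool
    n_obs: int
    n_groups: int
    message: str = ""
    _eb: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def k_params(self) -> int:
        """Fixed coefficients + 1 variance parameter."""
        return len(self.beta) + (1 if self.spec.grouping else 0)

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.vcov.index)

    def require_converged(self):
        if not self.converged:
            raise RuntimeError(f"fit did not converge: {self.message}")

    def linear_predictor(self, newdata: pd.DataFrame) -> np.ndarray:
        d = build_design(self.spec, newdata, template=self.design, require_response=False)
        return d.X @ self.beta_centred

    def to_json(self) -> str:
        d = {
            "formula": self.spec.formula(),
            "colnames": self.design.colnames,
            "factor_levels": self.design.factor_levels,
            "cont_means": self.design.cont_means,
            "beta_natural": self.beta.to_dict(),
            "beta_centred": self.beta_centred.tolist(),
            "sigma_b": self.sigma_b,
            "loglik": self.loglik,
            "n_quad": self.n_quad,
            "converged": self.converged,
            "boundary": self.boundary,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "vcov": self.vcov.to_numpy().tolist(),
            "vcov_internal": self.vcov_internal.tolist(),
        }
        return json.dumps(d, indent=1, default=lambda o: o.item() if hasattr(o, "item") else str(o))


def _start_values(y, X):
    """Plain-logistic starting values (statsmodels), zeros on failure."""
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(beta)):
            return np.clip(beta, -15, 15)
    except Exception:
        pass
    return np.zeros(X.shape[1])


def _numerical_hessian(f, x, step=1e-4):
    p = len(x)
    H = np.empty((p, p))
    h = step * (1 + np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_glmm(
    design: Design,
    n_quad: int = 11,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> FittedGLMM:
    """Fit by maximizing the adaptive-quadrature marginal likelihood.

    Parameters
    ----------
    design : Design
        From :func:`build_design`; must include a grouping factor (use a
        plain logistic model otherwise).
    n_quad : int
        Gauss-Hermite nodes per group (the default 11 is sufficient for
        stability in this problem class; see the methods note).
    tol, max_iter
        L-BFGS-B convergence controls on (beta, log sigma_b).
    """
    if design.group_idx is None:
        raise ValueError("design has no grouping factor; fit a plain logistic model")
    y, X, gidx = design.y, design.X, design.group_idx
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary")
    if n_quad < 1:
        raise ValueError("n_quad must be >= 1")
    ngroups = design.n_groups
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(w)
    b_cache: dict = {}

    def nll(theta):
        return -_marginal_loglik(theta, y, X, gidx, ngroups, z, logw, b_cache)

    theta0 = np.concatenate([_start_values(y, X), [0.0]])
    bounds = [(-40, 40)] * X.shape[1] + [(-8.0, 5.0)]
    options = {"maxiter": max_iter, "maxfun": 200_000, "ftol": tol, "gtol": 1e-7}
    res = minimize(nll, theta0, method="L-BFGS-B", bounds=bounds, options=options)
    if not res.success and "EVALUATIONS EXCEEDS" in str(res.message):
        res = minimize(nll, res.x, method="L-BFGS-B", bounds=bounds, options=options)
    theta = res.x
    beta_c = theta[:-1]
    sigma_b = float(np.exp(theta[-1]))
    loglik = -float(res.fun)
    converged = bool(res.success)
    boundary = theta[-1] <= -4.0
    if np.max(np.abs(beta_c)) > 30:
        warnings.warn(
            "very large coefficient magnitude: possible separation in the data",
            RuntimeWarning,
        )

    H = _numerical_hessian(nll, theta)
    # observed information; pseudo-inverse guards boundary sigma
    try:
        vcov_theta = np.linalg.inv(H)
        if not np.all(np.isfinite(vcov_theta)) or np.any(np.diag(vcov_theta) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov_theta = np.linalg.pinv(H)
        vcov_theta = (vcov_theta + vcov_theta.T) / 2
        d = np.diag(vcov_theta).copy()
        if np.any(d < 0):
            warnings.warn("information matrix not PD; SEs unreliable", RuntimeWarning)

    M = design.natural_transform
    p = X.shape[1]
    J = np.zeros((p + 1, p + 1))
    J[:p, :p] = M
    J[p, p] = sigma_b  # d sigma / d log sigma
    vcov_nat = J @ vcov_theta @ J.T
    vcov_nat = (vcov_nat + vcov_nat.T) / 2
    names = list(design.colnames) + ["sigma_b"]
    beta_nat = pd.Series(M @ beta_c, index=design.colnames)

    return FittedGLMM(
        spec=design.spec,
        design=design,
        beta=beta_nat,
        beta_centred=beta_c,
        sigma_b=sigma_b,
        vcov=pd.DataFrame(vcov_nat, index=names, columns=names),
        vcov_internal=vcov_theta,
        loglik=loglik,
        n_quad=n_quad,
        converged=converged,
        boundary=boundary,
        n_obs=design.n_obs,
        n_groups=ngroups,
        message=str(res.message),
    )


@dataclass
class RandomEffects:
    """Per-company empirical-Bayes modes with curvature-based SDs."""

    table: pd.DataFrame  # columns: company, mode, sd

    @property
    def modes(self) -> np.ndarray:
        return self.table["mode"].to_numpy()


def eb_modes(fit: FittedGLMM) -> RandomEffects:
    """Empirical-Bayes company effects at the ML estimates.

    Each company's mode maximizes the conditional posterior of its random
    intercept; the SD is from the curvature at the mode.  As sigma_b -> 0
    the prior dominates and all modes shrink to 0.
    """
    fit.require_converged()
    d = fit.design
    eta = d.X @ fit.beta_centred
    sigma = max(fit.sigma_b, 1e-8)
    b, h2 = _posterior_modes(d.y, eta, d.group_idx, d.n_groups, sigma)
    out = pd.DataFrame(
        {"company": d.group_labels, "mode": b, "sd": 1.0 / np.sqrt(-h2)}
    )
    fit._eb = out
    return RandomEffects(out)


def predict_ss(
    fit: FittedGLMM, newdata: pd.DataFrame, mode: str = "at_zero"
) -> np.ndarray:
    """Subject-specific probabilities ``logistic(x beta + b_hat)``.

    ``mode='at_zero'`` uses b = 0 (a typical company); ``'at_eb_mode'``
    plugs in each company's empirical-Bayes mode, falling back to 0 with a
    warning for companies not seen in training.
    """
    fit.require_converged()
    if mode not in ("at_zero", "at_eb_mode"):
        raise ValueError("mode must be 'at_zero' or 'at_eb_mode'")
    eta = fit.linear_predictor(newdata)
    if mode == "at_eb_mode":
        re = eb_modes(fit) if fit._eb is None else RandomEffects(fit._eb)
        lut = dict(zip(re.table["company"], re.table["mode"]))
        comps = newdata[fit.spec.grouping].astype(str)
        unseen = sorted(set(comps) - set(lut))
        if unseen:
            warnings.warn(
                f"companies {unseen} not in training data; using b = 0", RuntimeWarning
            )
        eta = eta + comps.map(lambda c: lut.get(c, 0.0)).to_numpy()
    return expit(eta)


def aicc(fit: FittedGLMM) -> float:
    """Small-sample corrected AIC: ``-2 l + 2k + 2k(k+1)/(n - k - 1)``.

    ``k`` counts the fixed coefficients plus one variance parameter.
    """
    k = fit.k_params
    n = fit.n_obs
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n = {n} <= k + 1 = {k + 1}")
    return -2.0 * fit.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)
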