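"""Shared fixtures: small synthetic datasets and hand-built GLMM fits."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from isoscreen.glmm import FittedGLMM, ModelSpec, build_design, fit_glmm
from isoscreen.synth import default_config, default_model_config, generate


@pytest.fixture(scope="session")
def default_table() -> pd.DataFrame:
    """One descriptive-mode dataset from the default configuration."""
    return generate(default_config(seed=20240101))


@pytest.fixture(scope="session")
def model_table() -> pd.DataFrame:
    """One model-mode dataset (known truth: intercept -3.2, d15n 0.8, sigma 1.5)."""
    return generate(default_model_config(seed=20240202))


@pytest.fixture(scope="session")
def model_fit(model_table) -> FittedGLMM:
    spec = ModelSpec.from_formula("system ~ d15n + (1 | company)")
    fit = fit_glmm(build_design(spec, model_table))
    assert fit.converged
    return fit


def simulate_glmm(
    seed: int,
    n_groups: int = 40,
    per_group: int = 8,
    beta=(0.3, 0.8),
    sigma_b: float = 1.0,
) -> pd.DataFrame:
    """Direct random-intercept logistic simulation (independent of synth)."""
    rng = np.random.default_rng(seed)
    n = n_groups * per_group
    g = np.repeat(np.arange(n_groups), per_group)
    x = rng.normal(0.0, 1.0, n)
    b = rng.normal(0.0, sigma_b, n_groups)
    eta = beta[0] + beta[1] * x + b[g]
    y = (rng.random(n) < expit(eta)).astype(float)
    return pd.DataFrame({"y": y, "x": x, "g": [f"g{i:03d}" for i in g]})


def make_fit(df: pd.DataFrame, formula: str, beta_natural, sigma_b: float) -> FittedGLMM:
    """FittedGLMM with coefficients fixed by hand (for oracle tests).

    The design is built from ``df``; ``beta_natural`` is on the natural
    scale and converted through the centering transform.  The covariance is
    a small identity placeholder.
    """
    design = build_design(ModelSpec.from_formula(formula), df)
    M = design.natural_transform
    if isinstance(beta_natural, dict):
        unknown = set(beta_natural) - set(design.colnames)
        assert not unknown, f"unknown coefficients {unknown}"
        beta_natural = [beta_natural.get(c, 0.0) for c in design.colnames]
    beta_nat = np.asarray(beta_natural, dtype=float)
    beta_c = np.linalg.solve(M, beta_nat)
    p = len(beta_c)
    names = list(design.colnames) + ["sigma_b"]
    return FittedGLMM(
        spec=design.spec,
        design=design,
        beta=pd.Series(beta_nat, index=design.colnames),
        beta_centred=beta_c,
        sigma_b=sigma_b,
        vcov=pd.DataFrame(np.eye(p + 1) * 1e-4, index=names, columns=names),
        vcov_internal=np.eye(p + 1) * 1e-4,
        loglik=0.0,
        n_quad=11,
        converged=True,
        boundary=False,
        n_obs=design.n_obs,
        n_groups=design.n_groups,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def scaled_config(seed: int, factor: float = 0.1):
    """Default descriptive config with all cell counts scaled down."""
    cfg = default_config(seed=seed)
    profiles = tuple(
        dataclasses.replace(p, n_samples=max(2, int(round(p.n_samples * factor))))
        for p in cfg.profiles
    )
    return dataclasses.replace(cfg, profiles=profiles)
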