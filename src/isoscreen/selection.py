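"""AICc model selection over hierarchical candidate GLMMs.

Candidates are all hierarchical specifications with main effects and
pairwise interactions drawn from a user-supplied variable list (the random
intercept is always present and never enters the fixed terms).  Exhaustive
enumeration is capped; past the cap a greedy forward AICc search is
offered instead.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .glmm import FittedGLMM, ModelSpec, aicc, build_design, fit_glmm

logger = logging.getLogger(__name__)

__all__ = ["SelectionResult", "enumerate_candidates", "select", "forward_search"]


@dataclass
class SelectionResult:
    """Ranked AICc table and the chosen specification.

    ``table`` columns: formula, k, loglik, aicc, delta_aicc, converged —
    sorted ascending by AICc with non-converged candidates unranked at the
    bottom (delta_aicc = NaN).
    """

    table: pd.DataFrame
    best: ModelSpec
    best_fit: FittedGLMM


def n_candidates(n_variables: int) -> int:
    """Number of hierarchical specs for ``n_variables`` candidate variables."""
    total = 0
    for k in range(n_variables + 1):
        n_pairs = k * (k - 1) // 2
        from math import comb

        total += comb(n_variables, k) * 2**n_pairs
    return total


def enumerate_candidates(
    variables: list[str],
    response: str = "system",
    grouping: str | None = "company",
    max_order: int = 2,
    hierarchy: bool = True,
    cap: int = 4096,
) -> list[ModelSpec]:
    """All hierarchical specs up to pairwise interactions, deduplicated.

    Deterministic order: by number of main effects, then mains
    lexicographically, then by number of interactions, then interactions
    lexicographically.  Raises if the candidate count exceeds ``cap`` with
    a pointer to :func:`forward_search`.
    """
    if not variables:
        raise ValueError("variables must be non-empty")
    if len(set(variables)) != len(variables):
        raise ValueError("duplicate variables")
    if max_order not in (1, 2):
        raise ValueError("max_order must be 1 or 2")
    if not hierarchy:
        raise ValueError("non-hierarchical enumeration is not supported")
    if n_candidates(len(variables)) > cap and max_order == 2:
        raise ValueError(
            f"{n_candidates(len(variables))} candidates exceed cap {cap}; "
            "use forward_search() for a restricted AICc search"
        )
    specs = []
    for k in range(len(variables) + 1):
        for mains in itertools.combinations(sorted(variables), k):
            pairs = (
                list(itertools.combinations(mains, 2)) if max_order == 2 else []
            )
            for r in range(len(pairs) + 1):
                for inter in itertools.combinations(pairs, r):
                    terms = tuple((m,) for m in mains) + tuple(
                        tuple(sorted(p)) for p in inter
                    )
                    specs.append(
                        ModelSpec(response=response, fixed_terms=terms, grouping=grouping)
                    )
    return specs


def _fit_candidate(spec: ModelSpec, table: pd.DataFrame, n_quad: int):
    try:
        fit = fit_glmm(build_design(spec, table), n_quad=n_quad)
        return fit, aicc(fit) if fit.converged else float("nan")
    except Exception as exc:  # noqa: BLE001 - candidate failures are data
        logger.warning("candidate %s failed: %s", spec.formula(), exc)
        return None, float("nan")


def select(
    candidates: list[ModelSpec],
    table: pd.DataFrame,
    n_quad: int = 11,
) -> SelectionResult:
    """Fit every candidate and rank converged fits by AICc.

    Only converged fits are ranked; the chosen model is the converged fit
    with minimum AICc (delta_aicc = 0 by definition).  Raises if no
    candidate converges.
    """
    if not candidates:
        raise ValueError("no candidates")
    rows = []
    fits: list[FittedGLMM | None] = []
    for spec in candidates:
        fit, crit = _fit_candidate(spec, table, n_quad)
        fits.append(fit)
        rows.append(
            {
                "formula": spec.formula(),
                "k": (fit.k_params if fit is not None else None),
                "loglik": (fit.loglik if fit is not None else None),
                "aicc": crit,
                "converged": bool(fit is not None and fit.converged),
            }
        )
    df = pd.DataFrame(rows)
    if not df["converged"].any():
        raise RuntimeError(
            "no candidate converged; per-candidate failures were logged"
        )
    best_aicc = df.loc[df.converged, "aicc"].min()
    df["delta_aicc"] = df["aicc"] - best_aicc
    df.loc[~df.converged, "delta_aicc"] = float("nan")
    order = df["aicc"].fillna(float("inf")).argsort(kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    best_i = int(
        min(
            (i for i in range(len(candidates)) if rows[i]["converged"]),
            key=lambda i: rows[i]["aicc"],
        )
    )
    return SelectionResult(table=df, best=candidates[best_i], best_fit=fits[best_i])


def forward_search(
    variables: list[str],
    table: pd.DataFrame,
    response: str = "system",
    grouping: str | None = "company",
    n_quad: int = 11,
    max_steps: int = 30,
) -> SelectionResult:
    """Greedy forward AICc search (used past the enumeration cap).

    Starts from the intercept-only model and, at each step, adds the single
    main effect or hierarchy-admissible interaction that most lowers AICc;
    stops when no addition improves.
    """
    current: tuple[tuple[str, ...], ...] = ()
    spec = ModelSpec(response=response, fixed_terms=current, grouping=grouping)
    fit, crit = _fit_candidate(spec, table, n_quad)
    if fit is None:
        raise RuntimeError("intercept-only model failed to fit")
    history = [
        {"formula": spec.formula(), "k": fit.k_params, "loglik": fit.loglik,
         "aicc": crit, "converged": fit.converged}
    ]
    best_spec, best_fit, best_crit = spec, fit, crit
    for _ in range(max_steps):
        mains = {t[0] for t in current if len(t) == 1}
        moves = [(v,) for v in variables if (v,) not in current]
        moves += [
            tuple(sorted(p))
            for p in itertools.combinations(sorted(mains), 2)
            if tuple(sorted(p)) not in current
        ]
        step_best = None
        for mv in moves:
            cand = ModelSpec(
                response=response,
                fixed_terms=tuple(sorted(current + (mv,), key=lambda t: (len(t), t))),
                grouping=grouping,
            )
            f, c = _fit_candidate(cand, table, n_quad)
            if f is None or not f.converged:
                continue
            history.append(
                {"formula": cand.formula(), "k": f.k_params, "loglik": f.loglik,
                 "aicc": c, "converged": True}
            )
            if step_best is None or c < step_best[2]:
                step_best = (cand, f, c)
        if step_best is None or step_best[2] >= best_crit:
            break
        best_spec, best_fit, best_crit = step_best
        current = best_spec.fixed_terms
    df = pd.DataFrame(history).sort_values("aicc", kind="stable").reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - best_crit
    return SelectionResult(table=df, best=best_spec, best_fit=best_fit)
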