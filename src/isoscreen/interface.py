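"""Shared plumbing: schema-checked CSV I/O, config, pipeline driver.

The pipeline chains the full analysis into one reproducible run:
generate (or ingest) -> describe -> select -> fit -> diagnose ->
marginalize -> screen -> report.  Every artifact is CSV/JSON/text with a
sidecar JSON recording the schema version, master seed and config hash, so
a rerun with the same configuration is byte-identical for the
deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from . import thresholds as thr
from .descriptive import summarize_groups
from .glmm import ModelSpec, aicc, build_design, eb_modes, fit_glmm, predict_ss
from .marginal import auroc, marginalize_coefs, predict_pa
from .selection import enumerate_candidates, select
from .synth import CROPS, ORIGINS, SYSTEMS, GeneratorConfig, default_config, generate

logger = logging.getLogger(__name__)

__all__ = ["SCHEMA", "PipelineConfig", "read_samples", "write_samples", "run_pipeline"]

SCHEMA_VERSION = "1"
SCHEMA = [
    "sample_id",
    "crop",
    "system",
    "company",
    "origin",
    "c_pct",
    "n_pct",
    "cn_ratio",
    "d13c",
    "d15n",
]
_NUMERIC = ["c_pct", "n_pct", "cn_ratio", "d13c", "d15n"]


def read_samples(path) -> pd.DataFrame:
    """Read and validate a sample table.

    The header must contain the schema columns (order-insensitive; a
    missing ``cn_ratio`` is recomputed from c_pct / n_pct and logged).
    Unknown crop/system/origin levels raise with the offending rows;
    stored cn_ratio inconsistent with c_pct / n_pct beyond 1 % relative
    tolerance triggers a warning naming the rows.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=["NA"])
    missing = set(SCHEMA) - {"cn_ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    for col, allowed in (("crop", CROPS), ("system", SYSTEMS), ("origin", ORIGINS)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            rows = df.index[bad].tolist()[:10]
            raise ValueError(
                f"unknown {col} level(s) {sorted(df.loc[bad, col].unique())} "
                f"in rows {rows}"
            )
    recomputed = df["c_pct"] / df["n_pct"]
    if "cn_ratio" not in df.columns:
        logger.info("cn_ratio column absent; recomputed from c_pct / n_pct")
        df["cn_ratio"] = recomputed
    else:
        rel = np.abs(df["cn_ratio"] - recomputed) / np.abs(recomputed)
        bad = rel > 0.01
        if bad.any():
            warnings.warn(
                f"cn_ratio inconsistent with c_pct/n_pct in rows "
                f"{df.index[bad].tolist()[:10]}",
                RuntimeWarning,
            )
    return df[SCHEMA]


def write_samples(df: pd.DataFrame, path) -> None:
    """Write a sample table with the fixed schema header."""
    missing = set(SCHEMA) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df[SCHEMA].to_csv(path, index=False, na_rep="NA")


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    ``generator`` may be a :class:`GeneratorConfig` or a path to a CSV to
    ingest.  ``selection_variables=None`` skips the AICc search and fits
    ``formula`` directly.  All randomness derives from ``seed``.
    """

    outdir: str = "isoscreen_run"
    seed: int = 0
    generator: GeneratorConfig | str | None = None
    formula: str = (
        "system ~ crop + cn_ratio + c_pct + d15n + crop:d15n + crop:cn_ratio"
        " + (1 | company)"
    )
    selection_variables: list[str] | None = None
    n_quad: int = 11
    hl_bins: int = 10
    mc_draws: int = 5000
    threshold_target: float = 0.01
    threshold_confidence: float = 0.95
    bootstrap_replicates: int = 2000
    profile_covariates: list[str] = field(
        default_factory=lambda: ["d15n", "cn_ratio", "c_pct"]
    )

    def content_hash(self) -> str:
        d = dataclasses.asdict(self)
        if isinstance(self.generator, GeneratorConfig):
            d["generator"] = self.generator.to_json()
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sidecar(path: Path, config: PipelineConfig, stage: str, t0: float, rows: int):
    meta = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "stage": stage,
        "rows": rows,
        "elapsed_s": round(time.time() - t0, 3),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))
    logger.info("stage %-12s rows=%-6d elapsed=%.2fs -> %s", stage, rows,
                meta["elapsed_s"], path.name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full screening analysis; returns the run directory.

    Produces eight documented artifacts: ``samples.csv``,
    ``descriptive_d15n.csv``, ``selection.csv``, ``model.json``,
    ``diagnostics.csv``, ``marginal_coefs.csv``, ``screening.csv`` and
    ``report.txt`` (plus a ``.meta.json`` sidecar each).  Any stage
    failure raises with the stage name; artifacts written so far persist.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "generate"
    try:
        # ---- generate / ingest
        t0 = time.time()
        if isinstance(config.generator, (str, Path)):
            table = read_samples(config.generator)
        else:
            gcfg = config.generator or default_config(seed=config.seed)
            if gcfg.seed != config.seed:
                gcfg = dataclasses.replace(gcfg, seed=config.seed)
            table = generate(gcfg)
        p = out / "samples.csv"
        write_samples(table, p)
        _sidecar(p, config, stage, t0, len(table))

        # ---- describe
        stage = "describe"
        t0 = time.time()
        summary = summarize_groups(table, rows="origin", cols="system", variable="d15n")
        p = out / "descriptive_d15n.csv"
        summary.to_csv(p, index=False)
        _sidecar(p, config, stage, t0, len(summary))

        # ---- select / fit
        stage = "select"
        t0 = time.time()
        if config.selection_variables:
            spec0 = ModelSpec.from_formula(config.formula)
            cands = enumerate_candidates(
                config.selection_variables,
                response=spec0.response,
                grouping=spec0.grouping,
            )
            sel = select(cands, table, n_quad=config.n_quad)
            sel_table, fit = sel.table, sel.best_fit
        else:
            spec = ModelSpec.from_formula(config.formula)
            fit = fit_glmm(build_design(spec, table), n_quad=config.n_quad)
            fit.require_converged()
            sel_table = pd.DataFrame(
                [{
                    "formula": spec.formula(), "k": fit.k_params,
                    "loglik": fit.loglik, "aicc": aicc(fit),
                    "converged": fit.converged, "delta_aicc": 0.0,
                }]
            )
        p = out / "selection.csv"
        sel_table.to_csv(p, index=False)
        _sidecar(p, config, stage, t0, len(sel_table))

        stage = "fit"
        t0 = time.time()
        p = out / "model.json"
        p.write_text(fit.to_json())
        _sidecar(p, config, stage, t0, fit.n_obs)

        # ---- diagnose
        stage = "diagnose"
        t0 = time.time()
        probs_ss = predict_ss(fit, table, mode="at_eb_mode")
        d = fit.design
        gof = [
            diag.hosmer_lemeshow(probs_ss, d.y, bins=config.hl_bins),
            diag.osius_rojek(probs_ss, d.y, d.X),
            diag.stukel(probs_ss, d.y, d.X),
            diag.re_normality(eb_modes(fit)),
        ]
        diag_rows = [dataclasses.asdict(g) for g in gof]
        try:
            imp = diag.rao_importance(fit.spec, table)
            for _, r in imp.iterrows():
                diag_rows.append(
                    {"test": f"rao[{r['term']}]", "statistic": r["statistic"],
                     "df": r["df"], "p": r["p"], "note": r["note"]}
                )
        except Exception as exc:  # noqa: BLE001
            diag_rows.append({"test": "rao", "statistic": float("nan"),
                              "df": None, "p": float("nan"), "note": str(exc)})
        diag_df = pd.DataFrame(diag_rows)
        p = out / "diagnostics.csv"
        diag_df.to_csv(p, index=False)
        _sidecar(p, config, stage, t0, len(diag_df))

        # ---- marginalize
        stage = "marginalize"
        t0 = time.time()
        marg = marginalize_coefs(fit, draws=config.mc_draws, seed=config.seed)
        probs_pa = predict_pa(fit, table)
        auc_ss, _ = auroc(probs_ss, table["system"])
        auc_pa, _ = auroc(probs_pa, table["system"])
        mtab = pd.DataFrame(
            {"coef": marg.beta_pa.index, "beta_ss": fit.beta.to_numpy(),
             "beta_pa": marg.beta_pa.to_numpy(), "robust_se": marg.robust_se.to_numpy()}
        )
        p = out / "marginal_coefs.csv"
        mtab.to_csv(p, index=False)
        _sidecar(p, config, stage, t0, len(mtab))

        # ---- screen
        stage = "screen"
        t0 = time.time()
        ss = np.random.SeedSequence([config.seed, 7])
        screen_rows = []
        for i, crop in enumerate(sorted(table["crop"].unique())):
            m = (table["crop"] == crop).to_numpy()
            sub_probs, sub_y = probs_pa[m], table.loc[m, "system"]
            if sub_y.nunique() < 2:
                continue
            dec = thr.select_threshold(
                sub_probs,
                sub_y,
                target=config.threshold_target,
                confidence=config.threshold_confidence,
                replicates=config.bootstrap_replicates,
                seed=int(ss.generate_state(1)[0] % (2**31)) + i,
                crop=crop,
            )
            if dec.achievable:
                for cov in config.profile_covariates:
                    if cov not in fit.design.cont_means:
                        continue
                    cut = thr.invert_cutoff(fit, crop, cov, dec.threshold, table)
                    if cut is not None:
                        dec.cutoffs.append(cut)
            for cut in dec.cutoffs or [None]:
                screen_rows.append(
                    {
                        "crop": crop,
                        "threshold": dec.threshold,
                        "fnr_point": dec.fnr_point,
                        "fnr_upper95": dec.fnr_upper95,
                        "achievable": dec.achievable,
                        "accuracy": dec.accuracy,
                        "cutoff_covariate": cut.covariate if cut else "NA",
                        "cutoff_value": cut.value if cut else float("nan"),
                        "cutoff_direction": cut.direction if cut else "NA",
                    }
                )
        screen_df = pd.DataFrame(screen_rows)
        p = out / "screening.csv"
        screen_df.to_csv(p, index=False)
        _sidecar(p, config, stage, t0, len(screen_df))

        # ---- report
        stage = "report"
        t0 = time.time()
        lines = [
            "isoscreen run report",
            f"seed: {config.seed}   config hash: {config.content_hash()}",
            f"samples: {len(table)}  companies: {table['company'].nunique()}",
            f"model: {fit.spec.formula()}",
            f"loglik: {fit.loglik:.3f}  AICc: {aicc(fit):.3f}  sigma_b: {fit.sigma_b:.3f}",
            f"AUROC subject-specific: {auc_ss:.3f}  population-averaged: {auc_pa:.3f}",
            "",
            "screening decisions (FNR-controlled thresholds):",
        ]
        for r in screen_rows:
            lines.append(
                f"  {r['crop']:<12} thr={r['threshold']:.4f} "
                f"fnr<={r['fnr_upper95']:.4f} achievable={r['achievable']} "
                f"cutoff={r['cutoff_covariate']} {r['cutoff_direction']} "
                f"{r['cutoff_value']:.3g}"
            )
        p = out / "report.txt"
        p.write_text("\n".join(lines) + "\n")
        _sidecar(p, config, stage, t0, len(screen_rows))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
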