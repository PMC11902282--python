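"""Population-averaged screening thresholds with FNR control.

Marginalizes the company random effect out of a fitted GLMM, compares
subject-specific vs population-averaged AUROC, then selects the highest
probability threshold whose false negative rate (true organics flagged
as conventional) stays under 1 % with 95 % bootstrap confidence, and
inverts it into a delta15N cutoff for raspberries.
"""

from isoscreen import (
    ModelSpec, auroc, build_design, default_model_config, fit_glmm, generate,
    invert_cutoff, marginalize_coefs, predict_pa, predict_ss, select_threshold,
)

table = generate(default_model_config(seed=7))
spec = ModelSpec.from_formula("system ~ d15n + (1 | company)")
fit = fit_glmm(build_design(spec, table))

probs_ss = predict_ss(fit, table, mode="at_eb_mode")
probs_pa = predict_pa(fit, table)
auc_ss, _ = auroc(probs_ss, table["system"])
auc_pa, _ = auroc(probs_pa, table["system"])
print(f"AUROC subject-specific {auc_ss:.3f} vs population-averaged {auc_pa:.3f}")

marg = marginalize_coefs(fit, draws=5000, seed=0)
print(f"delta15N slope: SS {fit.beta['d15n']:.3f} -> PA "
      f"{marg.beta_pa['d15n']:.3f} (robust SE {marg.robust_se['d15n']:.3f})")

dec = select_threshold(probs_pa, table["system"], target=0.01,
                       confidence=0.95, replicates=2000, seed=1)
print(f"\nthreshold {dec.threshold:.4f}: FNR point {dec.fnr_point:.4f}, "
      f"95% bound {dec.fnr_upper95:.4f}, achievable={dec.achievable}, "
      f"accuracy {dec.accuracy:.3f}")

cut = invert_cutoff(fit, "raspberry", "d15n", dec.threshold, table)
if cut is not None:
    print(f"raspberry rule: flag samples with d15n {cut.direction} "
          f"{cut.value:.2f} per mil as suspect non-organic")
# The PA model ranks worse than the SS model (it cannot use producer
# identity) but is the one a company-agnostic screening rule needs.
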