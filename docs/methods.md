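# Methods

This note documents the statistical models, the calibration of the
synthetic-data generator, the numerical choices, and the known
limitations of `isoscreen`.

## The screening problem

The observable is a produce sample with crop type, producer company,
geographic origin, total C and N mass fractions (%), their ratio C/N, and
the stable-isotope signatures δ¹³C and δ¹⁵N (‰ relative to the
international standards; `compute_delta` implements the δ definition).
The target is the labelled production system, organic coded 1. Because
organic fertilizers (manure, compost, protein meals) are ¹⁵N-enriched
while Haber–Bosch N is near 0 ‰, δ¹⁵N carries most of the discriminating
signal; crop identity and elemental composition modulate it.

## Model

The core model is a random-intercept logistic GLMM:

    logit P(Y_ij = 1 | b_i) = x_ij' β + b_i,   b_i ~ N(0, σ_b²)

with one intercept per producer company. Companies are modelled as random
rather than fixed because many are sparsely sampled and screening rules
must generalize to producers not in the data. The default fixed-effect
structure is crop + C/N + C% + δ¹⁵N + crop:δ¹⁵N + crop:C/N.

**Fitting.** The marginal likelihood integrates each company's Bernoulli
likelihood over its random intercept. The integral is approximated per
company by Gauss–Hermite quadrature with nodes recentred at the posterior
mode of b_i and rescaled by the curvature there (adaptive quadrature);
the mode is found by damped Newton on the strictly concave conditional
log-density. 11 nodes are the default; the test suite verifies agreement
with 20,001-point dense-grid integration to 1e-4 in log-likelihood and
stability of the coefficients between 11 and 25 nodes. Optimization is
L-BFGS-B over (β, log σ_b) — the log parameterization enforces σ_b ≥ 0,
and fits with log σ_b ≤ −4 are flagged as boundary cases. Continuous
covariates are centred internally for conditioning; coefficients and
covariances are mapped back to the natural scale by the exact linear
transform of the centering. Standard errors come from the
finite-difference observed information at the optimum. Starting values
are the ordinary logistic fit (σ_b = 1).

**Model selection** minimizes AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), k
counting fixed coefficients plus the variance parameter. Candidates are
every hierarchical spec (interactions only with both mains present) over
a user-chosen variable list; the candidate variable list is configuration
rather than a hard-coded set. Exhaustive enumeration is capped at 4096
candidates, past which a greedy forward AICc search is provided and
labelled as such.

**Diagnostics.** Goodness of fit uses the classical battery on the fitted
probabilities: Hosmer–Lemeshow deciles of risk (ties broken by stable
sort on observation index; zero-expectation bins merged), the Osius–Rojek
normal approximation to the Pearson statistic (each row its own covariate
pattern; the statistic is centred at n − p — presentations differ between
n − p and n − p − 1, and the implemented version is validated by null
simulation in the test suite), and Stukel's two-parameter score test.
Variable importance uses hierarchical term-deletion Rao score tests in
the *fully fixed* model: the random intercept is replaced by fixed
company indicators (singleton companies pooled into a reference level),
and deleting a variable removes its main effect plus every interaction
containing it. System-exclusive producers make the company indicators
quasi-separated, so reduced models are fit by IRLS with a weak ridge
(α = 1e-6, intercept unpenalized), which keeps the score test computable
while perturbing identified coefficients negligibly. Normality of the
random effects is checked by Shapiro–Wilk on the empirical-Bayes modes.

**Population averaging.** Screening must be company-agnostic, so
predictions marginalize the random effect: PA(x) = E_b[logit⁻¹(x′β + b)],
computed by 41-node Gauss–Hermite quadrature (deterministic; used for
predictions, profiles and cutoff inversion) or Monte Carlo (used, per the
method's definition, for coefficient marginalization; default 5000
draws). Marginal coefficients β_PA are the least-squares projection of
the marginal logits onto the design — the operative definition adopted
here, since several variants exist. Their "robust" SEs combine
delta-method propagation of the fit covariance through the (quadrature)
marginalization map with the Monte Carlo projection error. Under a logit
link the PA slopes are attenuated by roughly 1/√(1 + c²σ_b²),
c = 16√3/(15π); dense-grid computation shows this classical factor is
itself accurate only for moderate σ (≈1.6 % error at σ = 0.5, ≈6 % at
σ = 2), so tests assert the 3 % agreement band at σ ≤ 0.75 and exact
equality of PA and SS at σ = 0.

**Thresholds.** For each crop, candidate thresholds are the sorted unique
PA probabilities (plus 0). The dataset is bootstrapped nonparametrically
(2000 replicates, resampling rows with replacement, stratified so both
classes survive every replicate); the FNR of each candidate gets a
one-sided upper bound at the 95 % empirical quantile, and the rule takes
the **highest** candidate whose bound stays below the 1 % target —
FNR control protects honest organic growers, and the highest such
threshold maximizes power to flag violations. Fitted probabilities are
treated as fixed scores during the bootstrap (the model is not refit per
replicate); out-of-sample simulations in the test suite and acceptance
script confirm the selected rules hold their FNR target on independent
100,000-sample test sets. Where the crop's PA profile is strictly
monotone in one covariate (others at crop-specific sample means), the
probability threshold is inverted by bracketed bisection into a
univariate cutoff whose flag direction follows the slope sign;
non-monotone profiles or thresholds outside the observed range yield "no
univariate cutoff".

## Synthetic-data generator

The generator reproduces the *structure* of the survey, not its rows.

* **Counts**: the published 7 × 2 table, 369 conventional + 422 organic =
  791.
* **δ¹⁵N**: sample mean = system mean (1.84 / 5.98 ‰) + crop offset +
  origin deviation + company shift. Crop offsets encode the published
  crop ordering and are recentred to a count-weighted zero mean per
  system, so system-level means are exact by construction; with the
  published counts the implied overall mean is 4.049 ‰. Origin deviations
  are the published per-origin means minus the system mean, and origin
  weights are solved so their weighted mean vanishes. The conventional
  "Other" share is fixed at 3 %; for organic produce the published
  per-origin means (USA 6.74, Mexico 6.45, Other 1.07 ‰) are only
  consistent with the 5.98 ‰ system mean if the "Other" share is ≈11 %,
  which the generator adopts — the survey's "97 % from Mexico and the
  U.S." cannot hold simultaneously, and system-level calibration takes
  priority. Residual SDs are set so the total system-level variance
  matches the published 2.19 / 3.38 ‰ after removing the crop, origin and
  company components (floor 0.8 ‰).
* **δ¹³C**: per-origin published means/SDs, with berry/vegetable crop
  offsets recentred the same way.
* **N %**: published per-crop means (celery split 2.17 / 1.45 % by
  system); SDs set to 25 % CV, a typical within-crop spread, truncated at
  a 0.05 % physical floor with redraw. **C %**: anchored at the published
  celery (35.4 %) and raspberry (43.8 %, SD 1.7) values, other crops
  interpolated so the implied mean C/N ordering matches the published
  ordering. C/N is always computed as C/N, never sampled.
* **Companies**: 99 producers, 40 % organic-only / 40 % conventional-only
  / 20 % mixed (exclusivity is documented in the survey, proportions are
  not; these are configuration knobs). In descriptive mode the company
  effect is a N(0, 1 ‰) shift on δ¹⁵N; in model mode it acts on the
  log-odds (default σ_b = 1.5). Both channels exist because the survey
  does not say which one operates in real data.
* **Model mode** draws covariates from system-pooled profiles (labels do
  not influence covariates), then samples the label from
  logit⁻¹(x′β + b_company). The default model-mode coefficients
  (intercept −3.2, δ¹⁵N slope 0.8, σ_b = 1.5) give the
  clear-but-imperfect separation regime the screening problem lives in.
* One master seed; every stochastic step uses a dedicated
  `SeedSequence`-spawned child stream.

What the generator does **not** emulate: IRMS measurement error as a
separate variance component, non-normal measurement distributions,
company × crop specialization, or any row-level feature of the real
data. Passing tests therefore demonstrate correctness of the estimators
and the calibration machinery on data with the assumed structure — not
that real produce follows these distributions.

## Problem sizes in the checks

Validation simulations are sized to be informative yet quick: Wald
coverage uses 200 replicates of a 40-company × 8-observation design;
null-calibration of the goodness-of-fit battery uses 200 replicates of
n = 2000 logistic samples; out-of-sample FNR checks use default-size
(791) training sets with ~100,000-sample test sets, 20 repetitions in the
acceptance script and 5 in the test suite.

## Design notes and limitations

* The crop factor uses treatment coding against the alphabetically first
  level (blackberry); reported contrasts are coding-invariant.
* The cli surface listed alongside the pipeline is fulfilled by the
  public functions, `run_pipeline`, and the `examples/` scripts; the
  package is a library, not a shell tool.
* Descriptive-mode default data contain system-exclusive producers, so
  the company random intercept is quasi-separated: σ_b estimates run
  large (the likelihood is flat in σ_b beyond ~5) and GLMM fits on the
  full 22-column model take ~15 s. This mirrors the real survey, where
  company was the dominant predictor.
* Bootstrap threshold selection treats fitted probabilities as fixed;
  per-replicate refitting (2000 GLMM fits) is conceptually supported by
  composing `fit_glmm` with resampling but is not a packaged fast path.
* Univariate cutoffs are conditional on holding other covariates at
  crop-specific means; interaction effects mean the cutoffs shift for
  atypical covariate profiles.
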