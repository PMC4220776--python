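# Methods

`utilmap` re-implements, as a reusable library, a mapping ("crosswalk")
analysis between the FACT-G cancer-specific quality-of-life instrument and
two preference-based utility indices, the EQ-5D-3L and the SF-6D.  This note
records the models, the numerical choices, and what the synthetic cohort
generator does and does not emulate.

## The mapping problem

A utility index u assigns a preference weight to a health state, anchored at
1 (full health) and 0 (dead).  Cancer trials usually administer a
disease-specific profile instrument (here the FACT-G, 27 items in four
domains: physical, social/family, emotional and functional well-being, global
score 0–108) but not a preference-based one, so utilities for QALY
calculations must be *mapped* from the profile scores.  The estimated mapping
has the generic form

    u_i = f(x_i'β) + ε_i,

with three nested predictor sets ("models"):

* **Model 1**: the rescaled (0–100) FACT-G global score;
* **Model 2**: the rescaled PWB, FWB and EWB domain scores (SWB is excluded —
  its marginal association with either utility is negligible);
* **Model 3**: Model 2 plus age, sex (female = 1), tumour-site dummies
  (colorectal, lung; breast reference) and stage dummies (stage 2–4; stage 1
  reference).  Interaction terms (PWB×FWB, PWB×EWB, age², age×sex) are
  available but disabled by default: they are known not to improve fit in
  this setting.

and three estimators:

* **OLS** with an HC1 heteroscedasticity-robust sandwich vcov (HC0/HC2/HC3
  selectable).  The HC1 variant is the conventional "robust" default of
  econometric software.
* **GLM with a log link** (Gaussian family by default, Gamma selectable), so
  the conditional mean is exp(x'β).  The family/link pair is a package
  choice: a negative constant with positive slopes on a response bounded
  near 1 is the signature of a log link, and the Gaussian family keeps the
  additive-error interpretation; Gamma requires strictly positive responses.
* **CLAD** (censored least absolute deviations): β minimising
  Σ|y_i − min(x_i'β, c)| with the ceiling c = 1.  CLAD is the median-
  regression analogue of the Tobit and stays consistent under
  heteroscedasticity, non-normal errors and ceiling censoring — the reason it
  exists here: 23% of EQ-5D responses sit exactly at 1, which biases the OLS
  slope toward zero.

## Numerical choices

**LAD subproblems** are solved exactly as linear programs (HiGHS, sparse
formulation, split residuals u⁺−u⁻).  When the argmin is a segment (even n,
intercept-only), the LP's deterministic pivoting under a fixed row order
returns one canonical vertex; the *objective*, not the argmin, is the
reproducible contract.

**CLAD** uses two solvers.  For problems with at most two coefficients and at
most 40 observations, the global minimum is found exactly by enumerating the
vertices of the piecewise-linear objective — every intersection of k
hyperplanes drawn from {y_i = x_i'β} ∪ {x_i'β = c}.  Larger problems use the
iterative linear-programming algorithm (ILPA): fit LAD on the full sample,
retain observations with x_i'β < c, refit on the retained set, iterate until
the retained set is stable (max 50 iterations); if retained sets cycle, the
iterate with the smallest objective is kept.  The small-sample exact path
exists because ILPA, like any trimming scheme, can stall in a local optimum
of the non-convex objective when n is tiny and censoring heavy; at realistic
sample sizes the trimming fixed point is the standard estimator.
`FittedModel.stats["solver"]` records which path ran.

**CLAD inference** is a nonparametric case bootstrap (patients resampled with
replacement, the whole fit re-run; B = 1000 by default, seeded).  Replicates
whose fit fails are dropped and counted; more than 50% failures aborts.
Standard errors are replicate SDs; 95% intervals are percentile.

**GLM fitting** is IRLS (statsmodels) with relative tolerance 1e-8, at most
100 iterations, started from the OLS fit of log(y); non-convergence raises
with the deviance trace attached.

**Wilcoxon matched-pairs signed-rank test**: zero differences are dropped
(Wilcoxon's convention; the Pratt variant is selectable), tied absolute
differences get average ranks.  For ≤ 25 nonzero pairs the two-sided p-value
comes from the exact null distribution, computed by convolving the doubled
(hence integer) ranks — exact even with ties.  Beyond 25 pairs a
tie-corrected normal approximation with continuity correction is used; the
two agree within 0.01 for n between 20 and 25.

**Percentiles** use linear interpolation between closest ranks (the numpy
`linear` convention), so the 10th percentile of 1..100 is 10.9.

**Significance stars** follow the three-symbol scheme * p<0.05, ** p<0.01,
*** p<0.001, computed from robust (OLS), model-based (GLM) or bootstrap
(CLAD) standard errors with a normal reference.

**Rescaling convention.**  Scores are rescaled by their own maxima
(PWB/SWB/FWB /28, EWB /24, global /108, ×100).  Whether the published
crosswalk coefficients were estimated on rescaled or raw scores is ambiguous
in their source (back-substituting the printed GLM constants favours raw
units for the global score), so both conventions are implemented everywhere
and `crosswalk_predict` refuses to guess: callers must pass
`convention="rescaled"` or `"raw"` explicitly.

**FACT-G scoring** follows FACIT v4 guidance: reversed items (all PWB; all
EWB except GE2) contribute 4 − response; a domain is prorated by
items/answered and valid only when strictly more than half its items were
answered; the global score requires all four domains valid and ≥ 80% of all
27 items answered.  The instrument's published tables do not state these
thresholds or the polarity map, so both are packaged, overridable defaults.

## The synthetic cohort generator

No patient-level dataset accompanies the original analysis, so
`utilmap.cohort` generates cohorts reproducing its printed marginal
structure.  What is calibrated:

* **Utility margins**: each utility is a normal latent censored at 1.  Given
  a target observed mean m and ceiling fraction f, the ceiling condition
  fixes α = (1−μ)/σ = Φ⁻¹(1−f), which makes the censored-mean identity
  E[min(Y,1)] = μΦ(α) − σφ(α) + 1 − Φ(α) linear in σ; the solver is closed
  form and verifies both residuals < 1e-10.  The EQ-5D targets (m = 0.82,
  f = 0.234) give (μ, σ) ≈ (0.8485, 0.2087); the SF-6D targets (0.71,
  0.0137) give (0.7107, 0.1312).  The targets over-determine a two-parameter
  family: mean and ceiling are matched, and the implied SD (≈ 0.17 for the
  EQ-5D vs 0.14 printed) is a documented diagnostic — real utilities are not
  censored-normal.
* **Rank correlations**: a Gaussian copula links the FACT-G factor and the
  two utility latents.  Latent Pearson correlations come from the
  bivariate-normal identity ρ_s = (6/π)·asin(r/2), i.e. r = 2 sin(πρ_s/6):
  targets 0.649 and 0.714 give r ≈ 0.6667 and 0.7304.  Correlations are
  calibrated on the *latent* scale; the observed (post-censoring) Spearman
  is attenuated by the ties at the ceiling (by roughly 0.01–0.02 for the
  EQ-5D), which is accepted and reported, not re-calibrated.  The
  EQ-5D–SF-6D latent correlation is not published; 0.70 is used as a typical
  value from the mapping literature.
* **FACT-G domain scores** come from a one-factor model: each domain latent
  loads 0.8 on the common factor around means proportional to the global
  target (78.87·domain-max/108) with idiosyncratic noise scaled so the
  global-score SD hits 15.47; scores are rounded and clipped to their
  ranges, and the global score is their exact sum.  The factor structure
  gives Model-2 designs genuine inter-domain variation; the attenuation it
  induces between the copula coordinate and the summed global score is
  compensated analytically so cohort-level latent correlations still hit the
  published targets.  Rounding and clipping shrink the realised global mean
  by ≈ 0.5 points — a known, accepted bias.
* **Item responses** are synthesised to reproduce each domain score exactly
  under the packaged polarity map (integer spreading with seeded
  redistribution), so scoring the generated items recovers the generated
  scores bit-for-bit.  Generation can be disabled
  (`generate_items=False`) for large calibration-only draws.
* **Demographics** follow the published margins: 67% female, age
  ~N(58.7, 11.5²) truncated at 18, site 38/31/31% breast/colorectal/lung,
  stage 11/15/24/50% and ECOG 35/50/11/3% of the *observed* counts.  Stage
  and ECOG are missing for 9/367 and 16/367 patients respectively (and
  EQ-5D/SF-6D for 4 and 3), which is what shrinks covariate-adjusted model
  Ns under listwise deletion.
* **Severity coupling** (invented — the source only shows severity gradients
  graphically): stage and ECOG are assigned by an ordered-probit on the
  negative health factor with coupling strength 0.5 by default, so mean
  utilities decline with stage and ECOG.  Setting the strength to 0 makes
  demographics independent of health.
* An optional **effect structure** replaces the copula utilities with a known
  linear (or censored-linear) map from rescaled scores plus symmetric
  normal/Laplace noise — the harness for parameter-recovery experiments.

What the generator does **not** emulate: EQ-5D/SF-6D level profiles (tariff
evaluation is generic but utilities are generated directly), the exact
shapes of the real score distributions beyond first moments and ceiling
mass, item-level response psychology (items are an exact decomposition of
the domain score, not psychometrically realistic), and any longitudinal
structure.  Tests passing on synthetic cohorts therefore demonstrate the
*estimators and pipeline* are correct under the study's statistical
structure, not that the published coefficient values are recoverable — those
depend on undeposited patient data and are shipped verbatim in the crosswalk
module instead.

## Problem sizes used in the test battery

Parameter recovery uses cohorts of n = 2000 with 200 Monte-Carlo
replicates (median coefficient bias < 0.005 without censoring; with ~25%
ceiling mass, the CLAD slope bias is required to be smaller than the OLS
slope bias).  Generator calibration is checked at n = 10⁶.  The full
pipeline-shape run uses a 367-patient cohort, a 184/183 split and B = 200
bootstrap replicates.

## Known limitations

* Spec-3 (covariate-adjusted) crosswalks are incomplete: the published table
  omits the estimated age and sex coefficients, so those crosswalks demand an
  explicit `allow_incomplete=True` acknowledgement and are flagged in their
  output.
* CLAD standard errors depend on the bootstrap seed; only the point
  estimates are deterministic given the data.
* The censored-normal margin cannot match mean, SD and ceiling
  simultaneously (two parameters, three targets); SD is the sacrificed
  moment.
* The Gamma-family GLM requires strictly positive utilities and therefore
  cannot be used when states worse than dead (u ≤ 0) occur.
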