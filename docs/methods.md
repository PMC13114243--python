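# Methods

This note documents the statistical procedures implemented in `sparsepk`,
the defaults they use, and the limits of what the synthetic-study tests can
show.  It records design choices in the places where the methodology was
genuinely open.

## Study structure and data model

The package assumes a destructive (sparse) sampling design: every animal
contributes exactly one plasma sample, ~3 animals per nominal timepoint, with
separate arms per analyte and route (IV or SQ bolus).  A `StudyArm` enforces
one-sample-per-animal; a `Profile` is the composite concentration-time curve,
either raw (replicate points at shared times) or pooled per timepoint.
Pooling uses exact nominal-time equality: actual draw times are generally not
recorded in such studies, so times are the scheduled ones.  Raw observed
concentrations are never modified; the sample `status`
(`observed / blq / imputed / dropped_blq / excluded_outlier`) is the only
mutable annotation, which keeps every preprocessing decision auditable.

## BLQ handling (Beal M6)

Censored samples are handled by the M6 rule: at the earliest post-peak
timepoint containing below-LLOQ samples, each censored sample is imputed at
LLOQ/2; censored samples at later timepoints are dropped.  "First" is
interpreted at the timepoint level because a per-animal "first BLQ" is
undefined when each animal has a single sample; a strict per-sample mode
(`mode="per_sample"`) imputes only the chronologically first censored sample
for sensitivity analysis.  Pre-peak censored samples (possible on
extravascular arms) are dropped, never imputed.

Imputed values participate in NCA, where they close the AUC tail, but are
**excluded from maximum-likelihood model fitting by default**
(`include_imputed=True` restores the strict M6 dataset).  Rationale: when the
true curve has decayed far below the assay limit, the LLOQ/2 value sits
orders of magnitude above the model prediction at that time; under a
log-scale error model that single point dominates the likelihood and drags
the terminal rate low.  For the built-in MPA truth (beta = 0.65 /h, LLOQ
0.500 ng/mL) the model value at 18 h is ~0.004 ng/mL, 4-5 log-sigma below the
0.25 ng/mL imputed value; including it pulls the fitted beta to ~0.24 /h. The
half-life flattening that the imputed point causes in the lambda_z regression
is, conversely, left in place for NCA, since that is how composite NCA on M6
data behaves.

## Outlier screening

Each timepoint with at least three eligible samples is screened with the
classic two-sided single-outlier Grubbs test (default alpha = 0.05),
one pass, at most one exclusion per timepoint; iterative re-testing is
disabled to avoid masking artifacts.  Post-peak groups are screened on log
concentrations (decaying concentrations are right-skewed on the raw scale);
`scale="linear"` is available.  A caveat worth knowing: with n = 3 the
largest attainable Grubbs statistic (1.1547) barely exceeds the alpha = 0.05
critical value (1.1543), so the test has almost no power at triplicate
timepoints unless the two clean values nearly coincide.  Tests of the
screening therefore use a four-animal timepoint for the contaminated case.

## Noncompartmental analysis

* **lambda_z** - ordinary least squares of ln C on t.  `best_fit` scans every
  suffix window of >= 3 distinct post-peak times (the Cmax point excluded)
  and keeps the highest adjusted R^2 among negative-slope windows, ties going
  to the longer window; a manual time window overrides.  The regression can
  run on raw replicate points or on the pooled curve (`pool=` option) - the
  published composite half-lives depend on this choice, which is why both
  are exposed.
* **AUC** - linear-up/log-down trapezoids: rising or non-positive segments
  use the linear rule, strictly declining positive segments the log rule
  (exact for mono-exponential decay through the two points).  Partial AUC
  truncates at an interpolated cutoff.  IV profiles are anchored at
  (0, C0) with C0 from log-linear back-extrapolation through the first two
  points; extravascular profiles at (0, 0).
* **AUC0-inf** - AUC_last + C_last/lambda_z with percent extrapolated
  100 x tail/AUC0-inf; C_last is the last eligible (possibly imputed) pooled
  concentration.
* **Bioavailability** - 100 x dose-normalized extravascular AUC0-inf over
  its IV counterpart; dose normalization divides by dose in ng (ug x 1000).
* Summary statistics (Cmax, Tmax, AUC) are computed on the pooled per-time
  profile (mean by default, median available): with one sample per animal
  these are summary, not per-animal, quantities.

## Macroconstant fitting

Naive-pooled maximum likelihood of C(t) = sum A_i exp(-lambda_i t).  With one
sample per animal, between-animal random effects are unidentifiable, so all
samples enter a single residual likelihood; the fixed effects alone define
the UIR, which is the quantity of interest.  Error models: additive,
log-additive (full lognormal density, so -2LL values are comparable across
models), and power with variance sigma^2 f^(2 gamma); gamma defaults to 1
(proportional) and is held fixed.

Numerics:

* Unconstrained parameterization: log coefficients, log slowest rate, log
  gaps between successive rates - positivity and strict rate ordering hold
  by construction.
* sigma is profiled out in closed form at every structural evaluation; the
  profiled variance is floored (1e-10 of the RMS signal) so a perfect
  noise-free fit has a finite, well-defined optimum.
* Initial estimates by curve stripping: the best-adjusted-R^2 terminal
  window gives the slowest term (exp(intercept), -slope); its contribution
  is subtracted from the pre-window points and the residual curve stripped
  recursively.  Residuals are floored at 1% of the observed value before
  logging, and if fewer than two early times carry meaningful residual the
  earliest floored points are retained - the sparse design often has exactly
  one timepoint inside the fast phase.  A heuristic fallback start (fast
  rate ln(20)/t_second) covers data the stripper deems non-identifiable.
* Multi-start Nelder-Mead (default 10 starts: stripped and heuristic inits,
  deterministic sweeps along the fast-phase ridge, seeded jitter), best
  objective kept, then a tight simplex polish and a BFGS step retained only
  if it improves the objective.
* **Identifiability cap**: the fastest rate is bounded at 5/t_min (t_min =
  earliest positive sampling time).  A phase decaying faster than that has
  vanished by the first sample; the likelihood is flat beyond the bound, and
  without it bootstrap refits wander to arbitrarily large (A, alpha) along
  the ridge.
* CV% from the observed information: finite-difference Hessian of the full
  -2LL (structural parameters plus log sigma), inverted and mapped to the
  natural scale by the delta method.  Condition number is the singular-value
  ratio of the correlation-scaled Hessian; fits with any CV% > 50% or
  condition number > 1000 are flagged in model selection, which otherwise
  ranks converged candidates by AIC (= -2LL + 2p), ties to fewer parameters.

### What the sparse design can and cannot identify

On the built-in 8-timepoint schedule the fast phase of the CAB-like truth is
informed essentially by the single 0.08 h timepoint (by 1 h the fast term is
<1% of the signal).  A and alpha are then identified only through the product
A exp(-0.08 alpha), and their naive-pooled MLEs are ridge-distributed with
heavy tails: across replicate simulated studies at 10% proportional noise,
median B and beta recover within ~1%, while median A and alpha can sit tens
of percent or more from truth and vary strongly between seed sets.  This is a
property of the estimator-design pair, not of the optimizer (exhaustive
profile-likelihood searches find the same optima), and it is consistent with
the wide reported bootstrap interval for A in this kind of study.
Mixed-effects estimators with shrinkage regularize this ridge; they are
deliberately out of scope here because the sparse one-sample-per-animal data
cannot inform interindividual variability.  Downstream UIR uses are mostly
insensitive: the ridge preserves the early-time product and the slow phase
dominates exposure.

## Validation

* **Bootstrap** (default 250 resamples): animals resampled with replacement
  within timepoint strata (preserving the information content of the
  destructive design; unstratified resampling available), refit from the
  reference estimates with a single start, percentile 95% CIs over
  successful refits; > 50% refit failure aborts with diagnostics.
* **VPC** (default 250 simulated datasets): replicate studies at the
  observed design from the fitted fixed effects and residual model, LLOQ
  censoring plus M6 applied exactly as for observed data (a no-censoring
  mode exists), and per-timepoint 5th/50th/95th percentile bands.
* **GOF**: observed vs predicted and standardized residuals on the fit's own
  scale - (y-f)/sigma, (ln y - ln f)/sigma, or (y-f)/(sigma f^gamma) - with
  a running-mean smoother for plotting.  These are naive-pooled standardized
  residuals, not FOCE-style conditional weighted residuals.

## UIR and deconvolution

`uir_from_fit` divides fitted coefficients by the dose in ng.  Convolution
with a staircase input rate is evaluated in exact closed form (per term and
interval), and first-order subcutaneous input has its own closed form
(rejected when ka collides with a disposition rate rather than silently
switching to the degenerate t exp(-lambda t) solution).  Deconvolution
estimates non-negative staircase rates on knots (default: 0 plus observation
times) by NNLS against the exact forward model; a log-scale objective
refines the NNLS solution by bounded least squares.  No smoothing or
regularization is applied by default - the transparent baseline - and the
condition number of the convolution matrix is reported with a warning when
it exceeds 1e8.  Cumulative absorption is non-decreasing by construction;
the residual amount is F x dose - cumulative when a bioavailability F is
supplied ("absorbed" = reached systemic circulation), otherwise
dose - cumulative.

## Synthetic studies

`default_truth` encodes biexponential mouse disposition truths for a
cabotegravir-like analyte (A = 16,621 ng/mL, alpha = 4.52 /h, B = 30,206
ng/mL, beta = 0.053 /h at 66 ug IV; LLOQ 25.0 ng/mL) and a
medroxyprogesterone-acetate-like analyte (A = 2,506, alpha = 10.5, B = 439,
beta = 0.65 at 65 ug IV; LLOQ 0.500 ng/mL), stored dose-normalized.  IV arms
sample 0.08, 1, 3, 6, 8, 18, 24, 30 h with 3 animals per timepoint; SQ arms
extend the grid (to 72 h and 720 h respectively) and use first-order
absorption with bioavailability 0.61 (CAB-like, ka = 0.3 /h, giving a
nominal-grid Tmax of 6 h) and 0.42 (MPA-like, ka = 1.0 /h, nominal-grid Tmax
1 h).  Residual-error magnitudes are not reported for such studies, so the
defaults were fixed once at sigma = 0.15 (power, gamma = 1, for the CAB-like
truth; log-additive for the MPA-like truth), the scale of the +/-15%
bioanalytical acceptance window; negative draws under additive/power error
are redrawn because assay concentrations are non-negative (disable with
`truncate_negative=False`).  By default the generator has **no
between-animal random effect** - the analyses assume none is identifiable -
but an optional lognormal animal-level multiplier
(`animal_variability_cv`) exists for robustness testing.

What the generator does *not* emulate: real between-animal variability,
actual (vs nominal) draw times, assay heteroscedasticity beyond the chosen
error model, and correlated analytical drift.  Green simulation tests
therefore demonstrate the internal consistency of the chain (estimators
recover their own generative truths at the study design), not the field
accuracy of any specific animal study.

## Problem sizes in the test suite

The simulation suites use 100 replicate studies for parameter-recovery
medians, structure selection, and VPC coverage, 250 bootstrap resamples and
250 VPC simulations where those operations are exercised at their default
sizes, and 20-replicate versions in unit tests; these sizes give stable
medians/rates while keeping the suite quick on a single CPU.
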