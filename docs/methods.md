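# Methods

## Model

Positive-node counts in truly node-positive patients follow a
beta-binomial law: given *n* examined nodes, *k* | *p* ~ Binomial(*n*,
*p*) with *p* ~ Beta(α, β) integrated out analytically.  The model
assumes (i) no false-positive nodes, (ii) exchangeable nodes — every node
of a patient is equally likely to harbor metastasis, and (iii) equally
sensitive examination of every node.  These assumptions are knowingly
idealized: in PTC the central compartment is involved more often than
lateral or mediastinal basins, and the package deliberately does not model
per-basin heterogeneity or covariate-dependent shapes.

The derived quantities:

* false-negative staging probability
  p₀(n) = B(α, β + n)/B(α, β) = ∏ᵢ₌₀ⁿ⁻¹ (β + i)/(α + β + i),
  strictly decreasing in *n*, p₀(0) = 1;
* corrected stratum prevalence π̂ = #observed-positive / Σᵢ (1 − p₀(nᵢ)),
  the solution of the unbiased moment equation
  E[#positive] = π Σᵢ (1 − p₀(nᵢ)), with the sum over all patients of the
  stratum.  It always revises the observed prevalence upward and is
  clipped at 1 (with a warning) when sampling noise pushes the moment
  estimator above 1, which happens occasionally in small high-prevalence
  strata.  An EM formulation would give the full-likelihood analogue; the
  moment form was chosen because it is closed-form, unbiased at the score
  level, and reproduces the published adjusted incidences' direction and
  magnitude;
* nodal staging score NSS(n) = (1 − π)/((1 − π) + π p₀(n)), the posterior
  probability of true node-negativity given *n* examined all-negative
  nodes; NSS(0) = 1 − π;
* nodes-needed: the smallest n ≥ 1 with NSS(n) ≥ t, scanned up to
  `n_max` (default 100); unreachable thresholds render as an em-dash.

The prevalence-correction estimator assumes examined-node count carries no
information about the latent nodal status.  If dissections are more
extensive precisely in patients who truly harbor metastases, the moment
estimator overstates π; the synthetic generator exposes this as a
sensitivity knob (status-keyed node-count laws) but defaults to a single
shared law.

## Fitting

The shapes are estimated on node-positive patients only, so each patient
contributes log P(k | n) − log(1 − p₀(n)) — the zero-truncated
log-likelihood.  Patients with n = 1 carry no information after
truncation (P(k=1 | k≥1, n=1) = 1 identically), so a fitting set composed
entirely of such records is rejected as non-identifiable rather than
returning an arbitrary value.

Numerics: all pmf evaluation in log space via log-gamma; 1 − p₀ through
`log1p`/`expm1` with a complementary branch when p₀ > 0.99; duplicate
(k, n) pairs aggregated with frequency weights.  Optimization is
quasi-Newton (L-BFGS-B) on (log α, log β) within |log shape| ≤ 12 — wide
enough to be effectively unconstrained for data with any signal — from
three starts: method-of-moments on k/n, (1, 1), and an overdispersed
fallback (2, 0.5); gradient tolerance 1e-8.  Non-finite objective probes
(extreme shapes where 1 − p₀ underflows) return a large penalty.  A
maximizer within 1e-3 of the log-bound is flagged `converged=False` with
a warning — the degenerate all-nodes-positive case lands here by design
instead of crashing.  Standard errors come from a central-difference
observed-information matrix in log space, delta-transformed to (α, β).

## Synthetic cohort generator

The generator emulates the structure of a registry PTC cohort
(N = 12,431 by default) with ground-truth occult labels that real
pathology data cannot provide:

1. latent true nodal status ~ Bernoulli(π̄), π̄ ≈ 0.589 — the mean over
   factors of the frequency-weighted adjusted incidences;
2. six factor levels drawn conditionally on that status by Bayes
   inversion of the configured marginal frequencies and per-level
   adjusted incidences (defaults: the published values).  This
   latent-class construction matches every factor's marginal prevalence
   to within ~0.015 while keeping factors conditionally independent given
   status.  Real cohorts have richer factor dependence (e.g. T stage and
   tumor size are logically linked); the generator makes no attempt to
   reproduce the joint covariate law;
3. examined-node count from a zero-truncated negative binomial
   (untruncated mean 3.0, dispersion 0.5 → median 3, IQR 1–6, ~1% of
   counts above 25), drawn independently of the latent status — see the
   estimator assumption above.  Observed LN+ patients nevertheless show
   higher node counts, because detection conditions on k ≥ 1;
4. positive nodes: beta-binomial(n, α, β) for truly positive patients —
   a draw of k = 0 *is* an occult false negative — and 0 otherwise
   (α = 1.51, β = 1.15 by default);
5. survival: exponential with baseline hazard 0.002/month, hazard ratio
   2.0 for truly node-positive status, censoring uniform on (0, 120)
   months;
6. tumor size set to an explicit missing category for 6.9% of patients;
   missing-size patients are excluded from size-stratified estimates.

Everything is reproducible from the config seed.  What passing tests on
this generator do **not** show: robustness to per-basin heterogeneity,
to covariate-dependent dissection extent, to non-exponential hazards, or
to the real joint covariate distribution.

## Survival comparison

Per-patient scores use the patient's factor-level NSS curve at the
patient's own examined-node count.  The default comparison scores
pathologically node-negative (pN0) patients only — the population the
score is defined for; among them 1 − NSS(n) is exactly the per-patient
occult-metastasis probability, so the quartile gradient in survival is
the quantity of interest.  Including observed LN+ patients (whose latent
status is known, making their curve value uninformative) is available as
a switch.  The default stratification factor is T stage, the factor with
the widest corrected-prevalence contrast (0.424–0.957) and hence the most
informative score spread; any of the six factors can be selected.

Quartile cut points are the empirical 25/50/75 percentiles with ties
assigned to the lower group; with heavily discrete scores the four groups
are unequal — sizes are reported, not hidden.  Fewer than four distinct
scores is an explicit error.

Kaplan–Meier and the k-sample log-rank test are implemented directly:
at each distinct event time the per-group events are compared with their
hypergeometric expectation given the risk sets; the statistic is the
quadratic form of the summed O − E vector in its estimated covariance
(first k − 1 groups, pseudo-inverse for safety), referred to χ² with
k − 1 degrees of freedom.  Risk sets of size ≤ 1 contribute nothing.
The implementation is cross-checked against lifelines in the test suite;
lifelines is never used in the pipeline itself.

## Table formatting

Percentages are rounded half-up to one decimal (matching the published
tables); the machine-readable long-format output always carries the
unrounded values.  Unreachable nodes-needed cells print an em-dash.

## Problem sizes in the test suite

The suite works at the scales the analysis itself uses: full-size
synthetic cohorts of 12,431 patients for end-to-end recovery and the
survival power check (60 seeds), 50 replicates of 5,000 node-positive
patients for refitting bias, 200,000 patients for the Bayes-consistency
check of the score, and 200 replicates for log-rank null calibration.

## Known limitations

* The printed source tables are internally inconsistent at the 0.1–0.2
  level in a handful of cells (and up to a few points in extreme strata);
  the package follows the formulas and the printed inputs, and asserts
  only cells that an exact-arithmetic oracle reproduces.
* The moment prevalence correction is a documented choice; the original
  adjustment formula behind the published incidences is unstated.
* No confidence intervals on NSS, no recurrence prediction, no Cox
  modelling, no per-basin compartment modelling.
* The 4-group log-rank power under the default survival fixture sits
  near 95%; with other stratification factors (smaller prevalence
  contrasts) it is materially lower.
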