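# Methods

## Problem and scope

Statins lower LDL cholesterol, but in routine primary care many patients
take them irregularly. Two quantities organise the analysis this package
implements:

- **Adherence** as *proportion of days covered*,
  `PDC = 100 × (tablets prescribed in a study window) / (window length in
  days)`, assuming a one-tablet-per-day regimen. Values above 100% are
  retained (multi-tablet regimens are real); values above 200% are treated
  as data errors and excluded.
- **Response** as the LDL change ratio `Y = LDL1/LDL0` for the first
  on-treatment measure, and the fractional reduction
  `LR_k = (LDL_k − LDL_0)/LDL_0` at follow-up visit k = 1..K for the
  longitudinal analysis (negative = reduction; `Y = 1 + LR_1`
  identically).

The causal question is what sustained adherence would do to LDL-c
reduction over several years. This is a sequential-exposure problem with
time-varying confounding: past LDL response influences future adherence
(patients who respond stay engaged), and past adherence influences future
response, so naive regression of LR on the PDC history suffers
post-treatment bias. The package estimates a marginal structural model by
inverse-probability-of-treatment weighting with covariate-balancing
weights, on synthetic cohorts with known ground truth (the real
primary-care linkage data this design mirrors is access-controlled).

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
every downstream claim is evaluated under.

**Fixed confounders.** Age at first statin ~ Normal(61, 7.3) truncated to
[40, 79]; female with probability 0.423; baseline LDL-c
LDL_0 ~ Normal(3.8, 1.05) mmol/L truncated to [1, 8]; six education
categories at frequencies (0.287, 0.029, 0.124, 0.173, 0.146, 0.241); six
assessment centres; a biallelic genotype dose (MAF 0.15) and a prevalent
cardiovascular disease indicator (probability 0.23). These marginals match
descriptive statistics of UK primary-care statin initiators.

**Structural equations.** With LR_0 = 0, for k = 1..K (default K = 3):

    PDC_k = clip( c_p + x'γ_p + φ·LR_{k−1} + ε_pk , 0, 150 )
    LR_k  = β_k·PDC_k + ρ·LR_{k−1} + x'γ_l + c_l + ε_lk

with defaults c_p = 88, φ (feedback) = −30 %/LR-unit, ε_pk ~ N(0, 15²),
β = (−0.0020, −0.0005, −0.0010) LR-units per PDC percentage point,
ρ (carry-over) = 0.4, c_l = −0.15, ε_lk ~ N(0, 0.08²). The PDC-channel
confounder coefficients γ_p follow observational gradients (age 0.34/year,
female +0.64, baseline LDL 0.55 per mmol/L, a rising education gradient up
to +2.52 for degree holders); the LR-channel coefficients γ_l are small
plausible values (e.g. −0.015 per mmol/L baseline LDL) whose purpose is to
make fixed confounding material. The feedback sign means a deeper past
reduction raises future adherence; at the defaults the unweighted
correlation between PDC_2 and LR_1 is ≈ −0.2, so time-varying confounding
is far from negligible.

A linear-Gaussian system was chosen deliberately: it is the minimal
structure with all the arrows the weighting method must handle, and it
makes the true *total* effect of PDC_j on LR_k under a joint intervention
analytically known, namely `β_j · ρ^(k−j)` (a joint intervention severs
the feedback path). The direct effects sum to −0.35 per 100 PDC points
(`Σβ_k·100 = −35`), a calibration chosen so the magnitude of full
adherence effects is of the order reported for statin therapy; with
ρ = 0.4 the implied all-100-vs-all-0 contrast at k = 3 is
`100·(β_1ρ² + β_2ρ + β_3) = −0.152`, i.e. a 15-percentage-point LDL
difference — carry-over means the contrast and the direct-effect sum are
different quantities.

**Visit times.** Inter-visit gaps are Uniform(240, 490) days, so the mean
time from initiation to the third follow-up measure is 3.0 years (the
calibration target); the baseline measure falls uniformly within 60 days
before the first prescription. Dates are integer day offsets from the
first prescription (day 0).

**Prescription rendering.** Interval PDCs are inverted into a realistic
script stream: within each inter-visit window the total tablet count is
`round(PDC/100 × window length)`, issued as 28-tablet scripts at spacing
`28/(PDC/100)` days plus one remainder script, with optional Gaussian
date jitter (default SD 2 days; the first script stays at day 0 because it
defines the index date). The remainder script keeps the quantisation error
below half a tablet per window, so the PDC engine recovers the latent
value well within ±2 percentage points at zero jitter even at PDC = 10.
Non-zero jitter moves scripts across window boundaries, making recomputed
interval PDCs a noisy measure of the latent exposure; this is deliberate
realism, and it produces the expected classical measurement-error
attenuation (a few percent) in estimates obtained through the raw-table
path, absent from the latent-panel studies.

**Plausibility clamp.** Emitted follow-up LDL values are clamped to
[1.005, 7.995] mmol/L so the base cohort contains no accidental
validity-filter hits and planted violations reconcile exactly with filter
reports. The latent truth table keeps the unclamped LR. The clamp binds
for a small fraction of low-baseline patients and is one reason the
raw-table pipeline is checked at a looser tolerance than the latent-panel
Monte-Carlo studies.

**Violation planting.** `plant_violations` injects exact counts of four
violation classes (first-year PDC driven above 200% by duplicate same-day
scripts, follow-up measures set to 0.5 mmol/L, death at day 45,
cardiovascular discharge at day −30) into disjoint randomly chosen
patients and returns a ledger; filter reports are tested against the
ledger for equality, not approximation.

**What the generator does not emulate.** Dose titration and switching,
stockpiling behaviour, missed-visit informative censoring, measurement
batch effects, non-linear or interaction effects of adherence, and
genotype effects on response (the genotype column is plumbing for the
cross-sectional model). Passing tests therefore demonstrate that the
estimator recovers known effects under the assumed linear additive
structure with observed confounders — the same assumption the method makes
on real data — not that the assumption holds in any particular cohort.

## PDC engine

PDC is a pure ratio over a half-open integer-day window `[start, end)`; a
script issued on a visit day belongs to the next window. No stockpiling or
day-level coverage walk is modelled — the printed formula is a ratio, and
that is what is computed (verified against an explicit per-day tablet
tally oracle).

First-year adherence PDC_1 handles the window edge: if any prescription
exists at day ≥ 365 the window extends to the first such script (the time
to the next supply is observed coverage); if the final script predates day
365 with no successor its supply is unobserved, so its tablets are dropped
and the window ends at its issue date (flagged). A patient whose only
script is that trailing one has no observable coverage and PDC_1 is
missing. Categories are `<50`, `[50, 95]`, `>95` — the middle band closed
on both ends so the three bands partition the line. "Three months" is
operationalised as 90 days throughout (death exclusion, post-discharge
rule).

## Trajectory builder

Measure-level validity filters run *before* baseline/follow-up selection
(an extreme value must not be selected as baseline and then discarded
patient-and-all): individual measures outside (1, 8) mmol/L are dropped
(bounds exclusive — exactly 1.0 or 8.0 survives). Patients first
prescribed a statin within 90 days after a cardiovascular hospital
discharge are removed entirely (the stricter patient-level reading;
measure-level removal is available by argument). Baseline is the measure
closest to and at most 180 days before the first prescription; a same-day
measure counts as pre-treatment, and same-day duplicates are averaged and
flagged. Follow-up selection: earliest measure within 365 days (year-1
mode) or the first three post-statin measures within 3652 days
(longitudinal mode; fewer than three drops the patient).

## Weighting estimator

**Stage 1 — stabilized density-ratio weights.** For each k the exposure
PDC_k given the fixed confounders, lagged PDC/LR, and the visit time is
modelled as Gaussian-linear; the numerator is the Gaussian law of PDC_k
given past exposures only. The patient weight is the product over k of
numerator/denominator densities, normalised to mean 1. Degenerate fits
(n too small, zero residual variance) fall back to unit weights for that
time point, so a single-patient input yields w = 1.

**Stage 2 — balance calibration.** The stabilized weights are
exponentially tilted: with moment matrix G containing every standardized
exposure, every standardized covariate, and all exposure×covariate
cross-products (fixed confounders against every k; lagged LR, lagged PDC
and visit time against their own k), the tilt solves
`min_δ log Σ_i w_i exp(g_i'δ)` by damped Newton iterations with
backtracking. At the optimum the tilted weights zero every weighted
exposure–covariate covariance *exactly* (typically to ~1e-9 in four to
five Newton steps at n = 5000). This is the covariate-balancing
construction for continuous sequential treatments: the density-ratio
weights supply consistency under the (true, up to clipping)
Gaussian-linear exposure law, the calibration removes finite-sample
imbalance and is what the balance diagnostic actually certifies. The
non-parametric variant (`npcbps_fallback`) applies the same tilt to
uniform base weights, dropping the parametric density; `stabilized_ipw`
skips the tilt. If the Newton solve fails the estimator falls back to
plain stabilized weights and records a warning in the weight set's
provenance. Truncation is off by default; optional percentile truncation
is applied last and recorded.

**Balance diagnostic.** Weighted Pearson and weighted Spearman
(rank-then-weighted-Pearson) correlations for every (exposure k,
covariate) pair; a covariate passes when the average of |r| across time
points and both correlation families is below 0.1. Zero-variance
covariates are reported as `n/a` — never as balanced. Covariates that fail
are forced into the stage-2 regressions (lagged exposures are skipped
there because they already appear as regressors).

**Stage 2 regressions and uncertainty.** For each k, weighted OLS of LR_k
on an intercept, PDC_1..PDC_k, and any forced covariates. The coefficient
array is lower-triangular; the k-diagonal entry is the direct effect of
the contemporaneous PDC, off-diagonal entries are total effects through
intermediate reductions. Confidence intervals come from a nonparametric
patient-level bootstrap in which the weights are re-estimated inside every
replicate (warm-started from the full-sample tilt solution), because the
weights are estimated quantities whose variability must propagate. The
API default is 500 replicates with percentile intervals; the Monte-Carlo
studies use 50 replicates with normal-interval CIs (point ± 1.96 × bootstrap
SD), which is accurate for this nearly-Gaussian estimator and keeps
repeated-simulation studies tractable. With zero bootstrap replicates,
analytic HC0 WLS intervals are reported instead.

**Contrasts.** `intervention_contrast` evaluates
`Σ_j b_{k,j}(a_j − b_j)` for two PDC profiles (so all-100 vs all-0 at
k = 3 is `100·Σ_j b_{3,j}`), exactly additive in profiles by
construction; `personal_max_contrast` holds each patient at their own
maximum observed interval PDC and averages the final-time-point contrast
over the cohort. Both propagate the bootstrap coefficient draws through
the same linear form.

**Interpretation choices.** Weights are cumulative products across time
points (standard marginal-structural-model practice), not per-k
cross-sectional weights. Stage-2 fits and their CIs are per time point;
the cumulative contrast CI is propagated from the per-k bootstrap draws.

## Cross-sectional response model

Y = LDL1/LDL0 is regressed on time-to-follow-up in days with a quadratic
term, optionally a group factor (PDC_1 category or additively-coded
genotype dose) with group×time and group×time² interactions, plus fixed
adjustment covariates. A convex fit (positive quadratic coefficient)
yields the week of maximal reduction at the vertex `−b_t/(2 b_t²)`, with a
parametric-bootstrap CI from the coefficient covariance; a non-positive
quadratic coefficient, or a vertex outside the observed follow-up window
(the numerically-degenerate case), is reported as a boundary diagnosis
rather than an extremum. Group summaries are raw means of Y per one-week
bin with `reduction% = 100·(1 − mean Y)`; model curves are a separate
overlay, not mixed into the bins.

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng`; simulation
  configs carry their seed and identical (config, seed) pairs produce
  byte-identical tables (verified by hashing). Monte-Carlo studies spawn
  per-replicate seeds from a single `SeedSequence`.
- Monte-Carlo study sizes: recovery and balance studies run 200 replicates
  at n = 5000 with a 50-draw bootstrap per replicate; the zero-confounding
  agreement study runs 200 replicates at n = 2000; the acceptance script
  uses 100 recovery replicates. These sizes give Monte-Carlo standard
  errors an order of magnitude below the effects being checked.
- The recovery studies consume the latent panel (interval PDCs and LRs as
  generated) — the exact quantities the estimator would receive after the
  table stages, whose own fidelity (rendering → PDC engine → trajectories)
  is covered by exact round-trip and end-to-end tests with day-rounding
  tolerances.
- Bias is judged against the Monte-Carlo SD of the estimator (bias below
  half an SD is immaterial for inference at this scale); coverage of the
  95% bootstrap CI is required to land in [90%, 99%].
- Collinear confounder matrices are rejected up front with the offending
  columns named; bootstrap replicates that fail (singular resample) are
  dropped and counted in the estimate's provenance.

## Known limitations

- The estimator assumes all confounders are observed — true in the
  simulator by construction, untestable on real data; nothing here
  addresses unmeasured confounding.
- The Gaussian-linear exposure model is correct for the simulator up to
  the [0, 150] clipping; heavy-tailed or strongly non-linear real exposure
  processes would lean entirely on the balance calibration.
- PDC measures prescription supply, not ingestion; the package inherits
  that interpretation gap.
- Censoring weights are out of scope: the longitudinal analysis
  conditions on patients having three measures, as does the design it
  implements.
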