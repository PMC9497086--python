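# Methods

This note records the statistical model behind each module, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
cohorts do and do not establish about real data.

## Scoring

**Percentiles.** A density d is mapped against a sorted reference vector R
by the mid-rank rule `100 · (#{R < d} + ½·#{R = d}) / |R|`. The convention
is symmetric (a reference value scored against its own vector averages to
50), deterministic, bounded in [0, 100], and monotone non-decreasing in d.
Alternatives (strict-rank, Hazen plotting positions) differ only at ties
and reference endpoints; mid-rank was fixed once because the consensus
assay's exact convention is not published.

**Categories.** The mean of the four channel percentiles is binned with
lower bins closed on the right at each cut-point: two categories at 25;
three at 25/70; five at 10/25/70/95. This reading follows the printed
interval notation (`0–25` vs `>25–70`), under which 25 → Lo/I1, 70 → Int/I2
and 95 → I3. The three schemes nest exactly: {I0,I1} = Lo, {I2} = Int,
{I3,I4} = Hi, and two-category Lo coincides with three-category Lo. A test
sweeps the whole grid 0.00–100.00 in steps of 0.01 to verify this.

**Reference distribution.** The assay's training reference is proprietary,
so the reference is an explicit input (`reference.csv`); a cohort may also
be scored against itself. Which choice a real validation made matters for
the category split — see the generator's reference shift below.

**Quality control.** A measurement is excluded iff any of: either tumor
region unavailable; staining intensity ≤ 152 AU (the threshold is
instrument-specific and therefore configurable); a damaged-slide flag
(always an input, never inferred); more than 3 failed antigen-retrieval
attempts. Exactly one reason is recorded per exclusion, in that fixed
priority order, so QC reports are deterministic.

## Endpoints

OS is (death/censor time, death indicator). TTR is (recurrence time, event)
for recurrences and otherwise censors at the death/censoring time — death
without recurrence is a censoring event for TTR, the standard convention
when the endpoint targets disease recurrence specifically. DFS takes the
earlier of recurrence and death with the OR of the two indicators; hence
DFS time ≤ OS time and the DFS indicator is exactly TTR-event OR OS-event.

Median follow-up uses the reverse Kaplan–Meier estimator (event and
censoring roles swapped), with the median's CI read off the log(−log)
pointwise bands (Brookmeyer–Crowley style).

**Risk groups.** Stage-II pathology risk combines primary-tumor extent and
VELIPI (vascular emboli, lymphatic or perineural invasion). The package
uses the disjoint partition very-high = T4 AND VELIPI+, high = exactly one
of the two, low = neither. The defining source material states the and/or
combinations inconsistently between text and figure legends, and its
printed group sizes overlap; the disjoint reading is the only
self-consistent one and is applied uniformly. The combined
"Immunoscore × risk" table row instead uses the strict definition
(high = T4 AND VELIPI+ vs low = all others), matching how that particular
tabulation is conventionally presented.

## Survival engine

**Kaplan–Meier.** Product-limit estimate stepping at event times only, with
Greenwood variance and log(−log S) 95 % intervals (these respect [0, 1] even
near S = 1). Landmark rates (36/60 months) take the left step value between
steps; queries beyond follow-up return the last value flagged
`extrapolated`.

**Log-rank family.** The k-sample statistic is `(O−E)' V⁻ (O−E)` over the
first k−1 groups with the hypergeometric covariance, df = k−1. The trend
test uses equally spaced integer scores 0, 1, 2, … over the stated group
order: `(c'(O−E))² / (c'Vc)`, df = 1. Equal spacing was chosen because no
score vector is canonical; the choice is documented rather than inferred
from any published result. On tie-free data the two-group statistic equals
the squared Cox score z of the group indicator (verified in tests).

**Cox model.** The stratified partial likelihood sums over strata, each
with its own risk sets; ties use the Efron approximation by default (better
with monthly ties) with Breslow selectable, and the two agree exactly on
tie-free data. Maximisation is Newton–Raphson with step-halving. Numerical
conventions:

* convergence when the gradient max-norm falls below 1e-9, with a cap of
  50 iterations;
* on large data the achievable gradient floor is set by floating-point
  accumulation noise, so a vanishing likelihood change across an accepted
  Newton step (below `1e-11·(1+|ℓ|)`) also closes the fit as converged;
* step acceptance tolerates likelihood decreases up to the same scaled
  slack, halving at most 20 times;
* monotone likelihoods (e.g. a level with zero events in it or in the
  reference) are detected by coefficient divergence beyond |β| > 15 and
  reported — the fit is flagged, the affected term summarised as HR = ∞,
  CI (0, ∞), p = NA — rather than raised, because real tabulations contain
  such rows.

Wald summaries are `exp(β ± 1.96·SE)` with two-sided normal p-values; the
likelihood-ratio test of nested fits requires identical data, strata and
ties method. All p-values in the package are two-sided and uncorrected for
multiplicity (none is applied in the study design being mirrored).

**Concordance.** Harrell's C counts a pair as comparable when the earlier
time is an event and the other subject was observed longer (or as long but
censored); score ties count ½; tied event times are not comparable. The
95 % CI is a seeded 200-resample bootstrap percentile interval — the
original analysis's CI method is unstated, so the bootstrap is this
package's own choice and is deterministic under a fixed seed.

**RMST.** Area under the KM curve to τ, variance by the standard
large-sample sum over KM increments, difference tested normally. Default
τ is the smaller of the two groups' largest observed times, since no τ is
canonical.

**Relative importance.** For a fitted multivariable model each variable's
Wald chi-square is `β' V⁻¹ β` over its coefficient block (factors
contribute multi-column blocks); importance is the block's share of the
total, summing to 1. Singular blocks are flagged NA and the rest
renormalised.

## Cohort analyses

The bivariable sweep reproduces a Table-1-style layout: per variable and
level, complete-case n and percent (complete-case per variable, never
listwise — real tables show varying denominators), landmark rates,
unadjusted center-stratified Cox HR against a reference level, a
variable-level C-index from the single-variable fit's linear predictor,
and RMST differences. In the five-category scheme the HR reference is I3
and the RMST reference I4, mirroring how such tables are printed when the
extreme category has no events. Whether unadjusted HRs should carry center
strata is ambiguous in the mirrored design; stratified is the default and
a flag (`--unstratified-hr`) exposes the alternative.

The multivariable model adjusts the two-category Immunoscore for age
(per year), gender, T-stage (T3/T4 vs T1–2 pooled), N-stage (N1/N2 vs N0),
sidedness and MSI, stratified by center, on complete cases; strata with no
events are dropped with a warning. Age groups for the association screen
are left-closed: [0,60), [60,70), [70,85), [85,∞) — the printed bin labels
are reproduced and a boundary age of exactly 60 falls in the second bin.
Cohort comparison uses Welch-free two-sample t (age) and chi-square tests,
falling back to Fisher's exact test for 2×2 tables with any expected cell
below 5.

## Synthetic cohorts

The generator emulates a four-center Asian stage I–III colon-cancer cohort:

* **Covariates.** Center weights (0.30/0.28/0.22/0.20), stage weights
  0.158/0.593/0.249, 54.6 % male, age N(64.7, 12.1²) clipped to [20, 95],
  T/N stages drawn consistently with TNM stage, VELIPI 71.2 %, mucinous
  4.7 %, proximal 44.2 %, chemotherapy 64.5 %, MSI missing 35.7 % and
  MSI-H 9.6 % among known — the marginal frequencies such cohorts report.
* **Densities.** The four log-densities are jointly Gaussian with one
  exchangeable correlation (a Gaussian copula over log-normal marginals),
  default ρ = 0.85: CD3/CD8 infiltration in the two regions is strongly
  co-regulated, and this value, together with the reference shift below,
  reproduces a realistic category split. Channel log-means/SDs
  (6.0/1.0, 6.4/0.9, 5.2/1.1, 5.6/1.0) give right-skewed densities with
  medians of a few hundred cells/mm²; no published summaries exist for
  them, so they are plausibility choices made once.
* **Reference shift.** The reference vectors are drawn from the same
  family offset by +0.4 log-SD. A cohort scored against a more infiltrated
  external training population lands disproportionately in the Low bins;
  with ρ = 0.85 this yields ≈37/47/16 % Lo/Int/Hi, the split that scoring
  against an own-cohort reference (which forces the mean percentile to
  concentrate near 50) cannot produce.
* **Outcome model.** Recurrence times are exponential proportional-hazards
  with linear predictor `log(1.9)·1[Lo]` plus configurable clinical
  effects (defaults: T4 HR 3.0, N1 1.9, N2 4.5); the exponential baseline
  keeps the Cox estimand exactly the generating coefficient. Death is the
  earlier of background mortality (5.5e-4/month) and an exponential
  post-recurrence clock (mean 22 months), so TTR, OS and DFS genuinely
  differ. Censoring is administrative at 84 months minus uniform entry
  staggering over 24 months (median potential follow-up ≈72 months). The
  baseline hazard of 1e-3/month makes the default cohort show ≈15.4 %
  recurrences and ≈14.7 % deaths, the study conditions being emulated;
  configurations that switch off the clinical effects re-set the baseline
  (0.00175, or 0.00235 under a fully null model) to keep that event rate.
* **Determinism.** All draws flow from `numpy.random.default_rng` seeded
  by the config; identical configs give byte-identical CSV output, and the
  truth record (generating parameters, per-patient true category, flagged
  QC failures) is always serialised next to the cohort.

**What passing tests show — and not.** Recovery and calibration results
demonstrate that the estimators are correct under a proportional-hazards
exponential world with independent censoring and exactly known category
membership. Real cohorts add non-proportional hazards, informative
censoring, inter-center measurement drift, and reference-set mismatch;
agreement on synthetic data bounds software error, not those biases.

## Problem sizes

Test-suite simulations use n = 200–2000 patients with 200 coverage
replicates and 500 calibration replicates; these sizes give Monte-Carlo
error comfortably inside the asserted tolerances (e.g. a ±3σ binomial band
for 95 % coverage at 200 replicates is roughly [0.90, 0.99]) while keeping
the suite fast. The acceptance script uses the same sizes.

## Known limitations

* No time-varying covariates, competing risks, or frailty terms.
* The C-index bootstrap resamples patients, not centers.
* The trend-test score vector and RMST τ are conventions, not inferences.
* Five-category analyses on n ≈ 423 routinely produce empty or event-free
  extreme categories; the Inf/NA reporting path is therefore exercised in
  normal operation, and consumers must expect non-finite hazard ratios.
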