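# Methods

This note documents the models implemented in `resilac`, the choices made
where the procedure admits more than one reasonable reading, what the
synthetic-data generator does and does not emulate, and the numerical
details that matter for reproducing results.

## The expected lactation curve and its robust fit

The expected lactation curve (ELC) is the counterfactual perturbation-free
daily-yield trajectory of one cow-parity. Because perturbations depress
yield but never raise it, the ELC is estimated by a *one-sided* robust
procedure on the complete (imputed) 305-day series:

1. A two-sided weighted moving average (window 5, weights
   0.1/0.2/0.4/0.2/0.1, boundary weights renormalized to sum to one)
   suppresses day-to-day measurement noise.
2. Four curve models are fitted on all 305 days: Wood (nonlinear least
   squares on the kg scale, started from the log-linear OLS solution),
   Nelder (OLS on the reciprocal response `1/Y = a + b/t + ct`), Wilmink
   (OLS on regressors `1, e^{−0.05t}, t`; the exponential rate is fixed at
   0.05 as is conventional) and Ali–Schaeffer (OLS on
   `1, t, t², ln t, (ln t)²`). R² is always computed on the kg scale; the
   model with the highest R² is locked in for the lactation (ties resolve
   in the listed order).
3. Days whose deviation from the fit is below `LQ − 1.5·IQR` of the
   current deviations (quartiles by linear interpolation, the numpy
   default) are deleted and the same model is refitted, until no day is
   deleted. High deviations are never removed.
4. Secondary QC accepts the curve only if every fitted daily value lies in
   (0, 100] kg and the final R² exceeds 0.75 (strict).

Safeguards beyond the core definition: an iteration cap of 50 and a
minimum retained-day count of p+2 (p = parameter count). Hitting either
marks the lactation failed rather than raising.

Two ambiguities are resolved as switches with documented defaults.
*Fitting is performed on the smoothed series by default*
(`iterate_elc(..., smooth=True)`); the raw mode exists because the filter's
boundary renormalization biases the first/last two days of steep curves —
on a noise-free Wood curve by over 2 kg at DIM 1 — which matters for
exact-recovery experiments where there is no noise to remove. *Deviations
for the resilience traits always use the unsmoothed imputed series* against
the ELC: the traits are defined on actual records.

## Resilience indicators

With `dev(t) = actual(t) − fitted(t)`, a **fluctuation** is a maximal run
of ≥ 10 consecutive days with `dev < 0` (strict) containing at least one
day with `actual < 0.9·fitted` (strict). A run of any length is one event.
Per event: duration DML, loss `MLF = Σ (fitted − actual)`, nadir day
(largest shortfall, earliest on ties), and the lactation-stage class of the
start day (1–44, 45–99, 100–199, 200–305). Per lactation: `ML = Σ MLF`,
`NML` = event count, `TDML = Σ DML`, `MLP = 100·ML/MY305`, with MY305 the
sum of the complete daily series.

The variability traits are computed on four windows of the deviation
series — DIM 1–305, 11–295, 60–90, and the negative-deviation days in DIM
order: `Lnsd = ln(SD)` (n−1 denominator), `Ra` the lag-1 autocorrelation
over adjacent positions of the ordered window (window 4 pairs retained
days across DIM gaps; the signed deviations are used), and `Ske` the
adjusted Fisher–Pearson sample skewness. Windows shorter than 3 values or
with zero SD yield missing traits. The motivation comes from critical
slowing down: systems near a tipping point show inflated variance and
autocorrelation of fluctuations, so low Lnsd/Ra signal resilient animals.
`1.96·exp(Lnsd)` converts an Lnsd value back to the kg half-width of the
95 % deviation interval.

Final cohort filters before genetic analysis: lactations with MY305 three
or more SD from the cohort mean, and cows with unknown sire or dam, are
removed.

## Clustering and imputation

Lactations are Z-scored over observed days (n−1 denominator), reduced to
24 ten-day means over DIM 31–270 (a lactation with an empty bin or zero SD
is excluded from clustering and later attached to the nearest profile),
projected on the first five principal components of the covariance of the
bin matrix (rows are already scale-free; columns are centred only), and
clustered by Ward's minimum-variance criterion on Euclidean distances with
the cluster count chosen by mean silhouette over k = 2…10 (ties to the
smaller k). Within each cluster, observed records `|y − mean| ≥ 3·SD` at a
DIM are removed once (not iterated); the rule operates on raw kg within
cluster-DIM cells, and a zero-SD cell removes nothing.

Imputation first fills missing DIM 1–4 and 305 from the cluster's mean
Z-scored profile (`ŷ = z̄·SD + mean` of the lactation's non-missing days),
guaranteeing a terminal anchor, then scans n = 5…304 in DIM order and
fills each missing day from the OLS line through days n−4…n−1 and the next
day holding a value. Previously imputed days serve as predictors — the
procedure is sequential by design. Imputed values are not clamped; extreme
imputations are left for the ELC QC to catch.

## Genetic models

The single-trait animal model is `y = Xb + Za + e`,
`a ~ N(0, A σ²ₐ)`, `e ~ N(0, I σ²ₑ)`, with fixed effects (as available)
herd-year-season (season = calendar quarter of calving), parity class
(1, 2, 3, 4, 5+), cluster group, curve model, and age-at-first-calving
class (≤22, 23–24, 25–26, ≥27 months). The repeatability model for
per-event traits adds a permanent-environment effect `pe ~ N(0, I σ²ₚₑ)`
and the lactation-stage class of the event start as a fixed effect. The
bivariate model stacks two traits with `var(a) = G₀ ⊗ A` and residual
covariance between the two traits' records on the same cow-parity unit.

`A⁻¹` is assembled directly from pedigree by Henderson's rules with
inbreeding coefficients from the Meuwissen–Luo recursion (the tabular A is
kept for oracle tests; `log|A| = Σ log Dᵢ` from the `A = T D T'`
factorization). Fixed-effect designs are intercept + drop-first dummies
with pivoted-QR removal of confounded columns.

REML maximizes the restricted log-likelihood
`ℓ_R = −½(log|V| + log|X'V⁻¹X| + y'Py)` (constants dropped) over the
linear covariance structure `V(θ) = Σ θₖ Sₖ`: the engine forms V densely,
computes the exact gradient `−½(tr(P Sₖ) − y'P Sₖ P y)` and the average
information `AIₖₗ = ½ (Sₖ Py)' P (Sₗ Py)`, and takes AI steps with
(a) an EM fallback `θₖ += θₖ²(y'P Sₖ P y − tr(P Sₖ))/qₖ` when an AI step
proposes an out-of-bounds variance, (b) step halving whenever a step would
decrease ℓ_R (so accepted iterations are monotone), and (c) for bivariate
fits, eigenvalue-clipping of the 2×2 genetic and residual blocks back to
positive semidefinite. Convergence: relative parameter change < 1e−8 or
|Δℓ_R| < 1e−9, cap 200 iterations. Variances are floored at
1e−8 × var(y). Standard errors come from the inverse AI matrix; h² and r_G
standard errors by the delta method. Bivariate starting values are the
single-trait fits with covariances at `0.1·√(σ²₁σ²₂)`.

Breeding values come from the sparse mixed-model equations
`[X'X, X'Z; Z'X, Z'Z + A⁻¹λ] s = W'y` (λ = σ²ₑ/σ²ₐ); reliabilities are
`1 − PEV/σ²ₐ` with PEV from the animal block of the inverse coefficient
matrix (direct inverse — intended for cohort-scale systems, not national
evaluations). Note a structural identifiability fact exercised by the
tests: in a single-sire cohort with only an intercept, the sire contrast is
absorbed by the mean and his reliability is exactly zero.

Validation follows the forward design: sires with ≥ 40 recorded daughters
are kept; each sire's daughters are split by birth date, the oldest
⌊0.8·n⌋ forming the prediction set. Validation EBVs are solved from
prediction-set phenotypes only (the leakage test perturbs validation
phenotypes and checks EBVs are bit-identical). The top and bottom ⌊0.2·n⌋
EBV animals (for Lnsd-type traits, *lowest* EBV = most resilient;
direction is a flag) are compared per companion trait with Welch's
unequal-variance t test — the conservative reading of a two-sample
"Student t test".

## The synthetic generator

Real herd daily-yield datasets of this kind are proprietary, so the
generator is a first-class module. It simulates:

- a three-generation pedigree (founder sires and dams, one recorded
  daughter per dam), daughters' birth dates spread over the configured
  calving years;
- breeding values by gene dropping: founders `N(0, σ²ₐ)`, non-founders
  parent-average plus a Mendelian-sampling deviate with variance
  `½σ²ₐ(1 − (F_s + F_d)/2)`;
- per-lactation potential curves from six shape archetypes (early peak
  with fast decline; flat persistent; mid peak; and the ~5 % atypical
  minority: delayed peak, monotone increasing, U-shaped/reversal), with
  5 % multiplicative parameter jitter and a parity scale (1.0 → 1.2);
- perturbation events: Poisson count (default rate 3.7 per lactation),
  onset days with elevated early (DIM ≤ 30, 3×) and late (DIM ≥ 270, 2×)
  risk, log-normal durations (median ≈ 17 d, mean ≈ 20 d, minimum 5 d),
  Beta(2, 6) nadir depths (mean 25 % of potential), each event a
  piecewise-linear drop to the nadir over the first third and linear
  recovery reaching zero the day after the event. The animal's
  standardized resilience breeding value shifts log-duration (−0.15 per
  SD) and logit-depth (−0.30 per SD) — a phenomenological link that gives
  the milk-loss traits genetic variance without committing to a mechanism;
- daily records `potential·(1 − depth) + N(0, exp(lnsd)²)` where the
  per-lactation log residual SD is `lnsd = 0.97 + a + e` with default
  σ²ₐ = 0.027 and σ²ₑ = 0.080 (h² ≈ 0.25 on a phenotypic variance of
  ~0.107, the scale of published Lnsd estimates); herd-year-quarter
  additive shifts `N(0, 1 kg²)`; per-day missingness (3 %), occasional
  multi-day gaps (Poisson 0.4 per lactation, lengths 3–12 d so some
  lactations fail the >10-day gap filter), and negative noisy yields
  truncated to zero and treated as missing;
- `simulate_trait_cohort` generates per-cow Lnsd-type phenotypes directly
  (mean + hys + parity + a + e), skipping the daily-record layer; it is
  the substrate for heritability-recovery experiments at scale.

Everything is reproducible from the config seed (numpy `SeedSequence`
spawning), and a `TruthTable` retains breeding values, potential curves
and events.

**What the generator does not emulate** — and hence what green tests do
not certify about real data: no weather/disease covariates behind events
(onsets are exchangeable given the stage profile), no milk-composition or
milking-shift structure, no genetic trend across years, no heterogeneous
residual variance along the lactation, and Gaussian residuals where real
deviations are heavier-tailed. Detected event counts are lower than the
true simulated rate because shallow, tapered or noise-broken events fail
the ≥10-day/90 % rule; this mirrors the strictness of the definition, not
a defect of the detector.

## Problem sizes and numerical choices

The dense-V REML engine is exact but O(n³) per iteration; it is
comfortable to roughly 5,000 records on one CPU. The calibrated recovery
experiment uses 3,000 cows (100 sires × 30 daughters; ~6,100 pedigree
animals), where AI-REML converges in ~5 iterations and ~20 s, giving
h² SE ≈ 0.05 — so the true value 0.25 sits well within two SEs across
seeds. Repeatability recovery is exercised at ~2,400 records (3 records ×
800 cows). Null-heritability simulations at these family structures have
SE(ĥ²) ≈ 0.05; the null check therefore asserts consistency with zero at
2.5 SE rather than a fixed small constant, which would require tens of
thousands of animals. The brute-force fluctuation oracle runs on 1,000
random AR(1) deviation vectors in a few seconds.

Known limitations: no genomic relationships; bivariate only (no ≥3-trait
models); reliabilities require a dense inverse of the MME coefficient
matrix; the generator's event-onset distribution and resilience links are
plausible placeholders, not estimated from data.
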