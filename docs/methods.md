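# Methods

This note documents the models, assumptions, parameter choices and numerical
decisions behind `empyema_pba`. It is written for a user who wants to know
exactly what the package computes and what passing its tests does — and does
not — demonstrate.

## 1. Study design being emulated

The pipeline reproduces a retrospective database study of adults (≥ 40 y)
admitted with empyema, treated with thoracostomy and intravenous antibiotics
on the admission day or the next day (day offsets 0/1). The exposure contrast
is *empirical anti-pseudomonal* vs *non-anti-pseudomonal* antibiotics; the
outcomes are thoracic surgery and all-cause death within 90 days, analyzed as
cause-specific hazards because death precludes later surgery. Patients on
day-0/1 intravenous vasopressors and patients who died or were transferred
within 24 h are excluded. A subgroup analysis restricts to patients with at
least one risk factor for multidrug-resistant organisms (healthcare-facility
residence, dialysis, antibiotics within the previous 90 days, or
immunodeficiency).

### Outcome convention

For the *surgery* cause, death and loss to follow-up censor, with
administrative censoring at day 90. For the *death* cause, a prior surgery
does **not** censor — death after surgery is still a death event. Same-day
surgery and death contribute a surgery event and a death event at the same
time (surgery can precede same-day death; the reverse cannot). An event on
day 90 counts as an event. Eligible records cannot have a death on day 0 (the
24-hour exclusion), so all follow-up times are positive.

### Covariate definitions

Age continuous (years); sex; ADL dependence = Barthel index < 50; low
exercise tolerance = Hugh-Jones class > 3; immunodeficiency; prior
antibiotics within 90 days; source of infection dichotomized
community vs hospital/nursing; abnormal mental status = Japan Coma Scale > 0;
blood urea nitrogen in bins [0, 14), [14, 22.4), [22.4, ∞) mg/dL (the high
bin is closed at 22.4 on the left, consistent with the moderate bin's upper
bound); low albumin ≤ 2.7 g/dL; oxygen use on admission. Any missing source
field marks the row incomplete; all modeling is complete-case, reflecting the
low missingness (~7%) this kind of extract shows.

## 2. Synthetic cohort generator

No public data exist for this design, so `simulate.generate_cohort` produces
raw admission records with the joint structure the analysis assumes. Its
defaults *are* the study conditions used throughout the tests:

| quantity | default | rationale |
|---|---|---|
| raw records `n_total` | 908 | yields ~855 eligible after the filters |
| exposure prevalence | ~31.7% | logistic assignment, intercept −0.87 |
| age | N(75.2, 12.3²), floor 40 | elderly cohort |
| 90-day death risk | ~9.5% (8%/12% by arm) | baseline hazard 0.52e−3/day |
| 90-day surgery risk | ~10.5% | baseline hazard 1.40e−3/day |
| loss to follow-up by day 90 | ~38% | censoring hazard 5.9e−3/day |
| true exposure effects | HR 1.63 surgery, 1.52 death | planted truths for recovery tests |
| per-covariate missingness | 1.5% MCAR on 5 fields | ~7% incomplete rows overall |
| ineligible fractions | 1% age, 1% timing, 3.6% vasopressor, 0.11% early death | exercises every filter |

Event times come from independent latent clocks per cause: cumulative hazard
λ·t^k (exponential by default, Weibull shape `weibull_shape` ≠ 1 available
for proportional-hazards stress testing), with λ multiplied by
exp(covariate log-HRs) and — when a confounder is planted — by RR_CD on the
death clock. Latent times are rounded up to integer days (so no day-0
events), and the observed record keeps whichever events precede censoring,
with death never censored by surgery. The independent-latent-clock mechanism
is the simplest one consistent with the cause-specific hazards being modeled;
it implies randomly ordered competing events rather than any biological
dependence between the surgery and death processes.

The hidden confounder is drawn *conditional on exposure* with prevalences
p1/p0 — matching the PBA's parameter semantics exactly, which is what makes
the bias-analysis module testable against generator truth. Missingness is
MCAR, the minimal mechanism compatible with a complete-case analysis.

What the generator does **not** emulate: hospital-level clustering, seasonal
admission patterns, informative censoring, covariate-dependent missingness,
bacterial-culture results, or time-varying treatment. Consequently, passing
parameter-recovery tests shows the estimators are correct *under the stated
model*, not that the design is robust to violations of it.

## 3. Propensity model and weighting

The exposure model is logistic regression fit by Newton–Raphson with
step-halving; convergence at max |score| < 1e-8 (≤ 100 iterations). A rank
check names the collinear covariate before fitting; perfect separation is
reported both when coefficients diverge and when the maximized log-likelihood
reaches zero (saturated probabilities can silence the score). ATE weights are
1/e (exposed) and 1/(1−e) (unexposed), untruncated by default — truncation at
chosen percentiles is available for sensitivity analyses but is not part of
the primary method. Balance is summarized by standardized mean differences
with the pooled SD always computed from the unweighted arms; |SMD| < 0.1 is a
reporting convention, not a gate. The subgroup propensity model drops the
covariates that define the subgroup (immunodeficiency, prior antibiotics,
source of infection) and keeps the remainder.

## 4. Weighted Cox, sandwich variance, curves

The cause-specific fit maximizes the case-weighted partial likelihood with
**Efron** tie handling (integer-day data make ties ubiquitous; Efron is the
less biased convention) by Newton iteration to score tolerance 1e-8. Exposure
is the sole covariate in the study analysis; the fitter accepts arbitrary
designs and has a fully vectorized single-covariate path used by the PBA
inner loop.

Robust variance is the subject-level sandwich I⁻¹ B I⁻¹ with
B = Σᵢ (wᵢ Lᵢ)(wᵢ Lᵢ)ᵀ, where Lᵢ is the per-subject score residual evaluated
at the weighted fit (Breslow-form residual aggregation; the information
matrix uses the exact Efron form). Weights are treated as fixed known
quantities — propensity-estimation uncertainty is *not* propagated, matching
common IPTW practice; `cox.bootstrap_se` offers a nonparametric bootstrap
that optionally refits the propensity model per resample for users who want
that uncertainty included. The bootstrap skips resamples in which an arm has
zero events of the cause (the log-HR is unidentified there). Doubling all
weights provably leaves both the estimate and the sandwich SE unchanged.
Confidence intervals are normal-theory on the log scale; p-values are
two-sided Wald. A single-event fit returns a finite SE flagged
`low_information`.

Unadjusted cumulative incidence uses the Aalen–Johansen estimator on the
first-event decomposition (tie rule: surgery first), computed jointly for
both causes so that CIF₁ + CIF₂ + S(t) = 1 holds to machine precision at
every time point. Pointwise variance uses the standard delta-method estimator
for competing risks, and 95% bands use the log(−log) transform (undefined at
CIF = 0, where the band degenerates to the estimate). Weighted survival
curves take the per-group product-integral of the weighted Breslow hazard
increments, S_g(t) = Π(1 − e^{βg}·dH₀); with β = 0 and unit weights this *is*
the Kaplan–Meier curve. Curve bands reflect only the robust uncertainty in β
(the baseline arm carries a degenerate band).

## 5. Probabilistic bias analysis

Per grid cell (p1, p0, RR_CD) and per iteration:

1. draw p1 ~ Beta(α1, β1), p0 ~ Beta(α0, β0),
   RR ~ Trapezoidal(RR_CD−0.2, RR_CD−0.1, RR_CD+0.1, RR_CD+0.2);
2. with the observed arm-specific 90-day death risks Pr(D | E=e), compute
   q_e = Pr(D|E=e)/(1 − p_e + RR·p_e) and
   Pr(C | E=e, D=1) = p_e·RR/(1 − p_e + RR·p_e),
   Pr(C | E=e, D=0) = p_e·(1 − RR·q_e)/(1 − Pr(D|E=e));
   a draw implying Pr(D | C=1, E) > 1 is skipped and counted;
3. impute C per record by an independent Bernoulli draw with the
   (E, D)-matched probability; the law of total probability is verified to
   1e-10 on every admissible draw;
4. refit the subgroup propensity model with C appended, recompute ATE
   weights, refit the weighted cause-specific Cox model for death, record the
   log-HR.

Summaries per cell: median HR and the 2.5/97.5 percentiles of the iteration
distribution — a *simulation interval* describing systematic-bias
uncertainty, not sampling error. An option adds a normal draw scaled by the
robust SE per iteration for users who want sampling error folded in; it is
off by default. Cells with > 20% skipped iterations are flagged unreliable.

Design choices that were genuinely open:

- **D is the binary 90-day death status**, ignoring censoring time; records
  censored before day 90 keep their last-seen status (alive). The imputation
  conditions on outcome *levels*, not times — a logged approximation.
- **C enters through the propensity model** (re-weighting), keeping exposure
  the sole Cox covariate — "the same subgroup analysis" with one more
  confounder. The alternative (C as a Cox covariate) is available via
  `adjustment="cox_covariate"`.
- **Beta priors**: the mean is pinned exactly at the grid value and the
  single free concentration parameter is solved (Brent root-find, tolerance
  1e-6) so the central 95% *width* equals 0.2. For the symmetric mean 0.5
  both percentiles then sit exactly at mean ± 0.1; for asymmetric means Beta
  skew makes simultaneous percentile matching impossible, and the width
  criterion is the coherent compromise (residual percentile asymmetry
  ≲ 0.005). An interval reaching outside [0, 1] raises a solver error; a
  boundary-touching interval (mean 0.1 ± 0.1) is allowed, since the Beta
  quantiles remain interior.
- **RR_CD grid {3, 4, 5}** follows the magnitude of observed
  confounder-death risk ratios in this clinical setting (median ≈ 3.2).
- **Iterations**: 2 000 by default per cell (desk scale; median Monte-Carlo
  error ≪ 0.05 on the log scale); 100 000 reproduces a publication-scale run.
- Per-cell RNG streams are spawned from (seed, cell-index), so results are
  reproducible cell by cell and independent of grid order.

A known behavior, demonstrated in the test suite: PBA adjusts by the
*expected* bias implied by the assumed parameters. In a cohort where sampling
luck alone produced a near-null crude estimate, adjustment overshoots; the
method recenters the *distribution* of estimates on the truth but cannot
adapt to the realized confounder imbalance of a single dataset.

## 6. Tabulation

Exploratory two-group comparisons use Pearson's chi-squared with Yates
continuity correction (clamped, 1 df), which is what reproduces printed
reference p-values such as 0.028/0.076/0.720 from their 2×2 counts; a flag
disables the correction, which provably only increases the statistic when
|ad − bc| > n/2. A zero margin raises an error suggesting an exact test.
Descriptive tables report count (%) with missing as a category (percentages
within a variable sum to 100), mean (SD) for age with the SD left blank for a
single observation, and per-agent antibiotic frequencies where a patient
counts once under every agent received (so within-class percentages may
exceed 100); denominators are always the classified arm sizes.

## 7. Pipeline and reproducibility

`RunConfig` drives simulate → build → analyze → bias → report; exactly one of
`input_csv` / `generator` must be set (the bare CLI invocation fills in the
default generator). The pipeline's default bias grid is the nine-cell
desk-scale set pairing matched prevalences (0.4, 0.1), (0.5, 0.2), (0.6, 0.3)
with each RR_CD; `bias.default_grid()` provides the full 27-cell factorial. One global seed spawns independent
integer sub-seeds per stochastic stage (generation; PBA) via
`numpy.random.SeedSequence`, so re-running any stage from cached artifacts is
byte-identical. All artifacts are plain CSV/JSON; the Markdown report
collates the selection flow, balance, hazard-ratio table and PBA forest
table. The `empyema-pba` CLI is a thin click wrapper over the stage
functions; invoking a stage before its upstream artifact exists names the
missing stage.

## 8. Problem sizes used in the test and acceptance suites

Simulation-based checks run at the study scale (n ≈ 855 eligible):
type-I error of the robust Wald test over 500 null replicates (accepted band
[0.03, 0.07]); recovery of a true death HR of 1.5 and CI coverage
(90–98%) over 200 replicates; bootstrap agreement of the sandwich SE within
25% at n ≈ 200 with 500 resamples; PBA null-parameter consistency at 2 000
iterations; planted-confounder correction over 50 replicate cohorts at 200
iterations per replicate. These sizes keep the full suite around two minutes
while leaving each check's Monte-Carlo error well inside its assertion
margin.

## 9. Known limitations

- The sandwich ignores propensity-estimation uncertainty (by design; it is
  therefore mildly conservative for the ATE contrast under correct
  specification).
- Score residuals use Breslow-form aggregation at tied times while the
  likelihood uses Efron; the discrepancy is far below the estimator's own
  noise (cross-checked against an independent implementation within 2%).
- The PBA conditions imputation on (E, D) only, not on covariates or time.
- No Fine–Gray subdistribution model, no time-varying effects, no
  proportionality diagnostics beyond an optional residual export; the
  cause-specific hazard is the chosen estimand.
- The generator's calibration targets crude 90-day risks, not event-time
  shapes; length-of-stay distributions are not modeled.
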