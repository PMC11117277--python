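# empyema-pba

Comparative-effectiveness analysis of **empirical anti-pseudomonal vs
non-anti-pseudomonal antibiotics in empyema**, packaged as a tested, reusable
Python pipeline: cohort construction from raw admission records, propensity
score weighting, cause-specific Cox models under competing risks with robust
variance, exploratory contingency tests, and a nine-step **probabilistic bias
analysis (PBA)** for an unmeasured binary confounder. Because real-world
hospital databases of this kind are proprietary, the package ships a
first-class **synthetic cohort generator** that reproduces the statistical
structure such an analysis assumes, so every stage can be exercised, tested
and calibrated end to end.

Intended users: epidemiologists and biostatisticians running
database-style comparative-effectiveness studies with competing risks, and
anyone who wants a worked, testable implementation of record-level
probabilistic bias analysis.

## The statistical core

**Cohort.** Adults ≥ 40 with empyema who underwent thoracostomy and received
intravenous antibiotics on admission day 0/1; exclusions: day-0/1 intravenous
vasopressors, death/transfer within 24 h. Exposure E = 1 if *any* day-0/1
intravenous antibiotic is anti-pseudomonal. Outcomes over a 90-day horizon:
thoracic surgery and all-cause death, with death a competing risk for
surgery.

**IPTW.** Propensity e(x) = Pr(E=1 | x) by logistic ML; average-treatment-
effect weights w = E/e + (1−E)/(1−e); balance by standardized mean
differences.

**Cause-specific hazards.** For each cause k the weighted Cox partial
likelihood (Efron ties) with exposure as the sole covariate estimates
HR_k = exp(β_k); variance is the subject-level sandwich
I⁻¹ (Σᵢ wᵢ²LᵢLᵢᵀ) I⁻¹ with weights treated as fixed. Unadjusted cumulative
incidence uses the Aalen–Johansen estimator, which conserves
CIF_surgery + CIF_death + S(t) = 1 exactly.

**PBA.** For bias parameters (p1, p0, RR_CD) — prevalence of an unmeasured
binary confounder C among exposed/unexposed and its risk ratio on death —
each Monte-Carlo iteration samples p1, p0 ~ Beta (mean fixed, 95% interval
± 0.1), RR_CD ~ Trapezoidal(RR−0.2, RR−0.1, RR+0.1, RR+0.2), derives
Pr(C | E, D) by Bayes' rule from the observed arm-specific death risks,
imputes C per record, refits the propensity model with C, and re-estimates
the weighted cause-specific death HR. Each grid cell is summarized by the
median and 2.5/97.5 percentiles of the adjusted HRs.

## Worked example

```bash
python examples/04_probabilistic_bias_analysis.py
```

generates a cohort with a *planted* confounder (p1 = 0.5, p0 = 0.2,
RR_CD = 3) and a null true exposure effect, then adjusts for it:

```
crude subgroup death HR (confounded): 1.47 (truth is 1.00; planted bias ~ 1.43x)

bias-adjusted death HR by assumed (p1, p0, RRcd):
 p1  p0  rr_cd  median_hr  hr_ci95_low  hr_ci95_high
0.5 0.2    3.0   0.966509     0.645703      1.239911
0.4 0.1    3.0   0.913314     0.573779      1.264251
0.6 0.3    5.0   0.878143     0.604856      1.184742
```

The crude subgroup hazard ratio (1.47) carries the confounder-induced bias;
at the true bias-parameter cell the adjusted median (0.97) returns to the
null. The other examples cover cohort simulation (`01`), IPTW + cause-
specific hazard ratios (`02`, true HRs 1.63/1.52 by construction), and
cumulative incidence (`03`).

The same pipeline runs from a shell:

```bash
empyema-pba run --seed 1 --out run_dir          # simulate → build → analyze → bias → report
empyema-pba analyze --config cfg.yaml           # or stage by stage
```

## Layout

```
src/empyema_pba/   simulate, cohort, propensity, cox, bias, tables, pipeline, cli
examples/          one narrative script per capability
tests/             unit + property + acceptance suites
docs/methods.md    models, assumptions, numerical choices, limitations
```
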