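"""Propensity weighting and cause-specific hazard ratios.

Fits the exposure propensity model on the complete-case cohort, forms ATE
inverse-probability weights, checks balance, and estimates the weighted Cox
hazard ratio of anti-pseudomonal (vs non-anti-pseudomonal) antibiotics for
thoracic surgery and for death, each treating the other as a competing risk.
The generator's true effects are HR 1.63 (surgery) and 1.52 (death), so the
printed estimates should hover around those values within sampling noise.
"""

from empyema_pba import (
    GeneratorConfig,
    build_analysis_table,
    fit_iptw,
    fit_weighted_cox,
    generate_cohort,
)
from empyema_pba.cohort import MAIN_COVARIATES, SUBGROUP_COVARIATES

_, cohort = build_analysis_table(generate_cohort(GeneratorConfig(seed=1)))
cc = cohort[cohort.complete_case].reset_index(drop=True)
sub = cc[cc.mdr_risk].reset_index(drop=True)

for label, data, covariates in (("main", cc, MAIN_COVARIATES),
                                ("MDR-risk subgroup", sub, SUBGROUP_COVARIATES)):
    ps = fit_iptw(data, covariates)
    worst = ps.smd_table.smd_weighted.abs().max()
    print(f"\n{label} analysis (n={len(data)}): "
          f"max weighted |SMD| = {worst:.3f} (balance achieved below 0.1)")
    for cause in ("surgery", "death"):
        fit = fit_weighted_cox(data, ps.weights, cause)
        print(f"  {cause:8s} HR {fit.hr:4.2f} "
              f"(95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f}, robust SE, "
              f"p={fit.p_value:.3f}, {fit.n_events} events)")
# A CI crossing 1 means the data are compatible with no effect; the robust SE
# treats the estimated weights as fixed, as in standard IPTW practice.
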