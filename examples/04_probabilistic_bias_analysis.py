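"""Probabilistic bias analysis for an unmeasured binary confounder.

A confounder with prevalence 0.5 among exposed, 0.2 among unexposed and a
death risk ratio of 3 is planted in the generator, biasing the crude subgroup
hazard ratio upward by roughly exp(0.36) = 1.43. The PBA samples the bias
parameters from their priors, imputes the confounder record by record,
re-weights and refits; at the true parameter cell the adjusted median should
move back toward the generator's truth.
"""

import math

from empyema_pba import (
    BiasParameters,
    GeneratorConfig,
    build_analysis_table,
    fit_weighted_cox,
    generate_cohort,
    run_pba,
)
from empyema_pba.bias import forest_summary

cfg = GeneratorConfig(seed=4, confounder_spec={"p1": 0.5, "p0": 0.2, "rr_cd": 3.0})
cfg.hazard_spec["death"]["exposure"] = 0.0  # null true effect
_, cohort = build_analysis_table(generate_cohort(cfg))
sub = cohort[cohort.complete_case & cohort.mdr_risk].reset_index(drop=True)

crude = fit_weighted_cox(sub, None, "death")
print(f"crude subgroup death HR (confounded): {crude.hr:.2f} "
      f"(truth is 1.00; planted bias ~ {math.exp(0.357):.2f}x)")

grid = [BiasParameters(0.5, 0.2, 3.0),   # the true cell
        BiasParameters(0.4, 0.1, 3.0),
        BiasParameters(0.6, 0.3, 5.0)]
results = run_pba(sub, grid, iterations=500, seed=2)
print("\nbias-adjusted death HR by assumed (p1, p0, RRcd):")
print(forest_summary(results)[["p1", "p0", "rr_cd", "median_hr",
                               "hr_ci95_low", "hr_ci95_high"]].to_string(index=False))
# The first row assumes the true bias parameters: its median lands near 1.
# The interval is a simulation interval over the sampled bias parameters and
# imputations, not a sampling-error confidence interval.
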