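"""Unadjusted cumulative incidence of surgery and death by exposure arm.

The Aalen-Johansen estimator decomposes the first event into its competing
causes; at every time point the two incidences and the event-free probability
sum exactly to one.
"""

import numpy as np

from empyema_pba import GeneratorConfig, build_analysis_table, generate_cohort
from empyema_pba.cox import cumulative_incidence

_, cohort = build_analysis_table(generate_cohort(GeneratorConfig(seed=1)))

for group in ("anti_pseudomonal", "non_anti_pseudomonal"):
    est = cumulative_incidence(cohort, group)
    print(f"\n{group} (n={int((cohort.exposure_label == group).sum())})")
    print("  day   CIF surgery   CIF death   event-free")
    for day in (30, 60, 90):
        i = np.searchsorted(est.time_grid, day, side="right") - 1
        print(f"  {day:3d}   {est.cif_surgery[i]:10.3f}   "
              f"{est.cif_death[i]:8.3f}   {est.event_free[i]:9.3f}")
    total = est.cif_surgery + est.cif_death + est.event_free
    print(f"  mass conservation: max |sum - 1| = {np.abs(total - 1).max():.1e}")
# The anti-pseudomonal arm shows higher incidence of both events before any
# confounder adjustment, matching the generator's confounded assignment.
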