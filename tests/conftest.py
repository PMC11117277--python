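import math

import numpy as np
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("det", derandomize=True)
_hyp_settings.load_profile("det")
import pandas as pd
import pytest

from empyema_pba import (
    GeneratorConfig,
    build_analysis_table,
    fit_iptw,
    fit_weighted_cox,
    generate_cohort,
    load_drug_dictionary,
)
from empyema_pba.cohort import MAIN_COVARIATES


from empyema_pba.records import RawPatientRecord


def make_record(**kwargs):
    """An eligible single-admission record with sensible defaults."""
    base = dict(patient_id="T", age=70.0, sex="male",
                drug_events=[("ampicillin_sulbactam", 0)],
                procedure_events=[("thoracostomy", 0)],
                bun=15.0, albumin=3.5, barthel=80, hugh_jones=2, jcs=0)
    base.update(kwargs)
    return RawPatientRecord(**base)


@pytest.fixture(scope="session")
def drug_dict():
    return load_drug_dictionary()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (~855 eligible) with its analysis table."""
    elig, df = build_analysis_table(generate_cohort(GeneratorConfig(seed=11)))
    return elig, df


@pytest.fixture(scope="session")
def subgroup_rows(default_cohort):
    _, df = default_cohort
    return df[df.complete_case & df.mdr_risk].reset_index(drop=True)


def _replicate_death_fits(n_rep, base_seed, death_log_hr, surgery_log_hr=None):
    """Generate cohorts, run the IPTW + cause-specific Cox pipeline for death,
    and collect (log_hr, robust_se, p_value) per replicate."""
    out = []
    for r in range(n_rep):
        cfg = GeneratorConfig(seed=base_seed + r)
        cfg.hazard_spec["death"]["exposure"] = death_log_hr
        if surgery_log_hr is not None:
            cfg.hazard_spec["surgery"]["exposure"] = surgery_log_hr
        _, df = build_analysis_table(generate_cohort(cfg))
        cc = df[df.complete_case].reset_index(drop=True)
        ps = fit_iptw(cc, MAIN_COVARIATES)
        fit = fit_weighted_cox(cc, ps.weights, "death")
        out.append((fit.log_hr, fit.robust_se, fit.p_value))
    return pd.DataFrame(out, columns=["log_hr", "robust_se", "p_value"])


@pytest.fixture(scope="session")
def recovery_fits():
    """200 replicate pipelines at the study scale with true death HR 1.5."""
    return _replicate_death_fits(200, base_seed=20_000, death_log_hr=math.log(1.5))


@pytest.fixture(scope="session")
def null_fits():
    """500 replicate pipelines at the study scale with no true exposure effect
    on either cause."""
    return _replicate_death_fits(500, base_seed=50_000,
                                 death_log_hr=0.0, surgery_log_hr=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
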