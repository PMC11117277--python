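"""Cohort construction: eligibility, exposure, covariates, outcomes.

Eligibility mirrors the study selection: adults aged >= 40 with empyema who
underwent thoracostomy and received intravenous antibiotics upon admission or
the following day (day offsets 0/1); exclusions are intravenous vasopressors
on day 0/1 and death or transfer to another hospital within 24 h (day 0).
A record failing several rules is counted once, under the first failing rule
in the order: age, thoracostomy/antibiotic timing, vasopressor, early
death/transfer.

Exposure is *empirical anti-pseudomonal antibiotics*: any day-0/1 intravenous
antibiotic with anti-pseudomonal activity, regardless of dose; the comparator
is a day-0/1 regimen of non-anti-pseudomonal antibiotics only.

Outcomes follow the cause-specific convention for competing risks over a
90-day horizon: for thoracic surgery, death is a competing event that censors;
for death, a prior surgery does not preclude the event. Same-day surgery and
death contribute a surgery event and a death event at the same time (surgery
can precede same-day death; the reverse cannot happen).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import ContractViolation, RecordValidationError
from .records import RawPatientRecord

__all__ = [
    "load_drug_dictionary",
    "EligibilityResult",
    "apply_eligibility",
    "classify_exposure",
    "derive_covariates",
    "derive_outcomes",
    "flag_mdr_risk",
    "build_analysis_table",
    "MAIN_COVARIATES",
    "SUBGROUP_COVARIATES",
    "MDR_RISK_FACTORS",
]

#: propensity-model covariates of the main analysis
MAIN_COVARIATES = [
    "age", "male", "adl_dependent", "low_exercise_tolerance", "immunodeficiency",
    "prior_antibiotics_90d", "source_hospital_nursing", "abnormal_mental_status",
    "bun_mid", "bun_high", "low_albumin", "oxygen_use",
]

#: subgroup propensity model drops the covariates that define the
#: multidrug-resistance risk (and the overlapping source-of-infection term)
SUBGROUP_COVARIATES = [
    "age", "male", "adl_dependent", "low_exercise_tolerance",
    "abnormal_mental_status", "bun_mid", "bun_high", "low_albumin", "oxygen_use",
]

MDR_RISK_FACTORS = [
    "residence_healthcare_facility", "dialysis", "prior_antibiotics_90d",
    "immunodeficiency",
]

THORACOSTOMY_CODES = {"thoracostomy"}


def load_drug_dictionary(path=None) -> dict[str, str]:
    """Map drug code -> class (anti_pseudomonal / non_anti_pseudomonal /
    vasopressor / other). The packaged CSV is an editable default."""
    if path is None:
        src = resources.files("empyema_pba").joinpath("data/drug_dictionary.csv")
        with src.open(newline="") as fh:
            return {row["code"]: row["class"] for row in csv.DictReader(fh)}
    with open(path, newline="") as fh:
        return {row["code"]: row["class"] for row in csv.DictReader(fh)}


def _day01_antibiotics(record: RawPatientRecord, drug_dict: dict[str, str]) -> list[str]:
    return [code for code, day in record.drug_events
            if day in (0, 1)
            and drug_dict.get(code) in ("anti_pseudomonal", "non_anti_pseudomonal")]


def _has_day01_vasopressor(record: RawPatientRecord, drug_dict: dict[str, str]) -> bool:
    return any(day in (0, 1) and drug_dict.get(code) == "vasopressor"
               for code, day in record.drug_events)


@dataclass
class EligibilityResult:
    """Selection-flow counts plus a per-record reason code ('eligible', 'age',
    'antibiotic_timing', 'vasopressor', 'early_death_or_transfer')."""

    n_input: int = 0
    n_identified: int = 0
    n_excluded_vasopressor: int = 0
    n_excluded_early_death_or_transfer: int = 0
    n_analyzed: int = 0
    n_not_identified_age: int = 0
    n_not_identified_timing: int = 0
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n_input", "n_identified", "n_excluded_vasopressor",
                 "n_excluded_early_death_or_transfer", "n_analyzed",
                 "n_not_identified_age", "n_not_identified_timing")}


def apply_eligibility(records: list[RawPatientRecord],
                      drug_dict: dict[str, str] | None = None,
                      require_thoracostomy: bool = True,
                      thoracostomy_day01: bool = False) -> EligibilityResult:
    """Apply inclusion and exclusion rules, reason-coding each record.

    Inclusion failures (age < 40, no thoracostomy/day-0/1 intravenous
    antibiotic) leave a record outside ``n_identified``; the two exclusion
    rules partition ``n_identified`` with ``n_analyzed``. By default
    thoracostomy may occur on any day; ``thoracostomy_day01`` restricts it to
    day 0/1 as well.
    """
    if drug_dict is None:
        drug_dict = load_drug_dictionary()
    res = EligibilityResult(n_input=len(records))
    for rec in records:
        if rec.age < 40:
            res.n_not_identified_age += 1
            res.reasons.append("age")
            continue
        has_thora = any(code in THORACOSTOMY_CODES
                        and (not thoracostomy_day01 or day in (0, 1))
                        for code, day in rec.procedure_events)
        ok_thora = has_thora or not require_thoracostomy
        if not ok_thora or not _day01_antibiotics(rec, drug_dict):
            res.n_not_identified_timing += 1
            res.reasons.append("antibiotic_timing")
            continue
        res.n_identified += 1
        if _has_day01_vasopressor(rec, drug_dict):
            res.n_excluded_vasopressor += 1
            res.reasons.append("vasopressor")
            continue
        if rec.death_day == 0 or rec.transfer_day == 0:
            res.n_excluded_early_death_or_transfer += 1
            res.reasons.append("early_death_or_transfer")
            continue
        res.n_analyzed += 1
        res.reasons.append("eligible")
    return res


def classify_exposure(record: RawPatientRecord, drug_dict: dict[str, str]) -> str:
    """'anti_pseudomonal' if ANY day-0/1 intravenous antibiotic is
    anti-pseudomonal, else 'non_anti_pseudomonal'."""
    abx = _day01_antibiotics(record, drug_dict)
    if not abx:
        raise ContractViolation(
            f"{record.patient_id}: no day-0/1 intravenous antibiotic; "
            "record should have been filtered by eligibility")
    if any(drug_dict[c] == "anti_pseudomonal" for c in abx):
        return "anti_pseudomonal"
    return "non_anti_pseudomonal"


def derive_covariates(record: RawPatientRecord) -> dict:
    """Derive the categorical analysis covariates; missing source fields
    yield NaN and mark the row incomplete.

    Cutpoints: ADL dependence = Barthel < 50; low exercise tolerance =
    Hugh-Jones class > 3; abnormal mental status = JCS > 0; BUN bins
    [0,14), [14,22.4), [22.4,inf) mg/dL; low albumin <= 2.7 g/dL.
    """
    record.validate()
    cov: dict = {
        "age": float(record.age),
        "male": 1.0 if record.sex == "male" else 0.0,
        "immunodeficiency": float(record.immunodeficiency),
        "prior_antibiotics_90d": float(record.prior_antibiotics_90d),
        "dialysis": float(record.dialysis),
        "residence_healthcare_facility": float(record.residence_healthcare_facility),
        "source_hospital_nursing": 1.0 if record.source_of_infection in ("hospital", "nursing") else 0.0,
        "oxygen_use": float(record.oxygen_on_admission),
    }
    cov["adl_dependent"] = np.nan if record.barthel is None else float(record.barthel < 50)
    cov["low_exercise_tolerance"] = (np.nan if record.hugh_jones is None
                                     else float(record.hugh_jones > 3))
    cov["abnormal_mental_status"] = np.nan if record.jcs is None else float(record.jcs > 0)
    if record.bun is None:
        cov["bun_category"] = None
        cov["bun_mid"] = cov["bun_high"] = np.nan
    else:
        if record.bun < 14.0:
            cov["bun_category"] = "<14"
        elif record.bun < 22.4:
            cov["bun_category"] = "14-<22.4"
        else:
            cov["bun_category"] = ">=22.4"
        cov["bun_mid"] = float(cov["bun_category"] == "14-<22.4")
        cov["bun_high"] = float(cov["bun_category"] == ">=22.4")
    cov["low_albumin"] = np.nan if record.albumin is None else float(record.albumin <= 2.7)
    cov["complete_case"] = not any(
        isinstance(v, float) and np.isnan(v) for v in cov.values())
    return cov


def derive_outcomes(record: RawPatientRecord, horizon: int = 90):
    """Follow-up time and event indicator per cause.

    Returns ``(time_surgery, event_surgery, time_death, event_death)``.
    For surgery, death is the competing event; for death, surgery is not.
    Loss to follow-up / transfer censors both; everyone is administratively
    censored at ``horizon``.
    """
    inf = float("inf")
    censor = min(record.lost_to_followup_day if record.lost_to_followup_day is not None else inf,
                 record.transfer_day if record.transfer_day is not None else inf,
                 horizon)
    death = record.death_day if record.death_day is not None else inf
    surgery = record.surgery_day if record.surgery_day is not None else inf

    t_d = min(death, censor)
    e_d = int(death <= censor and death <= horizon)
    t_s = min(surgery, death, censor)
    e_s = int(surgery <= min(death, censor) and surgery <= horizon)
    return float(t_s), e_s, float(t_d), e_d


def flag_mdr_risk(covariates: dict) -> bool:
    """At least one risk factor for multidrug-resistant organisms."""
    return any(bool(covariates.get(k)) for k in MDR_RISK_FACTORS)


def build_analysis_table(records: list[RawPatientRecord],
                         drug_dict: dict[str, str] | None = None,
                         horizon: int = 90,
                         **eligibility_kwargs):
    """Run the full cohort build: eligibility, exposure, covariates, outcomes.

    Returns ``(EligibilityResult, DataFrame)`` with one analysis row per
    eligible record. ``death_90d`` is the binary 90-day death status used by
    the bias analysis (censored-before-90 records keep their last-seen
    status of alive).
    """
    if drug_dict is None:
        drug_dict = load_drug_dictionary()
    elig = apply_eligibility(records, drug_dict, **eligibility_kwargs)
    rows = []
    for rec, reason in zip(records, elig.reasons):
        if reason != "eligible":
            continue
        cov = derive_covariates(rec)
        t_s, e_s, t_d, e_d = derive_outcomes(rec, horizon)
        row = {
            "patient_id": rec.patient_id,
            "exposure_label": classify_exposure(rec, drug_dict),
            **cov,
            "time_surgery": t_s, "event_surgery": e_s,
            "time_death": t_d, "event_death": e_d,
            "death_90d": e_d,
        }
        row["exposure"] = 1 if row["exposure_label"] == "anti_pseudomonal" else 0
        row["mdr_risk"] = flag_mdr_risk(cov)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        # eligible rows must not carry a day-0 death
        assert (df.loc[df.event_death == 1, "time_death"] > 0).all()
    return elig, df
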