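"""Eligibility rules, exposure classification, covariate derivation and
cause-specific outcome construction."""

import numpy as np
import pytest

from empyema_pba import GeneratorConfig, generate_cohort
from empyema_pba.cohort import (
    apply_eligibility,
    build_analysis_table,
    classify_exposure,
    derive_covariates,
    derive_outcomes,
    flag_mdr_risk,
)
from empyema_pba.exceptions import ContractViolation, RecordValidationError
from empyema_pba.records import RawPatientRecord
from conftest import make_record


def selection_flow_fixture():
    """888 identified records of which 32 carry a day-0/1 vasopressor and one
    died within 24 h."""
    cfg = GeneratorConfig(n_total=888, seed=17)
    cfg.ineligible_fracs = {k: 0.0 for k in cfg.ineligible_fracs}
    records = generate_cohort(cfg)
    for rec in records[:32]:
        rec.drug_events.append(("noradrenaline", 0))
    records[40].death_day = 0
    records[40].surgery_day = None
    records[40].lost_to_followup_day = None
    return records


class TestEligibility:
    def test_selection_flow_counts(self, drug_dict):
        res = apply_eligibility(selection_flow_fixture(), drug_dict)
        assert res.n_identified == 888
        assert res.n_excluded_vasopressor == 32
        assert res.n_excluded_early_death_or_transfer == 1
        assert res.n_analyzed == 855

    def test_partition_invariant(self, drug_dict):
        records = generate_cohort(GeneratorConfig(n_total=500, seed=23))
        res = apply_eligibility(records, drug_dict)
        assert res.n_analyzed == (res.n_identified - res.n_excluded_vasopressor
                                  - res.n_excluded_early_death_or_transfer)
        assert res.n_input == (res.n_identified + res.n_not_identified_age
                               + res.n_not_identified_timing)
        assert len(res.reasons) == res.n_input

    def test_age_boundary(self, drug_dict):
        res = apply_eligibility([make_record(age=39.0)], drug_dict)
        assert res.reasons == ["age"]
        res = apply_eligibility([make_record(age=40.0)], drug_dict)
        assert res.reasons == ["eligible"]

    def test_antibiotic_outside_window(self, drug_dict):
        rec = make_record(drug_events=[("ampicillin_sulbactam", 2)])
        res = apply_eligibility([rec], drug_dict)
        assert res.reasons == ["antibiotic_timing"]

    def test_transfer_within_24h_excluded(self, drug_dict):
        res = apply_eligibility([make_record(transfer_day=0)], drug_dict)
        assert res.reasons == ["early_death_or_transfer"]

    def test_reason_precedence_age_first(self, drug_dict):
        rec = make_record(age=30.0, drug_events=[("ampicillin_sulbactam", 0),
                                                 ("noradrenaline", 0)])
        res = apply_eligibility([rec], drug_dict)
        assert res.reasons == ["age"]

    def test_empty_input(self, drug_dict):
        res = apply_eligibility([], drug_dict)
        assert res.n_input == res.n_analyzed == 0


class TestExposure:
    def test_any_anti_pseudomonal_wins(self, drug_dict):
        rec = make_record(drug_events=[("piperacillin_tazobactam", 0),
                                       ("vancomycin", 0)])
        assert classify_exposure(rec, drug_dict) == "anti_pseudomonal"

    def test_non_anti_pseudomonal_only(self, drug_dict):
        rec = make_record(drug_events=[("ampicillin_sulbactam", 0)])
        assert classify_exposure(rec, drug_dict) == "non_anti_pseudomonal"

    def test_day1_anti_pseudomonal_counts(self, drug_dict):
        rec = make_record(drug_events=[("ampicillin_sulbactam", 0),
                                       ("meropenem", 1)])
        assert classify_exposure(rec, drug_dict) == "anti_pseudomonal"

    def test_no_antibiotic_is_contract_violation(self, drug_dict):
        rec = make_record(drug_events=[("noradrenaline", 0)])
        with pytest.raises(ContractViolation):
            classify_exposure(rec, drug_dict)


class TestCovariates:
    @pytest.mark.parametrize("bun,expected", [
        (13.9, "<14"), (14.0, "14-<22.4"), (22.3, "14-<22.4"), (22.4, ">=22.4"),
    ])
    def test_bun_bins(self, bun, expected):
        assert derive_covariates(make_record(bun=bun))["bun_category"] == expected

    @pytest.mark.parametrize("albumin,low", [(2.7, 1.0), (2.8, 0.0)])
    def test_albumin_boundary(self, albumin, low):
        assert derive_covariates(make_record(albumin=albumin))["low_albumin"] == low

    @pytest.mark.parametrize("barthel,dep", [(49, 1.0), (50, 0.0)])
    def test_barthel_boundary(self, barthel, dep):
        assert derive_covariates(make_record(barthel=barthel))["adl_dependent"] == dep

    @pytest.mark.parametrize("hj,low", [(3, 0.0), (4, 1.0)])
    def test_hugh_jones_boundary(self, hj, low):
        cov = derive_covariates(make_record(hugh_jones=hj))
        assert cov["low_exercise_tolerance"] == low

    def test_jcs_boundary(self):
        assert derive_covariates(make_record(jcs=0))["abnormal_mental_status"] == 0.0
        assert derive_covariates(make_record(jcs=1))["abnormal_mental_status"] == 1.0

    def test_missing_marks_incomplete(self):
        cov = derive_covariates(make_record(bun=None))
        assert cov["bun_category"] is None
        assert not cov["complete_case"]
        assert derive_covariates(make_record())["complete_case"]

    @pytest.mark.parametrize("bad", [{"barthel": 101}, {"bun": -3.0}, {"albumin": -1.0},
                                     {"hugh_jones": 6}])
    def test_out_of_range_raw_values(self, bad):
        with pytest.raises(RecordValidationError):
            derive_covariates(make_record(**bad))


class TestOutcomes:
    def test_death_censors_surgery(self):
        t_s, e_s, t_d, e_d = derive_outcomes(make_record(death_day=30))
        assert (t_s, e_s) == (30.0, 0)
        assert (t_d, e_d) == (30.0, 1)

    def test_loss_to_followup_censors_both(self):
        t_s, e_s, t_d, e_d = derive_outcomes(make_record(lost_to_followup_day=45))
        assert (t_s, e_s, t_d, e_d) == (45.0, 0, 45.0, 0)

    def test_surgery_does_not_preclude_death(self):
        t_s, e_s, t_d, e_d = derive_outcomes(make_record(surgery_day=10, death_day=40))
        assert (t_s, e_s) == (10.0, 1)
        assert (t_d, e_d) == (40.0, 1)

    def test_same_day_surgery_and_death(self):
        t_s, e_s, t_d, e_d = derive_outcomes(make_record(surgery_day=25, death_day=25))
        assert (t_s, e_s) == (25.0, 1)
        assert (t_d, e_d) == (25.0, 1)

    def test_admin_censoring_at_horizon(self):
        t_s, e_s, t_d, e_d = derive_outcomes(make_record(death_day=120))
        assert (t_s, e_s, t_d, e_d) == (90.0, 0, 90.0, 0)

    def test_event_on_day_90_counts(self):
        _, _, t_d, e_d = derive_outcomes(make_record(death_day=90))
        assert (t_d, e_d) == (90.0, 1)

    def test_hand_enumerated_five_records(self):
        """Risk-set enumeration fixture: the cause-specific representation of
        five archetypal patients."""
        recs = [make_record(patient_id=str(i), **kw) for i, kw in enumerate([
            dict(surgery_day=5),
            dict(death_day=8),
            dict(surgery_day=12, death_day=20),
            dict(lost_to_followup_day=15),
            dict(),
        ])]
        got = [derive_outcomes(r) for r in recs]
        assert got == [(5.0, 1, 90.0, 0),
                       (8.0, 0, 8.0, 1),
                       (12.0, 1, 20.0, 1),
                       (15.0, 0, 15.0, 0),
                       (90.0, 0, 90.0, 0)]


class TestMdrRisk:
    def test_single_factor_flags(self):
        cov = derive_covariates(make_record(dialysis=True))
        assert flag_mdr_risk(cov)

    def test_no_factor(self):
        assert not flag_mdr_risk(derive_covariates(make_record()))

    @pytest.mark.parametrize("factor", ["residence_healthcare_facility",
                                        "immunodeficiency", "prior_antibiotics_90d"])
    def test_each_factor(self, factor):
        assert flag_mdr_risk(derive_covariates(make_record(**{factor: True})))


def test_build_analysis_table_invariants(default_cohort):
    elig, df = default_cohort
    assert len(df) == elig.n_analyzed
    assert (df.time_surgery <= 90).all() and (df.time_death <= 90).all()
    assert (df.time_surgery >= 0).all()
    assert (df.loc[df.event_death == 1, "time_death"] > 0).all()
    # surgery time never exceeds death time (competing-risk representation)
    assert (df.time_surgery <= df.time_death).all()


def test_complete_case_all_true_without_missingness(drug_dict):
    cfg = GeneratorConfig(n_total=400, seed=31, missing_rate=0.0)
    _, df = build_analysis_table(generate_cohort(cfg), drug_dict)
    assert df.complete_case.all()
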