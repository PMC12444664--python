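from __future__ import annotations

from datetime import date, timedelta

import pytest

from hnclaims.cohort import (
    SelectionConfig,
    attrition_log,
    baseline_table,
    compute_eci,
    determine_index_date,
    load_default_eci_mapping,
    select_cohort,
    select_patient,
)
from hnclaims.io import percentage
from hnclaims.model import (
    ClaimsBundle,
    DiagnosisClaim,
    PatientRecord,
    Setting,
    Sex,
    Stage,
    StagingClaim,
)


def patient(pid="Q1", birth_year=1950, **kw):
    defaults = dict(
        enroll_start=date(2016, 1, 1),
        enroll_end=date(2021, 12, 31),
        sex=Sex.MALE,
    )
    defaults.update(kw)
    return PatientRecord(patient_id=pid, birth_year=birth_year, **defaults)


def bundle(diagnoses=(), staging=(), **kw):
    b = ClaimsBundle(patient=patient(**kw))
    for d, code, setting, primary in diagnoses:
        b.diagnoses.append(DiagnosisClaim("Q1", d, code, setting, primary))
    for d, st in staging:
        b.staging.append(StagingClaim("Q1", d, st))
    return b.sort()


CFG = SelectionConfig()


class TestIndexDate:
    def test_inpatient_dx_with_stage_in_window(self):
        b = bundle(
            diagnoses=[(date(2018, 3, 1), "C32.0", Setting.INPATIENT, True)],
            staging=[(date(2018, 3, 20), Stage.III)],
        )
        assert determine_index_date(b, CFG) == date(2018, 3, 1)

    def test_single_outpatient_claim_not_confirmed(self):
        b = bundle(
            diagnoses=[(date(2019, 1, 10), "C10.9", Setting.OUTPATIENT, True)],
            staging=[(date(2019, 1, 20), Stage.IVA)],
        )
        assert determine_index_date(b, CFG) is None
        assert select_patient(b, CFG).exclusion_reason == "no_confirmed_dx"

    def test_two_outpatient_primary_claims_confirm_earliest(self):
        b = bundle(
            diagnoses=[
                (date(2019, 1, 10), "C10.9", Setting.OUTPATIENT, True),
                (date(2019, 2, 1), "C10.9", Setting.OUTPATIENT, True),
            ],
            staging=[(date(2019, 2, 15), Stage.IVA)],
        )
        assert determine_index_date(b, CFG) == date(2019, 1, 10)

    @pytest.mark.parametrize("delta,found", [(60, True), (61, False)])
    def test_staging_window_boundary(self, delta, found):
        b = bundle(
            diagnoses=[(date(2018, 3, 1), "C32.0", Setting.INPATIENT, True)],
            staging=[(date(2018, 3, 1) + timedelta(days=delta), Stage.III)],
        )
        assert (determine_index_date(b, CFG) is not None) == found

    def test_stage_claim_may_precede_diagnosis(self):
        b = bundle(
            diagnoses=[(date(2018, 3, 1), "C32.0", Setting.INPATIENT, True)],
            staging=[(date(2018, 2, 1), Stage.IVB)],
        )
        assert determine_index_date(b, CFG) == date(2018, 3, 1)

    def test_dx_outside_accrual_window_ignored(self):
        b = bundle(
            diagnoses=[(date(2015, 6, 1), "C32.0", Setting.INPATIENT, True)],
            staging=[(date(2015, 6, 10), Stage.III)],
        )
        assert determine_index_date(b, CFG) is None

    def test_non_la_stage_does_not_qualify(self):
        b = bundle(
            diagnoses=[(date(2018, 3, 1), "C32.0", Setting.INPATIENT, True)],
            staging=[(date(2018, 3, 5), Stage.II)],
        )
        assert determine_index_date(b, CFG) is None
        assert select_patient(b, CFG).exclusion_reason == "no_valid_stage"


class TestExclusions:
    def _eligible_bundle(self, **kw):
        return bundle(
            diagnoses=[(date(2018, 3, 1), "C32.0", Setting.INPATIENT, True)],
            staging=[(date(2018, 3, 10), Stage.III)],
            **kw,
        )

    def test_under_18_excluded(self):
        b = self._eligible_bundle(birth_year=2003)
        assert select_patient(b, CFG).exclusion_reason == "age"

    def test_prior_metastasis_code_excluded(self):
        b = self._eligible_bundle()
        b.diagnoses.append(
            DiagnosisClaim("Q1", date(2018, 1, 30), "C78.0", Setting.INPATIENT, False)
        )
        assert select_patient(b.sort(), CFG).exclusion_reason == "prior_metastasis"

    def test_prior_low_stage_excluded(self):
        b = self._eligible_bundle()
        b.staging.append(StagingClaim("Q1", date(2017, 6, 1), Stage.I))
        assert select_patient(b.sort(), CFG).exclusion_reason == "prior_other_stage"

    def test_other_primary_cancer_in_pre_index_excluded(self):
        b = self._eligible_bundle()
        b.diagnoses.append(
            DiagnosisClaim("Q1", date(2017, 9, 1), "C61", Setting.OUTPATIENT, False)
        )
        assert select_patient(b.sort(), CFG).exclusion_reason == "other_primary_cancer"

    def test_short_pre_index_enrollment_excluded(self):
        b = self._eligible_bundle(enroll_start=date(2018, 1, 1))
        assert select_patient(b, CFG).exclusion_reason == "insufficient_pre_index"

    def test_chemo_only_excluded_but_neck_dissection_exempts(self):
        from hnclaims.model import Agent, DrugClaim, ProcedureCategory, ProcedureClaim

        b = self._eligible_bundle()
        b.drugs.append(DrugClaim("Q1", date(2018, 4, 1), Agent.CISPLATIN, atc="L01XA01"))
        assert select_patient(b.sort(), CFG).exclusion_reason == "chemo_only"
        b.procedures.append(
            ProcedureClaim("Q1", date(2018, 5, 1), ProcedureCategory.NECK_DISSECTION)
        )
        assert select_patient(b.sort(), CFG).eligible

    def test_trial_participation_excluded_last(self):
        b = self._eligible_bundle(in_clinical_trial=True)
        assert select_patient(b, CFG).exclusion_reason == "clinical_trial"

    def test_eligible_record_fields(self):
        rec = select_patient(self._eligible_bundle(), CFG)
        assert rec.eligible and rec.exclusion_reason is None
        assert rec.age_at_index == 68
        assert rec.age_band == "65-75"
        assert rec.site == "larynx"
        assert rec.stage == Stage.III

    def test_verdict_invariant_to_event_order(self):
        b = self._eligible_bundle()
        b.diagnoses.append(
            DiagnosisClaim("Q1", date(2017, 9, 1), "C61", Setting.OUTPATIENT, False)
        )
        r1 = select_patient(b, CFG)
        b.diagnoses.reverse()
        r2 = select_patient(b, CFG)
        assert (r1.eligible, r1.exclusion_reason) == (r2.eligible, r2.exclusion_reason)


class TestEci:
    MAPPING = load_default_eci_mapping()

    def test_weight_table_analytic_bounds(self):
        assert self.MAPPING.max_score == 89
        assert self.MAPPING.min_score == -19
        assert len(self.MAPPING.categories) == 30

    def test_no_comorbidities_scores_zero(self):
        b = bundle(
            diagnoses=[(date(2018, 3, 1), "C32.0", Setting.INPATIENT, True)],
        )
        score, flags = compute_eci(b, date(2018, 3, 1), self.MAPPING)
        assert score == 0
        assert not any(flags.values())

    def test_all_categories_flagged_scores_70(self):
        b = bundle()
        idx = date(2018, 3, 1)
        for prefixes, _ in self.MAPPING.categories.values():
            code = prefixes[0]
            code = code if len(code) > 3 else code  # representative prefix as code
            b.diagnoses.append(
                DiagnosisClaim("Q1", idx - timedelta(days=30), code, Setting.OUTPATIENT, False)
            )
        score, flags = compute_eci(b.sort(), idx, self.MAPPING)
        assert all(flags.values())
        assert score == 70  # 89 - 19

    def test_duplicate_codes_count_once(self):
        idx = date(2018, 3, 1)
        b = bundle()
        for _ in range(3):
            b.diagnoses.append(
                DiagnosisClaim("Q1", idx - timedelta(days=10), "I50.0", Setting.OUTPATIENT, False)
            )
        score1, _ = compute_eci(b.sort(), idx, self.MAPPING)
        b2 = bundle()
        b2.diagnoses.append(
            DiagnosisClaim("Q1", idx - timedelta(days=10), "I50.0", Setting.OUTPATIENT, False)
        )
        score2, _ = compute_eci(b2.sort(), idx, self.MAPPING)
        assert score1 == score2 == 7

    def test_index_date_code_not_counted(self):
        idx = date(2018, 3, 1)
        b = bundle()
        b.diagnoses.append(DiagnosisClaim("Q1", idx, "I50.0", Setting.OUTPATIENT, False))
        score, _ = compute_eci(b.sort(), idx, self.MAPPING)
        assert score == 0

    def test_score_always_within_analytic_range(self):
        import random

        rng = random.Random(3)
        idx = date(2018, 3, 1)
        all_prefixes = [
            p for prefixes, _ in self.MAPPING.categories.values() for p in prefixes
        ]
        for _ in range(50):
            b = bundle()
            for code in rng.sample(all_prefixes, rng.randint(0, 20)):
                b.diagnoses.append(
                    DiagnosisClaim("Q1", idx - timedelta(days=rng.randint(1, 300)),
                                   code, Setting.OUTPATIENT, False)
                )
            score, _ = compute_eci(b.sort(), idx, self.MAPPING)
            assert -19 <= score <= 89


class TestBaselineAndAttrition:
    def test_published_stage_percentages(self):
        counts = {"III": 2266, "IVA": 3577, "IVB": 898}
        total = sum(counts.values())
        assert [percentage(v, total) for v in counts.values()] == [33.6, 53.1, 13.3]

    def test_baseline_partitions_sum_to_n(self, clean_cohort):
        bundles, _ = clean_cohort
        records = select_cohort(bundles)
        table = baseline_table(records)
        n = sum(1 for r in records if r.eligible)
        for var in ("age_band", "sex", "site", "stage"):
            sub = table[table["variable"] == var]
            assert sub["n"].sum() == n

    def test_single_patient_baseline_sd_zero_with_flag(self):
        b = bundle(
            diagnoses=[(date(2018, 3, 1), "C32.0", Setting.INPATIENT, True)],
            staging=[(date(2018, 3, 10), Stage.III)],
        )
        records = select_cohort([b])
        table = baseline_table(records)
        age_row = table[table["variable"] == "age_years"].iloc[0]
        assert age_row["mean"] == age_row["median"]
        assert age_row["sd"] == 0.0
        assert age_row["flag"] == "sd_undefined_reported_0"

    def test_empty_cohort_baseline_is_empty_table(self):
        assert baseline_table([]).empty

    def test_attrition_counts_match_truth_table(self, contaminated_cohort):
        bundles, truth = contaminated_cohort
        records = select_cohort(bundles)
        log = attrition_log(records)
        values = list(log.values())
        assert all(a >= b for a, b in zip(values[:-1], values[1:]))
        assert log["eligible"] == int(truth["eligible"].sum())
        by_reason = truth.loc[~truth["eligible"], "exclusion_reason"].value_counts()
        got = {}
        for r in records:
            if not r.eligible:
                got[r.exclusion_reason] = got.get(r.exclusion_reason, 0) + 1
        assert got == by_reason.to_dict()

    def test_attrition_without_contaminants_is_flat(self, clean_cohort):
        bundles, _ = clean_cohort
        records = select_cohort(bundles)
        log = attrition_log(records)
        assert len(set(log.values())) == 1
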