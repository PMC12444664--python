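"""Cohort construction: index date, inclusion/exclusion cascade, baselines.

The target population is adults with newly diagnosed locally advanced
(TNM stage III-IVB) squamous cell carcinoma of the head and neck in four
sites: oral cavity, oropharynx, hypopharynx, larynx.  The index date is the
first confirmed locally advanced diagnosis inside the accrual window; a
confirmed diagnosis needs either one inpatient HNC code or two outpatient
claims with a primary HNC code, plus a stage III/IVA/IVB claim within the
staging window of the diagnosis.

The exclusion cascade is evaluated in a fixed order and only the first
failing criterion is recorded, so the attrition log is a sequential flow.
Comorbidity burden is summarized with the Elixhauser Comorbidity Index
(30 ICD-10-coded categories, van Walraven weights; attainable range
-19 .. +89), shipped as an editable table ``data/eci_weights.csv``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ClaimsBundle, Setting, Sex, Stage, normalize_icd10

__all__ = [
    "SITE_CODES",
    "SelectionConfig",
    "CohortRecord",
    "EciMapping",
    "load_default_eci_mapping",
    "determine_index_date",
    "apply_exclusions",
    "compute_eci",
    "select_patient",
    "select_cohort",
    "baseline_table",
    "attrition_log",
    "EXCLUSION_ORDER",
]

# ICD-10 three-character prefixes per primary tumor site (dots removed).
SITE_CODES: dict[str, tuple[str, ...]] = {
    "oral_cavity": ("C00", "C02", "C03", "C04", "C05", "C06"),
    "oropharynx": ("C01", "C09", "C10"),
    "hypopharynx": ("C12", "C13"),
    "larynx": ("C32",),
}

LA_STAGES = (Stage.III, Stage.IVA, Stage.IVB)
NON_LA_STAGES = (Stage.I, Stage.II, Stage.IVC)

# Cascade order: inclusion steps first (confirmed diagnosis, valid stage),
# then exclusions in the order they are listed for the study population.
EXCLUSION_ORDER = (
    "no_confirmed_dx",
    "no_valid_stage",
    "age",
    "prior_metastasis",
    "prior_other_stage",
    "other_primary_cancer",
    "insufficient_pre_index",
    "chemo_only",
    "clinical_trial",
)


@dataclass(slots=True)
class SelectionConfig:
    diagnosis_window: tuple[date, date] = (date(2016, 1, 1), date(2021, 6, 30))
    staging_window_days: int = 60
    pre_index_days: int = 365
    min_age: int = 18
    treated_window_days: int = 183
    metastasis_prefixes: tuple[str, ...] = ("C78", "C79")
    site_codes: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(SITE_CODES)
    )

    @property
    def hnc_prefixes(self) -> tuple[str, ...]:
        return tuple(p for codes in self.site_codes.values() for p in codes)


@dataclass(slots=True)
class CohortRecord:
    patient_id: str
    index_date: Optional[date]
    eligible: bool
    exclusion_reason: Optional[str]
    age_at_index: Optional[int]
    age_band: Optional[str]
    sex: Sex
    site: Optional[str]
    stage: Optional[Stage]
    lymph_node: str
    eci_score: Optional[int]
    follow_up_days: Optional[int]


# ---------------------------------------------------------------------------
# Elixhauser Comorbidity Index


@dataclass(slots=True)
class EciMapping:
    """30 comorbidity categories, each an ICD-10 prefix set and a weight."""

    categories: dict[str, tuple[tuple[str, ...], int]]

    @classmethod
    def from_csv(cls, path: str | Path) -> "EciMapping":
        df = pd.read_csv(path)
        cats = {
            str(r.category): (
                tuple(p.strip().upper() for p in str(r.icd10_prefixes).split(";") if p.strip()),
                int(r.weight),
            )
            for r in df.itertuples(index=False)
        }
        return cls(categories=cats)

    def weight(self, category: str) -> int:
        return self.categories[category][1]

    @property
    def max_score(self) -> int:
        return sum(w for _, w in self.categories.values() if w > 0)

    @property
    def min_score(self) -> int:
        return sum(w for _, w in self.categories.values() if w < 0)

    def flag(self, code: str) -> list[str]:
        """Categories whose prefix set matches a (normalized) ICD-10 code."""
        norm = normalize_icd10(code)
        return [
            cat
            for cat, (prefixes, _) in self.categories.items()
            if any(norm.startswith(p) for p in prefixes)
        ]


def load_default_eci_mapping() -> EciMapping:
    ref = importlib.resources.files("hnclaims") / "data" / "eci_weights.csv"
    with importlib.resources.as_file(ref) as path:
        return EciMapping.from_csv(path)


def compute_eci(
    bundle: ClaimsBundle,
    index_date: date,
    mapping: EciMapping,
    *,
    pre_index_days: int = 365,
) -> tuple[int, dict[str, bool]]:
    """Score pre-index comorbidity burden.

    A category is flagged if any diagnosis claim strictly before the index
    date and within the pre-index window carries a code matching its prefix
    set; duplicate codes within a category count once.  The score is the sum
    of weights over flagged categories.
    """
    lo = index_date - timedelta(days=pre_index_days)
    flags = {cat: False for cat in mapping.categories}
    for dx in bundle.diagnoses:
        if lo <= dx.date < index_date:
            for cat in mapping.flag(dx.icd10):
                flags[cat] = True
    score = sum(mapping.weight(cat) for cat, on in flags.items() if on)
    return score, flags


# ---------------------------------------------------------------------------
# index date


def _site_of(code: str, config: SelectionConfig) -> Optional[str]:
    norm = normalize_icd10(code)
    for site, prefixes in config.site_codes.items():
        if any(norm.startswith(p) for p in prefixes):
            return site
    return None


def _is_hnc(code: str, config: SelectionConfig) -> bool:
    return _site_of(code, config) is not None


def determine_index_date(
    bundle: ClaimsBundle, config: SelectionConfig
) -> Optional[date]:
    """Earliest confirmed LA HNC diagnosis date inside the accrual window.

    Confirmation: the candidate claim is inpatient, or it is an outpatient
    primary-diagnosis claim and the patient has >= 2 outpatient primary HNC
    claims overall (the confirming claim may fall outside the window).  The
    candidate must additionally have a stage III/IVA/IVB claim within
    ``staging_window_days`` (the window is two-sided).
    """
    lo, hi = config.diagnosis_window
    hnc = [d for d in bundle.diagnoses if _is_hnc(d.icd10, config)]
    n_outpatient_primary = sum(
        1 for d in hnc if d.setting == Setting.OUTPATIENT and d.primary_dx
    )
    la_stage_dates = [s.date for s in bundle.staging if s.stage in LA_STAGES]

    w = config.staging_window_days
    for d in sorted(hnc, key=lambda c: c.date):
        if not (lo <= d.date <= hi):
            continue
        confirmed = d.setting == Setting.INPATIENT or (
            d.setting == Setting.OUTPATIENT
            and d.primary_dx
            and n_outpatient_primary >= 2
        )
        if not confirmed:
            continue
        if any(abs((s - d.date).days) <= w for s in la_stage_dates):
            return d.date
    return None


def _has_confirmed_dx(bundle: ClaimsBundle, config: SelectionConfig) -> bool:
    lo, hi = config.diagnosis_window
    hnc = [d for d in bundle.diagnoses if _is_hnc(d.icd10, config)]
    n_out = sum(1 for d in hnc if d.setting == Setting.OUTPATIENT and d.primary_dx)
    for d in hnc:
        if not (lo <= d.date <= hi):
            continue
        if d.setting == Setting.INPATIENT:
            return True
        if d.setting == Setting.OUTPATIENT and d.primary_dx and n_out >= 2:
            return True
    return False


# ---------------------------------------------------------------------------
# exclusion cascade


def _first_failure(bundle: ClaimsBundle, index_date: date, config: SelectionConfig) -> Optional[str]:
    p = bundle.patient
    age = index_date.year - p.birth_year
    if age < config.min_age:
        return "age"

    met = tuple(config.metastasis_prefixes)
    for dx in bundle.diagnoses:
        if dx.date < index_date and normalize_icd10(dx.icd10).startswith(met):
            return "prior_metastasis"

    for s in bundle.staging:
        if s.date < index_date and s.stage in NON_LA_STAGES:
            return "prior_other_stage"

    pre_lo = index_date - timedelta(days=config.pre_index_days)
    for dx in bundle.diagnoses:
        if pre_lo <= dx.date < index_date:
            norm = normalize_icd10(dx.icd10)
            if (
                norm.startswith("C")
                and not norm.startswith(met)
                and not _is_hnc(dx.icd10, config)
            ):
                return "other_primary_cancer"

    if p.enroll_start > index_date - timedelta(days=config.pre_index_days):
        return "insufficient_pre_index"

    # chemotherapy as the only treatment (non-squamous proxy), unless a neck
    # dissection was also performed; treatment presence is checked over a
    # 12-month post-index horizon so late adjuvant modalities still count;
    # all-cause prescriptions are utilization, not systemic therapy
    from .episodes import is_anticancer

    treated_hi = index_date + timedelta(days=config.treated_window_days)
    horizon = index_date + timedelta(days=365)
    has_systemic = any(
        index_date <= d.date <= treated_hi and is_anticancer(d) for d in bundle.drugs
    )
    if has_systemic:
        cats = {
            pr.category.value
            for pr in bundle.procedures
            if index_date <= pr.date <= horizon
        }
        if (
            "surgery_resection" not in cats
            and "radiotherapy_fraction" not in cats
            and "neck_dissection" not in cats
        ):
            return "chemo_only"

    if p.in_clinical_trial:
        return "clinical_trial"
    return None


def apply_exclusions(
    bundle: ClaimsBundle,
    index_date: date,
    config: SelectionConfig,
    *,
    eci_mapping: Optional[EciMapping] = None,
) -> CohortRecord:
    """Evaluate the exclusion cascade for a patient with a known index date."""
    reason = _first_failure(bundle, index_date, config)
    return _make_record(bundle, index_date, reason, config, eci_mapping)


def _age_band(age: int) -> str:
    if age <= 55:
        return "<=55"
    if age <= 65:
        return "55-65"
    if age <= 75:
        return "65-75"
    return ">75"


def _index_site_stage(
    bundle: ClaimsBundle, index_date: date, config: SelectionConfig
) -> tuple[Optional[str], Optional[Stage]]:
    site = None
    for dx in bundle.diagnoses:
        if dx.date == index_date:
            site = _site_of(dx.icd10, config)
            if site is not None:
                break
    w = config.staging_window_days
    candidates = [
        s
        for s in bundle.staging
        if s.stage in LA_STAGES and abs((s.date - index_date).days) <= w
    ]
    stage = None
    if candidates:
        stage = min(candidates, key=lambda s: (abs((s.date - index_date).days), s.date)).stage
    return site, stage


def _make_record(
    bundle: ClaimsBundle,
    index_date: Optional[date],
    reason: Optional[str],
    config: SelectionConfig,
    eci_mapping: Optional[EciMapping],
) -> CohortRecord:
    p = bundle.patient
    if index_date is None:
        return CohortRecord(
            patient_id=p.patient_id,
            index_date=None,
            eligible=False,
            exclusion_reason=reason,
            age_at_index=None,
            age_band=None,
            sex=p.sex,
            site=None,
            stage=None,
            lymph_node="unknown",
            eci_score=None,
            follow_up_days=None,
        )
    age = index_date.year - p.birth_year
    site, stage = _index_site_stage(bundle, index_date, config)
    end = p.enroll_end
    if p.death_date is not None and p.death_date < end:
        end = p.death_date
    score = None
    if eci_mapping is not None:
        score, _ = compute_eci(
            bundle, index_date, eci_mapping, pre_index_days=config.pre_index_days
        )
    return CohortRecord(
        patient_id=p.patient_id,
        index_date=index_date,
        eligible=reason is None,
        exclusion_reason=reason,
        age_at_index=age,
        age_band=_age_band(age),
        sex=p.sex,
        site=site,
        stage=stage,
        lymph_node="unknown",
        eci_score=score,
        follow_up_days=(end - index_date).days,
    )


def select_patient(
    bundle: ClaimsBundle,
    config: Optional[SelectionConfig] = None,
    *,
    eci_mapping: Optional[EciMapping] = None,
) -> CohortRecord:
    """Run the full cascade (index date + exclusions) for one patient."""
    config = config or SelectionConfig()
    index = determine_index_date(bundle, config)
    if index is None:
        reason = (
            "no_valid_stage"
            if _has_confirmed_dx(bundle, config)
            else "no_confirmed_dx"
        )
        return _make_record(bundle, None, reason, config, eci_mapping)
    return apply_exclusions(bundle, index, config, eci_mapping=eci_mapping)


def select_cohort(
    bundles: Iterable[ClaimsBundle],
    config: Optional[SelectionConfig] = None,
    *,
    eci_mapping: Optional[EciMapping] = None,
) -> list[CohortRecord]:
    config = config or SelectionConfig()
    if eci_mapping is None:
        eci_mapping = load_default_eci_mapping()
    return [select_patient(b, config, eci_mapping=eci_mapping) for b in bundles]


# ---------------------------------------------------------------------------
# reporting


def _num_summary(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return {"mean": np.nan, "sd": np.nan, "median": np.nan, "min": np.nan, "max": np.nan}
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return {
        "mean": float(np.mean(arr)),
        "sd": sd,
        "median": float(np.median(arr)),
        "min": float(np.min(arr)),
        "max": float(np.max(arr)),
    }


def baseline_table(records: Sequence[CohortRecord]) -> pd.DataFrame:
    """Baseline demographic/clinical characteristics of the eligible cohort.

    Continuous rows (age, follow-up) carry mean/SD/median/min/max; categorical
    rows carry counts and one-decimal percentages.  A single-patient cohort
    reports SD 0 with a flag; an empty cohort yields an empty sentinel table.
    """
    from .io import percentage

    elig = [r for r in records if r.eligible]
    n = len(elig)
    rows: list[dict] = []
    if n == 0:
        return pd.DataFrame(
            columns=["variable", "level", "n", "pct", "mean", "sd", "median", "min", "max", "flag"]
        )
    flag = "sd_undefined_reported_0" if n == 1 else ""
    ages = [r.age_at_index for r in elig]
    fups = [r.follow_up_days for r in elig]
    for var, vals in (("age_years", ages), ("follow_up_days", fups)):
        s = _num_summary(vals)
        rows.append({"variable": var, "level": "", "n": n, "pct": np.nan, **s, "flag": flag})

    def cat_rows(var: str, getter, levels: Sequence[str]) -> None:
        for lv in levels:
            k = sum(1 for r in elig if getter(r) == lv)
            rows.append(
                {
                    "variable": var, "level": lv, "n": k, "pct": percentage(k, n),
                    "mean": np.nan, "sd": np.nan, "median": np.nan,
                    "min": np.nan, "max": np.nan, "flag": "",
                }
            )

    cat_rows("age_band", lambda r: r.age_band, ["<=55", "55-65", "65-75", ">75"])
    cat_rows("sex", lambda r: r.sex.value, [s.value for s in Sex])
    cat_rows("site", lambda r: r.site, list(SITE_CODES))
    cat_rows("stage", lambda r: r.stage, list(LA_STAGES))
    return pd.DataFrame(rows)


def attrition_log(records: Sequence[CohortRecord]) -> dict[str, int]:
    """Ordered, non-increasing patient counts through the selection cascade."""
    n = len(records)
    reasons = [r.exclusion_reason for r in records]
    steps = {"all_patients": n}
    remaining = n
    labels = {
        "no_confirmed_dx": "confirmed_hnc_diagnosis",
        "no_valid_stage": "valid_la_stage",
        "age": "age_18_plus",
        "prior_metastasis": "no_prior_metastasis",
        "prior_other_stage": "no_prior_other_stage",
        "other_primary_cancer": "no_other_primary_cancer",
        "insufficient_pre_index": "sufficient_pre_index",
        "chemo_only": "not_chemo_only",
        "clinical_trial": "no_clinical_trial",
    }
    for reason in EXCLUSION_ORDER:
        remaining -= sum(1 for r in reasons if r == reason)
        steps[labels[reason]] = remaining
    steps["eligible"] = sum(1 for r in records if r.eligible)
    return steps
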