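"""Seeded synthetic claims generator.

Produces claims cohorts with the statistical structure the analysis
assumes -- per-patient event streams over a 2015-2022 calendar window with
head-and-neck cancer diagnoses at four sites, TNM stage claims, treatment
events realizing configurable pathway mixes, regimen menus per treatment
context, and utilization/cost event processes -- together with a truth
table recording each patient's intended eligibility verdict and pathway,
used as ground truth by the test suite.

Pathway realization is constructive (gaps are drawn inside the legal
ranges the sequencing rules imply), never rejection-based, so every
realized pathway classifies back to its requested label by design.  A
single root seed drives per-patient child streams, making cohorts stable
under changes of ``n_patients``.

Count distributions are negative binomial (moment-matched to published
mean/SD, truncated to >= 1 among users and clipped to the published
min/max); per-event costs are log-normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from math import log
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AdmissionRecord,
    Agent,
    ClaimsBundle,
    DiagnosisClaim,
    DrugClaim,
    PatientRecord,
    ProcedureCategory,
    ProcedureClaim,
    Setting,
    Sex,
    Stage,
    StagingClaim,
)

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "generate_cohort",
    "realize_pathway",
    "attach_hcru_stream",
    "PATHWAYS",
    "DEFAULT_PATHWAY_PROBS",
    "DEFAULT_REGIMEN_MENUS",
]


class ConfigError(ValueError):
    """Degenerate or inconsistent generator configuration."""


# pathway sub-sequence vocabulary (classification sub-labels plus the two
# top-level-only groups)
PATHWAYS = (
    "surgery_alone",
    "surgery_then_crt",
    "surgery_then_rt",
    "chemo_then_surgery",
    "other_resection",
    "crt_alone",
    "rt_alone",
    "chemo_then_rt",
    "rt_then_chemo",
    "chemo_neck_dissection",
    "not_treated",
)

# default pathway mix: published overall pattern counts out of 6741
_PATHWAY_COUNTS = {
    "surgery_alone": 1422,
    "surgery_then_crt": 405,
    "surgery_then_rt": 242,
    "chemo_then_surgery": 91,
    "other_resection": 22,
    "crt_alone": 2655,
    "rt_alone": 437,
    "chemo_then_rt": 331,
    "rt_then_chemo": 38,
    "chemo_neck_dissection": 13,
    "not_treated": 1085,
}
DEFAULT_PATHWAY_PROBS = {k: v / 6741 for k, v in _PATHWAY_COUNTS.items()}

_TOP_OF_PATHWAY = {
    "surgery_alone": "primary_resection",
    "surgery_then_crt": "primary_resection",
    "surgery_then_rt": "primary_resection",
    "chemo_then_surgery": "primary_resection",
    "other_resection": "primary_resection",
    "crt_alone": "definitive_nonsurgical",
    "rt_alone": "definitive_nonsurgical",
    "chemo_then_rt": "definitive_nonsurgical",
    "rt_then_chemo": "definitive_nonsurgical",
    "chemo_neck_dissection": "chemo_neck_dissection",
    "not_treated": "not_treated",
}

_CIS = (Agent.CISPLATIN.value,)
_FP = (Agent.FLUOROURACIL.value, Agent.CISPLATIN.value)
_TPF = (Agent.FLUOROURACIL.value, Agent.CISPLATIN.value, Agent.DOCETAXEL.value)
_PCE = (Agent.CETUXIMAB.value, Agent.PACLITAXEL.value, Agent.CARBOPLATIN.value)

# per-context regimen menus; probabilities follow the published initial-
# chemotherapy distributions (residual mass folded into cisplatin)
DEFAULT_REGIMEN_MENUS: dict[str, list[tuple[tuple[str, ...], float]]] = {
    "crt_backbone": [
        (_CIS, 0.764),
        ((Agent.CETUXIMAB.value,), 0.097),
        (_FP, 0.048),
        (_TPF, 0.022),
        ((Agent.TEGAFUR.value,), 0.022),
        ((Agent.CARBOPLATIN.value,), 0.018),
        ((Agent.NEDAPLATIN.value,), 0.011),
        ((Agent.FLUOROURACIL.value, Agent.CARBOPLATIN.value), 0.009),
        ((Agent.CISPLATIN.value, Agent.DOCETAXEL.value), 0.009),
    ],
    "adjuvant_crt": [
        (_CIS, 0.834),
        ((Agent.CETUXIMAB.value,), 0.054),
        (_FP, 0.030),
        ((Agent.TEGAFUR.value,), 0.030),
        ((Agent.NEDAPLATIN.value,), 0.020),
        ((Agent.CARBOPLATIN.value,), 0.012),
        ((Agent.FLUOROURACIL.value, Agent.CARBOPLATIN.value), 0.010),
        (_TPF, 0.007),
        ((Agent.CISPLATIN.value, Agent.DOCETAXEL.value), 0.003),
    ],
    "induction_pre_surgery": [
        (_FP, 0.462),
        (_TPF, 0.286),
        (_PCE, 0.066),
        (_CIS, 0.186),
    ],
    "induction_pre_rt": [
        (_TPF, 0.556),
        (_FP, 0.254),
        (_PCE, 0.082),
        (_CIS, 0.108),
    ],
}

# (user_probability, mean, sd, min, max) of annual counts, per category
DEFAULT_HCRU_RATES = {
    "physician_visits": (0.941, 18.9, 12.5, 1, 119),
    "admissions": (0.998, 2.2, 1.6, 1, 23),
    "prescriptions": (0.998, 466.4, 410.7, 1, 5221),
    "lab_tests": (0.991, 37.0, 33.1, 1, 347),
    "imaging": (0.855, 3.5, 2.1, 1, 18),
    "rehab_homecare": (0.551, 22.3, 21.8, 1, 241),
}

# mean per-event cost in JPY (published per-user annual mean / mean count)
DEFAULT_COST_PARAMS = {
    "physician_visits": 18315,
    "admissions": 1_641_237,
    "prescriptions": 1358,
    "lab_tests": 2054,
    "imaging": 1487,
    "rehab_homecare": 4155,
    "surgery_resection": 800_000,
    "neck_dissection": 500_000,
    "radiotherapy_fraction": 30_000,
    "anticancer_admin": 40_000,
}

DEFAULT_CONTAMINANT_PROBS = {
    "age": 0.02,
    "prior_metastasis": 0.03,
    "prior_other_stage": 0.03,
    "other_primary_cancer": 0.03,
    "insufficient_pre_index": 0.04,
    "chemo_only": 0.03,
    "clinical_trial": 0.02,
}

DEFAULT_SITE_PROBS = {
    "oral_cavity": 1749 / 6741,
    "oropharynx": 1925 / 6741,
    "hypopharynx": 1721 / 6741,
    "larynx": 1346 / 6741,
}
DEFAULT_STAGE_PROBS = {"III": 2266 / 6741, "IVA": 3577 / 6741, "IVB": 898 / 6741}

_SITE_INDEX_CODE = {
    "oral_cavity": "C04.9",
    "oropharynx": "C10.9",
    "hypopharynx": "C13.9",
    "larynx": "C32.9",
}

# comorbidity menu: ECI category -> (representative ICD-10 code, prevalence);
# independent draws; C-coded categories are deliberately absent because any
# pre-index malignancy code would (correctly) exclude the patient
DEFAULT_COMORBIDITY_MENU = {
    "hypertension": ("I10", 0.40),
    "diabetes_uncomplicated": ("E11.9", 0.20),
    "diabetes_complicated": ("E11.2", 0.04),
    "chronic_pulmonary_disease": ("J44.9", 0.12),
    "cardiac_arrhythmias": ("I48", 0.06),
    "fluid_electrolyte_disorders": ("E87.6", 0.08),
    "congestive_heart_failure": ("I50.0", 0.04),
    "renal_failure": ("N18.3", 0.03),
    "liver_disease": ("K74.6", 0.02),
    "hypothyroidism": ("E03.9", 0.05),
    "depression": ("F32.9", 0.05),
    "peptic_ulcer_disease": ("K25.9", 0.08),
    "valvular_disease": ("I35.0", 0.03),
    "weight_loss": ("R63.4", 0.05),
    "deficiency_anemia": ("D50.9", 0.06),
    "alcohol_abuse": ("F10.2", 0.06),
    "other_neurological_disorders": ("G40.9", 0.02),
    "peripheral_vascular_disorders": ("I70.2", 0.02),
    "coagulopathy": ("D68.9", 0.01),
    "obesity": ("E66.9", 0.03),
    "paralysis": ("G81.1", 0.005),
    "pulmonary_circulation_disorders": ("I27.9", 0.01),
    "psychoses": ("F29", 0.01),
    "rheumatoid_arthritis_collagen": ("M06.9", 0.02),
    "blood_loss_anemia": ("D50.0", 0.01),
    "drug_abuse": ("F19.2", 0.003),
}

_NON_ONCOLOGY_ATC = ("N02BE01", "A02BC01", "C09AA05", "B01AC06", "R03AC02")


@dataclass(slots=True)
class GeneratorConfig:
    n_patients: int = 100
    seed: int = 0
    calendar_window: tuple[date, date] = (date(2015, 1, 1), date(2022, 7, 31))
    accrual_window: tuple[date, date] = (date(2016, 1, 1), date(2021, 6, 30))
    site_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SITE_PROBS))
    stage_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STAGE_PROBS))
    pathway_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATHWAY_PROBS)
    )
    regimen_menus: dict[str, list[tuple[tuple[str, ...], float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_REGIMEN_MENUS.items()}
    )
    hcru_rates: dict[str, tuple[float, float, float, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_HCRU_RATES)
    )
    cost_params: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COST_PARAMS))
    contaminant_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINANT_PROBS)
    )
    comorbidity_menu: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_MENU)
    )
    include_hcru: bool = True
    male_prob: float = 0.809
    age_mean: float = 67.7
    age_sd: float = 11.8
    death_prob: float = 0.08

    def validate(self) -> None:
        for name, vec in (
            ("site_probs", self.site_probs),
            ("stage_probs", self.stage_probs),
            ("pathway_probs", self.pathway_probs),
        ):
            total = float(sum(vec.values()))
            if total <= 0:
                raise ConfigError(f"{name}: all-zero probability vector")
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name}: probabilities sum to {total}, not 1")
            if any(p < 0 for p in vec.values()):
                raise ConfigError(f"{name}: negative probability")
        for ctx, menu in self.regimen_menus.items():
            total = sum(p for _, p in menu)
            if total <= 0:
                raise ConfigError(f"regimen menu {ctx}: all-zero")
        for k in self.pathway_probs:
            if k not in PATHWAYS:
                raise ConfigError(f"unsupported pathway label: {k!r}")
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")


# ---------------------------------------------------------------------------
# helpers


def _choice(rng: np.random.Generator, items: Sequence, probs: Sequence[float]):
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    return items[int(rng.choice(len(items), p=p))]


def _draw_regimen(
    rng: np.random.Generator, config: GeneratorConfig, context: str
) -> tuple[str, ...]:
    menu = config.regimen_menus[context]
    return _choice(rng, [c for c, _ in menu], [p for _, p in menu])


def _lognormal_cost(rng: np.random.Generator, mean: float, sigma: float = 0.5) -> int:
    mu = log(mean) - sigma * sigma / 2.0
    return max(1, int(round(rng.lognormal(mu, sigma))))


def _systemic_cycles(
    rng: np.random.Generator,
    pid: str,
    components: tuple[str, ...],
    anchor: date,
    n_cycles: int,
    cost: int,
) -> list[DrugClaim]:
    """Administrations for one regimen: every component's first dose falls
    within 0-4 days of the anchor (inside the 8-day combination window),
    cycles every 21 days (inside the 60-day lapse rule)."""
    claims = []
    offsets = {c: (0 if i == 0 else int(rng.integers(0, 5))) for i, c in enumerate(components)}
    for cycle in range(n_cycles):
        for comp in components:
            d = anchor + timedelta(days=21 * cycle + offsets[comp])
            claims.append(
                DrugClaim(pid, d, Agent(comp), atc="L01XX00",
                          cost=_lognormal_cost(rng, cost))
            )
    return claims


def _rt_course(
    rng: np.random.Generator, pid: str, start: date, cost: int
) -> list[ProcedureClaim]:
    n_fractions = int(rng.integers(30, 36))
    claims = []
    d = start
    for _ in range(n_fractions):
        claims.append(
            ProcedureClaim(pid, d, ProcedureCategory.RADIOTHERAPY_FRACTION,
                           cost=_lognormal_cost(rng, cost, 0.2))
        )
        # daily fractions with weekend-like skips, never > 3-day gaps
        d = d + timedelta(days=int(rng.integers(1, 3)))
    return claims


# ---------------------------------------------------------------------------
# pathway realization


def realize_pathway(
    label: str,
    index_date: date,
    rng: np.random.Generator,
    config: Optional[GeneratorConfig] = None,
) -> tuple[list[DrugClaim], list[ProcedureClaim], Optional[tuple[str, ...]]]:
    """Emit treatment events realizing a pathway sub-sequence.

    Returns (drug claims, procedure claims, regimen drawn or None).  Gaps
    are drawn strictly inside the windows each label implies: a sequential
    (induction) systemic-to-radiotherapy start gap is 15-75 days, a
    concurrent one 0-14 days; combination components start within 0-4 days
    of the anchor; cycles repeat every 21 days.
    """
    if config is None:
        config = GeneratorConfig()
    if label not in PATHWAYS:
        raise ConfigError(f"unsupported pathway label: {label!r}")
    pid = ""  # patient_id filled by caller
    cp = config.cost_params
    drugs: list[DrugClaim] = []
    procs: list[ProcedureClaim] = []
    regimen: Optional[tuple[str, ...]] = None
    delay = int(rng.integers(5, 61))  # first treatment, well inside 183 days
    t0 = index_date + timedelta(days=delay)

    def surgery(on: date) -> None:
        procs.append(
            ProcedureClaim(pid, on, ProcedureCategory.SURGERY_RESECTION,
                           cost=_lognormal_cost(rng, cp["surgery_resection"]))
        )

    if label == "surgery_alone":
        surgery(t0)
    elif label == "surgery_then_rt":
        surgery(t0)
        procs += _rt_course(rng, pid, t0 + timedelta(days=int(rng.integers(15, 46))),
                            cp["radiotherapy_fraction"])
    elif label == "surgery_then_crt":
        surgery(t0)
        rt_start = t0 + timedelta(days=int(rng.integers(15, 41)))
        procs += _rt_course(rng, pid, rt_start, cp["radiotherapy_fraction"])
        regimen = _draw_regimen(rng, config, "adjuvant_crt")
        sys_start = rt_start + timedelta(days=int(rng.integers(0, 11)))
        drugs += _systemic_cycles(rng, pid, regimen, sys_start, 3, cp["anticancer_admin"])
    elif label == "chemo_then_surgery":
        regimen = _draw_regimen(rng, config, "induction_pre_surgery")
        drugs += _systemic_cycles(rng, pid, regimen, t0, 2, cp["anticancer_admin"])
        surgery(t0 + timedelta(days=int(rng.integers(40, 86))))
    elif label == "other_resection":
        # surgery -> chemotherapy -> radiotherapy, chemo and RT sequential
        surgery(t0)
        chemo_start = t0 + timedelta(days=int(rng.integers(20, 31)))
        regimen = _draw_regimen(rng, config, "induction_pre_rt")
        drugs += _systemic_cycles(rng, pid, regimen, chemo_start, 2, cp["anticancer_admin"])
        rt_start = chemo_start + timedelta(days=int(rng.integers(15, 26)))
        procs += _rt_course(rng, pid, rt_start, cp["radiotherapy_fraction"])
    elif label == "crt_alone":
        procs += _rt_course(rng, pid, t0, cp["radiotherapy_fraction"])
        regimen = _draw_regimen(rng, config, "crt_backbone")
        sys_start = t0 + timedelta(days=int(rng.integers(0, 15)))
        drugs += _systemic_cycles(rng, pid, regimen, sys_start, 3, cp["anticancer_admin"])
    elif label == "rt_alone":
        procs += _rt_course(rng, pid, t0, cp["radiotherapy_fraction"])
    elif label == "chemo_then_rt":
        regimen = _draw_regimen(rng, config, "induction_pre_rt")
        drugs += _systemic_cycles(rng, pid, regimen, t0, 2, cp["anticancer_admin"])
        rt_start = t0 + timedelta(days=int(rng.integers(15, 76)))
        procs += _rt_course(rng, pid, rt_start, cp["radiotherapy_fraction"])
    elif label == "rt_then_chemo":
        procs += _rt_course(rng, pid, t0, cp["radiotherapy_fraction"])
        regimen = _draw_regimen(rng, config, "crt_backbone")
        sys_start = t0 + timedelta(days=int(rng.integers(15, 76)))
        drugs += _systemic_cycles(rng, pid, regimen, sys_start, 2, cp["anticancer_admin"])
    elif label == "chemo_neck_dissection":
        regimen = _draw_regimen(rng, config, "induction_pre_surgery")
        drugs += _systemic_cycles(rng, pid, regimen, t0, 2, cp["anticancer_admin"])
        procs.append(
            ProcedureClaim(pid, t0 + timedelta(days=int(rng.integers(30, 81))),
                           ProcedureCategory.NECK_DISSECTION,
                           cost=_lognormal_cost(rng, cp["neck_dissection"]))
        )
    elif label == "not_treated":
        if rng.random() < 0.3:
            # late systemic therapy, outside the 6-month treated window
            regimen = _draw_regimen(rng, config, "crt_backbone")
            late = index_date + timedelta(days=int(rng.integers(190, 251)))
            drugs += _systemic_cycles(rng, pid, regimen, late, 1, cp["anticancer_admin"])
    return drugs, procs, regimen


# ---------------------------------------------------------------------------
# HCRU stream


def _nb_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    if var <= mean:
        var = mean * 1.5
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return r, p


def attach_hcru_stream(
    bundle: ClaimsBundle,
    index_date: date,
    rng: np.random.Generator,
    hcru_rates: Optional[dict] = None,
    cost_params: Optional[dict] = None,
) -> ClaimsBundle:
    """Attach visit/prescription/lab/imaging/rehab/admission events and costs
    over the first post-index year (clipped to the enrollment span)."""
    rates = hcru_rates if hcru_rates is not None else DEFAULT_HCRU_RATES
    costs = cost_params if cost_params is not None else DEFAULT_COST_PARAMS
    pid = bundle.patient_id
    window = min(365, (bundle.patient.enroll_end - index_date).days)
    if window < 1:
        return bundle

    cat_map = {
        "physician_visits": ProcedureCategory.PHYSICIAN_VISIT,
        "lab_tests": ProcedureCategory.LAB_TEST,
        "imaging": ProcedureCategory.IMAGING,
        "rehab_homecare": ProcedureCategory.REHAB_HOMECARE,
    }
    for cat, (user_prob, mean, sd, lo, hi) in rates.items():
        if user_prob <= 0 or mean <= 0:
            continue
        if rng.random() > user_prob:
            continue
        r, p = _nb_params(mean, sd)
        count = int(np.clip(rng.negative_binomial(r, p), max(1, lo), hi))
        offsets = rng.integers(0, window, size=count)
        if cat == "admissions":
            for off in offsets:
                admit = index_date + timedelta(days=int(off))
                stay = int(rng.integers(3, 21))
                discharge = min(admit + timedelta(days=stay), bundle.patient.enroll_end)
                bundle.admissions.append(
                    AdmissionRecord(pid, admit, discharge,
                                    cost=_lognormal_cost(rng, costs["admissions"], 0.6))
                )
        elif cat == "prescriptions":
            atcs = rng.integers(0, len(_NON_ONCOLOGY_ATC), size=count)
            for off, ai in zip(offsets, atcs):
                bundle.drugs.append(
                    DrugClaim(pid, index_date + timedelta(days=int(off)),
                              Agent.OTHER, atc=_NON_ONCOLOGY_ATC[int(ai)],
                              cost=_lognormal_cost(rng, costs["prescriptions"], 0.8))
                )
        else:
            pc = cat_map[cat]
            for off in offsets:
                bundle.procedures.append(
                    ProcedureClaim(pid, index_date + timedelta(days=int(off)), pc,
                                   cost=_lognormal_cost(rng, costs[cat], 0.4))
                )
    return bundle


# ---------------------------------------------------------------------------
# cohort generation


def _draw_follow_up(rng: np.random.Generator) -> int:
    # log-normal around a ~650-day median, clipped to the observed range
    return int(np.clip(rng.lognormal(log(652.0), 0.65), 60, 2427))


def _generate_patient(
    i: int, config: GeneratorConfig
) -> tuple[ClaimsBundle, dict]:
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, i])
    pid = f"P{i:07d}"
    cal_lo, cal_hi = config.calendar_window
    acc_lo, acc_hi = config.accrual_window

    # contaminant draw (at most one reason per patient)
    reasons = list(config.contaminant_probs)
    probs = [config.contaminant_probs[r] for r in reasons]
    total_cont = sum(probs)
    contaminant: Optional[str] = None
    if total_cont > 0 and rng.random() < total_cont:
        contaminant = _choice(rng, reasons, probs)

    index = acc_lo + timedelta(days=int(rng.integers(0, (acc_hi - acc_lo).days + 1)))
    sites = list(config.site_probs)
    site = _choice(rng, sites, [config.site_probs[s] for s in sites])
    stages = list(config.stage_probs)
    stage = _choice(rng, stages, [config.stage_probs[s] for s in stages])
    sex = Sex.MALE if rng.random() < config.male_prob else Sex.FEMALE
    if contaminant == "age":
        age = int(rng.integers(5, 18))
    else:
        age = int(np.clip(rng.normal(config.age_mean, config.age_sd), 20, 99))
    birth_year = index.year - age

    pathways = list(config.pathway_probs)
    pw_probs = [config.pathway_probs[p] for p in pathways]
    pathway = _choice(rng, pathways, pw_probs)
    if contaminant == "chemo_only":
        pathway = "chemo_neck_dissection"  # realized below without the dissection

    drugs, procs, regimen = realize_pathway(pathway, index, rng, config)
    if contaminant == "chemo_only":
        procs = [p for p in procs if p.category != ProcedureCategory.NECK_DISSECTION]

    last_event = index
    for c in drugs:
        last_event = max(last_event, c.date)
    for c in procs:
        last_event = max(last_event, c.date)

    fu = _draw_follow_up(rng)
    enroll_end = min(
        cal_hi, max(index + timedelta(days=fu), last_event + timedelta(days=30))
    )
    if contaminant == "insufficient_pre_index":
        enroll_start = index - timedelta(days=int(rng.integers(30, 300)))
    else:
        enroll_start = max(
            cal_lo, index - timedelta(days=365 + int(rng.integers(30, 500)))
        )
    death_date = None
    if enroll_end < cal_hi and rng.random() < config.death_prob:
        death_date = enroll_end

    patient = PatientRecord(
        patient_id=pid, birth_year=birth_year, sex=sex,
        enroll_start=enroll_start, enroll_end=enroll_end,
        death_date=death_date,
        in_clinical_trial=(contaminant == "clinical_trial"),
    )
    for c in drugs:
        c.patient_id = pid
    for c in procs:
        c.patient_id = pid
    bundle = ClaimsBundle(patient=patient, drugs=drugs, procedures=procs)

    # diagnosis claims establishing the index date
    if rng.random() < 0.7:
        bundle.diagnoses.append(
            DiagnosisClaim(pid, index, _SITE_INDEX_CODE[site], Setting.INPATIENT, True)
        )
    else:
        bundle.diagnoses.append(
            DiagnosisClaim(pid, index, _SITE_INDEX_CODE[site], Setting.OUTPATIENT, True)
        )
        second = min(index + timedelta(days=int(rng.integers(7, 31))), enroll_end)
        bundle.diagnoses.append(
            DiagnosisClaim(pid, second, _SITE_INDEX_CODE[site], Setting.OUTPATIENT, True)
        )
    bundle.staging.append(
        StagingClaim(pid, index + timedelta(days=int(rng.integers(0, 31))), Stage(stage))
    )

    # pre-index comorbidities
    pre_lo = max(enroll_start, index - timedelta(days=365))
    pre_span = (index - pre_lo).days
    if pre_span > 1:
        for cat, (code, prob) in config.comorbidity_menu.items():
            if rng.random() < prob:
                d = pre_lo + timedelta(days=int(rng.integers(0, pre_span)))
                bundle.diagnoses.append(
                    DiagnosisClaim(pid, d, code, Setting.OUTPATIENT, False)
                )

    # contaminant-defining pre-index events
    if contaminant == "prior_metastasis":
        d = index - timedelta(days=int(rng.integers(30, 200)))
        bundle.diagnoses.append(DiagnosisClaim(pid, d, "C78.0", Setting.INPATIENT, False))
    elif contaminant == "prior_other_stage":
        d = index - timedelta(days=int(rng.integers(70, 300)))
        bundle.staging.append(StagingClaim(pid, d, Stage.I))
    elif contaminant == "other_primary_cancer":
        d = index - timedelta(days=int(rng.integers(30, 300)))
        bundle.diagnoses.append(DiagnosisClaim(pid, d, "C61", Setting.OUTPATIENT, False))

    if config.include_hcru:
        attach_hcru_stream(bundle, index, rng, config.hcru_rates, config.cost_params)

    bundle.sort()

    if contaminant is not None:
        verdict, reason = False, contaminant
        truth_pathway, truth_top = "", ""
    else:
        verdict, reason = True, ""
        truth_pathway, truth_top = pathway, _TOP_OF_PATHWAY[pathway]
    truth = {
        "patient_id": pid,
        "eligible": verdict,
        "exclusion_reason": reason,
        "pathway": truth_pathway,
        "top": truth_top,
        "site": site,
        "stage": stage,
        "regimen": " + ".join(regimen) if regimen else "",
        "index_date": index.isoformat(),
        "follow_up_days": (enroll_end - index).days,
    }
    return bundle, truth


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[ClaimsBundle], pd.DataFrame]:
    """Generate ``n_patients`` claims bundles plus the ground-truth table.

    The truth table records, per patient, the intended eligibility verdict
    (with the exclusion reason for deliberately ineligible "contaminant"
    patients), the assigned pathway label, site, stage and regimen.  The
    same (config, seed) always produces an identical cohort; per-patient
    child seeds make cohorts stable under changes of ``n_patients``.
    """
    config.validate()
    bundles, rows = [], []
    for i in range(config.n_patients):
        b, t = _generate_patient(i, config)
        bundles.append(b)
        rows.append(t)
    return bundles, pd.DataFrame(rows)
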