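"""Core claims data model.

Claims here follow the shape of Japanese hospital administrative data:
per-patient dated streams of diagnoses (ICD-10), TNM staging claims, drug
administrations, procedures and hospital admissions, bounded by an
enrollment (observation) span.  All dates are calendar dates; downstream
window arithmetic is done on whole-day differences because claims carry
day resolution only.  Costs are integer JPY.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from typing import Optional

__all__ = [
    "Sex",
    "Setting",
    "Stage",
    "Agent",
    "ProcedureCategory",
    "PatientRecord",
    "DiagnosisClaim",
    "StagingClaim",
    "DrugClaim",
    "ProcedureClaim",
    "AdmissionRecord",
    "ClaimsBundle",
    "ClaimsValidationError",
    "normalize_icd10",
    "ICD10_RE",
]


class ClaimsValidationError(ValueError):
    """A claims row or bundle violates a model invariant."""


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Setting(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


class Stage(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IVA = "IVA"
    IVB = "IVB"
    IVC = "IVC"


class Agent(str, Enum):
    """Controlled vocabulary of systemic agents relevant to LA SCCHN.

    Unknown drug names are mapped to OTHER (with a warning) rather than
    rejected: all-cause prescription counting must not drop rows, and the
    regimen naming treats "other" as a distinct component.
    """

    CISPLATIN = "cisplatin"
    CARBOPLATIN = "carboplatin"
    NEDAPLATIN = "nedaplatin"
    FLUOROURACIL = "fluorouracil"
    DOCETAXEL = "docetaxel"
    PACLITAXEL = "paclitaxel"
    CETUXIMAB = "cetuximab"
    TEGAFUR = "tegafur_gimeracil_oteracil"
    OTHER = "other"


class ProcedureCategory(str, Enum):
    SURGERY_RESECTION = "surgery_resection"
    NECK_DISSECTION = "neck_dissection"
    RADIOTHERAPY_FRACTION = "radiotherapy_fraction"
    PHYSICIAN_VISIT = "physician_visit"
    LAB_TEST = "lab_test"
    IMAGING = "imaging"
    REHAB_HOMECARE = "rehab_homecare"


# letter + two digits + optional subcode ("C78.0" or compact "C780")
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(?:\.?[0-9A-Z]{1,4})?$")


def normalize_icd10(code: str) -> str:
    """Uppercase and strip the dot so prefix matching is uniform."""
    code = code.strip().upper().replace(".", "")
    if not ICD10_RE.match(code):
        raise ClaimsValidationError(f"malformed ICD-10 code: {code!r}")
    return code


@dataclass(slots=True)
class PatientRecord:
    patient_id: str
    birth_year: int
    sex: Sex
    enroll_start: date
    enroll_end: date
    death_date: Optional[date] = None
    in_clinical_trial: bool = False

    def validate(self) -> None:
        if self.enroll_start > self.enroll_end:
            raise ClaimsValidationError(
                f"patient {self.patient_id}: enroll_start {self.enroll_start} "
                f"after enroll_end {self.enroll_end}"
            )
        if self.death_date is not None and not (
            self.enroll_start <= self.death_date <= self.enroll_end
        ):
            raise ClaimsValidationError(
                f"patient {self.patient_id}: death_date {self.death_date} "
                "outside enrollment span"
            )


@dataclass(slots=True)
class DiagnosisClaim:
    patient_id: str
    date: date
    icd10: str
    setting: Setting
    primary_dx: bool

    def validate(self) -> None:
        normalize_icd10(self.icd10)


@dataclass(slots=True)
class StagingClaim:
    patient_id: str
    date: date
    stage: Stage


@dataclass(slots=True)
class DrugClaim:
    patient_id: str
    date: date
    agent: Agent
    atc: Optional[str] = None
    cost: int = 0

    def validate(self) -> None:
        if self.cost < 0:
            raise ClaimsValidationError(
                f"patient {self.patient_id}: negative drug cost on {self.date}"
            )


@dataclass(slots=True)
class ProcedureClaim:
    patient_id: str
    date: date
    category: ProcedureCategory
    cost: int = 0

    def validate(self) -> None:
        if self.cost < 0:
            raise ClaimsValidationError(
                f"patient {self.patient_id}: negative procedure cost on {self.date}"
            )


@dataclass(slots=True)
class AdmissionRecord:
    patient_id: str
    admit_date: date
    discharge_date: date
    cost: int = 0
    died_in_hospital: bool = False

    def validate(self) -> None:
        if self.admit_date > self.discharge_date:
            raise ClaimsValidationError(
                f"patient {self.patient_id}: admission {self.admit_date} "
                f"discharged earlier ({self.discharge_date})"
            )
        if self.cost < 0:
            raise ClaimsValidationError(
                f"patient {self.patient_id}: negative admission cost"
            )


@dataclass(slots=True)
class ClaimsBundle:
    """One patient's complete dated event stream.

    Canonical order is a stable sort by date within each claim list;
    re-sorting is idempotent, which makes every downstream stage invariant
    to input row shuffling.
    """

    patient: PatientRecord
    diagnoses: list[DiagnosisClaim] = field(default_factory=list)
    staging: list[StagingClaim] = field(default_factory=list)
    drugs: list[DrugClaim] = field(default_factory=list)
    procedures: list[ProcedureClaim] = field(default_factory=list)
    admissions: list[AdmissionRecord] = field(default_factory=list)

    @property
    def patient_id(self) -> str:
        return self.patient.patient_id

    def sort(self) -> "ClaimsBundle":
        """Put every claim list in canonical (stable by date) order, in place."""
        self.diagnoses.sort(key=lambda c: c.date)
        self.staging.sort(key=lambda c: c.date)
        self.drugs.sort(key=lambda c: c.date)
        self.procedures.sort(key=lambda c: c.date)
        self.admissions.sort(key=lambda c: c.admit_date)
        return self

    def validate(self) -> None:
        self.patient.validate()
        lo, hi = self.patient.enroll_start, self.patient.enroll_end
        for group in (self.diagnoses, self.staging, self.drugs, self.procedures):
            for claim in group:
                if hasattr(claim, "validate"):
                    claim.validate()
                if not (lo <= claim.date <= hi):
                    raise ClaimsValidationError(
                        f"patient {self.patient_id}: event dated {claim.date} "
                        f"outside enrollment span [{lo}, {hi}]"
                    )
        for adm in self.admissions:
            adm.validate()
            if not (lo <= adm.admit_date <= hi):
                raise ClaimsValidationError(
                    f"patient {self.patient_id}: admission dated {adm.admit_date} "
                    f"outside enrollment span [{lo}, {hi}]"
                )

    def copy(self) -> "ClaimsBundle":
        return ClaimsBundle(
            patient=replace(self.patient),
            diagnoses=[replace(c) for c in self.diagnoses],
            staging=[replace(c) for c in self.staging],
            drugs=[replace(c) for c in self.drugs],
            procedures=[replace(c) for c in self.procedures],
            admissions=[replace(c) for c in self.admissions],
        )
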