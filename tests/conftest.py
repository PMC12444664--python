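from __future__ import annotations

from datetime import date, timedelta

import pytest

from hnclaims.episodes import WindowConfig, derive_timeline
from hnclaims.model import (
    Agent,
    ClaimsBundle,
    DrugClaim,
    PatientRecord,
    ProcedureCategory,
    ProcedureClaim,
    Sex,
)
from hnclaims.synth import GeneratorConfig, generate_cohort

EPOCH = date(2018, 1, 1)


def day(n: int) -> date:
    return EPOCH + timedelta(days=int(n))


def make_bundle(events, *, patient_id="T1", enroll_days=1500):
    """Build a bundle from integer-day events:
    ("surgery", d) | ("rt", d) | ("drug", d, agent) | ("neck_dissection", d).
    The index date is day 0."""
    patient = PatientRecord(
        patient_id=patient_id,
        birth_year=1950,
        sex=Sex.MALE,
        enroll_start=EPOCH - timedelta(days=400),
        enroll_end=EPOCH + timedelta(days=enroll_days),
    )
    b = ClaimsBundle(patient=patient)
    for e in events:
        kind = e[0]
        if kind == "surgery":
            b.procedures.append(
                ProcedureClaim(patient_id, day(e[1]), ProcedureCategory.SURGERY_RESECTION)
            )
        elif kind == "neck_dissection":
            b.procedures.append(
                ProcedureClaim(patient_id, day(e[1]), ProcedureCategory.NECK_DISSECTION)
            )
        elif kind == "rt":
            b.procedures.append(
                ProcedureClaim(patient_id, day(e[1]), ProcedureCategory.RADIOTHERAPY_FRACTION)
            )
        elif kind == "drug":
            b.drugs.append(DrugClaim(patient_id, day(e[1]), Agent(e[2]), atc="L01XX00"))
        else:
            raise ValueError(kind)
    return b.sort()


def run_engine(events, *, index_day=0, config=None):
    bundle = make_bundle(events)
    return derive_timeline(bundle, day(index_day), config or WindowConfig())


def block_tuple(block):
    """Canonical comparable form of an engine block (integer days)."""
    return (
        block.modality,
        (block.start - EPOCH).days,
        (block.end - EPOCH).days,
        block.components,
        block.fraction_count,
    )


def oracle_tuple(block):
    return (
        block["modality"],
        block["start"],
        block["end"],
        block["components"],
        block["fractions"],
    )


@pytest.fixture(scope="session")
def clean_cohort():
    """300 synthetic patients, no contaminants, no utilization stream."""
    cfg = GeneratorConfig(n_patients=300, seed=20240901, include_hcru=False)
    cfg.contaminant_probs = {k: 0.0 for k in cfg.contaminant_probs}
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def contaminated_cohort():
    """400 synthetic patients with the default ~20% contaminant mix and the
    full utilization stream attached."""
    cfg = GeneratorConfig(n_patients=400, seed=77, include_hcru=True)
    return generate_cohort(cfg)
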