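"""CSV claims tables and TSV report tables.

Input dialect: UTF-8, comma-separated, header row required, ISO-8601 dates.
Six tables make up a claims extract: ``patients.csv``, ``diagnoses.csv``,
``staging.csv``, ``drugs.csv``, ``procedures.csv``, ``admissions.csv``.
Output report tables are TSVs whose count cells are rendered "n (p)" with
percentages at one decimal, round-half-up.
"""

from __future__ import annotations

import logging
from dataclasses import fields as dc_fields
from datetime import date, datetime
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    AdmissionRecord,
    Agent,
    ClaimsBundle,
    ClaimsValidationError,
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

logger = logging.getLogger("hnclaims")

__all__ = [
    "SchemaError",
    "RowError",
    "read_claims",
    "write_claims",
    "write_report",
    "percentage",
    "format_count_pct",
    "TABLE_FILES",
]

TABLE_FILES = {
    "patients": "patients.csv",
    "diagnoses": "diagnoses.csv",
    "staging": "staging.csv",
    "drugs": "drugs.csv",
    "procedures": "procedures.csv",
    "admissions": "admissions.csv",
}

_COLUMNS = {
    "patients": [
        "patient_id", "birth_year", "sex", "enroll_start", "enroll_end",
        "death_date", "in_clinical_trial",
    ],
    "diagnoses": ["patient_id", "date", "icd10", "setting", "primary_dx"],
    "staging": ["patient_id", "date", "stage"],
    "drugs": ["patient_id", "date", "agent", "atc", "cost"],
    "procedures": ["patient_id", "date", "category", "cost"],
    "admissions": [
        "patient_id", "admit_date", "discharge_date", "cost", "died_in_hospital",
    ],
}


class SchemaError(ClaimsValidationError):
    """A claims table is missing a required column or has malformed rows."""


class RowError(ClaimsValidationError):
    """A single claims row could not be parsed."""


# ---------------------------------------------------------------------------
# reading


def _parse_date(token: str, *, table: str, row: int, col: str) -> date:
    try:
        return datetime.strptime(str(token).strip(), "%Y-%m-%d").date()
    except ValueError as exc:
        raise RowError(
            f"{table}.csv row {row}: unparseable date {token!r} in column {col!r}"
        ) from exc


def _parse_enum(token, enum_cls, *, table: str, row: int, col: str):
    try:
        return enum_cls(str(token).strip())
    except ValueError as exc:
        admissible = ", ".join(e.value for e in enum_cls)
        raise RowError(
            f"{table}.csv row {row}: unknown {col} token {token!r}; "
            f"admissible: {admissible}"
        ) from exc


def _parse_agent(token, *, row: int) -> Agent:
    name = str(token).strip()
    try:
        return Agent(name)
    except ValueError:
        logger.warning(
            "drugs.csv row %d: unknown agent %r mapped to 'other'", row, name
        )
        return Agent.OTHER


def _parse_bool(token) -> bool:
    return str(token).strip().lower() in {"true", "1", "yes", "t"}


def _opt(token) -> Optional[str]:
    if token is None:
        return None
    s = str(token).strip()
    return s or None


def _load_table(path: Path, name: str) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing claims table: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _COLUMNS[name]:
        if col not in df.columns:
            raise SchemaError(f"{name}.csv: missing required column {col!r}")
    return df


def read_claims(path: str | Path, *, validate: bool = True) -> list[ClaimsBundle]:
    """Read a claims directory into one sorted :class:`ClaimsBundle` per patient.

    Row numbers in error messages are 1-based data rows (header excluded).
    """
    root = Path(path)
    tables = {name: _load_table(root / fn, name) for name, fn in TABLE_FILES.items()}

    bundles: dict[str, ClaimsBundle] = {}
    for i, r in enumerate(tables["patients"].itertuples(index=False), start=1):
        pid = str(r.patient_id)
        rec = PatientRecord(
            patient_id=pid,
            birth_year=int(r.birth_year),
            sex=_parse_enum(r.sex, Sex, table="patients", row=i, col="sex"),
            enroll_start=_parse_date(r.enroll_start, table="patients", row=i, col="enroll_start"),
            enroll_end=_parse_date(r.enroll_end, table="patients", row=i, col="enroll_end"),
            death_date=(
                _parse_date(r.death_date, table="patients", row=i, col="death_date")
                if _opt(r.death_date) else None
            ),
            in_clinical_trial=_parse_bool(r.in_clinical_trial),
        )
        if pid in bundles:
            raise RowError(f"patients.csv row {i}: duplicate patient_id {pid!r}")
        bundles[pid] = ClaimsBundle(patient=rec)

    def bundle_for(pid: str, table: str, row: int) -> ClaimsBundle:
        try:
            return bundles[str(pid)]
        except KeyError:
            raise RowError(
                f"{table}.csv row {row}: unknown patient_id {pid!r}"
            ) from None

    for i, r in enumerate(tables["diagnoses"].itertuples(index=False), start=1):
        bundle_for(r.patient_id, "diagnoses", i).diagnoses.append(
            DiagnosisClaim(
                patient_id=str(r.patient_id),
                date=_parse_date(r.date, table="diagnoses", row=i, col="date"),
                icd10=str(r.icd10).strip(),
                setting=_parse_enum(r.setting, Setting, table="diagnoses", row=i, col="setting"),
                primary_dx=_parse_bool(r.primary_dx),
            )
        )
    for i, r in enumerate(tables["staging"].itertuples(index=False), start=1):
        bundle_for(r.patient_id, "staging", i).staging.append(
            StagingClaim(
                patient_id=str(r.patient_id),
                date=_parse_date(r.date, table="staging", row=i, col="date"),
                stage=_parse_enum(r.stage, Stage, table="staging", row=i, col="stage"),
            )
        )
    for i, r in enumerate(tables["drugs"].itertuples(index=False), start=1):
        bundle_for(r.patient_id, "drugs", i).drugs.append(
            DrugClaim(
                patient_id=str(r.patient_id),
                date=_parse_date(r.date, table="drugs", row=i, col="date"),
                agent=_parse_agent(r.agent, row=i),
                atc=_opt(r.atc),
                cost=int(r.cost or 0),
            )
        )
    for i, r in enumerate(tables["procedures"].itertuples(index=False), start=1):
        bundle_for(r.patient_id, "procedures", i).procedures.append(
            ProcedureClaim(
                patient_id=str(r.patient_id),
                date=_parse_date(r.date, table="procedures", row=i, col="date"),
                category=_parse_enum(
                    r.category, ProcedureCategory, table="procedures", row=i, col="category"
                ),
                cost=int(r.cost or 0),
            )
        )
    for i, r in enumerate(tables["admissions"].itertuples(index=False), start=1):
        bundle_for(r.patient_id, "admissions", i).admissions.append(
            AdmissionRecord(
                patient_id=str(r.patient_id),
                admit_date=_parse_date(r.admit_date, table="admissions", row=i, col="admit_date"),
                discharge_date=_parse_date(
                    r.discharge_date, table="admissions", row=i, col="discharge_date"
                ),
                cost=int(r.cost or 0),
                died_in_hospital=_parse_bool(r.died_in_hospital),
            )
        )

    out = [b.sort() for _, b in sorted(bundles.items())]
    if validate:
        for b in out:
            b.validate()
    return out


# ---------------------------------------------------------------------------
# writing


def _iso(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def write_claims(bundles: Iterable[ClaimsBundle], out_dir: str | Path) -> dict[str, Path]:
    """Write bundles to the six claims CSVs with deterministic row order.

    Rows are ordered by (patient_id, date, stable input order), so identical
    input produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = sorted(bundles, key=lambda b: b.patient_id)

    rows: dict[str, list] = {name: [] for name in TABLE_FILES}
    for b in ordered:
        p = b.patient
        rows["patients"].append(
            (p.patient_id, p.birth_year, p.sex.value, _iso(p.enroll_start),
             _iso(p.enroll_end), _iso(p.death_date), p.in_clinical_trial)
        )
        for c in sorted(b.diagnoses, key=lambda c: c.date):
            rows["diagnoses"].append(
                (c.patient_id, _iso(c.date), c.icd10, c.setting.value, c.primary_dx)
            )
        for c in sorted(b.staging, key=lambda c: c.date):
            rows["staging"].append((c.patient_id, _iso(c.date), c.stage.value))
        for c in sorted(b.drugs, key=lambda c: c.date):
            rows["drugs"].append(
                (c.patient_id, _iso(c.date), c.agent.value, c.atc or "", c.cost)
            )
        for c in sorted(b.procedures, key=lambda c: c.date):
            rows["procedures"].append(
                (c.patient_id, _iso(c.date), c.category.value, c.cost)
            )
        for a in sorted(b.admissions, key=lambda a: a.admit_date):
            rows["admissions"].append(
                (a.patient_id, _iso(a.admit_date), _iso(a.discharge_date),
                 a.cost, a.died_in_hospital)
            )

    paths: dict[str, Path] = {}
    for name, fn in TABLE_FILES.items():
        df = pd.DataFrame(rows[name], columns=_COLUMNS[name])
        path = out / fn
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# report tables


def percentage(n: int, total: int) -> float:
    """100*n/total rounded half-up to one decimal (0.0 when total == 0)."""
    if total == 0:
        return 0.0
    q = (Decimal(100 * n) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


def format_count_pct(n: int, total: int) -> str:
    """Render a count cell as ``"n (p)"``, e.g. ``"3461 (51.3)"``."""
    return f"{n} ({percentage(n, total):.1f})"


def write_report(
    table: pd.DataFrame | Mapping[str, int],
    path: str | Path,
    *,
    total: Optional[int] = None,
    title: Optional[str] = None,
) -> pd.DataFrame:
    """Write a stratified summary as a TSV report table.

    ``table`` may be a mapping of row label -> count (``total`` defaults to
    the sum of counts), in which case a two-column ``row`` / ``n (%)`` table
    is produced; or a ready DataFrame, written as-is.  Returns the DataFrame
    actually written.
    """
    if isinstance(table, Mapping):
        n_total = total if total is not None else sum(table.values())
        df = pd.DataFrame(
            {
                "row": list(table.keys()),
                "n (%)": [format_count_pct(v, n_total) for v in table.values()],
            }
        )
    else:
        df = table
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if title:
            fh.write(f"# {title}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return df
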