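"""Healthcare resource utilization and cost aggregation.

Counts and costs are aggregated over the 12-month post-index window
(events dated in ``[index, index + 365)``); the HCRU cohort is restricted
to patients with at least 12 months of post-index follow-up, so patients
dying or losing coverage earlier are excluded by default.  Count summary
statistics (mean/SD/median/min/max) are computed among *users* (patients
with >= 1 event in the category).  Cost per patient-year divides each
category's total expenditure by the summed follow-up duration in years of
the denominator population; the denominator defaults to the full
(uncapped) follow-up of every patient in the HCRU cohort, with a
capped-at-one-year alternative available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortRecord
from .io import percentage
from .model import ClaimsBundle, ProcedureCategory

__all__ = [
    "HcruConfig",
    "HCRU_CATEGORIES",
    "hcru_cohort",
    "patient_category_events",
    "summarize_utilization",
    "summarize_costs",
]

HCRU_CATEGORIES = (
    "physician_visits",
    "admissions",
    "prescriptions",
    "lab_tests",
    "imaging",
    "la_scchn_surgeries",
    "radiotherapy",
    "rehab_homecare",
)

_PROC_MAP = {
    ProcedureCategory.PHYSICIAN_VISIT: "physician_visits",
    ProcedureCategory.LAB_TEST: "lab_tests",
    ProcedureCategory.IMAGING: "imaging",
    ProcedureCategory.SURGERY_RESECTION: "la_scchn_surgeries",
    ProcedureCategory.NECK_DISSECTION: "la_scchn_surgeries",
    ProcedureCategory.RADIOTHERAPY_FRACTION: "radiotherapy",
    ProcedureCategory.REHAB_HOMECARE: "rehab_homecare",
}


@dataclass(slots=True)
class HcruConfig:
    window_days: int = 365
    require_full_window: bool = True
    denominator: str = "full_followup"  # or "capped_1y"


def hcru_cohort(
    records: Sequence[CohortRecord], config: Optional[HcruConfig] = None
) -> list[CohortRecord]:
    """Eligible patients with at least the full post-index window observed."""
    config = config or HcruConfig()
    out = [r for r in records if r.eligible]
    if config.require_full_window:
        out = [r for r in out if (r.follow_up_days or 0) >= config.window_days]
    return out


def patient_category_events(
    bundle: ClaimsBundle, record: CohortRecord, config: Optional[HcruConfig] = None
) -> dict[str, tuple[int, int]]:
    """Per-category (event_count, total_cost) inside the post-index window.

    Admissions overlapping the window edge count if the admission date is
    inside the window, with their full cost.
    """
    config = config or HcruConfig()
    index = record.index_date
    hi = index + timedelta(days=config.window_days)
    counts = {cat: [0, 0] for cat in HCRU_CATEGORIES}
    for p in bundle.procedures:
        if index <= p.date < hi:
            cat = _PROC_MAP.get(p.category)
            if cat:
                counts[cat][0] += 1
                counts[cat][1] += p.cost
    for d in bundle.drugs:
        if index <= d.date < hi:
            counts["prescriptions"][0] += 1
            counts["prescriptions"][1] += d.cost
    for a in bundle.admissions:
        if index <= a.admit_date < hi:
            counts["admissions"][0] += 1
            counts["admissions"][1] += a.cost
    return {cat: (c, cost) for cat, (c, cost) in counts.items()}


def _collect(
    bundles: Mapping[str, ClaimsBundle],
    subset: Sequence[CohortRecord],
    config: HcruConfig,
    strata: Optional[Mapping[str, str]],
) -> pd.DataFrame:
    rows = []
    for r in subset:
        b = bundles[r.patient_id]
        per_cat = patient_category_events(b, r, config)
        stratum = strata.get(r.patient_id, "all") if strata else "all"
        for cat, (n, cost) in per_cat.items():
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "stratum": stratum,
                    "category": cat,
                    "events": n,
                    "cost": cost,
                    "follow_up_days": r.follow_up_days,
                }
            )
    return pd.DataFrame(rows)


def _user_stats(x: np.ndarray) -> dict[str, float]:
    if x.size == 0:
        return {"mean": np.nan, "sd": np.nan, "median": np.nan, "min": np.nan, "max": np.nan}
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "median": float(np.median(x)),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def summarize_utilization(
    bundles: Mapping[str, ClaimsBundle] | Iterable[ClaimsBundle],
    subset: Sequence[CohortRecord],
    config: Optional[HcruConfig] = None,
    strata: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """User counts/percentages and among-user count statistics per category."""
    config = config or HcruConfig()
    if not isinstance(bundles, Mapping):
        bundles = {b.patient_id: b for b in bundles}
    df = _collect(bundles, subset, config, strata)
    rows = []
    if df.empty:
        return pd.DataFrame(
            columns=["stratum", "category", "n_patients", "user_count", "user_pct",
                     "mean", "sd", "median", "min", "max", "flag"]
        )
    for (stratum, cat), g in df.groupby(["stratum", "category"], sort=True):
        users = g.loc[g["events"] > 0, "events"].to_numpy()
        n_stratum = g["patient_id"].nunique()
        stats = _user_stats(users)
        rows.append(
            {
                "stratum": stratum,
                "category": cat,
                "n_patients": n_stratum,
                "user_count": int(users.size),
                "user_pct": percentage(int(users.size), n_stratum),
                **stats,
                "flag": "empty" if users.size == 0 else "",
            }
        )
    return pd.DataFrame(rows)


def summarize_costs(
    bundles: Mapping[str, ClaimsBundle] | Iterable[ClaimsBundle],
    subset: Sequence[CohortRecord],
    config: Optional[HcruConfig] = None,
    strata: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Cost rows per category per stratum: mean/SD among users, total, cost/PY."""
    config = config or HcruConfig()
    if not isinstance(bundles, Mapping):
        bundles = {b.patient_id: b for b in bundles}
    df = _collect(bundles, subset, config, strata)
    rows = []
    if df.empty:
        return pd.DataFrame(
            columns=["stratum", "category", "user_count", "cost_mean", "cost_sd",
                     "total_sum", "patient_years", "cost_per_patient_year"]
        )
    for (stratum, cat), g in df.groupby(["stratum", "category"], sort=True):
        users = g[g["events"] > 0]
        costs = users["cost"].to_numpy(dtype=float)
        total = float(costs.sum())
        fup = g.drop_duplicates("patient_id")["follow_up_days"].to_numpy(dtype=float)
        if config.denominator == "capped_1y":
            fup = np.minimum(fup, config.window_days)
        patient_years = float(fup.sum()) / 365.25
        stats = _user_stats(costs)
        rows.append(
            {
                "stratum": stratum,
                "category": cat,
                "user_count": int(len(users)),
                "cost_mean": stats["mean"] if len(users) else 0.0,
                "cost_sd": stats["sd"] if len(users) else 0.0,
                "total_sum": total,
                "patient_years": patient_years,
                "cost_per_patient_year": total / patient_years if patient_years > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
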