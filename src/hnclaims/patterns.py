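"""Two-level treatment-pattern taxonomy and stratified pattern tables.

Top level: primary resection, definitive nonsurgical treatment,
chemotherapy + neck dissection, not treated.  Sub-sequences order the LA
treatment's elements (surgery, concurrent CRT unit, radiotherapy course,
systemic regimen) by start date.  A systemic regimen paired to a
radiotherapy course within the 14-day concurrency window is one CRT
element whose start is the earlier of the two starts; induction followed
by concurrent CRT therefore classifies as chemotherapy -> radiotherapy,
not CRT alone.  Multiple surgeries inside the 90-day window collapse into
a single surgery element (the taxonomy has no repeat-surgery label).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortRecord
from .episodes import EpisodeTimeline, TreatmentBlock
from .io import percentage
from .model import Agent

logger = logging.getLogger("hnclaims")

__all__ = [
    "TopPattern",
    "SubPattern",
    "PatternLabel",
    "classify",
    "tabulate_patterns",
    "regimen_distribution",
    "canonical_regimen",
    "AGENT_PRECEDENCE",
]


class TopPattern(str, Enum):
    PRIMARY_RESECTION = "primary_resection"
    DEFINITIVE_NONSURGICAL = "definitive_nonsurgical"
    CHEMO_NECK_DISSECTION = "chemo_neck_dissection"
    NOT_TREATED = "not_treated"


class SubPattern(str, Enum):
    SURGERY_ALONE = "surgery_alone"
    SURGERY_THEN_CRT = "surgery_then_crt"
    SURGERY_THEN_RT = "surgery_then_rt"
    CHEMO_THEN_SURGERY = "chemo_then_surgery"
    OTHER_RESECTION = "other_resection"
    CRT_ALONE = "crt_alone"
    RT_ALONE = "rt_alone"
    CHEMO_THEN_RT = "chemo_then_rt"
    RT_THEN_CHEMO = "rt_then_chemo"
    NONE = "none"


_TOP_OF_SUB = {
    SubPattern.SURGERY_ALONE: TopPattern.PRIMARY_RESECTION,
    SubPattern.SURGERY_THEN_CRT: TopPattern.PRIMARY_RESECTION,
    SubPattern.SURGERY_THEN_RT: TopPattern.PRIMARY_RESECTION,
    SubPattern.CHEMO_THEN_SURGERY: TopPattern.PRIMARY_RESECTION,
    SubPattern.OTHER_RESECTION: TopPattern.PRIMARY_RESECTION,
    SubPattern.CRT_ALONE: TopPattern.DEFINITIVE_NONSURGICAL,
    SubPattern.RT_ALONE: TopPattern.DEFINITIVE_NONSURGICAL,
    SubPattern.CHEMO_THEN_RT: TopPattern.DEFINITIVE_NONSURGICAL,
    SubPattern.RT_THEN_CHEMO: TopPattern.DEFINITIVE_NONSURGICAL,
}


@dataclass(frozen=True, slots=True)
class PatternLabel:
    top: TopPattern
    sub: SubPattern

    @classmethod
    def from_sub(cls, sub: SubPattern) -> "PatternLabel":
        return cls(top=_TOP_OF_SUB[sub], sub=sub)


# canonical component ordering used in regimen names (triplet conventions:
# "fluorouracil + cisplatin + docetaxel", "cetuximab + paclitaxel + carboplatin")
AGENT_PRECEDENCE = [
    Agent.FLUOROURACIL.value,
    Agent.CISPLATIN.value,
    Agent.CETUXIMAB.value,
    Agent.PACLITAXEL.value,
    Agent.CARBOPLATIN.value,
    Agent.NEDAPLATIN.value,
    Agent.DOCETAXEL.value,
    Agent.TEGAFUR.value,
    Agent.OTHER.value,
]
_PRECEDENCE = {a: i for i, a in enumerate(AGENT_PRECEDENCE)}


def canonical_regimen(components: Iterable[str]) -> str:
    parts = sorted(set(components), key=lambda a: (_PRECEDENCE.get(a, 99), a))
    return " + ".join(parts)


# ---------------------------------------------------------------------------
# sequence elements


@dataclass(slots=True)
class _Element:
    kind: str  # "surgery" | "crt" | "rt" | "chemo"
    start: object
    systemic_block: Optional[TreatmentBlock] = None


_KIND_ORDER = {"surgery": 0, "chemo": 1, "crt": 2, "rt": 3}


def _sequence_elements(timeline: EpisodeTimeline) -> list[_Element]:
    elements: list[_Element] = []
    seen_partners: set[int] = set()
    surgeries = [b for b in timeline.blocks if b.modality == "surgery"]
    if surgeries:
        elements.append(_Element("surgery", min(b.start for b in surgeries)))
    for b in timeline.blocks:
        if b.modality == "systemic":
            if b.concurrent_with is not None and any(
                rb is b.concurrent_with for rb in timeline.blocks
            ):
                if id(b) not in seen_partners:
                    elements.append(
                        _Element(
                            "crt",
                            min(b.start, b.concurrent_with.start),
                            systemic_block=b,
                        )
                    )
                    seen_partners.add(id(b.concurrent_with))
            else:
                elements.append(_Element("chemo", b.start, systemic_block=b))
        elif b.modality == "radiotherapy":
            if id(b) in seen_partners:
                continue
            if b.concurrent_with is not None and any(
                sb is b.concurrent_with for sb in timeline.blocks
            ):
                if not any(e.systemic_block is b.concurrent_with for e in elements):
                    elements.append(
                        _Element(
                            "crt",
                            min(b.start, b.concurrent_with.start),
                            systemic_block=b.concurrent_with,
                        )
                    )
            else:
                elements.append(_Element("rt", b.start))
    elements.sort(key=lambda e: (e.start, _KIND_ORDER[e.kind]))
    # collapse consecutive duplicates (e.g. two radiotherapy courses)
    out: list[_Element] = []
    for e in elements:
        if out and out[-1].kind == e.kind:
            continue
        out.append(e)
    return out


# ---------------------------------------------------------------------------
# classification


def classify(timeline: EpisodeTimeline) -> PatternLabel:
    """Map an assembled LA treatment to its (top, sub) pattern label.

    Unmappable sequences never crash: surgical residuals fall into
    ``other_resection``; a systemic-only sequence is labeled chemotherapy +
    neck dissection (when no dissection is present the combination is
    normally removed upstream by the chemotherapy-only exclusion, and the
    sequence is logged).
    """
    if not timeline.treated:
        return PatternLabel(TopPattern.NOT_TREATED, SubPattern.NONE)
    elements = _sequence_elements(timeline)
    kinds = tuple(e.kind for e in elements)

    if "surgery" in kinds:
        mapping = {
            ("surgery",): SubPattern.SURGERY_ALONE,
            ("surgery", "crt"): SubPattern.SURGERY_THEN_CRT,
            ("surgery", "rt"): SubPattern.SURGERY_THEN_RT,
            ("chemo", "surgery"): SubPattern.CHEMO_THEN_SURGERY,
        }
        sub = mapping.get(kinds)
        if sub is None:
            sub = SubPattern.OTHER_RESECTION
            logger.info("sequence %s classified as other_resection", " -> ".join(kinds))
        return PatternLabel.from_sub(sub)

    if kinds == ("chemo",):
        if not timeline.neck_dissection_dates:
            logger.warning(
                "systemic-only sequence without neck dissection reached the "
                "classifier; labeling chemo_neck_dissection"
            )
        return PatternLabel(TopPattern.CHEMO_NECK_DISSECTION, SubPattern.NONE)

    mapping = {
        ("crt",): SubPattern.CRT_ALONE,
        ("rt",): SubPattern.RT_ALONE,
        ("chemo", "rt"): SubPattern.CHEMO_THEN_RT,
        ("chemo", "crt"): SubPattern.CHEMO_THEN_RT,
        ("rt", "chemo"): SubPattern.RT_THEN_CHEMO,
    }
    sub = mapping.get(kinds)
    if sub is None:
        # longer nonsurgical sequences: label by the leading strategy
        if kinds and kinds[0] == "crt":
            sub = SubPattern.CRT_ALONE
        elif kinds and kinds[0] == "chemo" and any(k in ("rt", "crt") for k in kinds):
            sub = SubPattern.CHEMO_THEN_RT
        elif kinds and kinds[0] == "rt":
            sub = SubPattern.RT_THEN_CHEMO if "chemo" in kinds else SubPattern.RT_ALONE
        else:
            logger.warning("unmappable sequence %s", " -> ".join(kinds) or "<empty>")
            return PatternLabel(TopPattern.NOT_TREATED, SubPattern.NONE)
        logger.info("sequence %s folded into %s", " -> ".join(kinds), sub.value)
    return PatternLabel.from_sub(sub)


# ---------------------------------------------------------------------------
# tables


_AGE_BANDS = ["<=55", "55-65", "65-75", ">75"]


def _stratum_of(record: CohortRecord, stratifier: str) -> str:
    if stratifier == "overall":
        return "overall"
    if stratifier == "by_site":
        return record.site or "unknown"
    if stratifier == "by_stage":
        return record.stage.value if record.stage else "unknown"
    if stratifier == "by_age":
        return record.age_band or "unknown"
    raise ValueError(f"unknown stratifier: {stratifier!r}")


def tabulate_patterns(
    labels: dict[str, PatternLabel],
    records: Sequence[CohortRecord],
    stratifier: str = "overall",
    *,
    exclude_not_treated: bool = False,
) -> pd.DataFrame:
    """Counts and one-decimal percentages of pattern labels per stratum.

    ``stratifier`` is one of overall, by_site, by_stage, by_age,
    by_primary_treatment.  For ``by_stage`` the table also carries per-cell
    age mean/median.  ``exclude_not_treated`` removes the not-treated group
    from the stratum denominator (used for the site-within-stage view).
    """
    recs = [r for r in records if r.eligible and r.patient_id in labels]
    if stratifier == "by_primary_treatment":
        return _tabulate_by_primary(labels, recs)
    rows = []
    strata = sorted({_stratum_of(r, stratifier) for r in recs})
    for stratum in strata:
        in_stratum = [r for r in recs if _stratum_of(r, stratifier) == stratum]
        if exclude_not_treated:
            in_stratum = [
                r for r in in_stratum
                if labels[r.patient_id].top != TopPattern.NOT_TREATED
            ]
        n_stratum = len(in_stratum)
        for top in TopPattern:
            members = [r for r in in_stratum if labels[r.patient_id].top == top]
            rows.append(_cell(stratum, top.value, "", members, n_stratum, stratifier))
            for sub, t in _TOP_OF_SUB.items():
                if t != top:
                    continue
                sub_members = [
                    r for r in members if labels[r.patient_id].sub == sub
                ]
                rows.append(
                    _cell(stratum, top.value, sub.value, sub_members, n_stratum, stratifier)
                )
    return pd.DataFrame(rows)


def _cell(stratum, top, sub, members, n_stratum, stratifier) -> dict:
    n = len(members)
    row = {
        "stratum": stratum,
        "top": top,
        "sub": sub,
        "n": n,
        "pct": percentage(n, n_stratum),
        "stratum_n": n_stratum,
    }
    if stratifier == "by_stage":
        ages = [r.age_at_index for r in members if r.age_at_index is not None]
        row["age_mean"] = float(np.mean(ages)) if ages else np.nan
        row["age_median"] = float(np.median(ages)) if ages else np.nan
    return row


def _tabulate_by_primary(
    labels: dict[str, PatternLabel], recs: Sequence[CohortRecord]
) -> pd.DataFrame:
    rows = []
    for top in (TopPattern.PRIMARY_RESECTION, TopPattern.DEFINITIVE_NONSURGICAL):
        members = [r for r in recs if labels[r.patient_id].top == top]
        n_top = len(members)
        for sub, t in _TOP_OF_SUB.items():
            if t != top:
                continue
            k = sum(1 for r in members if labels[r.patient_id].sub == sub)
            rows.append(
                {
                    "stratum": top.value,
                    "top": top.value,
                    "sub": sub.value,
                    "n": k,
                    "pct": percentage(k, n_top),
                    "stratum_n": n_top,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regimen distributions


_CONTEXTS = ("crt_backbone", "induction_pre_surgery", "induction_pre_rt", "adjuvant_crt")


def _context_block(
    timeline: EpisodeTimeline, label: PatternLabel, context: str
) -> Optional[TreatmentBlock]:
    elements = _sequence_elements(timeline)
    if context == "crt_backbone":
        if label.sub != SubPattern.CRT_ALONE:
            return None
        for e in elements:
            if e.kind == "crt":
                return e.systemic_block
    elif context == "induction_pre_surgery":
        if label.sub != SubPattern.CHEMO_THEN_SURGERY:
            return None
        for e in elements:
            if e.kind == "chemo":
                return e.systemic_block
    elif context == "induction_pre_rt":
        if label.sub != SubPattern.CHEMO_THEN_RT:
            return None
        for e in elements:
            if e.kind == "chemo":
                return e.systemic_block
    elif context == "adjuvant_crt":
        if label.sub != SubPattern.SURGERY_THEN_CRT:
            return None
        for e in elements:
            if e.kind == "crt":
                return e.systemic_block
    else:
        raise ValueError(f"unknown regimen context: {context!r}")
    return None


def regimen_distribution(
    classified: Sequence[tuple[EpisodeTimeline, PatternLabel]],
    context: str,
) -> pd.DataFrame:
    """Frequency table of canonical regimen names within a treatment context.

    Contexts: ``crt_backbone`` (systemic component of definitive CRT),
    ``induction_pre_surgery``, ``induction_pre_rt`` (first induction
    regimen), ``adjuvant_crt`` (systemic component of post-surgical CRT).
    """
    if context not in _CONTEXTS:
        raise ValueError(
            f"unknown regimen context: {context!r}; admissible: {', '.join(_CONTEXTS)}"
        )
    names: list[str] = []
    for tl, label in classified:
        block = _context_block(tl, label, context)
        if block is not None:
            names.append(canonical_regimen(block.components))
    total = len(names)
    if total == 0:
        return pd.DataFrame(columns=["regimen", "n", "pct"])
    counts = pd.Series(names).value_counts()
    return pd.DataFrame(
        {
            "regimen": counts.index,
            "n": counts.values,
            "pct": [percentage(int(v), total) for v in counts.values],
        }
    ).reset_index(drop=True)
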