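"""Temporal treatment-sequencing engine.

Builds modality-level treatment blocks from raw dated claims and applies
the interval rules that define a locally advanced (LA) treatment:

* a patient is *treated* if the first treatment event of any modality
  falls within 183 days (6 months) of the index date;
* the LA treatment comprises the blocks starting within 90 days of the
  first treatment's start;
* agents first administered within 8 days of the first systemic
  administration form one combination regimen;
* a systemic regimen and a radiotherapy course given within 14 days of
  each other (start-to-start) are concurrent chemoradiotherapy (CRT);
* a >60-day lapse between administrations ends a regimen; switches and
  discontinuations are read off the current block's end against the
  successor's start.

All window comparisons are inclusive (``|delta| <= w`` days) and operate
on whole-day differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Sequence

from .model import Agent, ClaimsBundle, DrugClaim, ProcedureCategory

__all__ = [
    "WindowConfig",
    "TreatmentBlock",
    "EpisodeTimeline",
    "build_rt_courses",
    "build_systemic_regimens",
    "pair_concurrent_crt",
    "assemble_la_treatment",
    "detect_line_end",
    "derive_timeline",
    "is_anticancer",
]


@dataclass(slots=True)
class WindowConfig:
    treated_window_days: int = 183
    modality_window_days: int = 90
    combo_window_days: int = 8
    concurrent_window_days: int = 14
    gap_days: int = 60
    rt_course_merge_gap_days: int = 14


@dataclass(eq=False)
class TreatmentBlock:
    modality: str  # "surgery" | "radiotherapy" | "systemic"
    start: date
    end: date
    components: frozenset[str]
    concurrent_with: Optional["TreatmentBlock"] = None
    fraction_count: int = 0
    # last administration per component; lets the switch rules see a
    # component stopping while the rest of the regimen continues
    component_last: dict[str, date] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.component_last:
            self.component_last = {c: self.end for c in self.components}

    @property
    def is_crt_member(self) -> bool:
        return self.concurrent_with is not None

    def __repr__(self) -> str:  # compact, date-only
        comp = "+".join(sorted(self.components))
        return f"<{self.modality} {self.start}..{self.end} [{comp}]>"


@dataclass(slots=True)
class EpisodeTimeline:
    index_date: date
    blocks: list[TreatmentBlock] = field(default_factory=list)
    events_after_window: list[TreatmentBlock] = field(default_factory=list)
    first_treatment_date: Optional[date] = None
    treated: bool = False
    line_end: tuple[str, Optional[date]] = ("ongoing", None)
    neck_dissection_dates: list[date] = field(default_factory=list)


def is_anticancer(claim: DrugClaim) -> bool:
    """Systemic-therapy claims: named agents, or unknowns flagged ATC L01.

    All-cause prescriptions (agent "other" without an antineoplastic ATC
    code) are utilization events and never enter regimen construction.
    """
    if claim.agent != Agent.OTHER:
        return True
    return (claim.atc or "").upper().startswith("L01")


# ---------------------------------------------------------------------------
# block construction


def build_rt_courses(
    fraction_dates: Sequence[date], config: Optional[WindowConfig] = None
) -> list[TreatmentBlock]:
    """Merge radiotherapy fraction claims into courses.

    Consecutive fractions separated by at most ``rt_course_merge_gap_days``
    belong to one course; the course spans first to last fraction.
    """
    config = config or WindowConfig()
    if not fraction_dates:
        return []
    dates = sorted(fraction_dates)
    courses: list[TreatmentBlock] = []
    run = [dates[0]]
    for d in dates[1:]:
        if (d - run[-1]).days <= config.rt_course_merge_gap_days:
            run.append(d)
        else:
            courses.append(
                TreatmentBlock(
                    "radiotherapy", run[0], run[-1],
                    frozenset({"rt_course"}), fraction_count=len(run),
                )
            )
            run = [d]
    courses.append(
        TreatmentBlock(
            "radiotherapy", run[0], run[-1],
            frozenset({"rt_course"}), fraction_count=len(run),
        )
    )
    return courses


def build_systemic_regimens(
    drug_claims: Sequence[DrugClaim], config: Optional[WindowConfig] = None
) -> list[TreatmentBlock]:
    """Group systemic-therapy administrations into regimen blocks.

    The earliest unassigned administration anchors a regimen.  Agents whose
    first unassigned administration falls within ``combo_window_days`` of
    the anchor join the component set.  The block consumes the merged
    administration stream of its components until a ``> gap_days`` lapse;
    remaining administrations anchor later blocks (so an agent introduced
    after the combination window opens its own, possibly overlapping,
    block -- an add-on or a switch, resolved downstream).
    """
    config = config or WindowConfig()
    claims = sorted(
        (c for c in drug_claims if is_anticancer(c)),
        key=lambda c: (c.date, c.agent.value),
    )
    unassigned = list(claims)
    blocks: list[TreatmentBlock] = []
    while unassigned:
        anchor_date = unassigned[0].date
        first_admin: dict[str, date] = {}
        for c in unassigned:
            first_admin.setdefault(c.agent.value, c.date)
        components = frozenset(
            a
            for a, d in first_admin.items()
            if 0 <= (d - anchor_date).days <= config.combo_window_days
        )
        stream = [c for c in unassigned if c.agent.value in components]
        taken = [stream[0]]
        for c in stream[1:]:
            if (c.date - taken[-1].date).days > config.gap_days:
                break
            taken.append(c)
        taken_ids = {id(c) for c in taken}
        comp_last: dict[str, date] = {}
        for c in taken:
            prev = comp_last.get(c.agent.value)
            if prev is None or c.date > prev:
                comp_last[c.agent.value] = c.date
        blocks.append(
            TreatmentBlock(
                "systemic",
                anchor_date,
                taken[-1].date,
                frozenset(c.agent.value for c in taken),
                component_last=comp_last,
            )
        )
        unassigned = [c for c in unassigned if id(c) not in taken_ids]
    blocks.sort(key=lambda b: b.start)
    return blocks


def pair_concurrent_crt(
    blocks: Sequence[TreatmentBlock], config: Optional[WindowConfig] = None
) -> list[TreatmentBlock]:
    """Pair systemic regimens with radiotherapy courses into CRT units.

    A pair qualifies when the two starts are within
    ``concurrent_window_days`` of each other; each block pairs with at most
    one partner, nearest start first (ties to the earlier partner).
    Pairing is symmetric and recorded in-place via ``concurrent_with``.
    """
    config = config or WindowConfig()
    sys_blocks = [b for b in blocks if b.modality == "systemic"]
    rt_blocks = [b for b in blocks if b.modality == "radiotherapy"]
    candidates = sorted(
        (
            (abs((s.start - r.start).days), r.start, s.start, s, r)
            for s in sys_blocks
            for r in rt_blocks
            if abs((s.start - r.start).days) <= config.concurrent_window_days
        ),
        key=lambda t: (t[0], t[1], t[2]),
    )
    for _, _, _, s, r in candidates:
        if s.concurrent_with is None and r.concurrent_with is None:
            s.concurrent_with = r
            r.concurrent_with = s
    return list(blocks)


# ---------------------------------------------------------------------------
# LA treatment assembly


_MODALITY_ORDER = {"surgery": 0, "systemic": 1, "radiotherapy": 2}


def _block_sort_key(b: TreatmentBlock):
    # same-day ties: surgery < systemic < radiotherapy (deterministic; the
    # classifier also consults concurrency so this rarely matters)
    return (b.start, _MODALITY_ORDER[b.modality])


def assemble_la_treatment(
    blocks: Sequence[TreatmentBlock],
    index_date: date,
    config: Optional[WindowConfig] = None,
) -> EpisodeTimeline:
    """Fix the treated flag and the LA-treatment block set.

    The LA treatment is every block starting within ``modality_window_days``
    of the first treatment's start; a block paired as concurrent CRT with an
    in-window block is kept even if its own start falls just outside; blocks
    are never split at the window edge.  Blocks starting before the index
    date or outside the window are kept for reporting only.
    """
    config = config or WindowConfig()
    ordered = sorted(blocks, key=_block_sort_key)
    post = [b for b in ordered if b.start >= index_date]
    pre = [b for b in ordered if b.start < index_date]

    tl = EpisodeTimeline(index_date=index_date)
    tl.events_after_window.extend(pre)
    if not post:
        return tl
    first = post[0].start
    tl.first_treatment_date = first
    tl.treated = (first - index_date).days <= config.treated_window_days
    if not tl.treated:
        tl.events_after_window.extend(post)
        return tl
    in_window = [
        b for b in post if (b.start - first).days <= config.modality_window_days
    ]
    kept = set(id(b) for b in in_window)
    for b in post:
        if id(b) not in kept and b.concurrent_with is not None:
            if id(b.concurrent_with) in kept:
                in_window.append(b)
                kept.add(id(b))
    tl.blocks = sorted(in_window, key=_block_sort_key)
    tl.events_after_window.extend(b for b in post if id(b) not in kept)
    return tl


# ---------------------------------------------------------------------------
# line end


def detect_line_end(
    timeline: EpisodeTimeline,
    observation_end: Optional[date] = None,
    config: Optional[WindowConfig] = None,
) -> tuple[str, Optional[date]]:
    """Classify how the LA treatment line ends.

    The switch/discontinuation rules speak of prescriptions, so the walk
    runs over the patient's systemic blocks in start order:

    * switch (monotherapy): a different single agent starts after the
      current regimen ends, at least 8 days after the current regimen's
      start and within 60 days of its end;
    * switch (combination): one component is removed (its administrations
      cease) and a new agent is added within 60 days, the new combination
      persisting at least 8 days;
    * add-on: a new agent joining while the current regimen continues and
      nothing is removed extends the component set but neither ends nor
      advances the line;
    * discontinuation: a >60-day lapse with no qualifying successor;
    * ongoing: observation ends within 60 days of the last administration.

    Patients without systemic therapy fall back to the same lapse rule on
    the last treatment block of any modality.
    """
    config = config or WindowConfig()
    all_blocks = list(timeline.blocks) + list(timeline.events_after_window)
    sys_blocks = sorted(
        (b for b in all_blocks if b.modality == "systemic"),
        key=lambda b: (b.start, b.end),
    )
    if not sys_blocks:
        if not timeline.blocks:
            timeline.line_end = ("ongoing", None)
            return timeline.line_end
        last_end = max(b.end for b in timeline.blocks)
        if observation_end is not None and (observation_end - last_end).days <= config.gap_days:
            timeline.line_end = ("ongoing", None)
        else:
            timeline.line_end = ("discontinued", last_end)
        return timeline.line_end

    cur = sys_blocks[0]
    cur_start, cur_end = cur.start, cur.end
    comps = set(cur.components)
    comp_last = dict(cur.component_last)

    def merge(b: TreatmentBlock) -> None:
        nonlocal cur_end
        comps.update(b.components)
        for c, d in b.component_last.items():
            if c not in comp_last or d > comp_last[c]:
                comp_last[c] = d
        cur_end = max(cur_end, b.end)

    for b in sys_blocks[1:]:
        new = set(b.components)
        if b.start <= cur_end:
            removed = {
                c for c in comps
                if comp_last.get(c, cur_end) < b.start
                and (b.start - comp_last.get(c, cur_end)).days <= config.gap_days
            }
            added = new - comps
            if (
                len(comps) > 1
                and removed
                and added
                and (b.end - b.start).days >= config.combo_window_days
            ):
                timeline.line_end = ("switched", b.start)
                return timeline.line_end
            merge(b)
            continue
        gap = (b.start - cur_end).days
        if gap > config.gap_days:
            timeline.line_end = ("discontinued", cur_end)
            return timeline.line_end
        if len(comps) == 1 and len(new) == 1 and new != comps:
            if (b.start - cur_start).days >= config.combo_window_days:
                timeline.line_end = ("switched", b.start)
                return timeline.line_end
        if (
            len(comps) > 1
            and (comps - new)
            and (new - comps)
            and (b.end - b.start).days >= config.combo_window_days
        ):
            timeline.line_end = ("switched", b.start)
            return timeline.line_end
        merge(b)

    if observation_end is not None and (observation_end - cur_end).days <= config.gap_days:
        timeline.line_end = ("ongoing", None)
    else:
        timeline.line_end = ("discontinued", cur_end)
    return timeline.line_end


# ---------------------------------------------------------------------------
# driver


def derive_timeline(
    bundle: ClaimsBundle,
    index_date: date,
    config: Optional[WindowConfig] = None,
) -> EpisodeTimeline:
    """Full per-patient derivation: blocks, CRT pairing, LA assembly, line end."""
    config = config or WindowConfig()
    rt_dates = [
        p.date
        for p in bundle.procedures
        if p.category == ProcedureCategory.RADIOTHERAPY_FRACTION and p.date >= index_date
    ]
    surgery_blocks = [
        TreatmentBlock("surgery", p.date, p.date, frozenset({"surgery"}))
        for p in bundle.procedures
        if p.category == ProcedureCategory.SURGERY_RESECTION and p.date >= index_date
    ]
    rt_blocks = build_rt_courses(rt_dates, config)
    sys_blocks = build_systemic_regimens(
        [d for d in bundle.drugs if d.date >= index_date], config
    )
    blocks = surgery_blocks + rt_blocks + sys_blocks
    pair_concurrent_crt(blocks, config)
    tl = assemble_la_treatment(blocks, index_date, config)
    tl.neck_dissection_dates = [
        p.date
        for p in bundle.procedures
        if p.category == ProcedureCategory.NECK_DISSECTION and p.date >= index_date
    ]
    obs_end = bundle.patient.enroll_end
    if bundle.patient.death_date is not None and bundle.patient.death_date < obs_end:
        obs_end = bundle.patient.death_date
    detect_line_end(tl, observation_end=obs_end, config=config)
    return tl
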