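"""Independent brute-force day-scanner for the treatment-sequencing rules.

Deliberately written as literal day-stepping loops over integer day
offsets, with no code shared with the package's episode engine; used to
cross-check blocks, CRT pairings and line ends on random small timelines.

Events are tuples on an integer day axis:
    ("surgery", day) | ("rt", day) | ("drug", day, agent)
"""

from __future__ import annotations

COMBO = 8
CONCURRENT = 14
GAP = 60
RT_MERGE = 14
MODALITY_WINDOW = 90
TREATED_WINDOW = 183


def scan_rt_courses(days):
    """Walk the day axis; an idle stretch longer than RT_MERGE closes a course."""
    days = sorted(days)
    if not days:
        return []
    courses = []
    start = prev = days[0]
    count = 1
    for d in days[1:]:
        idle = 0
        day = prev
        while day < d:
            day += 1
            idle += 1
        if idle > RT_MERGE:
            courses.append({"modality": "radiotherapy", "start": start, "end": prev,
                            "components": frozenset({"rt_course"}), "fractions": count})
            start = d
            count = 0
        prev = d
        count += 1
    courses.append({"modality": "radiotherapy", "start": start, "end": prev,
                    "components": frozenset({"rt_course"}), "fractions": count})
    return courses


def scan_regimens(admins):
    """Day-stepping regimen scanner.

    Anchor at the earliest unused administration; agents whose first unused
    administration lies within COMBO days of the anchor are components; the
    block then advances one day at a time consuming component
    administrations until more than GAP consecutive idle days pass.
    """
    admins = sorted(admins)  # (day, agent)
    used = [False] * len(admins)
    blocks = []
    while not all(used):
        ai = min(i for i in range(len(admins)) if not used[i])
        a_day = admins[ai][0]
        first = {}
        for i, (d, ag) in enumerate(admins):
            if not used[i] and ag not in first:
                first[ag] = d
        comps = frozenset(ag for ag, d in first.items() if a_day <= d <= a_day + COMBO)
        comp_last = {}
        # consume the anchor day, then advance one day at a time; a day more
        # than GAP days after the last administration closes the block
        # before that day's administrations are looked at
        day = a_day
        end = a_day
        for i, (d, ag) in enumerate(admins):
            if not used[i] and d == a_day and ag in comps:
                used[i] = True
                comp_last[ag] = d
        horizon = max(d for d, _ in admins)
        idle = 0
        while day <= horizon:
            day += 1
            idle += 1
            if idle > GAP:
                break
            hit = False
            for i, (d, ag) in enumerate(admins):
                if not used[i] and d == day and ag in comps:
                    used[i] = True
                    hit = True
                    comp_last[ag] = d
            if hit:
                idle = 0
                end = day
        blocks.append({"modality": "systemic", "start": a_day, "end": end,
                       "components": comps, "fractions": 0,
                       "comp_last": comp_last})
    blocks.sort(key=lambda b: b["start"])
    return blocks


def scan_pairings(sys_blocks, rt_blocks):
    """Exhaustively test every (systemic, RT) pair against the 14-day rule,
    then assign partners nearest-start first, ties to the earlier block."""
    pairs = []
    for s in sys_blocks:
        for r in rt_blocks:
            diff = abs(s["start"] - r["start"])
            if diff <= CONCURRENT:
                pairs.append((diff, r["start"], s["start"], id(s), id(r), s, r))
    pairs.sort(key=lambda t: t[:3])
    taken = set()
    out = []
    for diff, _, _, sid, rid, s, r in pairs:
        if sid in taken or rid in taken:
            continue
        taken.add(sid)
        taken.add(rid)
        out.append((s["start"], r["start"]))
    return sorted(out)


def scan_timeline(events, index_day=0):
    """Blocks + treated flag + LA window membership + line end, from scratch."""
    surgery = [{"modality": "surgery", "start": d, "end": d,
                "components": frozenset({"surgery"}), "fractions": 0}
               for kind, d in ((e[0], e[1]) for e in events) if kind == "surgery"]
    rt = scan_rt_courses([e[1] for e in events if e[0] == "rt"])
    systemic = scan_regimens([(e[1], e[2]) for e in events if e[0] == "drug"])
    blocks = [b for b in surgery + rt + systemic if b["start"] >= index_day]
    pairings = scan_pairings(
        [b for b in blocks if b["modality"] == "systemic"],
        [b for b in blocks if b["modality"] == "radiotherapy"],
    )
    paired_starts = set()
    for s_start, r_start in pairings:
        paired_starts.add(("systemic", s_start))
        paired_starts.add(("radiotherapy", r_start))

    order = {"surgery": 0, "systemic": 1, "radiotherapy": 2}
    blocks.sort(key=lambda b: (b["start"], order[b["modality"]]))
    if not blocks:
        return {"treated": False, "la": [], "after": [], "pairings": pairings,
                "blocks": blocks, "line_end": ("ongoing", None)}
    first = blocks[0]["start"]
    treated = (first - index_day) <= TREATED_WINDOW
    if not treated:
        return {"treated": False, "la": [], "after": blocks, "pairings": pairings,
                "blocks": blocks, "line_end": ("ongoing", None)}

    partner_of = {}
    for s_start, r_start in pairings:
        partner_of[("systemic", s_start)] = ("radiotherapy", r_start)
        partner_of[("radiotherapy", r_start)] = ("systemic", s_start)

    la, after = [], []
    for b in blocks:
        if b["start"] - first <= MODALITY_WINDOW:
            la.append(b)
    la_keys = {(b["modality"], b["start"]) for b in la}
    for b in blocks:
        key = (b["modality"], b["start"])
        if key in la_keys:
            continue
        partner = partner_of.get(key)
        if partner is not None and partner in la_keys:
            la.append(b)
            la_keys.add(key)
        else:
            after.append(b)
    la.sort(key=lambda b: (b["start"], order[b["modality"]]))

    line_end = _scan_line_end(la, after)
    return {"treated": True, "la": la, "after": after, "pairings": pairings,
            "blocks": blocks, "line_end": line_end}


def _scan_line_end(la, after, observation_end=None):
    sys_blocks = sorted(
        (b for b in la + after if b["modality"] == "systemic"),
        key=lambda b: (b["start"], b["end"]),
    )
    if not sys_blocks:
        if not la:
            return ("ongoing", None)
        last_end = max(b["end"] for b in la)
        if observation_end is not None and observation_end - last_end <= GAP:
            return ("ongoing", None)
        return ("discontinued", last_end)
    cur = sys_blocks[0]
    cur_start, cur_end = cur["start"], cur["end"]
    comps = set(cur["components"])
    comp_last = dict(cur.get("comp_last", {c: cur["end"] for c in comps}))

    def merge(b):
        nonlocal cur_end
        comps.update(b["components"])
        for c, d in b.get("comp_last", {c: b["end"] for c in b["components"]}).items():
            if c not in comp_last or d > comp_last[c]:
                comp_last[c] = d
        cur_end = max(cur_end, b["end"])

    for b in sys_blocks[1:]:
        new = set(b["components"])
        if b["start"] <= cur_end:
            removed = {
                c for c in comps
                if comp_last.get(c, cur_end) < b["start"]
                and b["start"] - comp_last.get(c, cur_end) <= GAP
            }
            added = new - comps
            if len(comps) > 1 and removed and added and b["end"] - b["start"] >= COMBO:
                return ("switched", b["start"])
            merge(b)
            continue
        if b["start"] - cur_end > GAP:
            return ("discontinued", cur_end)
        if len(comps) == 1 and len(new) == 1 and new != comps:
            if b["start"] - cur_start >= COMBO:
                return ("switched", b["start"])
        if len(comps) > 1 and (comps - new) and (new - comps) and b["end"] - b["start"] >= COMBO:
            return ("switched", b["start"])
        merge(b)
    if observation_end is not None and observation_end - cur_end <= GAP:
        return ("ongoing", None)
    return ("discontinued", cur_end)
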