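from __future__ import annotations

import random

import numpy as np
import pytest

from hnclaims.episodes import (
    WindowConfig,
    build_rt_courses,
    build_systemic_regimens,
    detect_line_end,
    pair_concurrent_crt,
)
from hnclaims.model import Agent, DrugClaim

from conftest import block_tuple, day, make_bundle, oracle_tuple, run_engine
from oracle import scan_timeline


def drug(d, agent="cisplatin"):
    return ("drug", d, agent)


class TestRtCourses:
    def test_daily_fractions_form_one_course(self):
        blocks = build_rt_courses([day(i) for i in range(33)])
        assert len(blocks) == 1
        assert blocks[0].fraction_count == 33
        assert (blocks[0].start, blocks[0].end) == (day(0), day(32))

    def test_long_gap_splits_courses(self):
        days = [day(i) for i in range(0, 21)] + [day(i) for i in range(41, 61)]
        blocks = build_rt_courses(days)
        assert len(blocks) == 2

    def test_single_fraction(self):
        blocks = build_rt_courses([day(5)])
        assert blocks[0].start == blocks[0].end == day(5)
        assert blocks[0].fraction_count == 1

    @pytest.mark.parametrize("gap,n_courses", [(14, 1), (15, 2)])
    def test_merge_gap_boundary(self, gap, n_courses):
        blocks = build_rt_courses([day(0), day(gap)])
        assert len(blocks) == n_courses


class TestSystemicRegimens:
    def _claims(self, pairs):
        return [DrugClaim("x", day(d), Agent(a)) for d, a in pairs]

    def test_tpf_within_combo_window_is_one_block(self):
        blocks = build_systemic_regimens(
            self._claims([(0, "docetaxel"), (1, "cisplatin"), (1, "fluorouracil")])
        )
        assert len(blocks) == 1
        assert blocks[0].components == {"docetaxel", "cisplatin", "fluorouracil"}

    def test_late_agent_opens_its_own_block(self):
        blocks = build_systemic_regimens(
            self._claims([(0, "cisplatin"), (20, "cetuximab")])
        )
        assert len(blocks) == 2
        assert {b.components for b in blocks} == {
            frozenset({"cisplatin"}),
            frozenset({"cetuximab"}),
        }

    def test_cycles_within_gap_stay_one_block(self):
        blocks = build_systemic_regimens(
            self._claims([(0, "cisplatin"), (21, "cisplatin"), (42, "cisplatin")])
        )
        assert len(blocks) == 1
        assert blocks[0].end == day(42)

    @pytest.mark.parametrize("offset,n_blocks", [(8, 1), (9, 2)])
    def test_combo_window_boundary(self, offset, n_blocks):
        blocks = build_systemic_regimens(
            self._claims([(0, "cisplatin"), (offset, "fluorouracil")])
        )
        assert len(blocks) == n_blocks

    @pytest.mark.parametrize("gap,n_blocks", [(60, 1), (61, 2)])
    def test_lapse_boundary(self, gap, n_blocks):
        blocks = build_systemic_regimens(
            self._claims([(0, "cisplatin"), (gap, "cisplatin")])
        )
        assert len(blocks) == n_blocks

    def test_all_cause_prescriptions_ignored(self):
        claims = self._claims([(0, "cisplatin")]) + [
            DrugClaim("x", day(3), Agent.OTHER, atc="N02BE01")
        ]
        blocks = build_systemic_regimens(claims)
        assert len(blocks) == 1
        assert blocks[0].components == {"cisplatin"}

    def test_unknown_antineoplastic_by_atc_included(self):
        claims = [DrugClaim("x", day(0), Agent.OTHER, atc="L01XC08")]
        blocks = build_systemic_regimens(claims)
        assert len(blocks) == 1
        assert blocks[0].components == {"other"}


class TestCrtPairing:
    @pytest.mark.parametrize("sys_day,paired", [(30, True), (44, True), (45, False)])
    def test_concurrency_boundary(self, sys_day, paired):
        tl = run_engine([("rt", d) for d in range(30, 70)] + [drug(sys_day)])
        sys_block = next(b for b in tl.blocks if b.modality == "systemic")
        assert (sys_block.concurrent_with is not None) == paired

    def test_widening_window_never_unpairs(self):
        events = [("rt", d) for d in range(10, 50)] + [drug(20), drug(41)]
        paired_narrow = {
            (b.modality, b.start)
            for b in run_engine(events).blocks
            if b.concurrent_with is not None
        }
        wide = run_engine(events, config=WindowConfig(concurrent_window_days=30))
        paired_wide = {
            (b.modality, b.start) for b in wide.blocks if b.concurrent_with is not None
        }
        assert paired_narrow <= paired_wide


class TestAssembly:
    def test_surgery_then_rt_within_window(self):
        tl = run_engine([("surgery", 10)] + [("rt", d) for d in range(55, 95)])
        assert tl.treated
        assert {b.modality for b in tl.blocks} == {"surgery", "radiotherapy"}

    @pytest.mark.parametrize("start,treated", [(183, True), (184, False)])
    def test_treated_window_boundary(self, start, treated):
        tl = run_engine([drug(start)])
        assert tl.treated == treated
        if not treated:
            assert len(tl.events_after_window) == 1

    @pytest.mark.parametrize("second,inside", [(90, True), (91, False)])
    def test_modality_window_boundary(self, second, inside):
        tl = run_engine([("surgery", 0), ("surgery", second)])
        n_la = len(tl.blocks)
        assert (n_la == 2) == inside

    def test_no_blocks_means_not_treated(self):
        tl = run_engine([])
        assert not tl.treated
        assert tl.blocks == []

    def test_concurrent_partner_kept_past_window_edge(self):
        # RT starts on the window edge; its paired systemic starts just outside
        events = [("surgery", 0)] + [("rt", d) for d in range(88, 120)] + [drug(95)]
        tl = run_engine(events)
        assert any(b.modality == "systemic" for b in tl.blocks)


class TestLineEnd:
    @pytest.mark.parametrize("switch_day,status", [(130, "switched"), (170, "discontinued")])
    def test_monotherapy_switch_vs_discontinuation(self, switch_day, status):
        # cisplatin block runs day 10..100 (cycles); cetuximab starts later
        events = [drug(d) for d in (10, 60, 100)] + [drug(switch_day, "cetuximab")]
        tl = run_engine(events)
        assert tl.line_end[0] == status

    def test_combination_switch(self):
        # cisplatin+fluorouracil; fluorouracil stops, docetaxel joins on day
        # 20 and persists 30 days while cisplatin continues
        events = (
            [drug(0, "cisplatin"), drug(0, "fluorouracil"),
             drug(21, "cisplatin"), drug(42, "cisplatin")]
            + [drug(20, "docetaxel"), drug(35, "docetaxel"), drug(50, "docetaxel")]
        )
        tl = run_engine(events)
        assert tl.line_end == ("switched", day(20))

    def test_add_on_does_not_end_line(self):
        # cetuximab joins while cisplatin continues; nothing afterwards
        events = [drug(d) for d in (0, 21, 42, 63)] + [drug(30, "cetuximab")]
        tl = run_engine(events)
        assert tl.line_end[0] in ("ongoing", "discontinued")
        assert tl.line_end[0] != "switched"

    def test_ongoing_when_observation_ends_early(self):
        events = [drug(d) for d in (0, 21, 42)]
        bundle = make_bundle(events, enroll_days=80)
        from hnclaims.episodes import derive_timeline

        tl = derive_timeline(bundle, day(0))
        assert tl.line_end[0] == "ongoing"


AGENTS = ["cisplatin", "fluorouracil", "docetaxel", "cetuximab"]


def _random_events(rng: random.Random, n_events: int):
    events = []
    kinds = rng.choices(["surgery", "rt_run", "drug"], weights=[1, 2, 4], k=n_events)
    for kind in kinds:
        d = rng.randint(0, 230)
        if kind == "surgery":
            events.append(("surgery", d))
        elif kind == "rt_run":
            run_len = rng.randint(1, 8)
            step = rng.randint(1, 16)
            events.extend(("rt", d + i * step) for i in range(run_len))
        else:
            events.append(("drug", d, rng.choice(AGENTS)))
    return events


class TestOracleEquivalence:
    """The engine must agree with an independent day-by-day scanner."""

    def test_random_small_timelines(self):
        rng = random.Random(20240915)
        for trial in range(300):
            events = _random_events(rng, rng.randint(0, 12))
            tl = run_engine(events)
            want = scan_timeline(events)
            got_blocks = sorted(
                block_tuple(b) for b in tl.blocks + tl.events_after_window
            )
            want_blocks = sorted(oracle_tuple(b) for b in want["blocks"])
            assert got_blocks == want_blocks, f"trial {trial}: {events}"
            assert tl.treated == want["treated"], f"trial {trial}"
            got_la = sorted(block_tuple(b) for b in tl.blocks)
            want_la = sorted(oracle_tuple(b) for b in want["la"])
            assert got_la == want_la, f"trial {trial}: {events}"
            got_pairs = sorted(
                ((b.start - day(0)).days, (b.concurrent_with.start - day(0)).days)
                for b in tl.blocks + tl.events_after_window
                if b.modality == "systemic" and b.concurrent_with is not None
            )
            assert got_pairs == want["pairings"], f"trial {trial}: {events}"
            if want["treated"]:
                want_status, want_day = want["line_end"]
                got_status, got_date = tl.line_end
                # engine sees the enrollment span; align by ignoring the
                # ongoing/discontinued distinction only when the oracle has
                # no observation end — compare through the oracle's rule
                assert got_status == want_status or (
                    {got_status, want_status} <= {"ongoing", "discontinued"}
                ), f"trial {trial}: {events}"
                if got_status == want_status == "switched":
                    assert (got_date - day(0)).days == want_day

    def test_order_invariance(self):
        rng = random.Random(99)
        for _ in range(50):
            events = _random_events(rng, rng.randint(1, 12))
            tl1 = run_engine(events)
            shuffled = events[:]
            rng.shuffle(shuffled)
            tl2 = run_engine(shuffled)
            assert sorted(block_tuple(b) for b in tl1.blocks) == sorted(
                block_tuple(b) for b in tl2.blocks
            )
            assert tl1.treated == tl2.treated
            assert tl1.line_end == tl2.line_end
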