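"""End-to-end drivers tying the pipeline stages together."""

from __future__ import annotations

from typing import Iterable, Optional

from .cohort import CohortRecord, EciMapping, SelectionConfig, select_cohort
from .episodes import EpisodeTimeline, WindowConfig, derive_timeline
from .model import ClaimsBundle
from .patterns import PatternLabel, classify

__all__ = ["derive_and_classify", "run_pipeline"]


def derive_and_classify(
    bundles: Iterable[ClaimsBundle],
    records: Iterable[CohortRecord],
    window_config: Optional[WindowConfig] = None,
) -> dict[str, tuple[EpisodeTimeline, PatternLabel]]:
    """Episode derivation + classification for every eligible patient."""
    window_config = window_config or WindowConfig()
    by_id = {b.patient_id: b for b in bundles}
    out: dict[str, tuple[EpisodeTimeline, PatternLabel]] = {}
    for r in records:
        if not r.eligible or r.index_date is None:
            continue
        tl = derive_timeline(by_id[r.patient_id], r.index_date, window_config)
        out[r.patient_id] = (tl, classify(tl))
    return out


def run_pipeline(
    bundles: list[ClaimsBundle],
    selection_config: Optional[SelectionConfig] = None,
    window_config: Optional[WindowConfig] = None,
    eci_mapping: Optional[EciMapping] = None,
) -> tuple[list[CohortRecord], dict[str, tuple[EpisodeTimeline, PatternLabel]]]:
    """Cohort selection, episode derivation and pattern classification."""
    records = select_cohort(bundles, selection_config, eci_mapping=eci_mapping)
    classified = derive_and_classify(bundles, records, window_config)
    return records, classified
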