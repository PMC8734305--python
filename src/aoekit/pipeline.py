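"""End-to-end driver: screen -> group -> adjudicate -> outcomes.

This is the glue the CLI, the acceptance script and the tests share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

from .grouping import group_into_candidate_events
from .rules import build_review_view
from .screening import (
    ScreenResult,
    TermList,
    assemble_case_packages,
    packaged_aoe_terms,
    packaged_cardiac_failure_terms,
    packaged_symptom_terms,
    screen_adverse_events,
)
from .types import AdjudicatedOutcome, CandidateEvent, StudyDataset
from .workflow import CommitteeResult, Reviewer, default_roster, run_committee

log = logging.getLogger("aoekit.pipeline")


@dataclass
class PipelineResult:
    screen: ScreenResult
    events: List[CandidateEvent]
    committee: CommitteeResult
    outcomes: List[AdjudicatedOutcome] = field(default_factory=list)

    @property
    def aoe_outcomes(self) -> List[AdjudicatedOutcome]:
        return [o for o in self.outcomes if o.is_aoe]


def run_pipeline(
    ds: StudyDataset,
    aoe_terms: Optional[TermList] = None,
    cardiac_failure_terms: Optional[TermList] = None,
    symptom_terms: Optional[TermList] = None,
    roster: Optional[Sequence[Reviewer]] = None,
    window_hours: float = 48.0,
    seed: int = 0,
) -> PipelineResult:
    aoe_terms = aoe_terms or packaged_aoe_terms()
    cardiac_failure_terms = cardiac_failure_terms or packaged_cardiac_failure_terms()
    symptom_terms = symptom_terms or packaged_symptom_terms()
    roster = list(roster) if roster is not None else default_roster()

    screen = screen_adverse_events(ds, aoe_terms, cardiac_failure_terms)
    packages = assemble_case_packages(screen, ds)
    events = group_into_candidate_events(packages, window_hours=window_hours)

    views = [
        build_review_view(ev, death=ds.patients[ev.patient_id].death if ev.fatal else None)
        for ev in events
    ]
    committee = run_committee(events, views, roster, seed=seed, symptom_terms=symptom_terms)

    outcomes = []
    for event, trace in zip(events, committee.traces):
        d = trace.final
        outcomes.append(
            AdjudicatedOutcome(
                event_id=event.event_id,
                patient_id=event.patient_id,
                endpoint=d.endpoint,
                is_aoe=d.is_aoe,
                category=d.category,
                serious=event.serious,
                fatal=event.fatal,
                revascularization_associated=d.revascularization_associated,
                panel_review=d.panel_review,
                criteria_trace=d.trace,
                onset_day=event.onset_day,
                member_record_ids=event.member_record_ids,
            )
        )
    result = PipelineResult(screen=screen, events=events, committee=committee, outcomes=outcomes)
    log.info(
        "pipeline: %d events adjudicated, %d AOEs in %d patients",
        len(outcomes),
        len(result.aoe_outcomes),
        len({o.patient_id for o in result.aoe_outcomes}),
    )
    return result
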