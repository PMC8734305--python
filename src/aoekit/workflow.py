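"""Committee workflow: independent reviews, escalation, panels, consensus.

Two independent reviewers score each candidate event; agreement on
(endpoint, is_aoe) finalizes it.  Disagreements on the cardiac route go to
a third cardiologist (any 2-of-3 wins) and then to a panel; disagreements
on the stroke/DVT/PE/PVD route go straight to a panel including the
required specialist.  Fatal cases are decided by consensus of all
adjudicators.  Reviewers are the deterministic rule engine, optionally
perturbed with a per-criterion flip probability to exercise escalation.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .rules import (
    Decision,
    ReviewView,
    classify_candidate_event,
    classify_fatal_case,
)
from .screening import TermList
from .types import CandidateEvent, CriterionStatus, Route

log = logging.getLogger("aoekit.workflow")


class Specialty(str, enum.Enum):
    CARDIOLOGIST = "cardiologist"
    NEUROLOGIST = "neurologist"
    VASCULAR_SPECIALIST = "vascular_specialist"


@dataclass(frozen=True)
class Reviewer:
    reviewer_id: str
    specialty: Specialty
    flip_probability: float = 0.0

    def decide(self, view: ReviewView, rng: Optional[np.random.Generator],
               symptom_terms: Optional[TermList] = None) -> Decision:
        perturb = None
        if self.flip_probability > 0.0 and rng is not None:
            p = self.flip_probability

            def perturb(criterion_id, status):
                if rng.random() < p:
                    return (
                        CriterionStatus.NOT_MET
                        if status is CriterionStatus.MET
                        else CriterionStatus.MET
                    )
                return status

        if view.fatal and view.death is not None:
            return classify_fatal_case(view, perturb=perturb)
        return classify_candidate_event(view, symptom_terms=symptom_terms, perturb=perturb)


def default_roster(flip_probability: float = 0.0) -> List[Reviewer]:
    """3 cardiologists, 1 vascular neurologist, 1 vascular specialist."""
    return [
        Reviewer("C1", Specialty.CARDIOLOGIST, flip_probability),
        Reviewer("C2", Specialty.CARDIOLOGIST, flip_probability),
        Reviewer("C3", Specialty.CARDIOLOGIST, flip_probability),
        Reviewer("N1", Specialty.NEUROLOGIST, flip_probability),
        Reviewer("V1", Specialty.VASCULAR_SPECIALIST, flip_probability),
    ]


class Stage(str, enum.Enum):
    TWO_AGREE = "two_agree"
    THIRD_REVIEWER = "third_reviewer"
    PANEL = "panel"
    FATAL_CONSENSUS = "fatal_consensus"


@dataclass(frozen=True)
class AdjudicationTrace:
    event_id: str
    votes: tuple  # ((reviewer_id, Decision), ...)
    stage_reached: Stage
    final: Decision
    panel_specialty: Optional[Specialty] = None


def _panel_specialty_for(route: Route) -> Optional[Specialty]:
    if route is Route.STROKE_DVT_PE_PVD:
        return Specialty.NEUROLOGIST
    return None


def _panel_decision(view: ReviewView, symptom_terms=None) -> Decision:
    """Panel = deterministic rule engine with the conservative unknown
    policy (the charter gives no decision rule beyond discussion)."""
    if view.fatal and view.death is not None:
        return classify_fatal_case(view)
    return classify_candidate_event(view, symptom_terms=symptom_terms)


def adjudicate_case(
    event: CandidateEvent,
    view: ReviewView,
    roster: Sequence[Reviewer],
    seed=0,
    rng: Optional[np.random.Generator] = None,
    symptom_terms: Optional[TermList] = None,
) -> AdjudicationTrace:
    cardiologists = [r for r in roster if r.specialty is Specialty.CARDIOLOGIST]
    if len(cardiologists) < 3:
        raise ValueError("roster must include at least 3 cardiologists")

    if rng is None:
        rng = np.random.default_rng(seed)

    if event.fatal and view.death is not None:
        votes = [(r.reviewer_id, r.decide(view, rng, symptom_terms)) for r in roster]
        final = _panel_decision(view, symptom_terms)
        return AdjudicationTrace(
            event_id=event.event_id,
            votes=tuple(votes),
            stage_reached=Stage.FATAL_CONSENSUS,
            final=final,
        )

    first, second = cardiologists[0], cardiologists[1]
    v1 = first.decide(view, rng, symptom_terms)
    v2 = second.decide(view, rng, symptom_terms)
    votes = [(first.reviewer_id, v1), (second.reviewer_id, v2)]
    if v1.vote_key == v2.vote_key:
        return AdjudicationTrace(
            event_id=event.event_id,
            votes=tuple(votes),
            stage_reached=Stage.TWO_AGREE,
            final=v1,
        )

    if event.route is Route.STROKE_DVT_PE_PVD:
        specialty = _panel_specialty_for(event.route)
        if specialty is not None and not any(r.specialty is specialty for r in roster):
            raise ValueError(f"panel requires a {specialty.value} on the roster")
        return AdjudicationTrace(
            event_id=event.event_id,
            votes=tuple(votes),
            stage_reached=Stage.PANEL,
            final=_panel_decision(view, symptom_terms),
            panel_specialty=specialty,
        )

    third = cardiologists[2]
    v3 = third.decide(view, rng, symptom_terms)
    votes.append((third.reviewer_id, v3))
    tally = Counter(v.vote_key for _, v in votes)
    key, count = tally.most_common(1)[0]
    if count >= 2:
        final = next(v for _, v in votes if v.vote_key == key)
        return AdjudicationTrace(
            event_id=event.event_id,
            votes=tuple(votes),
            stage_reached=Stage.THIRD_REVIEWER,
            final=final,
        )
    return AdjudicationTrace(
        event_id=event.event_id,
        votes=tuple(votes),
        stage_reached=Stage.PANEL,
        final=_panel_decision(view, symptom_terms),
    )


@dataclass
class CommitteeResult:
    traces: List[AdjudicationTrace] = field(default_factory=list)
    stage_histogram: Counter = field(default_factory=Counter)

    @property
    def finals(self) -> List[Decision]:
        return [t.final for t in self.traces]


def run_committee(
    events: Sequence[CandidateEvent],
    views: Sequence[ReviewView],
    roster: Sequence[Reviewer],
    seed: int = 0,
    symptom_terms: Optional[TermList] = None,
) -> CommitteeResult:
    """Batch driver; deterministic given the seed (one child seed per
    case, so case order does not leak randomness between cases)."""
    if len(events) != len(views):
        raise ValueError("events and views must align")
    result = CommitteeResult()
    root = np.random.SeedSequence(seed)
    child_seeds = root.spawn(len(events)) if len(events) else []
    for event, view, child in zip(events, views, child_seeds):
        trace = adjudicate_case(
            event, view, roster,
            rng=np.random.default_rng(child),
            symptom_terms=symptom_terms,
        )
        result.traces.append(trace)
        result.stage_histogram[trace.stage_reached] += 1
    log.info("committee stages: %s", dict(result.stage_histogram))
    return result
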