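"""48-hour clustering of screened records into candidate clinical events.

Two records belong to the same candidate event iff they are connected by a
chain of pairwise onset gaps of at most the grouping window (single-linkage
/ transitive chaining).  When onset hours are absent the gap is computed on
calendar days, with a difference of <= 2 days counting as within a 48-h
window.
"""

from __future__ import annotations

import logging
from typing import Iterable, List

from .screening import CasePackage, normalize_term
from .types import CandidateEvent, EvidencePackage, Route, UNKNOWN_EVIDENCE

log = logging.getLogger("aoekit.grouping")

# PT fragments that push a cluster onto the stroke/DVT/PE/PVD review route
_RIGHT_ROUTE_MARKERS = (
    "stroke",
    "cerebr",
    "carotid",
    "transient ischaemic attack",
    "transient ischemic attack",
    "deep vein thrombosis",
    "pulmonary embolism",
    "peripheral arterial",
    "peripheral artery",
    "peripheral vascular",
    "peripheral ischaemia",
    "peripheral ischemia",
    "retinal",
    "lacunar",
    "basilar",
    "vertebral artery",
)


def records_within_window(a, b, window_hours: float) -> bool:
    """Pairwise window test honouring date-only records."""
    if a.onset_hour is None or b.onset_hour is None:
        return abs(a.onset_day - b.onset_day) <= int(window_hours // 24)
    return abs(a.onset_hours() - b.onset_hours()) <= window_hours


def _route_for(pts: Iterable[str]) -> Route:
    for pt in pts:
        npt = normalize_term(pt)
        if any(marker in npt for marker in _RIGHT_ROUTE_MARKERS):
            return Route.STROKE_DVT_PE_PVD
    return Route.AOE_HF


def merge_evidence(members: List[EvidencePackage]) -> EvidencePackage:
    """Pool member evidence: sets union, extremes win, known beats unknown."""
    if not members:
        raise ValueError("merge_evidence requires at least one package")
    merged = members[0]
    for ev in members[1:]:
        merged = _merge_pair(merged, ev)
    return merged


def _merge_pair(a: EvidencePackage, b: EvidencePackage) -> EvidencePackage:
    kwargs = {}
    for name in (
        "ecg",
        "imaging",
        "symptoms",
        "neuro_confirmation",
        "procedure",
    ):
        kwargs[name] = getattr(a, name) | getattr(b, name)
    for name in ("troponin_ratio_to_URL", "neuro_deficit_duration_hours"):
        va, vb = getattr(a, name), getattr(b, name)
        kwargs[name] = max((v for v in (va, vb) if v is not None), default=None)
    for name in ("hf_exam_findings_count", "hf_lab_findings_count"):
        kwargs[name] = max(getattr(a, name), getattr(b, name))
    for name in (
        "troponin_rise_fall",
        "ckmb_above_URL",
        "baseline_biomarker_normal",
        "biomarker_decreasing_prior",
        "stroke_abort_intervention",
        "non_stroke_cause_present",
        "hf_primary_diagnosis",
        "hf_treatment_intensified",
        "hf_oral_diuretic_only",
        "urgent_visit",
        "superficial_thrombosis_signs",
    ):
        va, vb = getattr(a, name), getattr(b, name)
        if va is None:
            kwargs[name] = vb
        elif vb is None:
            kwargs[name] = va
        else:
            if va != vb:
                log.warning("conflicting %s during evidence merge; keeping True", name)
            kwargs[name] = va or vb
    for name in (
        "hf_underlying_cause",
        "hospitalization",
        "mi_context",
        "pvd_vessel_side",
        "vte_location",
        "procedure_timing_hours",
        "cv_other_cause",
        "non_cv_cause",
    ):
        va, vb = getattr(a, name), getattr(b, name)
        kwargs[name] = va if va is not None else vb
    return EvidencePackage(**kwargs)


def group_into_candidate_events(
    packages: List[CasePackage], window_hours: float = 48.0
) -> List[CandidateEvent]:
    """Partition per-patient case packages into candidate events.

    The output is independent of input order: members are sorted by onset
    and clusters by (patient, window start).
    """
    if window_hours <= 0:
        raise ValueError("window_hours must be positive")

    by_patient: dict = {}
    for pkg in packages:
        by_patient.setdefault(pkg.record.patient_id, []).append(pkg)

    events: List[CandidateEvent] = []
    for pid in sorted(by_patient):
        pkgs = sorted(
            by_patient[pid],
            key=lambda p: (p.record.onset_day, p.record.onset_hour or 0, p.record.record_id),
        )
        # single-linkage over the sorted sequence: a gap > window between
        # consecutive onsets closes the cluster (equivalent to connected
        # components of the pairwise-gap graph on a line)
        clusters: List[List[CasePackage]] = []
        for pkg in pkgs:
            if clusters and records_within_window(
                clusters[-1][-1].record, pkg.record, window_hours
            ):
                clusters[-1].append(pkg)
            else:
                clusters.append([pkg])
        for cluster in clusters:
            events.append(_build_event(pid, cluster))
    for ev in events:
        log.debug("cluster %s: %d member(s)", ev.event_id, len(ev.members))
    log.info("grouped %d packages into %d candidate events", len(packages), len(events))
    return events


def _build_event(patient_id: str, cluster: List[CasePackage]) -> CandidateEvent:
    records = tuple(p.record for p in cluster)
    first, last = records[0], records[-1]
    known = [p.evidence for p in cluster if p.evidence_known]
    merged = merge_evidence(known) if known else UNKNOWN_EVIDENCE
    event_id = f"E-{patient_id}-{first.onset_day:05d}-{first.record_id}"
    return CandidateEvent(
        event_id=event_id,
        patient_id=patient_id,
        member_record_ids=tuple(r.record_id for r in records),
        members=records,
        window_start_day=first.onset_day,
        window_end_day=last.onset_day,
        window_start_hour=first.onset_hour,
        window_end_hour=last.onset_hour,
        serious=any(r.serious for r in records),
        fatal=any(r.fatal for r in records),
        merged_evidence=merged,
        route=_route_for(r.preferred_term for r in records),
    )
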