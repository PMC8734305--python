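"""Incidence, exposure, time-to-onset, risk-strata and dose summaries.

Printed-percent reproductions round half-away-from-zero to the integer, as
forced by the trial's own tables.  Patient-years use 365.25 days/year and
reporting months use 30.4375 days/month.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    AdjudicatedOutcome,
    AdverseEventRecord,
    Category,
    Cohort,
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    DOSE_ACTION_SEVERITY,
    DoseAction,
    IncidenceResult,
    PatientRecord,
    StudyDataset,
)

log = logging.getLogger("aoekit.analytics")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (2.5 -> 3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(numerator: int, denominator: int) -> int:
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return round_half_away(100.0 * numerator / denominator)


def _aoe_outcomes(outcomes: Iterable[AdjudicatedOutcome], serious_only=False,
                  category: Optional[Category] = None) -> List[AdjudicatedOutcome]:
    out = [o for o in outcomes if o.is_aoe]
    if serious_only:
        out = [o for o in out if o.serious]
    if category is not None:
        out = [o for o in out if o.category is category]
    return out


def patient_level_rates(
    outcomes: Sequence[AdjudicatedOutcome],
    patients: Dict[str, PatientRecord],
    cohort: Optional[Cohort] = None,
    serious_only: bool = False,
    category: Optional[Category] = None,
    source: str = "adjudicated",
    records: Optional[Sequence[AdverseEventRecord]] = None,
) -> IncidenceResult:
    """Distinct patients with >= 1 qualifying event over a cohort slice.

    ``source='nonadjudicated'`` uses the legacy PT-based AOE labels carried
    on the input AE records instead of adjudicated outcomes.
    """
    pool = {pid: p for pid, p in patients.items() if cohort is None or p.cohort is cohort}
    if not pool:
        raise ValueError("empty denominator population")
    if source == "adjudicated":
        qualifying = _aoe_outcomes(outcomes, serious_only, category)
        positive = {o.patient_id for o in qualifying if o.patient_id in pool}
    elif source == "nonadjudicated":
        if records is None:
            raise ValueError("nonadjudicated rates require the input AE records")
        positive = {
            r.patient_id
            for r in records
            if r.nonadjudicated_aoe
            and (not serious_only or r.serious)
            and r.patient_id in pool
        }
    else:
        raise ValueError(f"unknown source {source!r}")
    num, den = len(positive), len(pool)
    return IncidenceResult(
        stratum=f"{source}:{cohort.value if cohort else 'all'}"
        + (":serious" if serious_only else ""),
        numerator=num,
        denominator=den,
        rate_percent=percent(num, den),
    )


def first_events_by_patient(
    outcomes: Sequence[AdjudicatedOutcome],
    serious_only: bool = False,
    category: Optional[Category] = None,
) -> Dict[str, AdjudicatedOutcome]:
    firsts: Dict[str, AdjudicatedOutcome] = {}
    for o in _aoe_outcomes(outcomes, serious_only, category):
        if o.onset_day is None:
            continue
        cur = firsts.get(o.patient_id)
        if cur is None or o.onset_day < cur.onset_day:
            firsts[o.patient_id] = o
    return firsts


def exposure_adjusted_incidence(
    outcomes: Sequence[AdjudicatedOutcome],
    patients: Dict[str, PatientRecord],
    interval_years: Optional[Tuple[float, float]] = None,
    serious_only: bool = False,
    censor_at: str = "event_or_end",
) -> IncidenceResult:
    """First events in the interval per 100 patient-years at risk.

    Patients with a first event before the interval are excluded; exposure
    accrues from first dose to min(first event, end of follow-up), clipped
    to the interval.  ``censor_at='last_contact'`` is the sensitivity
    switch that ignores event censoring.
    """
    firsts = first_events_by_patient(outcomes, serious_only)
    lo_days = 0.0 if interval_years is None else interval_years[0] * DAYS_PER_YEAR
    hi_days = math.inf if interval_years is None else interval_years[1] * DAYS_PER_YEAR

    n_events = 0
    total_days = 0.0
    for pid, p in patients.items():
        first = firsts.get(pid)
        event_offset = (
            None if first is None else first.onset_day - p.first_dose_day
        )
        if event_offset is not None and event_offset < lo_days:
            continue  # prior event: excluded from later intervals
        follow_up = p.last_contact_day - p.first_dose_day + 1
        if censor_at == "last_contact":
            at_risk_until = follow_up
        else:
            at_risk_until = follow_up if event_offset is None else min(follow_up, event_offset + 1)
        if event_offset is not None and lo_days <= event_offset < hi_days:
            n_events += 1
        total_days += max(0.0, min(at_risk_until, hi_days) - lo_days)
    if total_days <= 0:
        raise ValueError("zero patient-years at risk in interval")
    py = total_days / DAYS_PER_YEAR
    return IncidenceResult(
        stratum=f"interval:{interval_years}" if interval_years else "interval:all",
        numerator=n_events,
        denominator=len(patients),
        patient_years=py,
        rate_per_100py=100.0 * n_events / py,
    )


@dataclass(frozen=True)
class TimeToEventSummary:
    n: int
    median_months: Optional[float]
    min_months: Optional[float]
    max_months: Optional[float]


def time_to_first_event_summary(
    outcomes: Sequence[AdjudicatedOutcome],
    patients: Dict[str, PatientRecord],
    category: Optional[Category] = None,
    cohort: Optional[Cohort] = None,
) -> TimeToEventSummary:
    firsts = first_events_by_patient(outcomes, category=category)
    months = []
    for pid, o in firsts.items():
        p = patients.get(pid)
        if p is None or (cohort is not None and p.cohort is not cohort):
            continue
        months.append((o.onset_day - p.first_dose_day + 1) / DAYS_PER_MONTH)
    if not months:
        return TimeToEventSummary(0, None, None, None)
    arr = np.asarray(sorted(months))
    return TimeToEventSummary(
        n=len(arr),
        median_months=float(np.median(arr)),
        min_months=float(arr[0]),
        max_months=float(arr[-1]),
    )


RISK_STRATA = ("0", "1-2", ">=3")


def risk_stratum_of(patient: PatientRecord) -> str:
    k = len(patient.risk_factors)
    return "0" if k == 0 else ("1-2" if k <= 2 else ">=3")


def risk_factor_strata(
    outcomes: Sequence[AdjudicatedOutcome],
    patients: Dict[str, PatientRecord],
) -> Dict[str, IncidenceResult]:
    positive = {o.patient_id for o in _aoe_outcomes(outcomes)}
    results = {}
    for stratum in RISK_STRATA:
        members = [p for p in patients.values() if risk_stratum_of(p) == stratum]
        num = sum(1 for p in members if p.patient_id in positive)
        results[stratum] = IncidenceResult(
            stratum=f"risk_factors:{stratum}",
            numerator=num,
            denominator=len(members),
            rate_percent=percent(num, len(members)) if members else None,
        )
    return results


@dataclass(frozen=True)
class RelativeRisk:
    rr: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    table: Tuple[int, int, int, int]  # a, b, c, d
    continuity_corrected: bool = False


def relative_risk_serious_aoe(
    outcomes: Sequence[AdjudicatedOutcome],
    patients: Dict[str, PatientRecord],
    factor,
) -> RelativeRisk:
    """RR of serious adjudicated AOE for carriers of one baseline factor,
    with a 95% log-normal CI."""
    serious = {o.patient_id for o in _aoe_outcomes(outcomes, serious_only=True)}
    a = b = c = d = 0
    for pid, p in patients.items():
        exposed = factor in p.risk_factors
        event = pid in serious
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return compute_relative_risk(a, b, c, d)


def compute_relative_risk(a: int, b: int, c: int, d: int) -> RelativeRisk:
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("empty exposure arm")
    if a == 0 or c == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        rr = (aa / (aa + bb)) / (cc / (cc + dd))
        return RelativeRisk(rr, None, None, (a, b, c, d), continuity_corrected=True)
    rr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return RelativeRisk(
        rr,
        rr * math.exp(-1.959963984540054 * se),
        rr * math.exp(1.959963984540054 * se),
        (a, b, c, d),
    )


@dataclass(frozen=True)
class DoseModificationSummary:
    counts: Dict[str, int]
    n_patients: int

    ROWS = (
        "no_dose_modification",
        "interrupted_only",
        "reduced_only",
        "reduced_and_interrupted",
        "interrupted_and_withdrawn",
        "withdrawn",
        "not_applicable_unknown",
    )


_ACTION_ROW = {
    DoseAction.NONE: "no_dose_modification",
    DoseAction.INTERRUPTED: "interrupted_only",
    DoseAction.REDUCED: "reduced_only",
    DoseAction.REDUCED_AND_INTERRUPTED: "reduced_and_interrupted",
    DoseAction.INTERRUPTED_THEN_WITHDRAWN: "interrupted_and_withdrawn",
    DoseAction.WITHDRAWN: "withdrawn",
    DoseAction.UNKNOWN: "not_applicable_unknown",
}


def worst_dose_action(actions: Iterable[DoseAction]) -> DoseAction:
    return max(actions, key=lambda a: DOSE_ACTION_SEVERITY[a])


def dose_modification_summary(
    outcomes: Sequence[AdjudicatedOutcome],
    dataset: StudyDataset,
    serious_only: bool = False,
) -> DoseModificationSummary:
    """Worst dose action per patient over their adjudicated-AOE events."""
    per_patient: Dict[str, List[DoseAction]] = {}
    for o in _aoe_outcomes(outcomes, serious_only):
        actions = [dataset.record(rid).dose_action for rid in o.member_record_ids]
        per_patient.setdefault(o.patient_id, []).extend(actions or [DoseAction.UNKNOWN])
    counts = {row: 0 for row in DoseModificationSummary.ROWS}
    for pid, actions in per_patient.items():
        counts[_ACTION_ROW[worst_dose_action(actions)]] += 1
    return DoseModificationSummary(counts=counts, n_patients=len(per_patient))


@dataclass(frozen=True)
class ResolutionSummary:
    single_event_patients: int
    single_event_resolved: int
    multi_event_patients: int
    multi_event_all_resolved: int

    @property
    def single_event_pct(self) -> Optional[int]:
        if self.single_event_patients == 0:
            return None
        return percent(self.single_event_resolved, self.single_event_patients)

    @property
    def multi_event_pct(self) -> Optional[int]:
        if self.multi_event_patients == 0:
            return None
        return percent(self.multi_event_all_resolved, self.multi_event_patients)


def resolution_summary(
    outcomes: Sequence[AdjudicatedOutcome],
    dataset: StudyDataset,
) -> ResolutionSummary:
    """An event resolves iff every member record resolved; a multi-event
    patient resolves only if all their AOE events resolved."""
    per_patient: Dict[str, List[bool]] = {}
    for o in _aoe_outcomes(outcomes):
        resolved = all(dataset.record(rid).resolved for rid in o.member_record_ids)
        per_patient.setdefault(o.patient_id, []).append(resolved)
    single = {p: flags for p, flags in per_patient.items() if len(flags) == 1}
    multi = {p: flags for p, flags in per_patient.items() if len(flags) > 1}
    return ResolutionSummary(
        single_event_patients=len(single),
        single_event_resolved=sum(1 for f in single.values() if f[0]),
        multi_event_patients=len(multi),
        multi_event_all_resolved=sum(1 for f in multi.values() if all(f)),
    )


def baseline_summary(patients: Dict[str, PatientRecord]) -> dict:
    """Cohort sizes, demographics and risk-factor prevalences."""
    vals = list(patients.values())
    n = len(vals)
    ages = sorted(p.age_years for p in vals)
    cohorts = {c: sum(1 for p in vals if p.cohort is c) for c in Cohort}
    factor_counts: Dict[str, int] = {}
    for p in vals:
        for f in p.risk_factors:
            factor_counts[f.value] = factor_counts.get(f.value, 0) + 1
    n_female = sum(1 for p in vals if p.sex.value == "female")
    return {
        "n_patients": n,
        "cohort_sizes": {c.value: cohorts[c] for c in Cohort},
        "median_age": float(np.median(ages)) if ages else None,
        "age_range": (ages[0], ages[-1]) if ages else None,
        "female_n": n_female,
        "female_pct": percent(n_female, n) if n else None,
        "risk_factor_counts": dict(sorted(factor_counts.items())),
        "risk_strata_sizes": {
            s: sum(1 for p in vals if risk_stratum_of(p) == s) for s in RISK_STRATA
        },
    }
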