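"""Deterministic endpoint classification with criteria traces.

Each classifier evaluates named criteria against a pooled
:class:`~aoekit.types.EvidencePackage` using three-valued logic
(met / not met / unknown).  Under the default policy an unknown criterion
counts as not met for automatic classification; when unknowns alone block
an otherwise-met endpoint the decision is flagged for panel review.

Criterion identifiers are stable strings (see ``criteria_catalog.md`` at
the repository root); the trace stored on every outcome re-evaluates to the
same statuses on the stored evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

from .screening import TermList, normalize_term, packaged_symptom_terms
from .types import (
    AdverseEventRecord,
    CandidateEvent,
    Category,
    CriterionStatus,
    DeathRecord,
    DoseAction,
    Endpoint,
    EvidencePackage,
    HFCause,
    HF_SYMPTOM_FLAGS,
    MIContext,
    MI_ENDPOINTS,
    STROKE_ENDPOINTS,
    VesselSide,
    VTELocation,
)

log = logging.getLogger("aoekit.rules")

MET = CriterionStatus.MET
NOT_MET = CriterionStatus.NOT_MET
UNKNOWN = CriterionStatus.UNKNOWN

AOE_HF_CAUSES = frozenset(
    {
        HFCause.CORONARY_ARTERY_DISEASE,
        HFCause.HYPERTENSION,
        HFCause.CARDIOMYOPATHY,
        HFCause.MYOCARDIAL_INFARCTION,
    }
)
NON_AOE_HF_CAUSES = frozenset(
    {HFCause.VALVE_DISORDER, HFCause.CONGENITAL, HFCause.ARRHYTHMIA}
)


def tri(value: Optional[bool]) -> CriterionStatus:
    if value is None:
        return UNKNOWN
    return MET if value else NOT_MET


def tri_not(value: Optional[bool]) -> CriterionStatus:
    if value is None:
        return UNKNOWN
    return MET if not value else NOT_MET


def tri_and(*statuses: CriterionStatus) -> CriterionStatus:
    if any(s is NOT_MET for s in statuses):
        return NOT_MET
    if any(s is UNKNOWN for s in statuses):
        return UNKNOWN
    return MET


def tri_or(*statuses: CriterionStatus) -> CriterionStatus:
    if any(s is MET for s in statuses):
        return MET
    if any(s is UNKNOWN for s in statuses):
        return UNKNOWN
    return NOT_MET


def tri_cmp(value: Optional[float], threshold: float, strict: bool) -> CriterionStatus:
    if value is None:
        return UNKNOWN
    ok = value > threshold if strict else value >= threshold
    return MET if ok else NOT_MET


class EvalContext:
    """Collects the criteria trace and applies the unknown policy.

    ``perturb`` is an optional hook ``(criterion_id, status) -> status``
    used by the simulated noisy reviewers; it may flip definite statuses
    but never manufactures knowledge out of ``UNKNOWN``.

    ``optimistic`` resolves unknown criteria as met — used only to detect
    decisions blocked solely by missing evidence (panel-review flag).
    """

    def __init__(self, evidence: EvidencePackage, perturb=None, optimistic: bool = False):
        self.evidence = evidence
        self.perturb = perturb
        self.optimistic = optimistic
        self.trace: List[Tuple[str, CriterionStatus]] = []

    def record(self, criterion_id: str, status: CriterionStatus) -> CriterionStatus:
        if self.perturb is not None and status is not UNKNOWN:
            status = self.perturb(criterion_id, status)
        self.trace.append((criterion_id, status))
        return status

    def passes(self, status: CriterionStatus) -> bool:
        if status is MET:
            return True
        return status is UNKNOWN and self.optimistic


# ---------------------------------------------------------------------------
# criterion primitives (id -> evaluation on raw evidence)

def _mi_biomarker_above_url(ev: EvidencePackage) -> CriterionStatus:
    rise_fall = tri_and(tri(ev.troponin_rise_fall), tri_cmp(ev.troponin_ratio_to_URL, 1.0, True))
    return tri_or(rise_fall, tri(ev.ckmb_above_URL))


def _mi_support_general(ev: EvidencePackage) -> CriterionStatus:
    imaging = bool(ev.imaging & {"new_nonviable_myocardium", "new_wall_motion_abnormality"})
    ecg = bool(ev.ecg & {"new_ST_elevation", "new_ST_depression_or_Twave", "new_LBBB",
                         "pathological_Q_waves"})
    return MET if (imaging or ecg) else NOT_MET


def _mi_support_4a(ev: EvidencePackage) -> CriterionStatus:
    symptoms = bool(ev.symptoms & {"ischemic_discomfort", "ischemic_discomfort_ge_10min_at_rest"})
    ecg = bool(ev.ecg & {"new_ST_elevation", "new_ST_depression_or_Twave", "new_LBBB"})
    angio = bool(ev.imaging & {"angiographic_culprit_lesion_ge_70pct", "graft_or_native_occlusion"})
    imaging = bool(ev.imaging & {"new_nonviable_myocardium", "new_wall_motion_abnormality"})
    return MET if (symptoms or ecg or angio or imaging) else NOT_MET


def _mi_support_5(ev: EvidencePackage) -> CriterionStatus:
    ecg = bool(ev.ecg & {"pathological_Q_waves", "new_LBBB"})
    occl = "graft_or_native_occlusion" in ev.imaging
    imaging = bool(ev.imaging & {"new_nonviable_myocardium", "new_wall_motion_abnormality"})
    return MET if (ecg or occl or imaging) else NOT_MET


def _context(expected: MIContext):
    def check(ev: EvidencePackage) -> CriterionStatus:
        if ev.mi_context is None:
            return UNKNOWN
        return MET if ev.mi_context is expected else NOT_MET

    return check


def _ischemic_symptoms(ev: EvidencePackage) -> CriterionStatus:
    return (
        MET
        if ev.symptoms & {"ischemic_discomfort", "ischemic_discomfort_ge_10min_at_rest"}
        else NOT_MET
    )


def _hosp_qualifying(ev: EvidencePackage) -> CriterionStatus:
    """Admitted with >= 24 h stay (calendar-date change)."""
    if ev.hospitalization is None:
        return UNKNOWN
    stay = ev.hospitalization.stay_at_least_24h()
    return tri(stay)


def _ua_hospitalization(ev: EvidencePackage) -> CriterionStatus:
    if ev.hospitalization is None:
        return UNKNOWN
    h = ev.hospitalization
    return tri_and(tri(h.unscheduled), tri(h.within_24h_of_symptoms), tri(h.stay_at_least_24h()))


def _biomarkers_negative(ev: EvidencePackage) -> CriterionStatus:
    positives = [
        tri(ev.troponin_rise_fall),
        tri(ev.ckmb_above_URL),
        tri_cmp(ev.troponin_ratio_to_URL, 1.0, True),
    ]
    if any(s is MET for s in positives):
        return NOT_MET
    if all(s is UNKNOWN for s in positives):
        return UNKNOWN
    return MET


def _hf_symptom(ev: EvidencePackage) -> CriterionStatus:
    return MET if ev.symptoms & HF_SYMPTOM_FLAGS else NOT_MET


def _hf_objective(ev: EvidencePackage) -> CriterionStatus:
    if ev.hf_exam_findings_count >= 2:
        return MET
    if ev.hf_exam_findings_count >= 1 and ev.hf_lab_findings_count >= 1:
        return MET
    return NOT_MET


def _neuro_deficit(ev: EvidencePackage) -> CriterionStatus:
    return MET if ev.symptoms & {"focal_neuro_deficit", "global_neuro_deficit"} else NOT_MET


def _stroke_duration(died: bool):
    def check(ev: EvidencePackage) -> CriterionStatus:
        brain_lesion = bool(ev.imaging & {"brain_CT_or_MRI_infarct", "brain_hemorrhage"})
        short_ok = tri_or(tri(ev.stroke_abort_intervention), tri(brain_lesion), tri(died))
        return tri_or(tri_cmp(ev.neuro_deficit_duration_hours, 24.0, False), short_ok)

    return check


def _stroke_confirmation(ev: EvidencePackage) -> CriterionStatus:
    # absent confirmation is a panel matter, never a definite pass/fail
    return MET if ev.neuro_confirmation else UNKNOWN


CRITERIA: dict = {
    "mi.biomarker_above_url": _mi_biomarker_above_url,
    "mi.support_general": _mi_support_general,
    "mi.support_4a": _mi_support_4a,
    "mi.support_5": _mi_support_5,
    "mi.context_spontaneous": _context(MIContext.SPONTANEOUS),
    "mi.context_supply_demand": _context(MIContext.SUPPLY_DEMAND),
    "mi.context_post_pci": _context(MIContext.POST_PCI_24H),
    "mi.context_stent_thrombosis": _context(MIContext.STENT_THROMBOSIS),
    "mi.context_stent_restenosis": _context(MIContext.STENT_RESTENOSIS),
    "mi.context_post_cabg": _context(MIContext.POST_CABG),
    "mi.tn_gt_5x_normal_baseline": lambda ev: tri_and(
        tri(ev.baseline_biomarker_normal), tri_cmp(ev.troponin_ratio_to_URL, 5.0, True)
    ),
    "mi.elevated_baseline_rise20": lambda ev: tri_and(
        tri_not(ev.baseline_biomarker_normal),
        tri(ev.troponin_rise_fall),
        tri(ev.biomarker_decreasing_prior),
    ),
    "mi.tn_gt_10x_normal_baseline": lambda ev: tri_and(
        tri(ev.baseline_biomarker_normal), tri_cmp(ev.troponin_ratio_to_URL, 10.0, True)
    ),
    "mi.stent_thrombus_confirmed": lambda ev: (
        MET if "stent_thrombus_confirmed" in ev.imaging else NOT_MET
    ),
    "mi.stent_restenosis_ge_50pct": lambda ev: (
        MET if "stent_restenosis_ge_50pct" in ev.imaging else NOT_MET
    ),
    "mi.rise_fall_above_url": lambda ev: tri_and(
        tri(ev.troponin_rise_fall), tri_cmp(ev.troponin_ratio_to_URL, 1.0, True)
    ),
    "mi.ischemic_symptoms": _ischemic_symptoms,
    "ua.biomarkers_negative": _biomarkers_negative,
    "ua.rest_ischemia_ge_10min": lambda ev: (
        MET if "ischemic_discomfort_ge_10min_at_rest" in ev.symptoms else NOT_MET
    ),
    "ua.unscheduled_hospitalization": _ua_hospitalization,
    "ua.objective_support": lambda ev: (
        MET
        if (
            ev.ecg & {"new_ST_depression_or_Twave", "transient_ST_elevation", "new_ST_elevation"}
            or "angiographic_culprit_lesion_ge_70pct" in ev.imaging
            or "revascularization_for_culprit" in ev.procedure
        )
        else NOT_MET
    ),
    "hf.primary_diagnosis": lambda ev: tri(ev.hf_primary_diagnosis),
    "hf.stay_ge_24h": _hosp_qualifying,
    "hf.symptom": _hf_symptom,
    "hf.objective_findings": _hf_objective,
    "hf.treatment_intensified": lambda ev: tri(ev.hf_treatment_intensified),
    "hf.urgent_visit": lambda ev: tri(ev.urgent_visit),
    "hf.beyond_oral_diuretic": lambda ev: tri_not(ev.hf_oral_diuretic_only),
    "stroke.acute_deficit": _neuro_deficit,
    "stroke.duration_or_equivalent": _stroke_duration(False),
    "stroke.duration_or_equivalent_fatal": _stroke_duration(True),
    "stroke.no_other_cause": lambda ev: tri_not(ev.non_stroke_cause_present),
    "stroke.confirmation": _stroke_confirmation,
    "venous.dvt_documented": lambda ev: (
        MET if "venous_ultrasound_or_venogram_positive" in ev.imaging else NOT_MET
    ),
    "venous.svt_documented": lambda ev: tri(ev.superficial_thrombosis_signs),
    "venous.pe_documented": lambda ev: (
        MET if "pulmonary_CT_or_VQ_positive" in ev.imaging else NOT_MET
    ),
    "pvd.documented": lambda ev: (
        MET if "doppler_or_ABI_or_angio_PVD" in ev.imaging else NOT_MET
    ),
    "pvd.side_known": lambda ev: tri(None if ev.pvd_vessel_side is None else True),
}


def evaluate_criterion(criterion_id: str, ev: EvidencePackage) -> CriterionStatus:
    return CRITERIA[criterion_id](ev)


def _check(ctx: EvalContext, criterion_id: str) -> bool:
    return ctx.passes(ctx.record(criterion_id, evaluate_criterion(criterion_id, ctx.evidence)))


# ---------------------------------------------------------------------------
# endpoint classifiers

def classify_myocardial_infarction(
    ev: EvidencePackage, ctx: Optional[EvalContext] = None
) -> Optional[Endpoint]:
    """At most one MI subtype; procedural contexts take precedence and
    type 4c is evaluated last because it must not meet any other class."""
    ctx = ctx or EvalContext(ev)
    if _check(ctx, "mi.context_stent_thrombosis"):
        if (
            _check(ctx, "mi.stent_thrombus_confirmed")
            and _check(ctx, "mi.ischemic_symptoms")
            and _check(ctx, "mi.rise_fall_above_url")
        ):
            return Endpoint.MI_TYPE4B
        return None
    if _check(ctx, "mi.context_post_pci"):
        biomarker = _check(ctx, "mi.tn_gt_5x_normal_baseline") or _check(
            ctx, "mi.elevated_baseline_rise20"
        )
        if biomarker and _check(ctx, "mi.support_4a"):
            return Endpoint.MI_TYPE4A
        return None
    if _check(ctx, "mi.context_post_cabg"):
        if _check(ctx, "mi.tn_gt_10x_normal_baseline") and _check(ctx, "mi.support_5"):
            return Endpoint.MI_TYPE5
        return None
    if _check(ctx, "mi.context_spontaneous"):
        if _check(ctx, "mi.biomarker_above_url") and _check(ctx, "mi.support_general"):
            return Endpoint.MI_TYPE1
        return None
    if _check(ctx, "mi.context_supply_demand"):
        if _check(ctx, "mi.biomarker_above_url") and _check(ctx, "mi.support_general"):
            return Endpoint.MI_TYPE2
        return None
    if _check(ctx, "mi.context_stent_restenosis"):
        if (
            _check(ctx, "mi.stent_restenosis_ge_50pct")
            and _check(ctx, "mi.ischemic_symptoms")
            and _check(ctx, "mi.rise_fall_above_url")
        ):
            return Endpoint.MI_TYPE4C
    return None


def classify_unstable_angina_hospitalization(
    ev: EvidencePackage, ctx: Optional[EvalContext] = None
) -> Optional[Endpoint]:
    ctx = ctx or EvalContext(ev)
    if classify_myocardial_infarction(ev, EvalContext(ev, optimistic=ctx.optimistic)) is not None:
        ctx.record("ua.no_mi", NOT_MET)
        return None
    ctx.record("ua.no_mi", MET)
    if (
        _check(ctx, "ua.biomarkers_negative")
        and _check(ctx, "ua.rest_ischemia_ge_10min")
        and _check(ctx, "ua.unscheduled_hospitalization")
        and _check(ctx, "ua.objective_support")
    ):
        return Endpoint.UA_HOSPITALIZATION
    return None


def classify_heart_failure_event(
    ev: EvidencePackage, ctx: Optional[EvalContext] = None
) -> Optional[Endpoint]:
    ctx = ctx or EvalContext(ev)
    core = (
        _check(ctx, "hf.primary_diagnosis")
        and _check(ctx, "hf.symptom")
        and _check(ctx, "hf.objective_findings")
        and _check(ctx, "hf.treatment_intensified")
    )
    if not core:
        return None
    if _check(ctx, "hf.stay_ge_24h"):
        return Endpoint.HF_HOSPITALIZATION
    if _check(ctx, "hf.urgent_visit") and _check(ctx, "hf.beyond_oral_diuretic"):
        return Endpoint.HF_URGENT_VISIT
    return None


def attribute_heart_failure_to_aoe(
    ev: EvidencePackage,
) -> Tuple[bool, bool]:
    """(attributed, panel_flag) per the underlying-cause rule."""
    cause = ev.hf_underlying_cause
    if cause in AOE_HF_CAUSES:
        return True, False
    if cause in NON_AOE_HF_CAUSES:
        return False, False
    return False, True  # unknown cause: default not attributed, panel flagged


def _retinal_from_pts(pts: Sequence[str]) -> bool:
    norm = [normalize_term(p) for p in pts]
    if norm and all("amaurosis" in p for p in norm):
        return False  # amaurosis fugax is excluded from the retinal endpoint
    return any(
        "retinal artery" in p or "retinal vascular" in p or ("retinal" in p and "occlusion" in p)
        for p in norm
    )


def _stroke_subtype(ev: EvidencePackage, pts: Sequence[str]) -> Endpoint:
    if _retinal_from_pts(pts):
        return Endpoint.STROKE_RETINAL_ARTERY
    infarct = "brain_CT_or_MRI_infarct" in ev.imaging
    hemorrhage = "brain_hemorrhage" in ev.imaging
    if infarct:
        # hemorrhagic transformation of an infarct stays ischemic
        return Endpoint.STROKE_ISCHEMIC
    if hemorrhage:
        return Endpoint.STROKE_HEMORRHAGIC
    norm = " ".join(normalize_term(p) for p in pts)
    if "infarct" in norm:
        return Endpoint.STROKE_ISCHEMIC
    if "haemorrhagic stroke" in norm or "hemorrhagic stroke" in norm:
        return Endpoint.STROKE_HEMORRHAGIC
    return Endpoint.STROKE_UNDETERMINED


def classify_stroke(
    ev: EvidencePackage,
    ctx: Optional[EvalContext] = None,
    pts: Sequence[str] = (),
    died: bool = False,
) -> Optional[Endpoint]:
    ctx = ctx or EvalContext(ev)
    duration_id = "stroke.duration_or_equivalent_fatal" if died else "stroke.duration_or_equivalent"
    if (
        _check(ctx, "stroke.acute_deficit")
        and _check(ctx, duration_id)
        and _check(ctx, "stroke.no_other_cause")
        and _check(ctx, "stroke.confirmation")
    ):
        return _stroke_subtype(ev, pts)
    return None


def classify_venous_event(
    ev: EvidencePackage, ctx: Optional[EvalContext] = None
) -> Optional[Endpoint]:
    ctx = ctx or EvalContext(ev)
    if _check(ctx, "venous.pe_documented"):
        return Endpoint.PE
    if _check(ctx, "venous.dvt_documented"):
        return Endpoint.DVT
    if _check(ctx, "venous.svt_documented"):
        return Endpoint.SVT
    return None


def classify_peripheral_vascular_disease(
    ev: EvidencePackage, ctx: Optional[EvalContext] = None
) -> Optional[Endpoint]:
    ctx = ctx or EvalContext(ev)
    if not _check(ctx, "pvd.documented"):
        return None
    if not _check(ctx, "pvd.side_known"):
        return None
    side = ev.pvd_vessel_side or VesselSide.ARTERIAL  # optimistic fallback
    return Endpoint.PVD_ARTERIAL if side is VesselSide.ARTERIAL else Endpoint.PVD_VENOUS


# ---------------------------------------------------------------------------
# symptom-only exclusion and the review view

@dataclass(frozen=True)
class ReviewView:
    """What a blinded reviewer sees: no dose fields, no causality opinion.

    ``medication_changed`` is a pre-abstracted boolean (any change in
    medication accompanied the event); the reviewer never sees which drug
    or what the dose action was.
    """

    preferred_terms: tuple
    max_severity_grade: int
    medication_changed: bool
    any_anatomic_diagnosis: bool
    serious: bool
    fatal: bool
    evidence: EvidencePackage
    death: Optional[DeathRecord] = None
    prior_outcomes: tuple = ()


def build_review_view(event: CandidateEvent, death: Optional[DeathRecord] = None,
                      prior_outcomes: tuple = ()) -> ReviewView:
    return ReviewView(
        preferred_terms=event.preferred_terms,
        max_severity_grade=max(m.severity_grade for m in event.members),
        medication_changed=any(
            m.dose_action not in (DoseAction.NONE, DoseAction.UNKNOWN) for m in event.members
        ),
        any_anatomic_diagnosis=any(m.anatomic_diagnosis for m in event.members),
        serious=event.serious,
        fatal=event.fatal,
        evidence=event.merged_evidence,
        death=death,
        prior_outcomes=prior_outcomes,
    )


def evaluate_symptom_only_exclusion(
    view: ReviewView, symptom_terms: Optional[TermList] = None
) -> bool:
    """True when the event is a low-grade symptom recording, not an AOE."""
    symptom_terms = symptom_terms or packaged_symptom_terms()
    if not all(pt in symptom_terms for pt in view.preferred_terms):
        return False
    if view.max_severity_grade > 2:
        return False
    if view.medication_changed:
        return False
    if view.evidence.hospitalization is not None or view.evidence.urgent_visit:
        return False
    if view.any_anatomic_diagnosis:
        return False
    return True


# ---------------------------------------------------------------------------
# category derivation

_HYPERTENSION_ONLY = ("hypertension",)

_PERIPHERAL_PT_MARKERS = (
    "peripheral",
    "mesenteric",
    "iliac",
    "femoral",
    "limb",
    "claudication",
    "subclavian",
    "renal artery",
    "splenic",
    "aortic",
    "coeliac",
    "celiac",
)
_CEREBRO_PT_MARKERS = (
    "carotid",
    "cerebr",
    "stroke",
    "lacunar",
    "basilar",
    "vertebral artery",
    "precerebral",
    "intracranial",
    "retinal",
)

_CARDIOVASCULAR_ENDPOINTS = MI_ENDPOINTS | {
    Endpoint.HF_HOSPITALIZATION,
    Endpoint.HF_URGENT_VISIT,
    Endpoint.UA_HOSPITALIZATION,
    Endpoint.CV_DEATH_MI,
    Endpoint.CV_DEATH_SUDDEN,
    Endpoint.CV_DEATH_HF,
    Endpoint.CV_DEATH_PROCEDURE,
}
_CEREBROVASCULAR_ENDPOINTS = STROKE_ENDPOINTS | {
    Endpoint.CV_DEATH_STROKE,
    Endpoint.CV_DEATH_HEMORRHAGE,
}
_NON_AOE_ENDPOINTS = {
    Endpoint.SVT,
    Endpoint.DVT,
    Endpoint.PE,
    Endpoint.PVD_VENOUS,
    Endpoint.NON_CV_DEATH,
    Endpoint.UNDETERMINED_DEATH,
    Endpoint.NOT_AN_EVENT,
}


def derive_endpoint_category(
    endpoint: Endpoint, pts: Sequence[str] = ()
) -> Tuple[bool, Optional[Category]]:
    """Map an endpoint (plus member PTs) to (is_aoe, category)."""
    norm = [normalize_term(p) for p in pts]
    if endpoint in _NON_AOE_ENDPOINTS:
        return False, None
    # arterial-hypertension AEs never produce an AOE category
    if norm and all("hypertension" in p for p in norm):
        return False, None
    if endpoint in _CARDIOVASCULAR_ENDPOINTS:
        return True, Category.CARDIOVASCULAR
    if endpoint in _CEREBROVASCULAR_ENDPOINTS:
        return True, Category.CEREBROVASCULAR
    if endpoint is Endpoint.PVD_ARTERIAL:
        if any(any(m in p for m in _CEREBRO_PT_MARKERS) for p in norm):
            return True, Category.CEREBROVASCULAR
        return True, Category.PERIPHERAL_VASCULAR
    if endpoint is Endpoint.CV_DEATH_OTHER:
        if any(any(m in p for m in _PERIPHERAL_PT_MARKERS) for p in norm):
            return True, Category.PERIPHERAL_VASCULAR
        if any(any(m in p for m in _CEREBRO_PT_MARKERS) for p in norm):
            return True, Category.CEREBROVASCULAR
        return True, Category.CARDIOVASCULAR
    raise ValueError(f"unmapped endpoint {endpoint!r}")


# ---------------------------------------------------------------------------
# death-cause classification

def classify_death_cause(
    death: DeathRecord,
    ev: EvidencePackage,
    history: Sequence = (),
    pts: Sequence[str] = (),
    ctx: Optional[EvalContext] = None,
) -> Tuple[Endpoint, tuple]:
    """Classify the principal cause of death under the charter precedence:
    MI > stroke > procedure > hemorrhage > HF > sudden > other CV >
    non-CV > undetermined."""
    ctx = ctx or EvalContext(ev)

    def prior(kinds, window_days=30):
        for out in history:
            if out.endpoint in kinds and out.onset_day is not None:
                if 0 <= death.death_day - out.onset_day <= window_days:
                    return True
        return False

    mi_here = classify_myocardial_infarction(ev, ctx) is not None
    if mi_here or prior(MI_ENDPOINTS):
        ctx.record("death.recent_mi", MET)
        return Endpoint.CV_DEATH_MI, tuple(ctx.trace)
    stroke_here = classify_stroke(ev, ctx, pts=pts, died=True) is not None
    if stroke_here or prior(STROKE_ENDPOINTS):
        ctx.record("death.recent_stroke", MET)
        return Endpoint.CV_DEATH_STROKE, tuple(ctx.trace)
    if ev.procedure and ev.procedure_timing_hours is not None:
        ctx.record("death.periprocedural", MET)
        return Endpoint.CV_DEATH_PROCEDURE, tuple(ctx.trace)
    if "brain_hemorrhage" in ev.imaging or (
        ev.cv_other_cause and "hemorrhage" in ev.cv_other_cause.lower()
    ):
        ctx.record("death.cv_hemorrhage", MET)
        return Endpoint.CV_DEATH_HEMORRHAGE, tuple(ctx.trace)
    hf_signs = ev.hf_primary_diagnosis or (
        ev.hf_exam_findings_count >= 1 and bool(ev.symptoms & HF_SYMPTOM_FLAGS)
    )
    if hf_signs:
        ctx.record("death.worsening_hf", MET)
        return Endpoint.CV_DEATH_HF, tuple(ctx.trace)
    seen_alive_24h = (
        death.last_seen_alive_hours_before is not None
        and death.last_seen_alive_hours_before <= 24.0
    )
    if death.witnessed or (seen_alive_24h and ev.non_cv_cause is None):
        ctx.record("death.sudden_cardiac", MET)
        return Endpoint.CV_DEATH_SUDDEN, tuple(ctx.trace)
    other_cv = (
        ev.cv_other_cause is not None
        or "pulmonary_CT_or_VQ_positive" in ev.imaging
        or "doppler_or_ABI_or_angio_PVD" in ev.imaging
    )
    if other_cv:
        ctx.record("death.other_cv_cause", MET)
        return Endpoint.CV_DEATH_OTHER, tuple(ctx.trace)
    if ev.non_cv_cause is not None:
        ctx.record("death.specific_non_cv_cause", MET)
        return Endpoint.NON_CV_DEATH, tuple(ctx.trace)
    ctx.record("death.unclassifiable", MET)
    return Endpoint.UNDETERMINED_DEATH, tuple(ctx.trace)


# ---------------------------------------------------------------------------
# full-event decision

@dataclass(frozen=True)
class Decision:
    endpoint: Endpoint
    is_aoe: bool
    category: Optional[Category]
    panel_review: bool
    trace: tuple
    revascularization_associated: Optional[bool] = None

    @property
    def vote_key(self) -> tuple:
        return (self.endpoint, self.is_aoe)


_CLASSIFIER_ORDER = (
    ("mi", classify_myocardial_infarction),
    ("ua", classify_unstable_angina_hospitalization),
    ("hf", classify_heart_failure_event),
    ("stroke", classify_stroke),
    ("pvd", classify_peripheral_vascular_disease),
    ("venous", classify_venous_event),
)


def _classify_once(view: ReviewView, perturb=None, optimistic: bool = False):
    ev = view.evidence
    ctx = EvalContext(ev, perturb=perturb, optimistic=optimistic)
    endpoint = None
    panel = False
    for name, classifier in _CLASSIFIER_ORDER:
        if name == "stroke":
            endpoint = classifier(ev, ctx, pts=view.preferred_terms, died=view.fatal)
        else:
            endpoint = classifier(ev, ctx)
        if endpoint is not None:
            break
    if endpoint is None:
        return None, False, tuple(ctx.trace)
    if endpoint in (Endpoint.HF_HOSPITALIZATION, Endpoint.HF_URGENT_VISIT):
        attributed, hf_panel = attribute_heart_failure_to_aoe(ev)
        panel = panel or hf_panel
        if not attributed:
            is_aoe, category = False, None
        else:
            is_aoe, category = derive_endpoint_category(endpoint, view.preferred_terms)
    else:
        is_aoe, category = derive_endpoint_category(endpoint, view.preferred_terms)
    return (endpoint, is_aoe, category, panel), panel, tuple(ctx.trace)


def classify_candidate_event(
    view: ReviewView,
    symptom_terms: Optional[TermList] = None,
    perturb=None,
) -> Decision:
    """Classify a non-fatal candidate event end to end."""
    if evaluate_symptom_only_exclusion(view, symptom_terms):
        return Decision(
            endpoint=Endpoint.NOT_AN_EVENT,
            is_aoe=False,
            category=None,
            panel_review=False,
            trace=(("triage.symptom_only_exclusion", MET),),
        )
    result, panel, trace = _classify_once(view, perturb=perturb)
    if result is None:
        # no endpoint met: flag for panel iff unknowns alone blocked one
        optimistic, _, _ = _classify_once(view, optimistic=True)
        return Decision(
            endpoint=Endpoint.NOT_AN_EVENT,
            is_aoe=False,
            category=None,
            panel_review=optimistic is not None,
            trace=trace,
        )
    endpoint, is_aoe, category, panel = result
    revasc = None
    if is_aoe:
        revasc = bool(
            view.evidence.procedure & {"PCI", "CABG", "PVI", "revascularization_for_culprit"}
        )
    return Decision(
        endpoint=endpoint,
        is_aoe=is_aoe,
        category=category,
        panel_review=panel,
        trace=trace,
        revascularization_associated=revasc,
    )


def classify_fatal_case(view: ReviewView, perturb=None) -> Decision:
    """Classify a fatal case (consensus route)."""
    if view.death is None:
        raise ValueError("fatal case without a death record")
    ctx = EvalContext(view.evidence, perturb=perturb)
    endpoint, trace = classify_death_cause(
        view.death, view.evidence, history=view.prior_outcomes,
        pts=view.preferred_terms, ctx=ctx,
    )
    is_aoe, category = derive_endpoint_category(endpoint, view.preferred_terms)
    return Decision(
        endpoint=endpoint,
        is_aoe=is_aoe,
        category=category,
        panel_review=False,
        trace=trace,
    )
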