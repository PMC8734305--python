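"""Domain types for the adjudication pipeline.

Conventions
-----------
* Study time is measured in 1-based integer study days from first dose;
  an optional ``onset_hour`` (0-23) refines an onset to hour resolution.
* Clinical-evidence fields are tri-state: a concrete value means
  *documented*, ``False``/empty means *explicitly absent*, and ``None``
  (or an empty set where noted) means *unknown*.  The rule engine's
  unknown policy lives in :mod:`aoekit.rules`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from typing import Optional

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25


class Cohort(str, enum.Enum):
    CP_CML = "CP-CML"
    AP_CML = "AP-CML"
    BP_CML = "BP-CML"
    PH_POS_ALL = "Ph+ALL"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class RiskFactor(str, enum.Enum):
    ARTERIAL_HYPERTENSION = "arterial_hypertension"
    HYPERCHOLESTEROLEMIA = "hypercholesterolemia"
    OBESITY = "obesity"
    DIABETES_MELLITUS = "diabetes_mellitus"
    NON_ISCHEMIC_CARDIAC_HISTORY = "non_ischemic_cardiac_history"
    ISCHEMIC_HISTORY = "ischemic_history"


class DoseAction(str, enum.Enum):
    """Action taken on study drug in response to an adverse event.

    ``UNKNOWN`` covers records where the action was not recorded; it ranks
    below ``NONE`` in the worst-action derivation and feeds the
    "Not applicable/unknown" row of the dose-modification summary.
    """

    NONE = "none"
    INTERRUPTED = "interrupted"
    REDUCED = "reduced"
    REDUCED_AND_INTERRUPTED = "reduced_and_interrupted"
    WITHDRAWN = "withdrawn"
    INTERRUPTED_THEN_WITHDRAWN = "interrupted_then_withdrawn"
    UNKNOWN = "unknown"


#: severity ranking used for the per-patient worst dose action
DOSE_ACTION_SEVERITY = {
    DoseAction.UNKNOWN: 0,
    DoseAction.NONE: 1,
    DoseAction.INTERRUPTED: 2,
    DoseAction.REDUCED: 3,
    DoseAction.REDUCED_AND_INTERRUPTED: 4,
    DoseAction.INTERRUPTED_THEN_WITHDRAWN: 5,
    DoseAction.WITHDRAWN: 6,
}


class MIContext(str, enum.Enum):
    SPONTANEOUS = "spontaneous"
    SUPPLY_DEMAND = "supply_demand"
    POST_PCI_24H = "post_PCI_24h"
    STENT_THROMBOSIS = "stent_thrombosis"
    STENT_RESTENOSIS = "stent_restenosis"
    POST_CABG = "post_CABG"


class HFCause(str, enum.Enum):
    CORONARY_ARTERY_DISEASE = "coronary_artery_disease"
    HYPERTENSION = "hypertension"
    CARDIOMYOPATHY = "cardiomyopathy"
    MYOCARDIAL_INFARCTION = "myocardial_infarction"
    VALVE_DISORDER = "valve_disorder"
    CONGENITAL = "congenital"
    ARRHYTHMIA = "arrhythmia"
    UNKNOWN = "unknown"


class VesselSide(str, enum.Enum):
    ARTERIAL = "arterial"
    VENOUS = "venous"


class VTELocation(str, enum.Enum):
    LOWER_LIMB = "lower_limb"
    UPPER_LIMB = "upper_limb"
    RETINAL_VEIN = "retinal_vein"
    ABDOMINAL_VISCERA = "abdominal_viscera"
    OTHER = "other"


# controlled vocabularies for the evidence flag sets
ECG_FLAGS = frozenset(
    {
        "new_ST_elevation",
        "new_ST_depression_or_Twave",
        "new_LBBB",
        "pathological_Q_waves",
        "transient_ST_elevation",
    }
)
IMAGING_FLAGS = frozenset(
    {
        "new_nonviable_myocardium",
        "new_wall_motion_abnormality",
        "brain_CT_or_MRI_infarct",
        "brain_hemorrhage",
        "angiographic_culprit_lesion_ge_70pct",
        "stent_thrombus_confirmed",
        "stent_restenosis_ge_50pct",
        "graft_or_native_occlusion",
        "pulmonary_CT_or_VQ_positive",
        "doppler_or_ABI_or_angio_PVD",
        "venous_ultrasound_or_venogram_positive",
    }
)
SYMPTOM_FLAGS = frozenset(
    {
        "ischemic_discomfort",
        "ischemic_discomfort_ge_10min_at_rest",
        "dyspnea",
        "orthopnea",
        "PND",
        "decreased_exercise_tolerance",
        "fatigue",
        "focal_neuro_deficit",
        "global_neuro_deficit",
    }
)
NEURO_CONFIRMATION_FLAGS = frozenset({"specialist", "brain_imaging", "lumbar_puncture"})
PROCEDURE_FLAGS = frozenset(
    {"PCI", "CABG", "PVI", "revascularization_for_culprit", "thrombolysis"}
)

HF_SYMPTOM_FLAGS = frozenset(
    {"dyspnea", "orthopnea", "PND", "decreased_exercise_tolerance", "fatigue"}
)


@dataclass(frozen=True)
class Hospitalization:
    admit_day: int
    discharge_day: Optional[int] = None
    unscheduled: bool = False
    within_24h_of_symptoms: bool = False
    primary_diagnosis: str = ""

    def stay_at_least_24h(self) -> Optional[bool]:
        """≥ 24 h stay, approximated by a calendar-date change."""
        if self.discharge_day is None:
            return None
        return self.discharge_day > self.admit_day


@dataclass(frozen=True)
class EvidencePackage:
    """Pooled clinical evidence backing one candidate event.

    Booleans are ``None`` when unknown; flag sets hold documented findings
    only (an empty set carries no positive evidence).
    """

    troponin_ratio_to_URL: Optional[float] = None
    troponin_rise_fall: Optional[bool] = None
    ckmb_above_URL: Optional[bool] = None
    baseline_biomarker_normal: Optional[bool] = None
    biomarker_decreasing_prior: Optional[bool] = None
    ecg: frozenset = frozenset()
    imaging: frozenset = frozenset()
    symptoms: frozenset = frozenset()
    neuro_deficit_duration_hours: Optional[float] = None
    stroke_abort_intervention: Optional[bool] = None
    neuro_confirmation: frozenset = frozenset()
    non_stroke_cause_present: Optional[bool] = None
    hf_exam_findings_count: int = 0
    hf_lab_findings_count: int = 0
    hf_primary_diagnosis: Optional[bool] = None
    hf_treatment_intensified: Optional[bool] = None
    hf_oral_diuretic_only: Optional[bool] = None
    hf_underlying_cause: Optional[HFCause] = None
    hospitalization: Optional[Hospitalization] = None
    urgent_visit: Optional[bool] = None
    procedure: frozenset = frozenset()
    procedure_timing_hours: Optional[float] = None
    mi_context: Optional[MIContext] = None
    pvd_vessel_side: Optional[VesselSide] = None
    vte_location: Optional[VTELocation] = None
    superficial_thrombosis_signs: Optional[bool] = None
    cv_other_cause: Optional[str] = None
    non_cv_cause: Optional[str] = None

    def __post_init__(self):
        if self.troponin_ratio_to_URL is not None and self.troponin_ratio_to_URL < 0:
            raise ValueError("troponin ratio must be >= 0")
        if self.hf_exam_findings_count < 0 or self.hf_lab_findings_count < 0:
            raise ValueError("finding counts must be non-negative")
        for attr, allowed in (
            ("ecg", ECG_FLAGS),
            ("imaging", IMAGING_FLAGS),
            ("symptoms", SYMPTOM_FLAGS),
            ("neuro_confirmation", NEURO_CONFIRMATION_FLAGS),
            ("procedure", PROCEDURE_FLAGS),
        ):
            vals = frozenset(getattr(self, attr))
            object.__setattr__(self, attr, vals)
            unknown = vals - allowed
            if unknown:
                raise ValueError(f"unknown {attr} flags: {sorted(unknown)}")


UNKNOWN_EVIDENCE = EvidencePackage()


@dataclass(frozen=True)
class DeathRecord:
    death_day: int
    witnessed: Optional[bool] = None
    last_seen_alive_hours_before: Optional[float] = None
    progression_attributed: bool = False
    narrative_key: Optional[str] = None

    def __post_init__(self):
        if (
            self.last_seen_alive_hours_before is not None
            and self.last_seen_alive_hours_before < 0
        ):
            raise ValueError("last_seen_alive_hours_before must be >= 0")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    cohort: Cohort
    age_years: int
    sex: Sex
    risk_factors: frozenset = frozenset()
    first_dose_day: int = 1
    last_contact_day: int = 1
    death: Optional[DeathRecord] = None

    def __post_init__(self):
        object.__setattr__(
            self,
            "risk_factors",
            frozenset(RiskFactor(f) for f in self.risk_factors),
        )
        if self.age_years < 18:
            raise ValueError(f"{self.patient_id}: age must be >= 18")
        if self.first_dose_day > self.last_contact_day:
            raise ValueError(f"{self.patient_id}: first_dose_day > last_contact_day")

    @property
    def exposure_days(self) -> int:
        return self.last_contact_day - self.first_dose_day + 1


@dataclass(frozen=True)
class AdverseEventRecord:
    record_id: str
    patient_id: str
    preferred_term: str
    onset_day: int
    onset_hour: Optional[int] = None
    resolution_day: Optional[int] = None
    resolved: bool = False
    severity_grade: int = 1
    serious: bool = False
    dose_action: DoseAction = DoseAction.NONE
    anatomic_diagnosis: Optional[str] = None
    fatal: bool = False
    nonadjudicated_aoe: bool = False  # legacy PT-based AOE category label

    def __post_init__(self):
        if not 1 <= self.severity_grade <= 5:
            raise ValueError(f"{self.record_id}: severity grade out of range")
        if self.onset_hour is not None and not 0 <= self.onset_hour <= 23:
            raise ValueError(f"{self.record_id}: onset hour out of range")

    def onset_hours(self) -> float:
        """Onset in hours from study day 0 (midnight of day boundary)."""
        return self.onset_day * 24.0 + (self.onset_hour or 0)


@dataclass
class StudyDataset:
    patients: dict = field(default_factory=dict)  # patient_id -> PatientRecord
    adverse_events: list = field(default_factory=list)  # [AdverseEventRecord]
    evidence: dict = field(default_factory=dict)  # key -> EvidencePackage
    provenance: dict = field(default_factory=dict)

    def patient(self, patient_id: str) -> PatientRecord:
        return self.patients[patient_id]

    def events_by_patient(self) -> dict:
        out: dict = {}
        for rec in self.adverse_events:
            out.setdefault(rec.patient_id, []).append(rec)
        return out

    def record(self, record_id: str) -> AdverseEventRecord:
        if not hasattr(self, "_record_index") or len(self._record_index) != len(
            self.adverse_events
        ):
            self._record_index = {r.record_id: r for r in self.adverse_events}
        return self._record_index[record_id]


class Endpoint(str, enum.Enum):
    MI_TYPE1 = "MI_type1"
    MI_TYPE2 = "MI_type2"
    MI_TYPE4A = "MI_type4a"
    MI_TYPE4B = "MI_type4b"
    MI_TYPE4C = "MI_type4c"
    MI_TYPE5 = "MI_type5"
    HF_HOSPITALIZATION = "HF_hospitalization"
    HF_URGENT_VISIT = "HF_urgent_visit"
    UA_HOSPITALIZATION = "UA_hospitalization"
    STROKE_ISCHEMIC = "stroke_ischemic"
    STROKE_HEMORRHAGIC = "stroke_hemorrhagic"
    STROKE_RETINAL_ARTERY = "stroke_retinal_artery"
    STROKE_UNDETERMINED = "stroke_undetermined"
    SVT = "SVT"
    DVT = "DVT"
    PE = "PE"
    PVD_ARTERIAL = "PVD_arterial"
    PVD_VENOUS = "PVD_venous"
    CV_DEATH_MI = "CV_death_MI"
    CV_DEATH_SUDDEN = "CV_death_sudden"
    CV_DEATH_HF = "CV_death_HF"
    CV_DEATH_STROKE = "CV_death_stroke"
    CV_DEATH_PROCEDURE = "CV_death_procedure"
    CV_DEATH_HEMORRHAGE = "CV_death_hemorrhage"
    CV_DEATH_OTHER = "CV_death_other"
    NON_CV_DEATH = "non_CV_death"
    UNDETERMINED_DEATH = "undetermined_death"
    NOT_AN_EVENT = "not_an_event"


MI_ENDPOINTS = frozenset(
    {
        Endpoint.MI_TYPE1,
        Endpoint.MI_TYPE2,
        Endpoint.MI_TYPE4A,
        Endpoint.MI_TYPE4B,
        Endpoint.MI_TYPE4C,
        Endpoint.MI_TYPE5,
    }
)
STROKE_ENDPOINTS = frozenset(
    {
        Endpoint.STROKE_ISCHEMIC,
        Endpoint.STROKE_HEMORRHAGIC,
        Endpoint.STROKE_RETINAL_ARTERY,
        Endpoint.STROKE_UNDETERMINED,
    }
)
DEATH_ENDPOINTS = frozenset(
    {
        Endpoint.CV_DEATH_MI,
        Endpoint.CV_DEATH_SUDDEN,
        Endpoint.CV_DEATH_HF,
        Endpoint.CV_DEATH_STROKE,
        Endpoint.CV_DEATH_PROCEDURE,
        Endpoint.CV_DEATH_HEMORRHAGE,
        Endpoint.CV_DEATH_OTHER,
        Endpoint.NON_CV_DEATH,
        Endpoint.UNDETERMINED_DEATH,
    }
)


class Category(str, enum.Enum):
    CARDIOVASCULAR = "cardiovascular"
    CEREBROVASCULAR = "cerebrovascular"
    PERIPHERAL_VASCULAR = "peripheral_vascular"


class CriterionStatus(str, enum.Enum):
    MET = "met"
    NOT_MET = "not_met"
    UNKNOWN = "unknown"


class Route(str, enum.Enum):
    """Specialty review-panel assignment used for escalation."""

    AOE_HF = "AOE_HF_route"
    STROKE_DVT_PE_PVD = "stroke_DVT_PE_PVD_route"


@dataclass(frozen=True)
class CandidateEvent:
    event_id: str
    patient_id: str
    member_record_ids: tuple
    members: tuple  # AdverseEventRecord, sorted by onset
    window_start_day: int
    window_end_day: int
    window_start_hour: Optional[int] = None
    window_end_hour: Optional[int] = None
    serious: bool = False
    fatal: bool = False
    merged_evidence: EvidencePackage = UNKNOWN_EVIDENCE
    route: Route = Route.AOE_HF

    @property
    def preferred_terms(self) -> tuple:
        return tuple(m.preferred_term for m in self.members)

    @property
    def onset_day(self) -> int:
        return self.window_start_day


@dataclass(frozen=True)
class AdjudicatedOutcome:
    event_id: str
    patient_id: str
    endpoint: Endpoint
    is_aoe: bool
    category: Optional[Category] = None
    serious: bool = False
    fatal: bool = False
    revascularization_associated: Optional[bool] = None
    panel_review: bool = False
    criteria_trace: tuple = ()  # ((criterion_id, CriterionStatus), ...)
    onset_day: Optional[int] = None
    member_record_ids: tuple = ()

    def __post_init__(self):
        if self.is_aoe and self.category is None:
            raise ValueError(f"{self.event_id}: AOE outcome requires a category")
        if self.endpoint is Endpoint.NOT_AN_EVENT and self.is_aoe:
            raise ValueError(f"{self.event_id}: not_an_event cannot be an AOE")


@dataclass(frozen=True)
class IncidenceResult:
    stratum: str
    numerator: int
    denominator: int
    patient_years: Optional[float] = None
    rate_percent: Optional[int] = None
    rate_per_100py: Optional[float] = None

    def __post_init__(self):
        if self.numerator > self.denominator:
            raise ValueError("numerator exceeds denominator")


def evidence_to_dict(ev: EvidencePackage) -> dict:
    """JSON-serializable dict, dropping unknown (None/empty) fields."""
    out = {}
    for f in fields(ev):
        val = getattr(ev, f.name)
        if val is None:
            continue
        if isinstance(val, frozenset):
            if not val:
                continue
            out[f.name] = sorted(val)
        elif isinstance(val, Hospitalization):
            out[f.name] = {
                "admit_day": val.admit_day,
                "discharge_day": val.discharge_day,
                "unscheduled": val.unscheduled,
                "within_24h_of_symptoms": val.within_24h_of_symptoms,
                "primary_diagnosis": val.primary_diagnosis,
            }
        elif isinstance(val, enum.Enum):
            out[f.name] = val.value
        elif isinstance(val, int) and f.name.endswith("_count") and val == 0:
            continue
        else:
            out[f.name] = val
    return out


def evidence_from_dict(data: dict) -> EvidencePackage:
    kwargs = dict(data)
    kwargs.pop("key", None)
    for name in ("ecg", "imaging", "symptoms", "neuro_confirmation", "procedure"):
        if name in kwargs:
            kwargs[name] = frozenset(kwargs[name])
    if "hospitalization" in kwargs and kwargs["hospitalization"] is not None:
        kwargs["hospitalization"] = Hospitalization(**kwargs["hospitalization"])
    if kwargs.get("hf_underlying_cause") is not None:
        kwargs["hf_underlying_cause"] = HFCause(kwargs["hf_underlying_cause"])
    if kwargs.get("mi_context") is not None:
        kwargs["mi_context"] = MIContext(kwargs["mi_context"])
    if kwargs.get("pvd_vessel_side") is not None:
        kwargs["pvd_vessel_side"] = VesselSide(kwargs["pvd_vessel_side"])
    if kwargs.get("vte_location") is not None:
        kwargs["vte_location"] = VTELocation(kwargs["vte_location"])
    return EvidencePackage(**kwargs)


__all__ = [name for name in dir() if not name.startswith("_")]
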