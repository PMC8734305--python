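"""Synthetic trials and the calibrated 449-patient fixture.

Two generators live here:

* :func:`generate_trial` — a seeded statistical generator (configurable
  cohort mix, risk-factor prevalences, multiplicative event hazards with
  yearly decay, symptom noise, evidence completeness) used for property
  tests and simulation studies.

* :func:`build_paper_calibrated_fixture` — a *constructive* dataset laid
  out so that running the real pipeline reproduces the published marginal
  counts exactly.  Records are placed to meet the printed totals; the
  fixture exercises the pipeline's aggregation logic and makes no claim of
  patient-level fidelity to the original trial.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import (
    AdverseEventRecord,
    Cohort,
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    DeathRecord,
    DoseAction,
    EvidencePackage,
    HFCause,
    Hospitalization,
    MIContext,
    PatientRecord,
    RiskFactor,
    Sex,
    StudyDataset,
    VesselSide,
)

log = logging.getLogger("aoekit.synthetic")


# ---------------------------------------------------------------------------
# evidence templates: minimal packages satisfying one endpoint each

def _hosp(admit: int, nights: int = 3, unscheduled: bool = True,
          within24: bool = True, dx: str = "") -> Hospitalization:
    return Hospitalization(
        admit_day=admit,
        discharge_day=admit + nights,
        unscheduled=unscheduled,
        within_24h_of_symptoms=within24,
        primary_diagnosis=dx,
    )


def evidence_mi_type1() -> EvidencePackage:
    return EvidencePackage(
        mi_context=MIContext.SPONTANEOUS,
        troponin_ratio_to_URL=3.0,
        troponin_rise_fall=True,
        ecg=frozenset({"new_ST_elevation"}),
        symptoms=frozenset({"ischemic_discomfort"}),
        non_stroke_cause_present=False,
    )


def evidence_mi_type2() -> EvidencePackage:
    return EvidencePackage(
        mi_context=MIContext.SUPPLY_DEMAND,
        troponin_ratio_to_URL=2.0,
        troponin_rise_fall=True,
        ecg=frozenset({"new_ST_depression_or_Twave"}),
        symptoms=frozenset({"ischemic_discomfort"}),
    )


def evidence_mi_type4a(onset_day: int = 100) -> EvidencePackage:
    return EvidencePackage(
        mi_context=MIContext.POST_PCI_24H,
        baseline_biomarker_normal=True,
        troponin_ratio_to_URL=6.0,
        troponin_rise_fall=True,
        ecg=frozenset({"new_ST_depression_or_Twave"}),
        procedure=frozenset({"PCI"}),
        procedure_timing_hours=6.0,
    )


def evidence_mi_type5() -> EvidencePackage:
    return EvidencePackage(
        mi_context=MIContext.POST_CABG,
        baseline_biomarker_normal=True,
        troponin_ratio_to_URL=12.0,
        ecg=frozenset({"pathological_Q_waves"}),
        procedure=frozenset({"CABG"}),
        procedure_timing_hours=12.0,
    )


def evidence_stroke_ischemic(onset_day: int = 100) -> EvidencePackage:
    return EvidencePackage(
        symptoms=frozenset({"focal_neuro_deficit"}),
        neuro_deficit_duration_hours=48.0,
        imaging=frozenset({"brain_CT_or_MRI_infarct"}),
        neuro_confirmation=frozenset({"specialist", "brain_imaging"}),
        non_stroke_cause_present=False,
    )


def evidence_hf_hospitalization(onset_day: int = 100) -> EvidencePackage:
    return EvidencePackage(
        hf_primary_diagnosis=True,
        hospitalization=_hosp(onset_day, nights=3, dx="heart failure"),
        symptoms=frozenset({"dyspnea"}),
        hf_exam_findings_count=2,
        hf_treatment_intensified=True,
        hf_oral_diuretic_only=False,
        hf_underlying_cause=HFCause.CORONARY_ARTERY_DISEASE,
    )


def evidence_pvd_arterial() -> EvidencePackage:
    return EvidencePackage(
        imaging=frozenset({"doppler_or_ABI_or_angio_PVD"}),
        pvd_vessel_side=VesselSide.ARTERIAL,
    )


def evidence_sudden_death() -> EvidencePackage:
    return EvidencePackage()


def evidence_hf_death() -> EvidencePackage:
    return EvidencePackage(
        symptoms=frozenset({"dyspnea"}),
        hf_exam_findings_count=2,
        hf_underlying_cause=HFCause.CARDIOMYOPATHY,
    )


def evidence_intracranial_hemorrhage_death() -> EvidencePackage:
    return EvidencePackage(imaging=frozenset({"brain_hemorrhage"}))


def evidence_peripheral_occlusion_death() -> EvidencePackage:
    return EvidencePackage(
        imaging=frozenset({"doppler_or_ABI_or_angio_PVD"}),
        pvd_vessel_side=VesselSide.ARTERIAL,
        cv_other_cause="mesenteric arterial occlusion",
    )


def evidence_non_cv_death(cause: str) -> EvidencePackage:
    return EvidencePackage(non_cv_cause=cause)


#: (preferred term, evidence factory) used for non-fatal adjudicated events
AOE_EVENT_TEMPLATES: Tuple = (
    ("Peripheral arterial occlusive disease", lambda d: evidence_pvd_arterial()),
    ("Acute myocardial infarction", lambda d: evidence_mi_type1()),
    ("Cerebral infarction", lambda d: evidence_stroke_ischemic(d)),
    ("Peripheral artery stenosis", lambda d: evidence_pvd_arterial()),
    ("Carotid artery stenosis", lambda d: evidence_pvd_arterial()),
    ("Acute coronary syndrome", lambda d: evidence_mi_type2()),
    ("Cardiac failure congestive", lambda d: evidence_hf_hospitalization(d)),
    ("Myocardial infarction", lambda d: evidence_mi_type4a(d)),
    ("Peripheral artery occlusion", lambda d: evidence_pvd_arterial()),
    ("Cerebrovascular accident", lambda d: evidence_stroke_ischemic(d)),
    ("Coronary artery disease", lambda d: evidence_mi_type5()),
    ("Peripheral ischaemia", lambda d: evidence_pvd_arterial()),
)

NUISANCE_PTS = (
    "Nausea",
    "Headache",
    "Diarrhoea",
    "Rash",
    "Abdominal pain",
    "Thrombocytopenia",
    "Anaemia",
    "Pyrexia",
    "Arthralgia",
    "Constipation",
)

SYMPTOM_NOISE_PTS = ("Chest pain", "Angina pectoris", "Intermittent claudication",
                     "Non-cardiac chest pain", "Peripheral coldness")


# ---------------------------------------------------------------------------
# statistical generator

@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 500
    cohort_fractions: Tuple[float, float, float, float] = (0.60, 0.19, 0.14, 0.07)
    risk_factor_prevalences: Dict[RiskFactor, float] = dc_field(
        default_factory=lambda: {
            RiskFactor.ARTERIAL_HYPERTENSION: 0.53,
            RiskFactor.HYPERCHOLESTEROLEMIA: 0.49,
            RiskFactor.OBESITY: 0.24,
            RiskFactor.DIABETES_MELLITUS: 0.16,
            RiskFactor.NON_ISCHEMIC_CARDIAC_HISTORY: 0.43,
            RiskFactor.ISCHEMIC_HISTORY: 0.23,
        }
    )
    baseline_hazard_per_year: float = 0.05
    factor_hazard_ratios: Dict[RiskFactor, float] = dc_field(
        default_factory=lambda: {
            RiskFactor.ARTERIAL_HYPERTENSION: 1.5,
            RiskFactor.HYPERCHOLESTEROLEMIA: 1.4,
            RiskFactor.OBESITY: 1.1,
            RiskFactor.DIABETES_MELLITUS: 1.5,
            RiskFactor.NON_ISCHEMIC_CARDIAC_HISTORY: 1.2,
            RiskFactor.ISCHEMIC_HISTORY: 1.8,
        }
    )
    yearly_decay: float = 0.7  # hazard multiplier per on-study year
    post_event_hazard_multiplier: float = 1.0  # renewal-process assumption
    symptom_noise_rate_per_year: float = 0.10
    nuisance_rate_per_year: float = 8.0
    evidence_completeness: float = 1.0
    min_follow_up_days: int = 180
    max_follow_up_days: int = 1825
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if abs(sum(self.cohort_fractions) - 1.0) > 1e-9:
            raise ValueError("cohort_fractions must sum to 1")
        for name, val in (
            ("baseline_hazard_per_year", self.baseline_hazard_per_year),
            ("symptom_noise_rate_per_year", self.symptom_noise_rate_per_year),
            ("nuisance_rate_per_year", self.nuisance_rate_per_year),
        ):
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        for p in list(self.risk_factor_prevalences.values()) + [self.evidence_completeness]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


_COHORTS = (Cohort.CP_CML, Cohort.AP_CML, Cohort.BP_CML, Cohort.PH_POS_ALL)


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # one stream per patient: adding patients never perturbs existing ones
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _sample_event_times(rng, hazard_per_year: float, decay: float,
                        post_multiplier: float, follow_up_years: float) -> List[float]:
    """Event times (years) from a piecewise-constant-hazard renewal process."""
    times: List[float] = []
    t = 0.0
    boost = 1.0
    while t < follow_up_years:
        lam = hazard_per_year * (decay ** int(t)) * boost
        if lam <= 0:
            break
        w = rng.exponential(1.0 / lam)
        boundary = float(int(t) + 1)
        if t + w >= boundary:
            t = boundary  # memoryless restart at the year boundary
            continue
        t += w
        if t >= follow_up_years:
            break
        times.append(t)
        boost = post_multiplier
    return times


def generate_trial(cfg: GeneratorConfig) -> StudyDataset:
    patients: Dict[str, PatientRecord] = {}
    records: List[AdverseEventRecord] = []
    evidence: Dict[str, EvidencePackage] = {}
    factors = list(RiskFactor)

    for i in range(cfg.n_patients):
        rng = _patient_rng(cfg.seed, i)
        pid = f"S{i + 1:05d}"
        cohort = _COHORTS[rng.choice(4, p=np.asarray(cfg.cohort_fractions))]
        pf = frozenset(
            f for f in factors if rng.random() < cfg.risk_factor_prevalences.get(f, 0.0)
        )
        follow_up = int(rng.integers(cfg.min_follow_up_days, cfg.max_follow_up_days + 1))
        patients[pid] = PatientRecord(
            patient_id=pid,
            cohort=cohort,
            age_years=int(rng.integers(18, 90)),
            sex=Sex.MALE if rng.random() < 0.53 else Sex.FEMALE,
            risk_factors=pf,
            first_dose_day=1,
            last_contact_day=follow_up,
        )

        hazard = cfg.baseline_hazard_per_year * float(
            np.prod([cfg.factor_hazard_ratios.get(f, 1.0) for f in pf])
        )
        fu_years = follow_up / DAYS_PER_YEAR
        event_times = _sample_event_times(
            rng, hazard, cfg.yearly_decay, cfg.post_event_hazard_multiplier, fu_years
        )
        counter = itertools.count(1)
        for t in event_times:
            onset = max(1, int(round(t * DAYS_PER_YEAR)))
            pt, factory = AOE_EVENT_TEMPLATES[int(rng.integers(len(AOE_EVENT_TEMPLATES)))]
            n_members = int(rng.integers(1, 4))
            ev = factory(onset)
            if cfg.evidence_completeness < 1.0 and rng.random() > cfg.evidence_completeness:
                ev = EvidencePackage()  # case package with no usable evidence
            for m in range(n_members):
                rid = f"{pid}-T{next(counter):03d}"
                records.append(
                    AdverseEventRecord(
                        record_id=rid,
                        patient_id=pid,
                        preferred_term=pt,
                        onset_day=onset + m,  # members within the 48-h window
                        resolved=bool(rng.random() < 0.7),
                        severity_grade=3,
                        serious=True,
                        dose_action=DoseAction.INTERRUPTED
                        if rng.random() < 0.5
                        else DoseAction.NONE,
                        nonadjudicated_aoe=True,
                    )
                )
                evidence[rid] = ev

        n_noise = rng.poisson(cfg.symptom_noise_rate_per_year * fu_years)
        for _ in range(n_noise):
            rid = f"{pid}-N{next(counter):03d}"
            records.append(
                AdverseEventRecord(
                    record_id=rid,
                    patient_id=pid,
                    preferred_term=SYMPTOM_NOISE_PTS[int(rng.integers(len(SYMPTOM_NOISE_PTS)))],
                    onset_day=int(rng.integers(1, follow_up + 1)),
                    resolved=True,
                    severity_grade=int(rng.integers(1, 3)),
                    serious=False,
                    dose_action=DoseAction.NONE,
                    nonadjudicated_aoe=True,
                )
            )
        n_nuisance = rng.poisson(cfg.nuisance_rate_per_year * fu_years)
        for _ in range(n_nuisance):
            rid = f"{pid}-X{next(counter):03d}"
            records.append(
                AdverseEventRecord(
                    record_id=rid,
                    patient_id=pid,
                    preferred_term=NUISANCE_PTS[int(rng.integers(len(NUISANCE_PTS)))],
                    onset_day=int(rng.integers(1, follow_up + 1)),
                    resolved=True,
                    severity_grade=1,
                    serious=False,
                )
            )

    records.sort(key=lambda r: (r.patient_id, r.onset_day, r.record_id))
    ds = StudyDataset(
        patients=patients,
        adverse_events=records,
        evidence=evidence,
        provenance={"generator": "generate_trial", "seed": cfg.seed},
    )
    log.info("generated %d patients, %d AE records", len(patients), len(records))
    return ds


# ---------------------------------------------------------------------------
# paper-calibrated fixture

N_PATIENTS = 449
COHORT_SIZES = {Cohort.CP_CML: 270, Cohort.AP_CML: 85, Cohort.BP_CML: 62, Cohort.PH_POS_ALL: 32}
TOTAL_AE_RECORDS = 12224
RISK_FACTOR_TOTALS = {
    RiskFactor.ARTERIAL_HYPERTENSION: 240,
    RiskFactor.HYPERCHOLESTEROLEMIA: 219,
    RiskFactor.OBESITY: 109,
    RiskFactor.DIABETES_MELLITUS: 72,
    RiskFactor.NON_ISCHEMIC_CARDIAC_HISTORY: 193,
    RiskFactor.ISCHEMIC_HISTORY: 102,
}

_ALIVE_LAST_CONTACT = 1700


def _first_onset_months() -> List[float]:
    """78 first-onset months: min 0.1, max 49.5, median exactly 14.1."""
    lows = [0.1 + (13.5 - 0.1) * i / 37 for i in range(38)]
    highs = [15.0 + (49.5 - 15.0) * i / 37 for i in range(38)]
    return lows + [14.1, 14.1] + highs


def _month_to_day(months: float) -> int:
    return max(1, int(round(months * DAYS_PER_MONTH)))


def _cohort_of_index(idx: int) -> Cohort:
    if idx <= 270:
        return Cohort.CP_CML
    if idx <= 355:
        return Cohort.AP_CML
    if idx <= 417:
        return Cohort.BP_CML
    return Cohort.PH_POS_ALL


def _assign_risk_factors(plan_sizes: Dict[str, List[str]]) -> Dict[str, frozenset]:
    """Greedy fill matching both the strata layout and the per-factor totals."""
    remaining = dict(RISK_FACTOR_TOTALS)
    assignment: Dict[str, frozenset] = {}
    # process larger demands first so quotas never strand
    ordered = sorted(plan_sizes.items(), key=lambda kv: -kv[1])  # type: ignore[operator]
    for pid, k in ordered:
        if k == 0:
            assignment[pid] = frozenset()
            continue
        chosen = sorted(remaining, key=lambda f: (-remaining[f], f.value))[:k]
        if any(remaining[f] <= 0 for f in chosen):
            raise RuntimeError("risk-factor quota exhausted; fixture layout bug")
        for f in chosen:
            remaining[f] -= 1
        assignment[pid] = frozenset(chosen)
    if any(v != 0 for v in remaining.values()):
        raise RuntimeError(f"risk-factor totals not exhausted: {remaining}")
    return assignment


@dataclass
class _EventPlan:
    onset_day: int
    pt: str
    evidence: Optional[EvidencePackage]
    serious: bool = True
    fatal: bool = False
    resolved: bool = True
    dose_action: DoseAction = DoseAction.NONE
    grade: int = 3
    nonadj: bool = True


@dataclass
class _PatientPlan:
    pid: str
    events: List[_EventPlan] = dc_field(default_factory=list)
    death: Optional[DeathRecord] = None
    extra_records: List[_EventPlan] = dc_field(default_factory=list)
    n_risk_factors: int = 0


def _fatal_event_specs():
    """(pt, evidence factory, witnessed) for the 11 fatal adjudicated AOEs.

    Mix mirrors the published fatal listing: 3 sudden arrests, 3 heart-
    failure deaths, 1 intracranial hemorrhage, 1 mesenteric occlusion,
    2 stroke deaths, 1 MI death.  The hemorrhage PT is deliberately outside
    the screening list so it reaches review only through the fatal route.
    """
    return [
        ("Cardiac arrest", evidence_sudden_death, True),
        ("Cardiac arrest", evidence_sudden_death, True),
        ("Cardiac failure", evidence_hf_death, False),
        ("Haemorrhage intracranial", evidence_intracranial_hemorrhage_death, False),
        ("Cardiac failure congestive", evidence_hf_death, False),
        ("Mesenteric arterial occlusion", evidence_peripheral_occlusion_death, False),
        ("Haemorrhagic cerebral infarction", lambda: evidence_stroke_ischemic(0), False),
        ("Acute myocardial infarction", lambda: evidence_mi_type1(), False),
        # fatal patients with a second, earlier AOE:
        ("Ischaemic stroke", lambda: evidence_stroke_ischemic(0), False),
        ("Cardiac arrest", evidence_sudden_death, True),
        ("Cardiac failure congestive", evidence_hf_death, False),
    ]


def build_paper_calibrated_fixture() -> StudyDataset:
    """449-patient dataset reproducing the published marginals end to end."""
    pid = lambda i: f"P{i:03d}"

    # --- role layout ------------------------------------------------------
    fatal_single_ids = [pid(i) for i in (1, 2, 3, 4)] + [pid(271), pid(272), pid(356), pid(357)]
    fatal_multi_ids = [pid(358), pid(418), pid(419)]
    fatal_ids = fatal_single_ids + fatal_multi_ids
    cp_rest = [pid(i) for i in range(5, 58)]  # 53 remaining CP adjudicated
    noncp_rest = (
        [pid(i) for i in range(273, 281)]  # 8 AP
        + [pid(i) for i in range(359, 364)]  # 5 BP
        + [pid(420)]  # 1 ALL
    )
    rest = cp_rest + noncp_rest  # 67
    nonserious_ids = {pid(55), pid(56), pid(57), pid(420)}
    nonfatal_single_ids = [p for p in rest if p not in nonserious_ids][:31] + sorted(
        nonserious_ids
    )  # 35 singles, incl. the 4 non-serious
    nonfatal_multi_ids = [p for p in rest if p not in set(nonfatal_single_ids)]  # 32
    assert len(nonfatal_single_ids) == 35 and len(nonfatal_multi_ids) == 32

    adjudicated_order = fatal_single_ids + fatal_multi_ids + nonfatal_single_ids + nonfatal_multi_ids
    assert len(adjudicated_order) == 78

    extras_ids = [pid(i) for i in range(58, 85)] + [pid(i) for i in range(281, 287)]  # 33
    extras_serious = set([pid(i) for i in range(58, 73)] + [pid(281)])  # 15 CP + 1 AP
    screened_only_ids = [pid(i) for i in range(85, 156)]  # 71 CP
    screened_noncv_death_ids = screened_only_ids[-14:]  # P142..P155
    fatal_only_noncv_ids = [pid(i) for i in range(156, 176)]  # 20
    progression_death_ids = [pid(i) for i in range(176, 196)]  # 20

    # --- dose-action buckets (worst per patient) --------------------------
    dose_by_patient: Dict[str, DoseAction] = {}
    for p in fatal_single_ids:
        dose_by_patient[p] = DoseAction.UNKNOWN  # 8 not-applicable/unknown
    for p in fatal_multi_ids:
        dose_by_patient[p] = DoseAction.INTERRUPTED
    pool = nonfatal_single_ids + nonfatal_multi_ids
    nonserious_sorted = sorted(nonserious_ids)
    assignable = [p for p in pool if p not in nonserious_ids]
    for p, action in zip(
        assignable,
        [DoseAction.WITHDRAWN] * 5
        + [DoseAction.INTERRUPTED_THEN_WITHDRAWN] * 2
        + [DoseAction.REDUCED_AND_INTERRUPTED] * 2
        + [DoseAction.INTERRUPTED] * 22,
    ):
        dose_by_patient[p] = action
    for p in pool:
        dose_by_patient.setdefault(p, DoseAction.NONE)
    from collections import Counter as _Counter

    tally = _Counter(dose_by_patient.values())
    assert tally == _Counter(
        {
            DoseAction.NONE: 36,
            DoseAction.INTERRUPTED: 25,
            DoseAction.UNKNOWN: 8,
            DoseAction.WITHDRAWN: 5,
            DoseAction.INTERRUPTED_THEN_WITHDRAWN: 2,
            DoseAction.REDUCED_AND_INTERRUPTED: 2,
        }
    ), tally

    # --- resolution buckets ----------------------------------------------
    # singles: 32/43 resolved (8 fatal + 3 others unresolved)
    unresolved_singles = set(fatal_single_ids) | set(nonfatal_single_ids[:3])
    # multis: 19/35 with all events resolved (3 fatal + 13 others not)
    not_all_resolved_multis = set(fatal_multi_ids) | set(nonfatal_multi_ids[:13])

    # --- first-onset schedule --------------------------------------------
    months = _first_onset_months()
    onset_by_patient = {
        p: _month_to_day(m) for p, m in zip(adjudicated_order, months)
    }

    # --- per-patient plans ------------------------------------------------
    plans: Dict[str, _PatientPlan] = {}
    fatal_specs = _fatal_event_specs()
    template_cycle = itertools.cycle(range(len(AOE_EVENT_TEMPLATES)))

    for idx, p in enumerate(fatal_single_ids):
        pt, factory, witnessed = fatal_specs[idx]
        day = onset_by_patient[p]
        plan = _PatientPlan(pid=p)
        plan.events.append(
            _EventPlan(
                onset_day=day,
                pt=pt,
                evidence=factory(),
                fatal=True,
                resolved=False,
                dose_action=DoseAction.UNKNOWN,
                grade=5,
            )
        )
        plan.death = DeathRecord(
            death_day=day,
            witnessed=witnessed,
            last_seen_alive_hours_before=None if witnessed else 48.0,
        )
        plans[p] = plan

    for j, p in enumerate(fatal_multi_ids):
        pt, factory, witnessed = fatal_specs[8 + j]
        first_day = onset_by_patient[p]
        death_day = first_day + 90
        plan = _PatientPlan(pid=p)
        plan.events.append(
            _EventPlan(
                onset_day=first_day,
                pt="Peripheral arterial occlusive disease",
                evidence=evidence_pvd_arterial(),
                resolved=False,
                dose_action=DoseAction.INTERRUPTED,
            )
        )
        plan.events.append(
            _EventPlan(
                onset_day=death_day,
                pt=pt,
                evidence=factory(),
                fatal=True,
                resolved=False,
                dose_action=DoseAction.UNKNOWN,
                grade=5,
            )
        )
        plan.death = DeathRecord(
            death_day=death_day,
            witnessed=witnessed,
            last_seen_alive_hours_before=None if witnessed else 48.0,
        )
        plans[p] = plan

    for p in nonfatal_single_ids:
        day = onset_by_patient[p]
        serious = p not in nonserious_ids
        t_idx = next(template_cycle)
        pt, factory = AOE_EVENT_TEMPLATES[t_idx]
        if not serious:
            # non-serious AOE: imaging-documented peripheral disease
            pt, factory = "Peripheral ischaemia", lambda d: evidence_pvd_arterial()
        resolved = p not in unresolved_singles
        plans[p] = _PatientPlan(
            pid=p,
            events=[
                _EventPlan(
                    onset_day=day,
                    pt=pt,
                    evidence=factory(day),
                    serious=serious,
                    resolved=resolved,
                    dose_action=dose_by_patient[p],
                    grade=3 if serious else 2,
                )
            ],
        )

    for p in nonfatal_multi_ids:
        day = onset_by_patient[p]
        all_resolved = p not in not_all_resolved_multis
        t1, t2 = next(template_cycle), next(template_cycle)
        pt1, f1 = AOE_EVENT_TEMPLATES[t1]
        pt2, f2 = AOE_EVENT_TEMPLATES[t2]
        plans[p] = _PatientPlan(
            pid=p,
            events=[
                _EventPlan(
                    onset_day=day,
                    pt=pt1,
                    evidence=f1(day),
                    resolved=True,
                    dose_action=dose_by_patient[p],
                ),
                _EventPlan(
                    onset_day=day + 90,
                    pt=pt2,
                    evidence=f2(day + 90),
                    resolved=all_resolved,
                    dose_action=DoseAction.NONE,
                ),
            ],
        )

    for i, p in enumerate(extras_ids):
        serious = p in extras_serious
        plans[p] = _PatientPlan(
            pid=p,
            events=[],
            extra_records=[
                _EventPlan(
                    onset_day=200 + i,
                    pt="Angina pectoris",
                    evidence=None,
                    serious=serious,
                    resolved=True,
                    dose_action=DoseAction.NONE,
                    grade=3 if serious else 2,
                    nonadj=True,
                )
            ],
        )

    for i, p in enumerate(screened_only_ids):
        plans[p] = _PatientPlan(
            pid=p,
            extra_records=[
                _EventPlan(
                    onset_day=150 + i,
                    pt="Chest pain",
                    evidence=None,
                    serious=False,
                    resolved=True,
                    grade=1,
                    nonadj=False,
                )
            ],
        )
    for i, p in enumerate(screened_noncv_death_ids):
        plans[p].extra_records.append(
            _EventPlan(
                onset_day=600,
                pt="Pneumonia",
                evidence=evidence_non_cv_death("pneumonia"),
                serious=True,
                fatal=True,
                resolved=False,
                dose_action=DoseAction.UNKNOWN,
                grade=5,
                nonadj=False,
            )
        )
        plans[p].death = DeathRecord(
            death_day=600, witnessed=False, last_seen_alive_hours_before=48.0
        )

    for i, p in enumerate(fatal_only_noncv_ids):
        plans[p] = _PatientPlan(
            pid=p,
            extra_records=[
                _EventPlan(
                    onset_day=400 + i,
                    pt="Sepsis",
                    evidence=evidence_non_cv_death("sepsis"),
                    serious=True,
                    fatal=True,
                    resolved=False,
                    dose_action=DoseAction.UNKNOWN,
                    grade=5,
                    nonadj=False,
                )
            ],
            death=DeathRecord(
                death_day=400 + i, witnessed=False, last_seen_alive_hours_before=48.0
            ),
        )

    for i, p in enumerate(progression_death_ids):
        plans[p] = _PatientPlan(
            pid=p,
            extra_records=[
                _EventPlan(
                    onset_day=300 + i,
                    pt="Disease progression",
                    evidence=None,
                    serious=True,
                    fatal=True,
                    resolved=False,
                    dose_action=DoseAction.UNKNOWN,
                    grade=5,
                    nonadj=False,
                )
            ],
            death=DeathRecord(death_day=300 + i, witnessed=False, progression_attributed=True),
        )

    # plain patients with no role
    for i in range(1, N_PATIENTS + 1):
        plans.setdefault(pid(i), _PatientPlan(pid=pid(i)))

    # --- in-list filler records to reach 455 flagged ----------------------
    dead_ids = {p for p, plan in plans.items() if plan.death is not None}
    screened_patient_ids = (
        [p for p in adjudicated_order if p != pid(4)] + extras_ids + screened_only_ids
    )
    filler_hosts = [p for p in screened_patient_ids if p not in dead_ids]
    n_flagged_core = (
        sum(len(plans[p].events) for p in adjudicated_order)
        - 1  # the intracranial-hemorrhage record is not in the screening list
        + len(extras_ids)
        + len(screened_only_ids)
    )
    n_fillers = 455 - n_flagged_core
    assert n_fillers >= 0, n_flagged_core
    for k in range(n_fillers):
        host = filler_hosts[k % len(filler_hosts)]
        plans[host].extra_records.append(
            _EventPlan(
                onset_day=1650 + (k // len(filler_hosts)),
                pt="Chest pain" if k % 2 == 0 else "Chest discomfort",
                evidence=None,
                serious=False,
                resolved=True,
                grade=1,
                nonadj=False,
            )
        )

    # --- risk factors -----------------------------------------------------
    # strata: 80 patients with 0 factors, 189 with 1-2, 180 with >= 3;
    # adjudicated-AOE membership 2 / 24 / 52; per-factor totals as published.
    aoe_zero = adjudicated_order[-2:]  # two AOE patients without risk factors
    aoe_pool = [p for p in adjudicated_order if p not in set(aoe_zero)]
    aoe_two = aoe_pool[:24]
    aoe_three = aoe_pool[24:]  # 52
    non_aoe = [pid(i) for i in range(1, N_PATIENTS + 1) if pid(i) not in set(adjudicated_order)]
    non_aoe_zero = non_aoe[:78]
    non_aoe_two = non_aoe[78 : 78 + 165]
    non_aoe_three = non_aoe[78 + 165 :]  # 128
    assert len(non_aoe_three) == 128

    demand: Dict[str, int] = {}
    for p in aoe_zero + non_aoe_zero:
        demand[p] = 0
    for p in aoe_two + non_aoe_two:
        demand[p] = 2
    for p in aoe_three:
        demand[p] = 3
    for i, p in enumerate(non_aoe_three):
        demand[p] = 4 if i < 17 else 3  # 17 four-factor patients balance the factor totals
    assert sum(demand.values()) == sum(RISK_FACTOR_TOTALS.values())
    risk_assignment = _assign_risk_factors(demand)

    # --- materialize ------------------------------------------------------
    patients: Dict[str, PatientRecord] = {}
    records: List[AdverseEventRecord] = []
    evidence: Dict[str, EvidencePackage] = {}
    rec_counter = itertools.count(1)

    for i in range(1, N_PATIENTS + 1):
        p = pid(i)
        plan = plans[p]
        last_contact = plan.death.death_day if plan.death else _ALIVE_LAST_CONTACT
        patients[p] = PatientRecord(
            patient_id=p,
            cohort=_cohort_of_index(i),
            age_years=40 + (i % 40),
            sex=Sex.FEMALE if i % 449 < 211 else Sex.MALE,
            risk_factors=risk_assignment[p],
            first_dose_day=1,
            last_contact_day=last_contact,
            death=plan.death,
        )
        for ev_plan in plan.events + plan.extra_records:
            rid = f"R{next(rec_counter):05d}"
            records.append(
                AdverseEventRecord(
                    record_id=rid,
                    patient_id=p,
                    preferred_term=ev_plan.pt,
                    onset_day=ev_plan.onset_day,
                    resolution_day=ev_plan.onset_day + 30 if ev_plan.resolved else None,
                    resolved=ev_plan.resolved,
                    severity_grade=ev_plan.grade,
                    serious=ev_plan.serious,
                    dose_action=ev_plan.dose_action,
                    fatal=ev_plan.fatal,
                    nonadjudicated_aoe=ev_plan.nonadj,
                )
            )
            if ev_plan.evidence is not None:
                evidence[rid] = ev_plan.evidence

    # --- out-of-list nuisance records up to 12,224 ------------------------
    alive_ids = [pid(i) for i in range(1, N_PATIENTS + 1) if pid(i) not in dead_ids]
    n_nuisance = TOTAL_AE_RECORDS - len(records)
    assert n_nuisance >= 0
    for k in range(n_nuisance):
        host = alive_ids[k % len(alive_ids)]
        rid = f"R{next(rec_counter):05d}"
        records.append(
            AdverseEventRecord(
                record_id=rid,
                patient_id=host,
                preferred_term=NUISANCE_PTS[k % len(NUISANCE_PTS)],
                onset_day=10 + 3 * (k // len(alive_ids)),
                resolved=True,
                severity_grade=1,
                serious=False,
            )
        )

    records.sort(key=lambda r: (r.patient_id, r.onset_day, r.record_id))
    ds = StudyDataset(
        patients=patients,
        adverse_events=records,
        evidence=evidence,
        provenance={"generator": "build_paper_calibrated_fixture"},
    )
    _check_fixture(ds)
    return ds


def _check_fixture(ds: StudyDataset) -> None:
    """Cheap structural self-checks; full marginals are covered by tests."""
    if len(ds.patients) != N_PATIENTS:
        raise RuntimeError(f"fixture has {len(ds.patients)} patients")
    if len(ds.adverse_events) != TOTAL_AE_RECORDS:
        raise RuntimeError(f"fixture has {len(ds.adverse_events)} AE records")
    sizes = {c: 0 for c in Cohort}
    for p in ds.patients.values():
        sizes[p.cohort] += 1
    if sizes != COHORT_SIZES:
        raise RuntimeError(f"cohort sizes off: {sizes}")
    factor_counts = {f: 0 for f in RiskFactor}
    for p in ds.patients.values():
        for f in p.risk_factors:
            factor_counts[f] += 1
    if factor_counts != RISK_FACTOR_TOTALS:
        raise RuntimeError(f"risk-factor totals off: {factor_counts}")


# ---------------------------------------------------------------------------
# fatal-event listing (11 published rows)

@dataclass(frozen=True)
class FatalEventRow:
    fatal_event: str
    fatal_pt: str
    other_aoe_pts: Tuple[str, ...]
    status: str  # "CML" or "ALL"
    cv_history: Tuple[str, ...]
    cv_risk_factors: Tuple[str, ...]

    @property
    def has_cv_history_or_risk(self) -> bool:
        return bool(self.cv_history or self.cv_risk_factors)


def table12_fixture() -> List[FatalEventRow]:
    """Typed transcription of the published fatal-AOE listing."""
    rows = [
        FatalEventRow(
            "Bradycardiac arrest",
            "Cardiac arrest",
            ("Dry gangrene", "Peripheral ischemia"),
            "CML",
            (
                "Congestive heart failure",
                "Impaired diastolic filling pattern",
                "Left atrium enlargement",
                "Mild tricuspid regurgitation",
                "Mitral valve calcification without significant mitral stenosis",
                "Intermittent ventricular tachycardia",
            ),
            ("Obesity", "Diabetes mellitus", "Arterial hypertension"),
        ),
        FatalEventRow(
            "Cardiac failure",
            "Cardiac failure",
            ("Myocardial infarction", "Coronary artery disease", "Pulmonary embolism"),
            "CML",
            ("Pericarditis", "Ischemic heart failure"),
            (),
        ),
        FatalEventRow(
            "Intracranial hemorrhage",
            "Haemorrhage intracranial",
            (),
            "CML",
            ("Aortic stenosis", "Calcified mitral annulus"),
            (),
        ),
        FatalEventRow(
            "Worsening of congestive heart failure",
            "Cardiac failure congestive",
            ("Myocardial infarction", "Deep vein thrombosis"),
            "CML",
            (
                "QTc prolongation with nilotinib use",
                "Stent placement",
                "Congestive heart failure",
                "Myocardial infarction",
                "Coronary artery disease",
                "Mitral regurgitation",
                "Trace of tricuspid valve regurgitation",
            ),
            ("Hyperlipidemia", "Arterial hypertension"),
        ),
        FatalEventRow(
            "Superior mesenteric artery occlusion",
            "Mesenteric arterial occlusion",
            ("Celiac artery occlusion",),
            "ALL",
            (
                "Paroxysmal atrial fibrillation",
                "Thrombophlebitis",
                "Bilateral leg deep vein thrombosis",
                "Cardiac catheterization",
            ),
            ("Hyperlipidemia", "Arterial hypertension"),
        ),
        FatalEventRow(
            "Cardiac arrest",
            "Cardiac arrest",
            ("Peripheral vascular disorder",),
            "ALL",
            (
                "Greater saphenous vein thrombosis and cellulitis",
                "Aortic valve slightly thickened",
                "Left axis deviation",
                "Left bundle branch block",
                "Mild aortic regurgitation",
                "Mild pulmonic valve regurgitation",
                "Mild to moderate tricuspid regurgitation",
            ),
            ("Hypertension", "Arterial hypertension"),
        ),
        FatalEventRow(
            "Hemorrhagic cerebral infarction",
            "Haemorrhagic cerebral infarction",
            ("Cerebral artery stenosis (2 events)", "Cerebral infarction (2 events)"),
            "CML",
            (),
            ("Diabetes mellitus", "Arterial hypertension"),
        ),
        FatalEventRow("Cardiac arrest", "Cardiac arrest", (), "CML", (), ()),
        FatalEventRow(
            "Cardiac arrest",
            "Cardiac arrest",
            (),
            "CML",
            ("Ischemic heart disease", "Angina pectoris", "Coronary artery disease"),
            ("Type 2 diabetes mellitus", "Hypertension"),
        ),
        FatalEventRow(
            "Congestive heart failure", "Cardiac failure congestive", (), "CML", (), ()
        ),
        FatalEventRow(
            "Stroke",
            "Cerebrovascular accident",
            ("Acute myocardial infarction (2 events)",),
            "CML",
            (
                "Ischemic stroke",
                "Ischemic heart disease",
                "Coronary artery disease",
                "Revascularization and coronary stent placement",
            ),
            ("Diabetes mellitus", "Arterial hypertension", "Hypercholesterolemia"),
        ),
    ]
    assert len(rows) == 11
    return rows
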