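import pytest

from aoekit.rules import (
    CRITERIA,
    Decision,
    EvalContext,
    ReviewView,
    attribute_heart_failure_to_aoe,
    classify_candidate_event,
    classify_death_cause,
    classify_fatal_case,
    classify_heart_failure_event,
    classify_myocardial_infarction,
    classify_peripheral_vascular_disease,
    classify_stroke,
    classify_unstable_angina_hospitalization,
    classify_venous_event,
    derive_endpoint_category,
    evaluate_criterion,
    evaluate_symptom_only_exclusion,
)
from aoekit.types import (
    AdjudicatedOutcome,
    Category,
    DeathRecord,
    Endpoint,
    EvidencePackage,
    HFCause,
    Hospitalization,
    MIContext,
    MI_ENDPOINTS,
    VesselSide,
)


def view(pts=("Myocardial infarction",), grade=3, med_change=False, anatomic=False,
         serious=True, fatal=False, evidence=None, death=None):
    return ReviewView(
        preferred_terms=tuple(pts),
        max_severity_grade=grade,
        medication_changed=med_change,
        any_anatomic_diagnosis=anatomic,
        serious=serious,
        fatal=fatal,
        evidence=evidence or EvidencePackage(),
        death=death,
    )


# --- symptom-only exclusion -------------------------------------------------

def test_low_grade_symptom_is_excluded():
    v = view(pts=("Non-cardiac chest pain",), grade=1, serious=False)
    assert evaluate_symptom_only_exclusion(v) is True


def test_anatomic_diagnosis_blocks_exclusion():
    v = view(pts=("Intermittent claudication",), grade=1, serious=False, anatomic=True)
    assert evaluate_symptom_only_exclusion(v) is False


def test_high_grade_hospitalized_angina_proceeds():
    ev = EvidencePackage(hospitalization=Hospitalization(admit_day=10, discharge_day=12))
    v = view(pts=("Angina pectoris",), grade=3, evidence=ev)
    assert evaluate_symptom_only_exclusion(v) is False


# --- myocardial infarction --------------------------------------------------

def mi1_evidence(**kw):
    base = dict(
        mi_context=MIContext.SPONTANEOUS,
        troponin_ratio_to_URL=2.0,
        troponin_rise_fall=True,
        ecg=frozenset({"new_ST_elevation"}),
    )
    base.update(kw)
    return EvidencePackage(**base)


def test_type1_spontaneous_with_rise_fall_and_ecg():
    assert classify_myocardial_infarction(mi1_evidence()) is Endpoint.MI_TYPE1


def test_type2_supply_demand():
    ev = mi1_evidence(mi_context=MIContext.SUPPLY_DEMAND)
    assert classify_myocardial_infarction(ev) is Endpoint.MI_TYPE2


def test_type4a_above_5x_threshold():
    ev = EvidencePackage(
        mi_context=MIContext.POST_PCI_24H,
        baseline_biomarker_normal=True,
        troponin_ratio_to_URL=6.0,
        ecg=frozenset({"new_ST_depression_or_Twave"}),
    )
    assert classify_myocardial_infarction(ev) is Endpoint.MI_TYPE4A


def test_type4a_below_5x_is_no_mi():
    ev = EvidencePackage(
        mi_context=MIContext.POST_PCI_24H,
        baseline_biomarker_normal=True,
        troponin_ratio_to_URL=4.0,
        ecg=frozenset({"new_ST_depression_or_Twave"}),
    )
    assert classify_myocardial_infarction(ev) is None


def test_type5_above_10x():
    ev = EvidencePackage(
        mi_context=MIContext.POST_CABG,
        baseline_biomarker_normal=True,
        troponin_ratio_to_URL=12.0,
        ecg=frozenset({"pathological_Q_waves"}),
    )
    assert classify_myocardial_infarction(ev) is Endpoint.MI_TYPE5


@pytest.mark.parametrize(
    "ratio,expected",
    [(5.0, None), (5.0 + 1e-9, Endpoint.MI_TYPE4A)],
)
def test_type4a_threshold_is_strict(ratio, expected):
    ev = EvidencePackage(
        mi_context=MIContext.POST_PCI_24H,
        baseline_biomarker_normal=True,
        troponin_ratio_to_URL=ratio,
        ecg=frozenset({"new_ST_elevation"}),
    )
    assert classify_myocardial_infarction(ev) is expected


@pytest.mark.parametrize(
    "ratio,expected",
    [(10.0, None), (10.0 + 1e-9, Endpoint.MI_TYPE5)],
)
def test_type5_threshold_is_strict(ratio, expected):
    ev = EvidencePackage(
        mi_context=MIContext.POST_CABG,
        baseline_biomarker_normal=True,
        troponin_ratio_to_URL=ratio,
        ecg=frozenset({"pathological_Q_waves"}),
    )
    assert classify_myocardial_infarction(ev) is expected


def test_type4b_stent_thrombosis():
    ev = EvidencePackage(
        mi_context=MIContext.STENT_THROMBOSIS,
        imaging=frozenset({"stent_thrombus_confirmed"}),
        symptoms=frozenset({"ischemic_discomfort"}),
        troponin_rise_fall=True,
        troponin_ratio_to_URL=2.0,
    )
    assert classify_myocardial_infarction(ev) is Endpoint.MI_TYPE4B


def test_at_most_one_mi_subtype():
    for ev in (mi1_evidence(), mi1_evidence(mi_context=MIContext.POST_PCI_24H,
                                            baseline_biomarker_normal=True,
                                            troponin_ratio_to_URL=6.0)):
        results = [classify_myocardial_infarction(ev) for _ in range(3)]
        assert len(set(results)) == 1
        assert results[0] is None or results[0] in MI_ENDPOINTS


# --- heart failure ----------------------------------------------------------

def hf_evidence(**kw):
    base = dict(
        hf_primary_diagnosis=True,
        hospitalization=Hospitalization(admit_day=10, discharge_day=13, unscheduled=True),
        symptoms=frozenset({"dyspnea"}),
        hf_exam_findings_count=2,
        hf_treatment_intensified=True,
        hf_underlying_cause=HFCause.CORONARY_ARTERY_DISEASE,
    )
    base.update(kw)
    return EvidencePackage(**base)


def test_hf_hospitalization_classifies():
    assert classify_heart_failure_event(hf_evidence()) is Endpoint.HF_HOSPITALIZATION


def test_hf_requires_treatment_intensification():
    assert classify_heart_failure_event(hf_evidence(hf_treatment_intensified=False)) is None


def test_hf_urgent_visit_oral_diuretic_only_insufficient():
    ev = hf_evidence(
        hospitalization=None,
        urgent_visit=True,
        hf_oral_diuretic_only=True,
    )
    assert classify_heart_failure_event(ev) is None


def test_hf_urgent_visit_with_real_intensification():
    ev = hf_evidence(hospitalization=None, urgent_visit=True, hf_oral_diuretic_only=False)
    assert classify_heart_failure_event(ev) is Endpoint.HF_URGENT_VISIT


def test_hf_one_exam_plus_lab_satisfies_objective():
    ev = hf_evidence(hf_exam_findings_count=1, hf_lab_findings_count=1)
    assert classify_heart_failure_event(ev) is Endpoint.HF_HOSPITALIZATION


@pytest.mark.parametrize(
    "cause,expected",
    [
        (HFCause.CORONARY_ARTERY_DISEASE, True),
        (HFCause.HYPERTENSION, True),
        (HFCause.VALVE_DISORDER, False),
        (HFCause.ARRHYTHMIA, False),
    ],
)
def test_hf_attribution(cause, expected):
    attributed, panel = attribute_heart_failure_to_aoe(EvidencePackage(hf_underlying_cause=cause))
    assert attributed is expected and panel is False


def test_hf_attribution_unknown_defaults_false_with_panel_flag():
    attributed, panel = attribute_heart_failure_to_aoe(EvidencePackage())
    assert attributed is False and panel is True


# --- unstable angina --------------------------------------------------------

def ua_evidence(**kw):
    base = dict(
        troponin_rise_fall=False,
        troponin_ratio_to_URL=0.5,
        symptoms=frozenset({"ischemic_discomfort_ge_10min_at_rest"}),
        hospitalization=Hospitalization(
            admit_day=10, discharge_day=12, unscheduled=True, within_24h_of_symptoms=True
        ),
        ecg=frozenset({"new_ST_depression_or_Twave"}),
    )
    base.update(kw)
    return EvidencePackage(**base)


def test_ua_classifies():
    assert classify_unstable_angina_hospitalization(ua_evidence()) is Endpoint.UA_HOSPITALIZATION


def test_ua_positive_biomarkers_block():
    ev = ua_evidence(troponin_rise_fall=True, troponin_ratio_to_URL=2.0)
    assert classify_unstable_angina_hospitalization(ev) is None


def test_ua_short_rest_angina_fails():
    ev = ua_evidence(symptoms=frozenset({"ischemic_discomfort"}))
    assert classify_unstable_angina_hospitalization(ev) is None


# --- stroke -----------------------------------------------------------------

def stroke_evidence(**kw):
    base = dict(
        symptoms=frozenset({"focal_neuro_deficit"}),
        neuro_deficit_duration_hours=30.0,
        imaging=frozenset({"brain_CT_or_MRI_infarct"}),
        neuro_confirmation=frozenset({"specialist"}),
        non_stroke_cause_present=False,
    )
    base.update(kw)
    return EvidencePackage(**base)


def test_stroke_ischemic_classifies():
    assert classify_stroke(stroke_evidence()) is Endpoint.STROKE_ISCHEMIC


def test_short_deficit_without_equivalents_is_not_stroke():
    ev = stroke_evidence(
        neuro_deficit_duration_hours=2.0,
        imaging=frozenset(),
        stroke_abort_intervention=False,
    )
    assert classify_stroke(ev, died=False) is None


def test_duration_boundary_24h_is_inclusive():
    ok = stroke_evidence(neuro_deficit_duration_hours=24.0, imaging=frozenset(),
                         stroke_abort_intervention=False)
    below = stroke_evidence(neuro_deficit_duration_hours=23.999, imaging=frozenset(),
                            stroke_abort_intervention=False)
    assert classify_stroke(ok) is Endpoint.STROKE_UNDETERMINED
    assert classify_stroke(below) is None


def test_hemorrhagic_transformation_stays_ischemic():
    ev = stroke_evidence(imaging=frozenset({"brain_CT_or_MRI_infarct", "brain_hemorrhage"}))
    assert classify_stroke(ev) is Endpoint.STROKE_ISCHEMIC


def test_pure_hemorrhage_is_hemorrhagic():
    ev = stroke_evidence(imaging=frozenset({"brain_hemorrhage"}))
    assert classify_stroke(ev) is Endpoint.STROKE_HEMORRHAGIC


def test_infarction_pt_forces_ischemic():
    ev = stroke_evidence(imaging=frozenset(), neuro_deficit_duration_hours=30.0)
    assert classify_stroke(ev, pts=("Cerebral infarction",)) is Endpoint.STROKE_ISCHEMIC


def test_retinal_artery_occlusion_subtype():
    ev = stroke_evidence(imaging=frozenset())
    assert classify_stroke(ev, pts=("Retinal artery occlusion",)) is Endpoint.STROKE_RETINAL_ARTERY


def test_amaurosis_fugax_vetoes_retinal():
    ev = stroke_evidence(imaging=frozenset())
    got = classify_stroke(ev, pts=("Amaurosis fugax",))
    assert got is not Endpoint.STROKE_RETINAL_ARTERY


# --- venous and PVD ---------------------------------------------------------

def test_dvt_documented_by_ultrasound():
    ev = EvidencePackage(
        imaging=frozenset({"venous_ultrasound_or_venogram_positive"}),
    )
    assert classify_venous_event(ev) is Endpoint.DVT
    assert derive_endpoint_category(Endpoint.DVT) == (False, None)


def test_pe_on_ct():
    ev = EvidencePackage(imaging=frozenset({"pulmonary_CT_or_VQ_positive"}))
    assert classify_venous_event(ev) is Endpoint.PE
    assert derive_endpoint_category(Endpoint.PE) == (False, None)


def test_svt_clinical_signs():
    ev = EvidencePackage(superficial_thrombosis_signs=True)
    assert classify_venous_event(ev) is Endpoint.SVT


def test_pvd_arterial_on_doppler():
    ev = EvidencePackage(
        imaging=frozenset({"doppler_or_ABI_or_angio_PVD"}),
        pvd_vessel_side=VesselSide.ARTERIAL,
    )
    assert classify_peripheral_vascular_disease(ev) is Endpoint.PVD_ARTERIAL
    assert derive_endpoint_category(Endpoint.PVD_ARTERIAL, ("Peripheral artery stenosis",)) == (
        True,
        Category.PERIPHERAL_VASCULAR,
    )


def test_pvd_venous_is_not_aoe():
    ev = EvidencePackage(
        imaging=frozenset({"doppler_or_ABI_or_angio_PVD"}),
        pvd_vessel_side=VesselSide.VENOUS,
    )
    assert classify_peripheral_vascular_disease(ev) is Endpoint.PVD_VENOUS
    assert derive_endpoint_category(Endpoint.PVD_VENOUS) == (False, None)


def test_pvd_without_documentation_is_none():
    assert classify_peripheral_vascular_disease(EvidencePackage()) is None


# --- categories -------------------------------------------------------------

def test_category_map_examples():
    assert derive_endpoint_category(Endpoint.MI_TYPE1) == (True, Category.CARDIOVASCULAR)
    assert derive_endpoint_category(Endpoint.STROKE_ISCHEMIC) == (
        True,
        Category.CEREBROVASCULAR,
    )


def test_carotid_pvd_maps_cerebrovascular():
    assert derive_endpoint_category(Endpoint.PVD_ARTERIAL, ("Carotid artery stenosis",)) == (
        True,
        Category.CEREBROVASCULAR,
    )


def test_hypertension_pts_never_aoe():
    assert derive_endpoint_category(Endpoint.MI_TYPE1, ("Arterial hypertension",)) == (
        False,
        None,
    )


def test_unmapped_endpoint_raises():
    with pytest.raises(ValueError):
        derive_endpoint_category("bogus")


# --- death classification ---------------------------------------------------

def test_death_after_mi_is_cv_death_mi():
    history = [
        AdjudicatedOutcome(
            event_id="E1", patient_id="P1", endpoint=Endpoint.MI_TYPE1, is_aoe=True,
            category=Category.CARDIOVASCULAR, onset_day=90,
        )
    ]
    d = DeathRecord(death_day=100, witnessed=False, last_seen_alive_hours_before=48.0)
    endpoint, _ = classify_death_cause(d, EvidencePackage(), history=history)
    assert endpoint is Endpoint.CV_DEATH_MI


def test_unwitnessed_seen_alive_within_24h_is_sudden():
    d = DeathRecord(death_day=100, witnessed=False, last_seen_alive_hours_before=20.0)
    endpoint, _ = classify_death_cause(d, EvidencePackage())
    assert endpoint is Endpoint.CV_DEATH_SUDDEN


def test_found_dead_after_days_without_cause_is_undetermined():
    d = DeathRecord(death_day=100, witnessed=False, last_seen_alive_hours_before=120.0)
    endpoint, _ = classify_death_cause(d, EvidencePackage())
    assert endpoint is Endpoint.UNDETERMINED_DEATH


def test_periprocedural_death_is_cv_procedure():
    d = DeathRecord(death_day=100, witnessed=True)
    ev = EvidencePackage(procedure=frozenset({"PCI"}), procedure_timing_hours=3.0)
    endpoint, _ = classify_death_cause(d, ev)
    assert endpoint is Endpoint.CV_DEATH_PROCEDURE


def test_specific_non_cv_cause():
    d = DeathRecord(death_day=100, witnessed=False, last_seen_alive_hours_before=10.0)
    endpoint, _ = classify_death_cause(d, EvidencePackage(non_cv_cause="sepsis"))
    assert endpoint is Endpoint.NON_CV_DEATH


# --- determinism, trace soundness, panel flag -------------------------------

def test_identical_evidence_identical_decision():
    v = view(evidence=mi1_evidence())
    d1 = classify_candidate_event(v)
    d2 = classify_candidate_event(v)
    assert d1 == d2
    assert d1.endpoint is Endpoint.MI_TYPE1 and d1.is_aoe


def test_trace_replays_to_same_statuses(calibrated_pipeline):
    checked = 0
    for outcome, event in zip(
        calibrated_pipeline.outcomes, calibrated_pipeline.events
    ):
        for cid, status in outcome.criteria_trace:
            if cid in CRITERIA:
                assert evaluate_criterion(cid, event.merged_evidence) is status, (
                    outcome.event_id,
                    cid,
                )
                checked += 1
    assert checked > 500


def test_unknowns_blocking_endpoint_raise_panel_flag():
    # MI evidence with unknown biomarkers: otherwise met -> panel review
    ev = EvidencePackage(
        mi_context=MIContext.SPONTANEOUS,
        ecg=frozenset({"new_ST_elevation"}),
    )
    d = classify_candidate_event(view(evidence=ev))
    assert d.endpoint is Endpoint.NOT_AN_EVENT
    assert d.panel_review is True


def test_definitely_failing_evidence_has_no_panel_flag():
    ev = EvidencePackage(
        mi_context=MIContext.SPONTANEOUS,
        troponin_rise_fall=False,
        troponin_ratio_to_URL=0.2,
        ckmb_above_URL=False,
        baseline_biomarker_normal=True,
        biomarker_decreasing_prior=False,
        non_stroke_cause_present=False,
        stroke_abort_intervention=False,
        hf_primary_diagnosis=False,
        hf_treatment_intensified=False,
        hf_oral_diuretic_only=True,
        urgent_visit=False,
        superficial_thrombosis_signs=False,
        neuro_deficit_duration_hours=1.0,
        hospitalization=Hospitalization(admit_day=1, discharge_day=1),
    )
    d = classify_candidate_event(view(evidence=ev))
    assert d.endpoint is Endpoint.NOT_AN_EVENT
    assert d.panel_review is False
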