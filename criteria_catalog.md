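# Criterion catalog

Stable identifiers used in adjudication criteria traces. Each criterion is
evaluated on the pooled evidence package with three-valued logic
(`met` / `not_met` / `unknown`); under the default policy an unknown
criterion does not support automatic classification and may raise the
`panel_review` flag.

## Myocardial infarction

| id | meaning |
|----|---------|
| `mi.context_spontaneous` | clinical setting is spontaneous ischemia (type 1) |
| `mi.context_supply_demand` | ischemia from supply/demand inequity (type 2) |
| `mi.context_post_pci` | within 24 h of PCI (type 4a) |
| `mi.context_stent_thrombosis` | stent-thrombosis setting (type 4b) |
| `mi.context_stent_restenosis` | stent-restenosis setting, > 48 h after index PCI (type 4c) |
| `mi.context_post_cabg` | CABG-associated setting (type 5) |
| `mi.biomarker_above_url` | troponin rise/fall above the 99th-percentile URL, or CK-MB above URL |
| `mi.rise_fall_above_url` | troponin rise and/or fall with at least one value above the URL |
| `mi.tn_gt_5x_normal_baseline` | normal baseline biomarker and peak > 5 × URL (strict) |
| `mi.elevated_baseline_rise20` | elevated baseline with a ≥ 20 % rise after documented decline |
| `mi.tn_gt_10x_normal_baseline` | normal baseline biomarker and peak > 10 × URL (strict) |
| `mi.stent_thrombus_confirmed` | stent thrombus confirmed angiographically or at autopsy |
| `mi.stent_restenosis_ge_50pct` | ≥ 50 % restenosis at prior successful stent site |
| `mi.ischemic_symptoms` | symptoms suggestive of myocardial ischemia |
| `mi.support_general` | imaging loss of viable myocardium / wall-motion abnormality, or new ischemic ECG / pathological Q |
| `mi.support_4a` | type-4a support: symptoms, new ischemic ECG/LBBB, angiographic complication, or imaging loss |
| `mi.support_5` | type-5 support: new Q/LBBB, documented graft or native occlusion, or imaging loss |

## Hospitalization for unstable angina

| id | meaning |
|----|---------|
| `ua.no_mi` | no acute-MI classification applies |
| `ua.biomarkers_negative` | cardiac biomarkers negative |
| `ua.rest_ischemia_ge_10min` | ischemic discomfort ≥ 10 min at rest |
| `ua.unscheduled_hospitalization` | unscheduled admission within 24 h of symptoms with ≥ 24 h stay |
| `ua.objective_support` | new/worsening ST-T changes, transient ST elevation, culprit lesion ≥ 70 %, or revascularization of the culprit lesion |

## Heart failure

| id | meaning |
|----|---------|
| `hf.primary_diagnosis` | admitted/seen with a primary diagnosis of heart failure |
| `hf.stay_ge_24h` | hospital stay ≥ 24 h (or calendar-date change) |
| `hf.symptom` | ≥ 1 new/worsening HF symptom (dyspnea, orthopnea, PND, reduced exercise tolerance, fatigue) |
| `hf.objective_findings` | ≥ 2 physical-exam findings, or 1 exam finding plus ≥ 1 laboratory criterion |
| `hf.treatment_intensified` | initiation or intensification of HF-specific treatment |
| `hf.urgent_visit` | urgent, unscheduled office or emergency-department visit |
| `hf.beyond_oral_diuretic` | intensification beyond oral diuretic therapy (oral diuretic alone is insufficient for urgent visits) |

## Stroke

| id | meaning |
|----|---------|
| `stroke.acute_deficit` | acute focal or global neurological deficit |
| `stroke.duration_or_equivalent` | deficit ≥ 24 h, or < 24 h with abort-intervention or imaging-documented lesion |
| `stroke.duration_or_equivalent_fatal` | as above, with death before 24 h also qualifying |
| `stroke.no_other_cause` | no readily identifiable non-stroke cause |
| `stroke.confirmation` | confirmation by specialist, brain imaging, or lumbar puncture (absent confirmation is a panel matter) |

## Venous thrombosis and peripheral vascular disease

| id | meaning |
|----|---------|
| `venous.pe_documented` | pulmonary embolism documented by CT, angiogram, V/Q scan, or autopsy |
| `venous.dvt_documented` | deep-vein clot documented by ultrasonography/CUS/IPG/venography/CT/MRI/autopsy |
| `venous.svt_documented` | superficial clot documented by clinical signs or duplex |
| `pvd.documented` | PVD documented by Doppler, ankle-brachial index, or angiography (incl. MRA/CTA) |
| `pvd.side_known` | arterial vs venous side recorded |

## Death classification and triage markers

| id | meaning |
|----|---------|
| `death.recent_mi` | death ≤ 30 d after MI or from a procedure treating MI |
| `death.recent_stroke` | death ≤ 30 d after stroke |
| `death.periprocedural` | immediate complication of a cardiovascular procedure |
| `death.cv_hemorrhage` | cardiovascular hemorrhage (non-stroke intracranial, vascular rupture, tamponade) |
| `death.worsening_hf` | worsening HF signs/symptoms, any etiology |
| `death.sudden_cardiac` | witnessed arrest rules, or unwitnessed but seen alive ≤ 24 h with no non-CV evidence |
| `death.other_cv_cause` | other specific cardiovascular cause (incl. PE, peripheral vascular disease) |
| `death.specific_non_cv_cause` | specific non-cardiovascular cause |
| `death.unclassifiable` | insufficient information; undetermined |
| `triage.symptom_only_exclusion` | low-grade symptom recording with no medication change, hospitalization, or anatomic diagnosis |

## ECG abstraction note

ECG criteria are consumed as pre-abstracted booleans
(`new_ST_elevation`, `new_ST_depression_or_Twave`, `new_LBBB`,
`pathological_Q_waves`, `transient_ST_elevation`). The millivolt/lead
definitions behind these flags (e.g., ST elevation at the J-point
≥ 0.2 mV in men / ≥ 0.15 mV in women in V2–V3; pathological Q ≥ 0.03 s and
≥ 0.1 mV deep in two contiguous leads) belong to the upstream evidence
abstraction; the trial database stores coded findings, not waveforms.
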