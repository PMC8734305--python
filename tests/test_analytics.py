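from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aoekit.analytics import (
    DoseModificationSummary,
    baseline_summary,
    compute_relative_risk,
    dose_modification_summary,
    exposure_adjusted_incidence,
    patient_level_rates,
    percent,
    resolution_summary,
    risk_factor_strata,
    round_half_away,
    time_to_first_event_summary,
    worst_dose_action,
)
from aoekit.types import (
    AdjudicatedOutcome,
    Category,
    Cohort,
    DAYS_PER_MONTH,
    DoseAction,
    Endpoint,
    RiskFactor,
    Sex,
)

from conftest import make_dataset, make_patient, make_record


def outcome(pid, event_id=None, onset=100, is_aoe=True, serious=True, rids=(), endpoint=None):
    return AdjudicatedOutcome(
        event_id=event_id or f"E-{pid}-{onset}",
        patient_id=pid,
        endpoint=endpoint or (Endpoint.MI_TYPE1 if is_aoe else Endpoint.NOT_AN_EVENT),
        is_aoe=is_aoe,
        category=Category.CARDIOVASCULAR if is_aoe else None,
        serious=serious,
        onset_day=onset,
        member_record_ids=tuple(rids),
    )


# --- rounding ---------------------------------------------------------------

@pytest.mark.parametrize("x,expected", [(2.5, 3), (16.48, 16), (17.37, 17), (0.5, 1), (0.49, 0)])
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected


@settings(max_examples=300, deadline=None)
@given(num=st.integers(0, 1000), den=st.integers(1, 1000))
def test_percent_matches_exact_rational_arithmetic(num, den):
    if num > den:
        num = num % (den + 1)
    frac = Fraction(100 * num, den)
    floor, rem = divmod(frac.numerator, frac.denominator)
    expected = floor + (1 if Fraction(rem, frac.denominator) >= Fraction(1, 2) else 0)
    assert percent(num, den) == expected


def test_2_of_80_rounds_to_3_percent():
    assert percent(2, 80) == 3  # the convention the published tables force


# --- patient-level rates ----------------------------------------------------

def test_78_of_449_is_17_percent():
    patients = {f"P{i}": make_patient(f"P{i}") for i in range(449)}
    outs = [outcome(f"P{i}") for i in range(78)]
    r = patient_level_rates(outs, patients)
    assert (r.numerator, r.denominator, r.rate_percent) == (78, 449, 17)


def test_zero_positive_is_zero_percent():
    patients = {f"P{i}": make_patient(f"P{i}") for i in range(100)}
    r = patient_level_rates([], patients)
    assert r.rate_percent == 0


def test_empty_denominator_errors():
    with pytest.raises(ValueError):
        patient_level_rates([], {}, cohort=Cohort.CP_CML)


def test_nonadjudicated_rates_use_input_flags():
    patients = {f"P{i}": make_patient(f"P{i}") for i in range(4)}
    records = [
        make_record("R1", "P0", nonadjudicated_aoe=True, serious=True),
        make_record("R2", "P1", nonadjudicated_aoe=True, serious=False),
        make_record("R3", "P2", nonadjudicated_aoe=False, serious=True),
    ]
    any_r = patient_level_rates([], patients, source="nonadjudicated", records=records)
    ser_r = patient_level_rates(
        [], patients, source="nonadjudicated", records=records, serious_only=True
    )
    assert any_r.numerator == 2
    assert ser_r.numerator == 1


# --- exposure-adjusted incidence --------------------------------------------

def test_exposure_adjusted_direct_formula():
    # 4 first events over 50.0 patient-years -> 8.0 per 100 PY
    days = round(12.5 * 365.25)
    patients = {f"P{i}": make_patient(f"P{i}", last_contact=days) for i in range(4)}
    outs = [outcome(f"P{i}", onset=days) for i in range(4)]
    r = exposure_adjusted_incidence(outs, patients)
    assert r.numerator == 4
    assert r.rate_per_100py == pytest.approx(8.0, rel=1e-3)


def test_exposure_adjusted_zero_events():
    patients = {"P0": make_patient("P0", last_contact=365)}
    r = exposure_adjusted_incidence([], patients)
    assert r.rate_per_100py == 0.0


def test_later_intervals_exclude_prior_event_patients():
    patients = {
        "P0": make_patient("P0", last_contact=800),
        "P1": make_patient("P1", last_contact=800),
    }
    outs = [outcome("P0", onset=100)]  # event in year 1
    year2 = exposure_adjusted_incidence(outs, patients, interval_years=(1.0, 2.0))
    assert year2.numerator == 0
    # only P1 contributes exposure in year 2 (clipped to the interval)
    assert year2.patient_years == pytest.approx(1.0, rel=1e-6)


def test_zero_patient_years_errors():
    patients = {"P0": make_patient("P0", last_contact=100)}
    with pytest.raises(ValueError):
        exposure_adjusted_incidence([], patients, interval_years=(3.0, 4.0))


def test_yearly_numerators_sum_to_total_first_events(calibrated_pipeline, calibrated_ds):
    outs = calibrated_pipeline.outcomes
    total = len({o.patient_id for o in outs if o.is_aoe})
    sum_firsts = 0
    for y in range(5):  # follow-up in the fixture ends inside year 5
        r = exposure_adjusted_incidence(outs, calibrated_ds.patients, interval_years=(y, y + 1))
        sum_firsts += r.numerator
    assert sum_firsts == total == 78


# --- time to first event ----------------------------------------------------

def test_median_of_three_onsets():
    patients = {f"P{i}": make_patient(f"P{i}") for i in range(3)}
    outs = [
        outcome(f"P{i}", onset=round(m * DAYS_PER_MONTH)) for i, m in enumerate([3, 6, 9])
    ]
    s = time_to_first_event_summary(outs, patients)
    assert s.n == 3
    assert s.median_months == pytest.approx(6, abs=0.05)


def test_single_onset_range_collapses():
    patients = {"P0": make_patient("P0")}
    outs = [outcome("P0", onset=round(14.1 * DAYS_PER_MONTH))]
    s = time_to_first_event_summary(outs, patients)
    assert round(s.median_months, 1) == 14.1
    assert round(s.min_months, 1) == round(s.max_months, 1) == 14.1


def test_no_qualifying_patients_is_empty_not_error():
    s = time_to_first_event_summary([], {"P0": make_patient("P0")})
    assert s.n == 0 and s.median_months is None


# --- risk strata ------------------------------------------------------------

def test_stratum_membership():
    p = make_patient(
        "P1",
        risk_factors=frozenset(
            {RiskFactor.ARTERIAL_HYPERTENSION, RiskFactor.DIABETES_MELLITUS}
        ),
    )
    strata = risk_factor_strata([], {"P1": p})
    assert strata["1-2"].denominator == 1
    assert strata["0"].denominator == 0


def test_published_strata_rates():
    patients = {}
    outs = []
    idx = 0
    for n, k, pos in ((80, 0, 2), (189, 2, 24), (180, 3, 52)):
        factors = frozenset(list(RiskFactor)[:k])
        for j in range(n):
            pid = f"P{idx}"
            idx += 1
            patients[pid] = make_patient(pid, risk_factors=factors)
            if j < pos:
                outs.append(outcome(pid))
    strata = risk_factor_strata(outs, patients)
    assert strata["0"].rate_percent == 3
    assert strata["1-2"].rate_percent == 13
    assert strata[">=3"].rate_percent == 29


# --- relative risk ----------------------------------------------------------

def test_rr_direct_arithmetic():
    rr = compute_relative_risk(20, 80, 10, 90)
    assert rr.rr == pytest.approx(2.0)


def test_rr_symmetry_is_one():
    rr = compute_relative_risk(15, 85, 15, 85)
    assert rr.rr == pytest.approx(1.0)


def test_rr_matches_hand_computation():
    import math

    a, b, c, d = 12, 48, 7, 83
    rr = compute_relative_risk(a, b, c, d)
    expected = (12 / 60) / (7 / 90)
    se = math.sqrt(1 / 12 - 1 / 60 + 1 / 7 - 1 / 90)
    assert rr.rr == pytest.approx(expected)
    assert rr.ci_low == pytest.approx(expected * math.exp(-1.96 * se), rel=1e-3)
    assert rr.ci_high == pytest.approx(expected * math.exp(1.96 * se), rel=1e-3)


def test_rr_zero_cell_gets_continuity_correction():
    rr = compute_relative_risk(0, 100, 10, 90)
    assert rr.continuity_corrected
    assert rr.ci_low is None and rr.ci_high is None


# --- dose modification ------------------------------------------------------

def test_worst_action_ordering():
    assert (
        worst_dose_action([DoseAction.INTERRUPTED, DoseAction.WITHDRAWN])
        is DoseAction.WITHDRAWN
    )
    assert (
        worst_dose_action([DoseAction.UNKNOWN, DoseAction.NONE]) is DoseAction.NONE
    )


def test_dose_summary_counts():
    patients = [make_patient("P1"), make_patient("P2")]
    records = [
        make_record("R1", "P1", dose_action=DoseAction.INTERRUPTED),
        make_record("R2", "P1", onset=200, dose_action=DoseAction.WITHDRAWN),
        make_record("R3", "P2", dose_action=DoseAction.NONE),
    ]
    ds = make_dataset(patients, records)
    outs = [
        outcome("P1", rids=("R1",), onset=10),
        outcome("P1", rids=("R2",), onset=200, event_id="E2"),
        outcome("P2", rids=("R3",)),
    ]
    summary = dose_modification_summary(outs, ds)
    assert summary.counts["withdrawn"] == 1
    assert summary.counts["no_dose_modification"] == 1
    assert summary.n_patients == 2


def test_unknown_action_counts_as_not_applicable():
    ds = make_dataset(
        [make_patient("P1")], [make_record("R1", "P1", dose_action=DoseAction.UNKNOWN)]
    )
    summary = dose_modification_summary([outcome("P1", rids=("R1",))], ds)
    assert summary.counts["not_applicable_unknown"] == 1


# --- resolution -------------------------------------------------------------

def test_multi_event_patient_with_one_unresolved_is_not_all_resolved():
    ds = make_dataset(
        [make_patient("P1")],
        [
            make_record("R1", "P1", resolved=True),
            make_record("R2", "P1", onset=200, resolved=False),
        ],
    )
    outs = [
        outcome("P1", rids=("R1",), onset=10),
        outcome("P1", rids=("R2",), onset=200, event_id="E2"),
    ]
    s = resolution_summary(outs, ds)
    assert s.multi_event_patients == 1
    assert s.multi_event_all_resolved == 0


# --- baseline summary -------------------------------------------------------

def test_baseline_cohort_sizes_on_fixture(calibrated_ds):
    b = baseline_summary(calibrated_ds.patients)
    assert b["cohort_sizes"] == {"CP-CML": 270, "AP-CML": 85, "BP-CML": 62, "Ph+ALL": 32}
    assert b["female_n"] == 211


def test_baseline_all_female_toy():
    patients = {f"P{i}": make_patient(f"P{i}", sex=Sex.FEMALE) for i in range(5)}
    assert baseline_summary(patients)["female_pct"] == 100


def test_baseline_median_age():
    patients = {
        f"P{i}": make_patient(f"P{i}", age_years=a) for i, a in enumerate([50, 59, 70])
    }
    assert baseline_summary(patients)["median_age"] == 59


# --- cross-invariants on the fixture ----------------------------------------

def test_serious_subset_of_any(calibrated_pipeline, calibrated_ds):
    outs = calibrated_pipeline.outcomes
    for cat in (None, Category.CARDIOVASCULAR, Category.CEREBROVASCULAR,
                Category.PERIPHERAL_VASCULAR):
        any_r = patient_level_rates(outs, calibrated_ds.patients, category=cat)
        ser_r = patient_level_rates(outs, calibrated_ds.patients, category=cat, serious_only=True)
        assert ser_r.numerator <= any_r.numerator
        if cat is not None:
            assert any_r.numerator <= patient_level_rates(outs, calibrated_ds.patients).numerator


def test_adjudicated_patients_subset_of_submitted(calibrated_pipeline, calibrated_ds):
    aoe_patients = {o.patient_id for o in calibrated_pipeline.outcomes if o.is_aoe}
    screened = set(calibrated_pipeline.screen.flagged_patients)
    fatal_patients = {
        calibrated_ds.record(rid).patient_id
        for rid in calibrated_pipeline.screen.fatal_review_records
    }
    assert aoe_patients <= screened | fatal_patients
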