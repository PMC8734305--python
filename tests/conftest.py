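import pytest

from aoekit import build_paper_calibrated_fixture, run_pipeline
from aoekit.types import (
    AdverseEventRecord,
    Cohort,
    DoseAction,
    PatientRecord,
    Sex,
    StudyDataset,
)


def make_patient(pid="P1", cohort=Cohort.CP_CML, last_contact=1000, **kw):
    defaults = dict(
        patient_id=pid,
        cohort=cohort,
        age_years=60,
        sex=Sex.FEMALE,
        first_dose_day=1,
        last_contact_day=last_contact,
    )
    defaults.update(kw)
    return PatientRecord(**defaults)


def make_record(rid="R1", pid="P1", pt="Myocardial infarction", onset=10, **kw):
    defaults = dict(
        record_id=rid,
        patient_id=pid,
        preferred_term=pt,
        onset_day=onset,
        resolved=True,
        severity_grade=1,
        serious=False,
        dose_action=DoseAction.NONE,
    )
    defaults.update(kw)
    return AdverseEventRecord(**defaults)


def make_dataset(patients, records, evidence=None):
    return StudyDataset(
        patients={p.patient_id: p for p in patients},
        adverse_events=list(records),
        evidence=dict(evidence or {}),
    )


@pytest.fixture(scope="session")
def calibrated_ds():
    return build_paper_calibrated_fixture()


@pytest.fixture(scope="session")
def calibrated_pipeline(calibrated_ds):
    return run_pipeline(calibrated_ds)
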