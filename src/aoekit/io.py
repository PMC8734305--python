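"""Readers and writers for the SDTM-flavored study tables.

Input layout (UTF-8, comma- or tab-delimited, header row):

* ``patients.csv`` — patient_id, cohort, age_years, sex, risk_factors
  (semicolon-joined), first_dose_day, last_contact_day
* ``adverse_events.csv`` — record_id, patient_id, preferred_term, onset_day,
  onset_hour, resolution_day, resolved, severity_grade, serious,
  dose_action, anatomic_diagnosis, fatal, nonadjudicated_aoe
* ``deaths.csv`` — patient_id, death_day, witnessed,
  last_seen_alive_hours_before, progression_attributed, narrative_key
* ``evidence.jsonl`` — one JSON object per line with a ``key`` naming the
  AE record (or ``death:<patient_id>``) it backs.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .types import (
    AdverseEventRecord,
    Cohort,
    DeathRecord,
    DoseAction,
    EvidencePackage,
    PatientRecord,
    RiskFactor,
    Sex,
    StudyDataset,
    evidence_from_dict,
    evidence_to_dict,
)

log = logging.getLogger("aoekit.io")

PATIENT_COLUMNS = [
    "patient_id",
    "cohort",
    "age_years",
    "sex",
    "risk_factors",
    "first_dose_day",
    "last_contact_day",
]
AE_COLUMNS = [
    "record_id",
    "patient_id",
    "preferred_term",
    "onset_day",
    "onset_hour",
    "resolution_day",
    "resolved",
    "severity_grade",
    "serious",
    "dose_action",
    "anatomic_diagnosis",
    "fatal",
    "nonadjudicated_aoe",
]
DEATH_COLUMNS = [
    "patient_id",
    "death_day",
    "witnessed",
    "last_seen_alive_hours_before",
    "progression_attributed",
    "narrative_key",
]


class StudyLoadError(ValueError):
    pass


def _sniff_reader(path: Path):
    text = path.read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    return csv.DictReader(text.splitlines(), delimiter=delimiter)


def _require_columns(reader, required, path):
    missing = [c for c in required if c not in (reader.fieldnames or [])]
    if missing:
        raise StudyLoadError(f"{path}: missing required column(s) {missing}")


def _parse_int(value: str, what: str, row: int, path) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise StudyLoadError(f"{path} row {row}: unparseable {what} {value!r}")


def _parse_opt_int(value, what, row, path) -> Optional[int]:
    if value in (None, "", "NA"):
        return None
    return _parse_int(value, what, row, path)


def _parse_bool(value, what, row, path) -> bool:
    if isinstance(value, bool):
        return value
    v = (value or "").strip().lower()
    if v in ("true", "1", "yes", "y"):
        return True
    if v in ("false", "0", "no", "n", ""):
        return False
    raise StudyLoadError(f"{path} row {row}: unparseable {what} {value!r}")


def _parse_opt_bool(value, what, row, path) -> Optional[bool]:
    if value in (None, "", "NA"):
        return None
    return _parse_bool(value, what, row, path)


def load_study_tables(paths: dict, config: Optional[dict] = None) -> StudyDataset:
    """Load and cross-reference the four study tables.

    ``paths`` maps keys ``patients``, ``adverse_events``, ``evidence`` and
    (optionally) ``deaths`` to file paths.
    """
    config = config or {}
    patients_path = Path(paths["patients"])
    ae_path = Path(paths["adverse_events"])
    deaths_path = Path(paths["deaths"]) if paths.get("deaths") else None
    evidence_path = Path(paths["evidence"]) if paths.get("evidence") else None

    deaths: dict = {}
    if deaths_path is not None and deaths_path.exists():
        reader = _sniff_reader(deaths_path)
        _require_columns(reader, DEATH_COLUMNS[:2], deaths_path)
        for i, row in enumerate(reader, start=2):
            pid = row["patient_id"]
            deaths[pid] = DeathRecord(
                death_day=_parse_int(row["death_day"], "death_day", i, deaths_path),
                witnessed=_parse_opt_bool(row.get("witnessed"), "witnessed", i, deaths_path),
                last_seen_alive_hours_before=(
                    float(row["last_seen_alive_hours_before"])
                    if row.get("last_seen_alive_hours_before") not in (None, "", "NA")
                    else None
                ),
                progression_attributed=_parse_bool(
                    row.get("progression_attributed"), "progression_attributed", i, deaths_path
                ),
                narrative_key=row.get("narrative_key") or None,
            )

    patients: dict = {}
    reader = _sniff_reader(patients_path)
    _require_columns(reader, PATIENT_COLUMNS, patients_path)
    for i, row in enumerate(reader, start=2):
        pid = row["patient_id"]
        factors = frozenset(
            RiskFactor(f) for f in (row["risk_factors"] or "").split(";") if f
        )
        patients[pid] = PatientRecord(
            patient_id=pid,
            cohort=Cohort(row["cohort"]),
            age_years=_parse_int(row["age_years"], "age", i, patients_path),
            sex=Sex(row["sex"]),
            risk_factors=factors,
            first_dose_day=_parse_int(row["first_dose_day"], "first_dose_day", i, patients_path),
            last_contact_day=_parse_int(
                row["last_contact_day"], "last_contact_day", i, patients_path
            ),
            death=deaths.get(pid),
        )

    dangling_deaths = sorted(set(deaths) - set(patients))
    if dangling_deaths:
        raise StudyLoadError(f"deaths reference unknown patient ids: {dangling_deaths}")

    adverse_events = []
    seen_records = set()
    dangling = []
    reader = _sniff_reader(ae_path)
    _require_columns(reader, AE_COLUMNS[:4], ae_path)
    for i, row in enumerate(reader, start=2):
        rid = row["record_id"]
        if rid in seen_records:
            raise StudyLoadError(f"{ae_path} row {i}: duplicate record_id {rid!r}")
        seen_records.add(rid)
        if row["patient_id"] not in patients:
            dangling.append(row["patient_id"])
            continue
        adverse_events.append(
            AdverseEventRecord(
                record_id=rid,
                patient_id=row["patient_id"],
                preferred_term=row["preferred_term"],
                onset_day=_parse_int(row["onset_day"], "onset_day", i, ae_path),
                onset_hour=_parse_opt_int(row.get("onset_hour"), "onset_hour", i, ae_path),
                resolution_day=_parse_opt_int(
                    row.get("resolution_day"), "resolution_day", i, ae_path
                ),
                resolved=_parse_bool(row.get("resolved"), "resolved", i, ae_path),
                severity_grade=_parse_int(
                    row.get("severity_grade") or 1, "severity_grade", i, ae_path
                ),
                serious=_parse_bool(row.get("serious"), "serious", i, ae_path),
                dose_action=DoseAction(row.get("dose_action") or "none"),
                anatomic_diagnosis=row.get("anatomic_diagnosis") or None,
                fatal=_parse_bool(row.get("fatal"), "fatal", i, ae_path),
                nonadjudicated_aoe=_parse_bool(
                    row.get("nonadjudicated_aoe"), "nonadjudicated_aoe", i, ae_path
                ),
            )
        )
    if dangling:
        raise StudyLoadError(
            f"adverse events reference unknown patient ids: {sorted(set(dangling))}"
        )

    evidence: dict = {}
    if evidence_path is not None and evidence_path.exists():
        with open(evidence_path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                key = obj.get("key")
                if key is None:
                    raise StudyLoadError(f"{evidence_path} line {i}: missing 'key'")
                evidence[key] = evidence_from_dict(obj)

    adverse_events.sort(key=lambda r: (r.patient_id, r.onset_day, r.record_id))
    ds = StudyDataset(
        patients=dict(sorted(patients.items())),
        adverse_events=adverse_events,
        evidence=evidence,
        provenance={"paths": {k: str(v) for k, v in paths.items()}, **config},
    )
    log.info(
        "loaded %d patients, %d AE records, %d evidence packages",
        len(ds.patients),
        len(ds.adverse_events),
        len(ds.evidence),
    )
    return ds


def write_study_tables(ds: StudyDataset, out_dir) -> dict:
    """Write the dataset back to the standard delimited layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "patients": out / "patients.csv",
        "adverse_events": out / "adverse_events.csv",
        "deaths": out / "deaths.csv",
        "evidence": out / "evidence.jsonl",
    }

    with open(paths["patients"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_COLUMNS)
        for p in ds.patients.values():
            w.writerow(
                [
                    p.patient_id,
                    p.cohort.value,
                    p.age_years,
                    p.sex.value,
                    ";".join(sorted(f.value for f in p.risk_factors)),
                    p.first_dose_day,
                    p.last_contact_day,
                ]
            )

    with open(paths["adverse_events"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(AE_COLUMNS)
        for r in ds.adverse_events:
            w.writerow(
                [
                    r.record_id,
                    r.patient_id,
                    r.preferred_term,
                    r.onset_day,
                    "" if r.onset_hour is None else r.onset_hour,
                    "" if r.resolution_day is None else r.resolution_day,
                    str(r.resolved).lower(),
                    r.severity_grade,
                    str(r.serious).lower(),
                    r.dose_action.value,
                    r.anatomic_diagnosis or "",
                    str(r.fatal).lower(),
                    str(r.nonadjudicated_aoe).lower(),
                ]
            )

    with open(paths["deaths"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(DEATH_COLUMNS)
        for p in ds.patients.values():
            d = p.death
            if d is None:
                continue
            w.writerow(
                [
                    p.patient_id,
                    d.death_day,
                    "" if d.witnessed is None else str(d.witnessed).lower(),
                    "" if d.last_seen_alive_hours_before is None else d.last_seen_alive_hours_before,
                    str(d.progression_attributed).lower(),
                    d.narrative_key or "",
                ]
            )

    with open(paths["evidence"], "w", encoding="utf-8") as fh:
        for key in sorted(ds.evidence):
            obj = {"key": key}
            obj.update(evidence_to_dict(ds.evidence[key]))
            fh.write(json.dumps(obj, sort_keys=True) + "\n")

    return {k: str(v) for k, v in paths.items()}


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    def add(self, where: str, message: str):
        self.violations.append((where, message))

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_study(ds: StudyDataset) -> ValidationReport:
    """Check dataset invariants; violations are reported, never raised."""
    report = ValidationReport()
    for p in ds.patients.values():
        if p.death is not None and p.death.death_day > p.last_contact_day + 1:
            report.add(p.patient_id, "death_day beyond last_contact_day + 1")
    seen = set()
    for r in ds.adverse_events:
        if r.record_id in seen:
            report.add(r.record_id, "duplicate record_id")
        seen.add(r.record_id)
        if r.patient_id not in ds.patients:
            report.add(r.record_id, f"dangling patient_id {r.patient_id!r}")
            continue
        p = ds.patients[r.patient_id]
        if r.onset_day < p.first_dose_day:
            report.add(r.record_id, "onset before first dose")
        if r.resolution_day is not None and r.resolution_day < r.onset_day:
            report.add(r.record_id, "resolution before onset")
        if r.fatal and not r.serious:
            report.add(r.record_id, "fatal record not marked serious")
        if r.fatal and p.death is None:
            report.add(r.record_id, "fatal record without death record")
    return report
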