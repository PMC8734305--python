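"""Preferred-term screening and case-package assembly.

Screening matches each adverse event's preferred term, after normalization,
against the packaged occlusive-event list (604 terms) unioned with the
cardiac-failure list.  Matching is exact on normalized strings — no
substring or fuzzy matching.  Deaths not attributed to disease progression
are pulled separately for fatal review.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from .types import AdverseEventRecord, EvidencePackage, StudyDataset, UNKNOWN_EVIDENCE

log = logging.getLogger("aoekit.screening")

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Case-fold, collapse whitespace, straighten apostrophes and dashes."""
    t = unicodedata.normalize("NFKC", term)
    t = t.replace("’", "'").replace("‘", "'")
    t = t.replace("–", "-").replace("—", "-").replace("‐", "-")
    t = _WS.sub(" ", t).strip()
    return t.casefold()


@dataclass(frozen=True)
class TermList:
    name: str
    terms: frozenset
    source_version: str = "MedDRA 21.0"

    def __post_init__(self):
        if not self.terms:
            raise ValueError(f"term list {self.name!r} is empty")

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def union(self, other: "TermList") -> "TermList":
        return TermList(
            name=f"{self.name}+{other.name}",
            terms=self.terms | other.terms,
            source_version=self.source_version,
        )


def load_term_list(path, name: Optional[str] = None) -> TermList:
    """Load a one-term-per-line list; ``#`` starts a comment."""
    path = Path(path)
    raw = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            raw.append(line)
    if not raw:
        raise ValueError(f"{path}: term list is empty")
    normalized = [normalize_term(t) for t in raw]
    seen, collisions = set(), []
    for t in normalized:
        if t in seen:
            collisions.append(t)
        seen.add(t)
    if collisions:
        log.warning("%s: duplicate terms after normalization: %s", path, sorted(set(collisions)))
    tl = TermList(name=name or path.stem, terms=frozenset(normalized))
    log.info("loaded %d terms from %s", len(tl), path)
    return tl


def _packaged(filename: str) -> TermList:
    with resources.as_file(resources.files("aoekit.data") / filename) as p:
        return load_term_list(p)


def packaged_aoe_terms() -> TermList:
    return _packaged("aoe_terms_604.txt")


def packaged_cardiac_failure_terms() -> TermList:
    return _packaged("cardiac_failure_terms.txt")


def packaged_symptom_terms() -> TermList:
    return _packaged("symptom_terms.txt")


@dataclass(frozen=True)
class ScreenResult:
    flagged_records: frozenset
    flagged_patients: frozenset
    fatal_review_records: frozenset
    totals: dict = field(default_factory=dict)


def screen_adverse_events(
    ds: StudyDataset,
    aoe_terms: TermList,
    cardiac_failure_terms: Optional[TermList] = None,
) -> ScreenResult:
    """Flag AE records whose normalized PT is in the combined term set."""
    combined = aoe_terms.terms
    if cardiac_failure_terms is not None:
        combined = combined | cardiac_failure_terms.terms
    flagged = frozenset(
        r.record_id for r in ds.adverse_events if normalize_term(r.preferred_term) in combined
    )
    patients = frozenset(
        r.patient_id for r in ds.adverse_events if r.record_id in flagged
    )
    fatal_review = screen_deaths(ds)
    result = ScreenResult(
        flagged_records=flagged,
        flagged_patients=patients,
        fatal_review_records=frozenset(fatal_review),
        totals={
            "records_screened": len(ds.adverse_events),
            "records_flagged": len(flagged),
            "patients_flagged": len(patients),
            "fatal_review_records": len(fatal_review),
        },
    )
    log.info("screen: %s", result.totals)
    return result


def screen_deaths(ds: StudyDataset) -> set:
    """Fatal AE records of deaths not attributed to disease progression."""
    out = set()
    for r in ds.adverse_events:
        if not r.fatal:
            continue
        death = ds.patients[r.patient_id].death
        if death is not None and not death.progression_attributed:
            out.add(r.record_id)
    return out


@dataclass(frozen=True)
class CasePackage:
    """One flagged or fatal-review record plus its clinical evidence."""

    record: AdverseEventRecord
    evidence: EvidencePackage
    evidence_known: bool
    fatal_review: bool
    medical_history: tuple = ()  # patient risk factors, as strings


def assemble_case_packages(screen: ScreenResult, ds: StudyDataset) -> list:
    """One package per flagged or fatal-review record, deduplicated by id."""
    wanted = sorted(screen.flagged_records | screen.fatal_review_records)
    packages = []
    missing = 0
    for rid in wanted:
        rec = ds.record(rid)
        ev = ds.evidence.get(rid)
        death_key = f"death:{rec.patient_id}"
        if ev is None and rec.fatal and death_key in ds.evidence:
            ev = ds.evidence[death_key]
        known = ev is not None
        if not known:
            missing += 1
            ev = UNKNOWN_EVIDENCE
        packages.append(
            CasePackage(
                record=rec,
                evidence=ev,
                evidence_known=known,
                fatal_review=rid in screen.fatal_review_records,
                medical_history=tuple(
                    sorted(f.value for f in ds.patients[rec.patient_id].risk_factors)
                ),
            )
        )
    if missing:
        log.warning("%d case packages assembled with all-unknown evidence", missing)
    log.info(
        "assembled %d case packages for %d patients",
        len(packages),
        len({p.record.patient_id for p in packages}),
    )
    return packages
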