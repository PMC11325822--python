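"""Seven-module record structures, bundle validation, and cohort selection.

Records are plain frozen dataclasses; invariant checking lives in
:func:`validate_bundle`, which reports violations as data rather than raising,
so that dirty inputs can be inspected instead of aborting the pipeline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, replace
from datetime import date
from typing import Iterator

from .catalogs import HPO_RE, ICD10GM_RE, CatalogBundle, CohortCriteria, match_icd10

__all__ = [
    "PersonRec", "VisitRec", "DiagnosisRec", "ProcedureRec", "LabRec",
    "MedicationRec", "PhenotypeRec", "GenotypeRec", "RDCDMBundle",
    "Violation", "ValidationReport", "validate_bundle", "select_cohort",
    "age_in_completed_years", "pseudonymize_id",
]

GENDERS = ("female", "male", "other", "unknown")
VISIT_KINDS = ("inpatient_full", "inpatient_partial")
GENOTYPE_STATUS = ("positive", "negative", "unknown")


@dataclass(frozen=True, order=True)
class PersonRec:
    person_id: str
    gender: str
    birth_date: date
    age_at_diagnosis: int
    postal_code: str
    race: str | None = None
    ethnicity: str | None = None


@dataclass(frozen=True, order=True)
class VisitRec:
    visit_id: str
    person_id: str
    admission_date: date
    discharge_date: date
    visit_kind: str


@dataclass(frozen=True, order=True)
class DiagnosisRec:
    person_id: str
    visit_id: str
    icd10gm_code: str
    diagnosis_date: date
    orpha_code: str | None = None


@dataclass(frozen=True, order=True)
class ProcedureRec:
    person_id: str
    visit_id: str
    ops_code: str
    procedure_date: date


@dataclass(frozen=True, order=True)
class LabRec:
    person_id: str
    visit_id: str
    loinc_code: str
    value: float
    ucum_unit: str
    measured_at: date


@dataclass(frozen=True, order=True)
class MedicationRec:
    person_id: str
    visit_id: str
    start_date: date
    atc_code: str | None = None
    rxnorm_code: str | None = None


@dataclass(frozen=True, order=True)
class PhenotypeRec:
    person_id: str
    visit_id: str
    hpo_code: str
    observed: bool
    noted_at: date


@dataclass(frozen=True, order=True)
class GenotypeRec:
    person_id: str
    visit_id: str
    feature_name: str
    value: str | float  # "positive"/"negative"/"unknown" or a decimal
    assayed_at: date


@dataclass(frozen=True)
class RDCDMBundle:
    """One cohort's records across the seven RD-CDM modules."""

    persons: tuple[PersonRec, ...] = ()
    visits: tuple[VisitRec, ...] = ()
    diagnoses: tuple[DiagnosisRec, ...] = ()
    procedures: tuple[ProcedureRec, ...] = ()
    labs: tuple[LabRec, ...] = ()
    medications: tuple[MedicationRec, ...] = ()
    phenotypes: tuple[PhenotypeRec, ...] = ()
    genotypes: tuple[GenotypeRec, ...] = ()
    domain: str = ""
    site: str = ""
    seed: int | None = None

    def canonical(self) -> "RDCDMBundle":
        """Copy with every module sorted into the deterministic on-disk order."""
        return replace(
            self,
            persons=tuple(sorted(self.persons)),
            visits=tuple(sorted(self.visits)),
            diagnoses=tuple(sorted(self.diagnoses)),
            procedures=tuple(sorted(self.procedures)),
            labs=tuple(sorted(self.labs)),
            medications=tuple(sorted(self.medications)),
            phenotypes=tuple(sorted(self.phenotypes)),
            genotypes=tuple(sorted(self.genotypes)),
        )

    def n_records(self) -> int:
        return (len(self.persons) + len(self.visits) + len(self.diagnoses)
                + len(self.procedures) + len(self.labs) + len(self.medications)
                + len(self.phenotypes) + len(self.genotypes))


@dataclass(frozen=True)
class Violation:
    locator: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, locator: str, rule: str, message: str) -> None:
        self.violations.append(Violation(locator, rule, message))


def _event_records(bundle: RDCDMBundle) -> Iterator[tuple[str, int, object]]:
    for module, records in (
        ("diagnosis", bundle.diagnoses), ("procedure", bundle.procedures),
        ("laboratory", bundle.labs), ("medication", bundle.medications),
        ("phenotype", bundle.phenotypes), ("genotype", bundle.genotypes),
    ):
        for i, rec in enumerate(records):
            yield module, i, rec


def validate_bundle(bundle: RDCDMBundle) -> ValidationReport:
    """Check every per-type invariant plus referential closure.

    Violations are returned as data; the bundle is never modified.
    """
    report = ValidationReport()
    person_ids: set[str] = set()
    for i, p in enumerate(bundle.persons):
        loc = f"person[{i}]:{p.person_id}"
        if p.person_id in person_ids:
            report.add(loc, "DUP_PERSON", f"duplicate person_id {p.person_id!r}")
        person_ids.add(p.person_id)
        if p.gender not in GENDERS:
            report.add(loc, "GENDER_ENUM", f"unknown gender {p.gender!r}")
        if p.age_at_diagnosis < 0:
            report.add(loc, "AGE_NEGATIVE", "age_at_diagnosis < 0")

    visit_ids: set[str] = set()
    visit_person: dict[str, str] = {}
    for i, v in enumerate(bundle.visits):
        loc = f"visit[{i}]:{v.visit_id}"
        if v.visit_id in visit_ids:
            report.add(loc, "DUP_VISIT", f"duplicate visit_id {v.visit_id!r}")
        visit_ids.add(v.visit_id)
        visit_person[v.visit_id] = v.person_id
        if v.person_id not in person_ids:
            report.add(loc, "FK_PERSON", f"person_id {v.person_id!r} not in bundle")
        if v.admission_date > v.discharge_date:
            report.add(loc, "DATE_ORDER", "discharge before admission")
        if v.visit_kind not in VISIT_KINDS:
            report.add(loc, "VISIT_KIND", f"unknown visit_kind {v.visit_kind!r}")

    for module, i, rec in _event_records(bundle):
        loc = f"{module}[{i}]"
        if rec.person_id not in person_ids:
            report.add(loc, "FK_PERSON", f"person_id {rec.person_id!r} not in bundle")
        if rec.visit_id not in visit_ids:
            report.add(loc, "FK_VISIT", f"visit_id {rec.visit_id!r} not in bundle")
        elif visit_person[rec.visit_id] != rec.person_id:
            report.add(loc, "FK_VISIT_PERSON",
                       "visit belongs to a different person")

    for i, d in enumerate(bundle.diagnoses):
        if not ICD10GM_RE.match(d.icd10gm_code):
            report.add(f"diagnosis[{i}]", "CODE_SYNTAX",
                       f"invalid ICD-10-GM code {d.icd10gm_code!r}")
    for i, ph in enumerate(bundle.phenotypes):
        if not HPO_RE.match(ph.hpo_code):
            report.add(f"phenotype[{i}]", "CODE_SYNTAX",
                       f"invalid HPO code {ph.hpo_code!r}")
    for i, lab in enumerate(bundle.labs):
        if lab.value is not None and not lab.ucum_unit:
            report.add(f"laboratory[{i}]", "UNIT_MISSING",
                       "ucum_unit empty with value present")
    for i, m in enumerate(bundle.medications):
        if m.atc_code is None and m.rxnorm_code is None:
            report.add(f"medication[{i}]", "MED_CODE_MISSING",
                       "neither atc_code nor rxnorm_code present")
    return report


def age_in_completed_years(birth: date, on: date) -> int:
    """Age in completed calendar years (floor) at a reference date."""
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def select_cohort(bundle: RDCDMBundle, criteria: CohortCriteria,
                  catalog: CatalogBundle | None = None) -> RDCDMBundle:
    """Apply the inclusion criteria and drop ineligible persons with all their records.

    A person is retained iff they have at least one visit whose admission and
    discharge both fall inside the criteria window and at which they are at
    least ``min_age_years`` old (completed years), and at least one diagnosis
    matching one of the criteria's ICD-10-GM patterns.
    """
    persons_by_id = {p.person_id: p for p in bundle.persons}
    eligible_visit_persons: set[str] = set()
    for v in bundle.visits:
        person = persons_by_id.get(v.person_id)
        if person is None:
            continue
        in_window = (criteria.window_start <= v.admission_date
                     and v.discharge_date <= criteria.window_end)
        old_enough = (age_in_completed_years(person.birth_date, v.admission_date)
                      >= criteria.min_age_years)
        if in_window and old_enough:
            eligible_visit_persons.add(v.person_id)

    diagnosed: set[str] = set()
    for d in bundle.diagnoses:
        if any(match_icd10(pat, d.icd10gm_code) for pat in criteria.icd10_patterns):
            diagnosed.add(d.person_id)

    keep = eligible_visit_persons & diagnosed
    kept_visits = tuple(v for v in bundle.visits if v.person_id in keep)
    kept_visit_ids = {v.visit_id for v in kept_visits}

    def _filter(records):
        return tuple(r for r in records
                     if r.person_id in keep and r.visit_id in kept_visit_ids)

    return replace(
        bundle,
        persons=tuple(p for p in bundle.persons if p.person_id in keep),
        visits=kept_visits,
        diagnoses=_filter(bundle.diagnoses),
        procedures=_filter(bundle.procedures),
        labs=_filter(bundle.labs),
        medications=_filter(bundle.medications),
        phenotypes=_filter(bundle.phenotypes),
        genotypes=_filter(bundle.genotypes),
    )


def pseudonymize_id(value: str, salt: str) -> str:
    """Salted stable pseudonym for external person/visit identifiers."""
    digest = hashlib.sha256(f"{salt}:{value}".encode("utf-8")).hexdigest()
    return digest[:16]
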