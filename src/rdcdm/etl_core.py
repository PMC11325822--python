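"""Direct ETL of the core RD-CDM modules (Person, Case, Diagnosis, Procedure,
Laboratory findings, Medications) into the OMOP store.

Concept resolution uses the bundled exact-match mini-map; any code it does not
know loads with concept_id 0 and the original code preserved in the
``*_source_value`` column (OHDSI convention).  Persons and visits must be
loaded before any clinical event to keep referential integrity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .catalogs import CatalogBundle
from .errors import EtlOrderingError, StoreIntegrityError
from .model import RDCDMBundle
from .omop import OMOPStore

__all__ = ["ETLReport", "EtlEntry", "transform_persons_visits",
           "transform_clinical_events", "run_core_etl"]


@dataclass(frozen=True)
class EtlEntry:
    locator: str
    source_value: str
    target_table: str
    concept_id: int
    status: str  # mapped | unmapped


@dataclass
class ETLReport:
    entries: list[EtlEntry] = field(default_factory=list)

    def add(self, locator: str, source_value: str, target_table: str,
            concept_id: int, status: str) -> None:
        self.entries.append(EtlEntry(locator, source_value, target_table,
                                     concept_id, status))

    def counts(self) -> dict[str, int]:
        out = {"rows_in": len(self.entries), "mapped": 0, "unmapped": 0}
        for e in self.entries:
            out[e.status] = out.get(e.status, 0) + 1
        return out

    def merge(self, other: "ETLReport") -> None:
        self.entries.extend(other.entries)

    def export(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(("locator", "source_value", "target_table",
                             "concept_id", "status"))
            for e in self.entries:
                writer.writerow((e.locator, e.source_value, e.target_table,
                                 e.concept_id, e.status))
        return path


def _id_maps(store: OMOPStore) -> tuple[dict[str, int], dict[str, int]]:
    persons = {str(r["person_source_value"]): int(r["person_id"])
               for r in store.fetch_rows("person")}
    visits = {str(r["visit_source_value"]): int(r["visit_occurrence_id"])
              for r in store.fetch_rows("visit_occurrence")}
    return persons, visits


def transform_persons_visits(bundle: RDCDMBundle, store: OMOPStore,
                             catalog: CatalogBundle) -> ETLReport:
    """Load one OMOP person row per PersonRec and one visit row per VisitRec.

    Integer surrogate keys are assigned in sorted source-id order so that the
    load is deterministic.  Duplicate source persons against the store raise.
    """
    report = ETLReport()
    existing, _ = _id_maps(store)
    dup = [p.person_id for p in bundle.persons if p.person_id in existing]
    if dup:
        raise StoreIntegrityError(f"persons already loaded: {dup[:5]}")

    next_pid = store.next_id("person")
    person_rows = []
    pid_of: dict[str, int] = {}
    for p in sorted(bundle.persons):
        gender = catalog.minimap_concept(p.gender, "Gender")
        gender_cid = gender.concept_id if gender else 0
        pid_of[p.person_id] = next_pid
        person_rows.append({
            "person_id": next_pid,
            "gender_concept_id": gender_cid,
            "year_of_birth": p.birth_date.year,
            "month_of_birth": p.birth_date.month,
            "day_of_birth": p.birth_date.day,
            "race_concept_id": 0,
            "ethnicity_concept_id": 0,
            "person_source_value": p.person_id,
            "gender_source_value": p.gender,
            "race_source_value": p.race,
            "ethnicity_source_value": p.ethnicity,
        })
        report.add(f"person:{p.person_id}", p.gender, "person", gender_cid,
                   "mapped" if gender_cid else "unmapped")
        next_pid += 1
    store.insert_rows("person", person_rows)

    next_vid = store.next_id("visit_occurrence")
    visit_rows = []
    for v in sorted(bundle.visits):
        visit_concept = catalog.minimap_concept(v.visit_kind, "Visit")
        vcid = visit_concept.concept_id if visit_concept else 0
        visit_rows.append({
            "visit_occurrence_id": next_vid,
            "person_id": pid_of[v.person_id],
            "visit_concept_id": vcid,
            "visit_start_date": v.admission_date.isoformat(),
            "visit_end_date": v.discharge_date.isoformat(),
            "visit_source_value": v.visit_id,
        })
        report.add(f"visit:{v.visit_id}", v.visit_kind, "visit_occurrence",
                   vcid, "mapped" if vcid else "unmapped")
        next_vid += 1
    store.insert_rows("visit_occurrence", visit_rows)
    return report


def transform_clinical_events(bundle: RDCDMBundle, catalog: CatalogBundle,
                              store: OMOPStore) -> ETLReport:
    """Route Diagnosis/Procedure/Laboratory/Medication records into OMOP.

    Raises :class:`EtlOrderingError` when a record references a person or visit
    that has not been loaded yet (i.e. the core person/visit stage was skipped).
    """
    pid_of, vid_of = _id_maps(store)

    def _resolve(rec, module: str, idx: int) -> tuple[int, int]:
        if rec.person_id not in pid_of or rec.visit_id not in vid_of:
            raise EtlOrderingError(
                f"{module}[{idx}] references unloaded person/visit "
                f"({rec.person_id}, {rec.visit_id}); run the person/visit "
                "stage first to guarantee referential integrity")
        return pid_of[rec.person_id], vid_of[rec.visit_id]

    report = ETLReport()
    cond_rows, proc_rows, meas_rows, drug_rows = [], [], [], []

    next_cond = store.next_id("condition_occurrence")
    for i, d in enumerate(sorted(bundle.diagnoses)):
        pid, vid = _resolve(d, "diagnosis", i)
        concept = catalog.minimap_concept(d.icd10gm_code, "ICD10GM")
        cid = concept.concept_id if concept else 0
        cond_rows.append({
            "condition_occurrence_id": next_cond,
            "person_id": pid, "visit_occurrence_id": vid,
            "condition_concept_id": cid,
            "condition_start_date": d.diagnosis_date.isoformat(),
            "condition_source_value": d.icd10gm_code,
        })
        report.add(f"diagnosis[{i}]", d.icd10gm_code, "condition_occurrence",
                   cid, "mapped" if cid else "unmapped")
        next_cond += 1

    next_proc = store.next_id("procedure_occurrence")
    for i, p in enumerate(sorted(bundle.procedures)):
        pid, vid = _resolve(p, "procedure", i)
        concept = catalog.minimap_concept(p.ops_code, "OPS")
        cid = concept.concept_id if concept else 0
        proc_rows.append({
            "procedure_occurrence_id": next_proc,
            "person_id": pid, "visit_occurrence_id": vid,
            "procedure_concept_id": cid,
            "procedure_date": p.procedure_date.isoformat(),
            "procedure_source_value": p.ops_code,
        })
        report.add(f"procedure[{i}]", p.ops_code, "procedure_occurrence",
                   cid, "mapped" if cid else "unmapped")
        next_proc += 1

    next_meas = store.next_id("measurement")
    for i, lab in enumerate(sorted(bundle.labs)):
        pid, vid = _resolve(lab, "laboratory", i)
        concept = catalog.minimap_concept(lab.loinc_code, "LOINC")
        cid = concept.concept_id if concept else 0
        meas_rows.append({
            "measurement_id": next_meas,
            "person_id": pid, "visit_occurrence_id": vid,
            "measurement_concept_id": cid,
            "measurement_date": lab.measured_at.isoformat(),
            "value_as_number": lab.value,
            "unit_source_value": lab.ucum_unit,
            "measurement_source_value": lab.loinc_code,
        })
        report.add(f"laboratory[{i}]", lab.loinc_code, "measurement",
                   cid, "mapped" if cid else "unmapped")
        next_meas += 1

    next_drug = store.next_id("drug_exposure")
    for i, m in enumerate(sorted(bundle.medications)):
        pid, vid = _resolve(m, "medication", i)
        code = m.atc_code or m.rxnorm_code or ""
        vocab = "ATC" if m.atc_code else "RxNorm"
        concept = catalog.minimap_concept(code, vocab)
        cid = concept.concept_id if concept else 0
        drug_rows.append({
            "drug_exposure_id": next_drug,
            "person_id": pid, "visit_occurrence_id": vid,
            "drug_concept_id": cid,
            "drug_exposure_start_date": m.start_date.isoformat(),
            "drug_source_value": code,
        })
        report.add(f"medication[{i}]", code, "drug_exposure",
                   cid, "mapped" if cid else "unmapped")
        next_drug += 1

    store.insert_rows("condition_occurrence", cond_rows)
    store.insert_rows("procedure_occurrence", proc_rows)
    store.insert_rows("measurement", meas_rows)
    store.insert_rows("drug_exposure", drug_rows)
    return report


def run_core_etl(bundle: RDCDMBundle, catalog: CatalogBundle,
                 store: OMOPStore) -> ETLReport:
    """Persons/visits first, then clinical events (the within-route ordering)."""
    report = transform_persons_visits(bundle, store, catalog)
    report.merge(transform_clinical_events(bundle, catalog, store))
    return report
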