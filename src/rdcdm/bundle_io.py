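"""Delimited-file layout for RD-CDM bundles: one UTF-8 CSV per module.

Writing is deterministic: rows are sorted by their natural key order, dates are
ISO-8601, and identical bundles produce byte-identical files.
"""

from __future__ import annotations

import csv
from dataclasses import replace
from datetime import date
from pathlib import Path

from .errors import BundleParseError
from .model import (
    DiagnosisRec, GenotypeRec, LabRec, MedicationRec, PersonRec, PhenotypeRec,
    ProcedureRec, RDCDMBundle, VisitRec, GENOTYPE_STATUS,
)

__all__ = ["read_bundle", "write_bundle", "MODULE_FILES"]

MODULE_FILES = {
    "person": ("person.csv",
               ("person_id", "gender", "birth_date", "age_at_diagnosis",
                "postal_code", "race", "ethnicity")),
    "visit": ("visit.csv",
              ("visit_id", "person_id", "admission_date", "discharge_date",
               "visit_kind")),
    "diagnosis": ("diagnosis.csv",
                  ("person_id", "visit_id", "icd10gm_code", "orpha_code",
                   "diagnosis_date")),
    "procedure": ("procedure.csv",
                  ("person_id", "visit_id", "ops_code", "procedure_date")),
    "laboratory": ("laboratory.csv",
                   ("person_id", "visit_id", "loinc_code", "value", "ucum_unit",
                    "measured_at")),
    "medication": ("medication.csv",
                   ("person_id", "visit_id", "atc_code", "rxnorm_code",
                    "start_date")),
    "phenotype": ("phenotype.csv",
                  ("person_id", "visit_id", "hpo_code", "observed", "noted_at")),
    "genotype": ("genotype.csv",
                 ("person_id", "visit_id", "feature_name", "value", "assayed_at")),
}

_META_FILE = "bundle_meta.csv"


def _opt(value: str) -> str | None:
    return value if value != "" else None


def _genotype_value(raw: str) -> str | float:
    return raw if raw in GENOTYPE_STATUS else float(raw)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, date):
        return value.isoformat()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_bundle(bundle: RDCDMBundle, directory: str | Path) -> list[Path]:
    """Serialize a bundle to its directory layout; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    canon = bundle.canonical()
    written: list[Path] = []

    def _dump(filename: str, columns: tuple[str, ...], records) -> None:
        path = directory / filename
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(columns)
            for rec in records:
                writer.writerow([_fmt(getattr(rec, c)) for c in columns])
        written.append(path)

    _dump(*MODULE_FILES["person"], canon.persons)
    _dump(*MODULE_FILES["visit"], canon.visits)
    _dump(*MODULE_FILES["diagnosis"], canon.diagnoses)
    _dump(*MODULE_FILES["procedure"], canon.procedures)
    _dump(*MODULE_FILES["laboratory"], canon.labs)
    _dump(*MODULE_FILES["medication"], canon.medications)
    _dump(*MODULE_FILES["phenotype"], canon.phenotypes)
    _dump(*MODULE_FILES["genotype"], canon.genotypes)

    meta = directory / _META_FILE
    with open(meta, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(("domain", "site", "seed"))
        writer.writerow((canon.domain, canon.site,
                         "" if canon.seed is None else canon.seed))
    written.append(meta)
    return written


def _load_rows(directory: Path, filename: str,
               columns: tuple[str, ...]) -> list[dict[str, str]]:
    path = directory / filename
    if not path.is_file():
        raise BundleParseError(f"missing module file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = tuple(reader.fieldnames or ())
        if header != columns:
            extra = set(header) - set(columns)
            missing = set(columns) - set(header)
            raise BundleParseError(
                f"{filename}: schema drift (extra columns {sorted(extra)}, "
                f"missing columns {sorted(missing)})")
        return list(reader)


def read_bundle(directory: str | Path) -> RDCDMBundle:
    """Parse a bundle directory; all eight module files must be present."""
    directory = Path(directory)

    persons = tuple(
        PersonRec(
            person_id=r["person_id"], gender=r["gender"],
            birth_date=date.fromisoformat(r["birth_date"]),
            age_at_diagnosis=int(r["age_at_diagnosis"]),
            postal_code=r["postal_code"],
            race=_opt(r["race"]), ethnicity=_opt(r["ethnicity"]))
        for r in _load_rows(directory, *MODULE_FILES["person"]))
    visits = tuple(
        VisitRec(
            visit_id=r["visit_id"], person_id=r["person_id"],
            admission_date=date.fromisoformat(r["admission_date"]),
            discharge_date=date.fromisoformat(r["discharge_date"]),
            visit_kind=r["visit_kind"])
        for r in _load_rows(directory, *MODULE_FILES["visit"]))
    diagnoses = tuple(
        DiagnosisRec(
            person_id=r["person_id"], visit_id=r["visit_id"],
            icd10gm_code=r["icd10gm_code"], orpha_code=_opt(r["orpha_code"]),
            diagnosis_date=date.fromisoformat(r["diagnosis_date"]))
        for r in _load_rows(directory, *MODULE_FILES["diagnosis"]))
    procedures = tuple(
        ProcedureRec(
            person_id=r["person_id"], visit_id=r["visit_id"],
            ops_code=r["ops_code"],
            procedure_date=date.fromisoformat(r["procedure_date"]))
        for r in _load_rows(directory, *MODULE_FILES["procedure"]))
    labs = tuple(
        LabRec(
            person_id=r["person_id"], visit_id=r["visit_id"],
            loinc_code=r["loinc_code"], value=float(r["value"]),
            ucum_unit=r["ucum_unit"],
            measured_at=date.fromisoformat(r["measured_at"]))
        for r in _load_rows(directory, *MODULE_FILES["laboratory"]))
    medications = tuple(
        MedicationRec(
            person_id=r["person_id"], visit_id=r["visit_id"],
            atc_code=_opt(r["atc_code"]), rxnorm_code=_opt(r["rxnorm_code"]),
            start_date=date.fromisoformat(r["start_date"]))
        for r in _load_rows(directory, *MODULE_FILES["medication"]))
    phenotypes = tuple(
        PhenotypeRec(
            person_id=r["person_id"], visit_id=r["visit_id"],
            hpo_code=r["hpo_code"], observed=r["observed"] == "true",
            noted_at=date.fromisoformat(r["noted_at"]))
        for r in _load_rows(directory, *MODULE_FILES["phenotype"]))
    genotypes = tuple(
        GenotypeRec(
            person_id=r["person_id"], visit_id=r["visit_id"],
            feature_name=r["feature_name"], value=_genotype_value(r["value"]),
            assayed_at=date.fromisoformat(r["assayed_at"]))
        for r in _load_rows(directory, *MODULE_FILES["genotype"]))

    bundle = RDCDMBundle(
        persons=persons, visits=visits, diagnoses=diagnoses,
        procedures=procedures, labs=labs, medications=medications,
        phenotypes=phenotypes, genotypes=genotypes)

    meta_path = directory / _META_FILE
    if meta_path.is_file():
        with open(meta_path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        if rows:
            seed = rows[0].get("seed") or None
            bundle = replace(
                bundle, domain=rows[0].get("domain", ""),
                site=rows[0].get("site", ""),
                seed=int(seed) if seed is not None else None)
    return bundle
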