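"""Genotype/Phenotype-to-OMOP ETL.

HPO is not available as a standard OMOP vocabulary, so the distinct HPO codes
of the input are first registered in SOURCE_TO_CONCEPT_MAP as individual source
codes with placeholder target concept ids (>= 2e9 local range).  Phenotype
records then become observation rows and genotype records become rows in the
concept map's target table (measurement by default).  Both transforms require
the core ETL to have loaded persons and visits first; violating that ordering
aborts before anything is written.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalogs import HPO_RE, CatalogBundle
from .errors import EtlOrderingError
from .model import GENOTYPE_STATUS, GenotypeRec, PhenotypeRec, RDCDMBundle
from .omop import OMOPStore

__all__ = [
    "MappingReport", "MappingOutcome", "register_hpo_codes",
    "transform_phenotypes", "transform_genotypes", "run_genopheno_etl",
    "melt_wide_genotypes", "hpo_placeholder_concept_id",
]

#: placeholder target ids for registered HPO codes: base + numeric part
_HPO_PLACEHOLDER_BASE = 2_100_000_000


def hpo_placeholder_concept_id(hpo_code: str) -> int:
    """Deterministic local-range concept id for a registered HPO source code."""
    return _HPO_PLACEHOLDER_BASE + int(hpo_code.split(":", 1)[1])


@dataclass(frozen=True)
class MappingOutcome:
    locator: str
    source: str
    target_table: str
    target_concept_id: int
    status: str  # mapped | unmapped | rejected
    reason: str = ""


@dataclass
class MappingReport:
    """Per-record ETL outcome ledger; the success rate is computed from it."""

    outcomes: list[MappingOutcome] = field(default_factory=list)

    def add(self, locator: str, source: str, target_table: str,
            concept_id: int, status: str, reason: str = "") -> None:
        self.outcomes.append(MappingOutcome(locator, source, target_table,
                                            concept_id, status, reason))

    @property
    def mapped(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "mapped")

    @property
    def unmapped(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "unmapped")

    @property
    def rejected(self) -> int:
        return sum(1 for o in self.outcomes if o.status == "rejected")

    @property
    def records_in(self) -> int:
        return len(self.outcomes)

    @property
    def success_rate(self) -> float:
        """Percent mapped of (mapped + unmapped); 100.0 when vacuous.

        Rejected (syntactically invalid) records are excluded from the
        denominator: the rate measures mappability, not input hygiene.
        """
        denom = self.mapped + self.unmapped
        if denom == 0:
            return 100.0
        return 100.0 * self.mapped / denom

    def merge(self, other: "MappingReport") -> None:
        self.outcomes.extend(other.outcomes)

    def export(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(("locator", "source", "target_table",
                             "target_concept_id", "status", "reason"))
            for o in self.outcomes:
                writer.writerow((o.locator, o.source, o.target_table,
                                 o.target_concept_id, o.status, o.reason))
        return path


def _id_maps(store: OMOPStore) -> tuple[dict[str, int], dict[str, int]]:
    persons = {str(r["person_source_value"]): int(r["person_id"])
               for r in store.fetch_rows("person")}
    visits = {str(r["visit_source_value"]): int(r["visit_occurrence_id"])
              for r in store.fetch_rows("visit_occurrence")}
    return persons, visits


def _require_loaded(records, pid_of, vid_of, what: str) -> None:
    for rec in records:
        if rec.person_id not in pid_of or rec.visit_id not in vid_of:
            raise EtlOrderingError(
                f"{what} record references unloaded person/visit "
                f"({rec.person_id}, {rec.visit_id}); the core ETL must run "
                "before the genotype/phenotype ETL to guarantee referential "
                "integrity")


def register_hpo_codes(phenotypes: Iterable[PhenotypeRec | str],
                       store: OMOPStore) -> int:
    """Register each distinct syntactically valid HPO code once; idempotent.

    Returns the number of newly inserted SOURCE_TO_CONCEPT_MAP rows.
    """
    codes = sorted({
        (p if isinstance(p, str) else p.hpo_code)
        for p in phenotypes
        if HPO_RE.match(p if isinstance(p, str) else p.hpo_code)})
    existing = {str(r["source_code"]) for r in store.fetch_rows(
        "source_to_concept_map", "source_vocabulary_id = ?", ("HPO",))}
    rows = [{
        "source_code": code,
        "source_concept_id": 0,
        "source_vocabulary_id": "HPO",
        "source_code_description": code,
        "target_concept_id": hpo_placeholder_concept_id(code),
        "target_vocabulary_id": "None",
        "valid_start_date": "1970-01-01",
        "valid_end_date": "2099-12-31",
    } for code in codes if code not in existing]
    return store.insert_rows("source_to_concept_map", rows)


def transform_phenotypes(phenotypes: Sequence[PhenotypeRec],
                         catalog: CatalogBundle, store: OMOPStore,
                         use_placeholder_concepts: bool = True) -> MappingReport:
    """Map phenotype records to observation rows.

    A record is ``mapped`` when its HPO code exists in the bundled symptom
    catalog or in the store's SOURCE_TO_CONCEPT_MAP; malformed codes are
    ``rejected`` and produce no row.
    """
    pid_of, vid_of = _id_maps(store)
    report = MappingReport()
    valid = [p for p in phenotypes if HPO_RE.match(p.hpo_code)]
    _require_loaded(valid, pid_of, vid_of, "phenotype")

    catalog_codes = {s.hpo_code for s in catalog.symptoms}
    registered = {str(r["source_code"]): int(r["target_concept_id"])
                  for r in store.fetch_rows(
                      "source_to_concept_map", "source_vocabulary_id = ?", ("HPO",))}
    pos = catalog.minimap_concept("positive", "Meas Value")
    neg = catalog.minimap_concept("negative", "Meas Value")

    rows = []
    next_oid = store.next_id("observation")
    for i, p in enumerate(phenotypes):
        loc = f"phenotype[{i}]"
        if not HPO_RE.match(p.hpo_code):
            report.add(loc, p.hpo_code, "observation", 0, "rejected",
                       "malformed HPO code")
            continue
        known = p.hpo_code in catalog_codes or p.hpo_code in registered
        concept_id = registered.get(p.hpo_code, 0) if use_placeholder_concepts else 0
        value_cid = (pos.concept_id if p.observed else neg.concept_id) \
            if pos and neg else None
        rows.append({
            "observation_id": next_oid,
            "person_id": pid_of[p.person_id],
            "visit_occurrence_id": vid_of[p.visit_id],
            "observation_concept_id": concept_id,
            "observation_date": p.noted_at.isoformat(),
            "value_as_concept_id": value_cid,
            "observation_source_value": p.hpo_code,
        })
        report.add(loc, p.hpo_code, "observation", concept_id,
                   "mapped" if known else "unmapped")
        next_oid += 1
    store.insert_rows("observation", rows)
    return report


def transform_genotypes(genotypes: Sequence[GenotypeRec],
                        catalog: CatalogBundle, store: OMOPStore,
                        emit_negative_rows: bool = True) -> MappingReport:
    """Map genotype records through the bundled concept map.

    Many-to-one mappings are allowed: each mapped input record yields its own
    output row even when concept ids coincide.  Feature names missing from the
    map are ``unmapped`` and produce no row; un-encodable values are
    ``rejected``.
    """
    pid_of, vid_of = _id_maps(store)
    report = MappingReport()
    _require_loaded(genotypes, pid_of, vid_of, "genotype")

    pos = catalog.minimap_concept("positive", "Meas Value")
    neg = catalog.minimap_concept("negative", "Meas Value")

    meas_rows, obs_rows = [], []
    next_mid = store.next_id("measurement")
    next_oid = store.next_id("observation")
    for i, g in enumerate(genotypes):
        loc = f"genotype[{i}]"
        row_def = catalog.genotype_row(g.feature_name)
        if row_def is None:
            report.add(loc, g.feature_name, "", 0, "unmapped",
                       "feature not in genotype concept map")
            continue
        value_as_number = None
        value_as_concept = None
        if isinstance(g.value, (int, float)) and not isinstance(g.value, bool):
            value_as_number = float(g.value)
        elif isinstance(g.value, str) and g.value in GENOTYPE_STATUS:
            if g.value == "negative" and not emit_negative_rows:
                report.add(loc, g.feature_name, row_def.target_table,
                           row_def.target_concept_id, "mapped",
                           "negative status suppressed by config")
                continue
            lut = {"positive": pos, "negative": neg}.get(g.value)
            value_as_concept = lut.concept_id if lut else 0
        else:
            report.add(loc, g.feature_name, row_def.target_table, 0, "rejected",
                       f"un-encodable value {g.value!r}")
            continue

        if row_def.target_table == "measurement":
            meas_rows.append({
                "measurement_id": next_mid,
                "person_id": pid_of[g.person_id],
                "visit_occurrence_id": vid_of[g.visit_id],
                "measurement_concept_id": row_def.target_concept_id,
                "measurement_date": g.assayed_at.isoformat(),
                "value_as_number": value_as_number,
                "value_as_concept_id": value_as_concept,
                "measurement_source_value": g.feature_name,
            })
            next_mid += 1
        else:
            obs_rows.append({
                "observation_id": next_oid,
                "person_id": pid_of[g.person_id],
                "visit_occurrence_id": vid_of[g.visit_id],
                "observation_concept_id": row_def.target_concept_id,
                "observation_date": g.assayed_at.isoformat(),
                "value_as_number": value_as_number,
                "value_as_concept_id": value_as_concept,
                "observation_source_value": g.feature_name,
            })
            next_oid += 1
        report.add(loc, g.feature_name, row_def.target_table,
                   row_def.target_concept_id, "mapped")
    store.insert_rows("measurement", meas_rows)
    store.insert_rows("observation", obs_rows)
    return report


def run_genopheno_etl(bundle: RDCDMBundle, catalog: CatalogBundle,
                      store: OMOPStore,
                      emit_negative_rows: bool = True) -> MappingReport:
    """Register HPO codes, then transform phenotypes and genotypes.

    The ordering precondition (core ETL already executed) is checked up front,
    before any write, so a violation leaves the store untouched.
    """
    pid_of, vid_of = _id_maps(store)
    valid_phenos = [p for p in bundle.phenotypes if HPO_RE.match(p.hpo_code)]
    _require_loaded(valid_phenos, pid_of, vid_of, "phenotype")
    _require_loaded(bundle.genotypes, pid_of, vid_of, "genotype")

    register_hpo_codes(bundle.phenotypes, store)
    report = transform_phenotypes(bundle.phenotypes, catalog, store)
    report.merge(transform_genotypes(bundle.genotypes, catalog, store,
                                     emit_negative_rows=emit_negative_rows))
    return report


def melt_wide_genotypes(path_or_frame: str | Path | pd.DataFrame,
                        assayed_at: date) -> list[GenotypeRec]:
    """Melt a wide per-patient feature file into genotype records.

    The file must carry ``person_id`` and ``visit_id`` identifier columns; every
    other column is treated as a feature.  Values equal to the status literals
    stay categorical; everything else is parsed as a decimal.  Empty cells are
    skipped.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        frame = path_or_frame
    else:
        frame = pd.read_csv(path_or_frame, dtype=str, keep_default_na=False)
    for col in ("person_id", "visit_id"):
        if col not in frame.columns:
            raise ValueError(f"wide genotype file lacks identifier column {col!r}")
    features = [c for c in frame.columns if c not in ("person_id", "visit_id")]
    records: list[GenotypeRec] = []
    for row in frame.itertuples(index=False):
        row_d = dict(zip(frame.columns, row))
        for feat in features:
            raw = str(row_d[feat])
            if raw == "":
                continue
            value: str | float
            value = raw if raw in GENOTYPE_STATUS else float(raw)
            records.append(GenotypeRec(
                person_id=str(row_d["person_id"]), visit_id=str(row_d["visit_id"]),
                feature_name=feat, value=value, assayed_at=assayed_at))
    return records
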