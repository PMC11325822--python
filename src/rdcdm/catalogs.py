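"""Bundled reference catalogs: diseases, symptoms, module routes, genotype concept map.

The catalogs ship as versioned delimited files under ``rdcdm/resources`` and are
loaded into an immutable :class:`CatalogBundle`.  Concept identifiers that have no
published standard id carry placeholder ids in the reserved local-concept range
(>= 2,000,000,000) and are flagged ``placeholder=True``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from datetime import date
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import CatalogValidationError, ConfigurationError

__all__ = [
    "DiseaseEntry",
    "SymptomEntry",
    "ModuleRoute",
    "GenotypeConceptMapRow",
    "CohortCriteria",
    "CatalogBundle",
    "default_resource_dir",
    "load_catalogs",
    "match_icd10",
    "shared_symptoms",
    "route_for_module",
]

ICD10GM_RE = re.compile(r"^[A-Z][0-9]{2}(\.([0-9A-Za-z]{1,2}|-))?$")
HPO_RE = re.compile(r"^HP:[0-9]{7}$")

DOMAINS = ("endocrinology", "gastroenterology", "pneumonology", "hematology")
RDCDM_MODULES = (
    "Person",
    "Diagnosis",
    "Procedure",
    "LaboratoryFindings",
    "Medication",
    "Genotype",
    "Phenotype",
)
OMOP_EVENT_TABLES = frozenset({
    "person",
    "visit_occurrence",
    "condition_occurrence",
    "procedure_occurrence",
    "measurement",
    "observation",
    "drug_exposure",
})

#: start of the OHDSI-convention local concept-id range used for placeholders
PLACEHOLDER_CONCEPT_START = 2_000_000_000


@dataclass(frozen=True)
class DiseaseEntry:
    domain: str
    disease_group: str
    disease_name: str
    icd10gm_code: str
    orpha_code: str | None = None

    @property
    def orpha_number(self) -> int | None:
        """Orpha code normalized to an integer (thousands separators stripped)."""
        if self.orpha_code is None:
            return None
        return int(self.orpha_code.split(":", 1)[1].replace(",", ""))


@dataclass(frozen=True)
class SymptomEntry:
    group: str
    symptom_name: str
    hpo_code: str
    disease_names: tuple[str, ...]


@dataclass(frozen=True)
class ModuleRoute:
    rdcdm_module: str
    omop_tables: tuple[str, ...]
    default_table: str
    vocabularies: tuple[str, ...]


@dataclass(frozen=True)
class GenotypeConceptMapRow:
    source_feature: str
    target_concept_id: int
    target_concept_name: str
    target_table: str
    vocabulary: str
    value_kind: str  # "binary" | "numeric"
    placeholder: bool


@dataclass(frozen=True)
class CohortCriteria:
    min_age_years: int
    window_start: date
    window_end: date
    icd10_patterns: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise ValueError("window_start must not be after window_end")
        if self.min_age_years < 0:
            raise ValueError("min_age_years must be >= 0")


@dataclass(frozen=True)
class ConceptMiniMapRow:
    source_code: str
    source_vocabulary: str
    concept_id: int
    concept_name: str
    placeholder: bool


@dataclass(frozen=True)
class DomainCodeRow:
    """Small per-domain LOINC/ATC/OPS code list used by the cohort generator."""

    domain: str
    kind: str
    code: str
    label: str
    unit: str | None


@dataclass(frozen=True)
class CatalogBundle:
    diseases: tuple[DiseaseEntry, ...]
    symptoms: tuple[SymptomEntry, ...]
    routes: tuple[ModuleRoute, ...]
    genotype_map: tuple[GenotypeConceptMapRow, ...]
    criteria: Mapping[str, CohortCriteria]
    reported_counts: Mapping[str, int]
    concept_minimap: tuple[ConceptMiniMapRow, ...]
    domain_codes: tuple[DomainCodeRow, ...]
    _genotype_by_feature: Mapping[str, GenotypeConceptMapRow] = field(
        default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_genotype_by_feature",
            {row.source_feature: row for row in self.genotype_map})

    # -- lookups -----------------------------------------------------------

    def genotype_row(self, feature: str) -> GenotypeConceptMapRow | None:
        return self._genotype_by_feature.get(feature)

    def symptom_groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.symptoms:
            seen.setdefault(s.group, None)
        return tuple(seen)

    def symptoms_in_group(self, group: str) -> tuple[SymptomEntry, ...]:
        out = tuple(s for s in self.symptoms if s.group == group)
        if not out:
            raise ValueError(f"unknown symptom group: {group!r}")
        return out

    def diseases_in_domain(self, domain: str) -> tuple[DiseaseEntry, ...]:
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain: {domain!r}")
        return tuple(d for d in self.diseases if d.domain == domain)

    def symptoms_for_disease(self, disease_name: str) -> tuple[SymptomEntry, ...]:
        return tuple(s for s in self.symptoms if disease_name in s.disease_names)

    def minimap_concept(self, source_code: str, vocabulary: str) -> ConceptMiniMapRow | None:
        for row in self.concept_minimap:
            if row.source_code == source_code and row.source_vocabulary == vocabulary:
                return row
        return None

    def domain_codes_of_kind(self, domain: str, kind: str) -> tuple[DomainCodeRow, ...]:
        return tuple(c for c in self.domain_codes if c.domain == domain and c.kind == kind)


# ---------------------------------------------------------------------------
# loading


def default_resource_dir() -> Path:
    return Path(str(importlib_resources.files("rdcdm") / "resources"))


def _read_rows(path: Path) -> list[dict[str, str]]:
    if not path.is_file():
        raise ConfigurationError(f"missing catalog file: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def _parse_diseases(path: Path) -> tuple[DiseaseEntry, ...]:
    entries: list[DiseaseEntry] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(_read_rows(path), start=2):
        code = row["icd10gm_code"]
        if not ICD10GM_RE.match(code):
            raise CatalogValidationError(
                f"malformed ICD-10-GM code {code!r}",
                file=path.name, row=i, field="icd10gm_code")
        orpha = row.get("orpha_code") or None
        if orpha is not None and not orpha.startswith("ORPHA:"):
            raise CatalogValidationError(
                f"malformed Orpha code {orpha!r}",
                file=path.name, row=i, field="orpha_code")
        key = (row["domain"], row["disease_name"], code)
        if key in seen:
            raise CatalogValidationError(
                f"duplicate disease entry {key}", file=path.name, row=i)
        seen.add(key)
        if row["domain"] not in DOMAINS:
            raise CatalogValidationError(
                f"unknown domain {row['domain']!r}",
                file=path.name, row=i, field="domain")
        entries.append(DiseaseEntry(
            domain=row["domain"],
            disease_group=row["disease_group"],
            disease_name=row["disease_name"],
            icd10gm_code=code,
            orpha_code=orpha,
        ))
    return tuple(entries)


def _parse_symptoms(path: Path) -> tuple[SymptomEntry, ...]:
    entries = []
    for i, row in enumerate(_read_rows(path), start=2):
        code = row["hpo_code"]
        if not HPO_RE.match(code):
            raise CatalogValidationError(
                f"malformed HPO code {code!r}",
                file=path.name, row=i, field="hpo_code")
        names = tuple(n for n in row["disease_names"].split(";") if n)
        if not names:
            raise CatalogValidationError(
                "empty disease_names", file=path.name, row=i, field="disease_names")
        entries.append(SymptomEntry(
            group=row["group"], symptom_name=row["symptom_name"],
            hpo_code=code, disease_names=names))
    return tuple(entries)


def _parse_routes(path: Path) -> tuple[ModuleRoute, ...]:
    entries = []
    seen_modules: set[str] = set()
    for i, row in enumerate(_read_rows(path), start=2):
        module = row["rdcdm_module"]
        if module not in RDCDM_MODULES:
            raise CatalogValidationError(
                f"unknown module {module!r}", file=path.name, row=i, field="rdcdm_module")
        if module in seen_modules:
            raise CatalogValidationError(
                f"duplicate route for {module}", file=path.name, row=i)
        seen_modules.add(module)
        tables = tuple(row["omop_tables"].split(";"))
        bad = [t for t in tables if t not in OMOP_EVENT_TABLES]
        if bad:
            raise CatalogValidationError(
                f"unknown OMOP tables {bad}", file=path.name, row=i, field="omop_tables")
        default = row["default_table"]
        if default not in tables:
            raise CatalogValidationError(
                f"default_table {default!r} not among omop_tables",
                file=path.name, row=i, field="default_table")
        entries.append(ModuleRoute(
            rdcdm_module=module, omop_tables=tables, default_table=default,
            vocabularies=tuple(row["vocabularies"].split(";"))))
    missing = set(RDCDM_MODULES) - seen_modules
    if missing:
        raise CatalogValidationError(f"routes missing for modules: {sorted(missing)}",
                                     file=path.name)
    return tuple(entries)


def _parse_genotype_map(path: Path) -> tuple[GenotypeConceptMapRow, ...]:
    entries = []
    seen: set[str] = set()
    for i, row in enumerate(_read_rows(path), start=2):
        feat = row["source_feature"]
        if feat in seen:
            raise CatalogValidationError(
                f"duplicate source_feature {feat!r}", file=path.name, row=i)
        seen.add(feat)
        cid = int(row["target_concept_id"])
        if cid <= 0:
            raise CatalogValidationError(
                f"non-positive concept id {cid}", file=path.name, row=i,
                field="target_concept_id")
        if row["target_table"] not in ("measurement", "observation"):
            raise CatalogValidationError(
                f"bad target_table {row['target_table']!r}", file=path.name, row=i,
                field="target_table")
        entries.append(GenotypeConceptMapRow(
            source_feature=feat,
            target_concept_id=cid,
            target_concept_name=row["target_concept_name"],
            target_table=row["target_table"],
            vocabulary=row["vocabulary"],
            value_kind=row["value_kind"],
            placeholder=row["placeholder"].lower() == "true",
        ))
    return tuple(entries)


def _parse_criteria(path: Path) -> tuple[dict[str, CohortCriteria], dict[str, int]]:
    criteria: dict[str, CohortCriteria] = {}
    counts: dict[str, int] = {}
    for i, row in enumerate(_read_rows(path), start=2):
        domain = row["domain"]
        patterns = tuple(row["icd10_patterns"].split(";"))
        for pat in patterns:
            if not ICD10GM_RE.match(pat):
                raise CatalogValidationError(
                    f"malformed ICD-10-GM pattern {pat!r}",
                    file=path.name, row=i, field="icd10_patterns")
        criteria[domain] = CohortCriteria(
            min_age_years=int(row["min_age_years"]),
            window_start=date.fromisoformat(row["window_start"]),
            window_end=date.fromisoformat(row["window_end"]),
            icd10_patterns=patterns,
        )
        counts[domain] = int(row["reported_n_patients"])
    return criteria, counts


def _parse_minimap(path: Path) -> tuple[ConceptMiniMapRow, ...]:
    return tuple(
        ConceptMiniMapRow(
            source_code=row["source_code"],
            source_vocabulary=row["source_vocabulary"],
            concept_id=int(row["concept_id"]),
            concept_name=row["concept_name"],
            placeholder=row["placeholder"].lower() == "true",
        )
        for row in _read_rows(path))


def _parse_domain_codes(path: Path) -> tuple[DomainCodeRow, ...]:
    return tuple(
        DomainCodeRow(
            domain=row["domain"], kind=row["kind"], code=row["code"],
            label=row["label"], unit=row["unit"] or None)
        for row in _read_rows(path))


def load_catalogs(resource_dir: str | Path | None = None) -> CatalogBundle:
    """Load and validate the bundled reference catalogs.

    Parameters
    ----------
    resource_dir
        Directory holding the catalog CSV files; defaults to the packaged data.

    Raises
    ------
    ConfigurationError
        If a catalog file is missing.
    CatalogValidationError
        If any row violates a type invariant; the error names file/row/field.
    """
    rdir = Path(resource_dir) if resource_dir is not None else default_resource_dir()
    criteria, counts = _parse_criteria(rdir / "cohort_criteria.csv")
    return CatalogBundle(
        diseases=_parse_diseases(rdir / "diseases.csv"),
        symptoms=_parse_symptoms(rdir / "symptoms.csv"),
        routes=_parse_routes(rdir / "module_routes.csv"),
        genotype_map=_parse_genotype_map(rdir / "genotype_concept_map.csv"),
        criteria=criteria,
        reported_counts=counts,
        concept_minimap=_parse_minimap(rdir / "concept_minimap.csv"),
        domain_codes=_parse_domain_codes(rdir / "domain_codes.csv"),
    )


# ---------------------------------------------------------------------------
# queries


def match_icd10(pattern: str, code: str) -> bool:
    """Match an ICD-10-GM code against a code or ``X99.-`` chapter wildcard.

    ``".-"`` means any subcode sharing the three-character stem, including the
    bare stem itself.
    """
    for arg, name in ((pattern, "pattern"), (code, "code")):
        if not ICD10GM_RE.match(arg):
            raise ValueError(f"syntactically invalid ICD-10-GM {name}: {arg!r}")
    if pattern.endswith(".-"):
        return code[:3] == pattern[:3]
    return code == pattern


def shared_symptoms(catalog: CatalogBundle, groups: Iterable[str]) -> set[str]:
    """Intersection of the HPO-code sets of the named symptom groups."""
    groups = list(groups)
    if not groups:
        raise ValueError("at least one group is required")
    known = set(catalog.symptom_groups())
    sets: list[set[str]] = []
    for g in groups:
        if g not in known:
            raise ValueError(f"unknown symptom group: {g!r}")
        sets.append({s.hpo_code for s in catalog.symptoms if s.group == g})
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def route_for_module(catalog: CatalogBundle, module: str) -> ModuleRoute:
    """Return the unique OMOP routing rule for an RD-CDM module."""
    if module not in RDCDM_MODULES:
        raise ValueError(f"unknown RD-CDM module: {module!r}")
    for route in catalog.routes:
        if route.rdcdm_module == module:
            return route
    raise ConfigurationError(f"no route loaded for module {module}")  # pragma: no cover
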