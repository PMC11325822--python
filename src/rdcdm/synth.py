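"""Seeded synthetic cohort generator.

Stands in for the two hospitals' source data: every emitted diagnosis code,
symptom, and genotype feature is drawn from the bundled catalogs, so a clean
cohort is fully mappable by construction.  A configurable dirty mode injects
unmapped features and malformed codes for negative-path testing.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import pandas as pd
import yaml

from .catalogs import DOMAINS, CatalogBundle, CohortCriteria
from .model import (
    DiagnosisRec, GenotypeRec, LabRec, MedicationRec, PersonRec, PhenotypeRec,
    ProcedureRec, RDCDMBundle, VisitRec,
)

__all__ = ["GeneratorConfig", "generate_domain_cohort", "generate_hematology"]

_RACES = ("white", "black or african american", "asian", "other")
_ETHNICITIES = ("not hispanic or latino", "hispanic or latino")


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable knobs for the generator, loadable from a YAML key/value file."""

    symptom_prob: float = 0.5
    dirty_fraction: float = 0.0
    mutation_prob: float = 0.15
    min_age_years: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


def _random_visit(rng: random.Random, criteria: CohortCriteria,
                  min_age: int) -> tuple[date, date, date]:
    """(birth, admission, discharge) satisfying window and age criteria."""
    span = (criteria.window_end - criteria.window_start).days - 30
    admission = criteria.window_start + timedelta(days=rng.randint(0, max(span, 0)))
    discharge = min(admission + timedelta(days=rng.randint(1, 21)),
                    criteria.window_end)
    # 366-day years guarantee >= `age` completed calendar years at admission
    age = rng.randint(min_age, 90)
    birth = admission - timedelta(days=age * 366 + rng.randint(0, 364))
    return birth, admission, discharge


def _dirty_hpo(rng: random.Random) -> str:
    return f"HP:{rng.randint(0, 9999)}"  # too few digits: malformed on purpose


def generate_domain_cohort(catalog: CatalogBundle, domain: str, n_patients: int,
                           seed: int, criteria: CohortCriteria | None = None,
                           config: GeneratorConfig | None = None,
                           site: str = "site-a") -> RDCDMBundle:
    """Generate a validated single-domain inpatient cohort.

    Every patient gets one eligible visit inside the criteria window, a
    diagnosis drawn from the domain's disease catalog (wildcard codes are
    refined to a concrete subcode), and symptoms sampled only from catalog
    entries linked to the assigned disease.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain: {domain!r}")
    if n_patients < 0:
        raise ValueError("n_patients must be >= 0")
    config = config or GeneratorConfig()
    criteria = criteria or catalog.criteria[domain]
    min_age = (config.min_age_years if config.min_age_years is not None
               else criteria.min_age_years)
    rng = random.Random(seed)

    diseases = catalog.diseases_in_domain(domain)
    loincs = catalog.domain_codes_of_kind(domain, "loinc")
    atcs = catalog.domain_codes_of_kind(domain, "atc")
    opss = catalog.domain_codes_of_kind(domain, "ops")
    binary_features = [g for g in catalog.genotype_map if g.value_kind == "binary"]

    persons, visits, diagnoses = [], [], []
    procedures, labs, medications, phenotypes, genotypes = [], [], [], [], []

    for i in range(n_patients):
        pid = f"{domain[:4].upper()}-{i:06d}"
        vid = f"{pid}-V1"
        birth, admission, discharge = _random_visit(rng, criteria, min_age)
        disease = rng.choice(diseases)
        code = disease.icd10gm_code
        if code.endswith(".-"):
            code = f"{code[:3]}.{rng.randint(0, 9)}"

        persons.append(PersonRec(
            person_id=pid, gender=rng.choice(("female", "male")),
            birth_date=birth,
            age_at_diagnosis=(admission - birth).days // 366,
            postal_code=f"{rng.randint(10000, 99999)}"))
        visits.append(VisitRec(
            visit_id=vid, person_id=pid, admission_date=admission,
            discharge_date=discharge,
            visit_kind=rng.choice(("inpatient_full", "inpatient_partial"))))
        diagnoses.append(DiagnosisRec(
            person_id=pid, visit_id=vid, icd10gm_code=code,
            orpha_code=disease.orpha_code, diagnosis_date=admission))

        for symptom in catalog.symptoms_for_disease(disease.disease_name):
            if rng.random() < config.symptom_prob:
                hpo = symptom.hpo_code
                if config.dirty_fraction and rng.random() < config.dirty_fraction:
                    hpo = _dirty_hpo(rng)
                phenotypes.append(PhenotypeRec(
                    person_id=pid, visit_id=vid, hpo_code=hpo,
                    observed=True, noted_at=admission))

        for lab in rng.sample(loincs, k=min(rng.randint(1, 3), len(loincs))):
            labs.append(LabRec(
                person_id=pid, visit_id=vid, loinc_code=lab.code,
                value=round(rng.uniform(0.1, 300.0), 2),
                ucum_unit=lab.unit or "1", measured_at=admission))
        for med in rng.sample(atcs, k=min(rng.randint(0, 2), len(atcs))):
            medications.append(MedicationRec(
                person_id=pid, visit_id=vid, atc_code=med.code,
                start_date=admission))
        for ops in rng.sample(opss, k=min(rng.randint(0, 2), len(opss))):
            procedures.append(ProcedureRec(
                person_id=pid, visit_id=vid, ops_code=ops.code,
                procedure_date=admission))

        if rng.random() < 0.3 and binary_features:
            for feat in rng.sample(binary_features,
                                   k=min(2, len(binary_features))):
                name = feat.source_feature
                if config.dirty_fraction and rng.random() < config.dirty_fraction:
                    name = f"UNMAPPED.{rng.randint(0, 999)}"
                genotypes.append(GenotypeRec(
                    person_id=pid, visit_id=vid, feature_name=name,
                    value=rng.choice(("positive", "negative")),
                    assayed_at=admission))

    return RDCDMBundle(
        persons=tuple(persons), visits=tuple(visits),
        diagnoses=tuple(diagnoses), procedures=tuple(procedures),
        labs=tuple(labs), medications=tuple(medications),
        phenotypes=tuple(phenotypes), genotypes=tuple(genotypes),
        domain=domain, site=site, seed=seed).canonical()


def generate_hematology(catalog: CatalogBundle, n_patients: int = 1674,
                        n_features: int = 124, seed: int = 0,
                        criteria: CohortCriteria | None = None,
                        config: GeneratorConfig | None = None,
                        site: str = "site-a",
                        ) -> tuple[RDCDMBundle, pd.DataFrame]:
    """AML-style cohort plus the wide per-patient feature file.

    The wide frame has ``person_id``/``visit_id`` identifier columns followed by
    exactly ``n_features`` feature columns, all pre-registered in the bundled
    genotype concept map; the first four are the CEBPA-derived features.  Every
    patient carries the C92.0 diagnosis and populated race/ethnicity.
    """
    if n_features < 5:
        raise ValueError("n_features must be >= 5 to cover the four CEBPA "
                         "features plus at least one more")
    available = [g.source_feature for g in catalog.genotype_map]
    if n_features > len(available):
        raise ValueError(
            f"n_features={n_features} exceeds the bundled concept map "
            f"({len(available)} features available): {available}")
    features = available[:n_features]
    by_feature = {g.source_feature: g for g in catalog.genotype_map}

    config = config or GeneratorConfig()
    criteria = criteria or catalog.criteria["hematology"]
    min_age = (config.min_age_years if config.min_age_years is not None
               else criteria.min_age_years)
    rng = random.Random(seed)

    aml = next(d for d in catalog.diseases_in_domain("hematology")
               if d.icd10gm_code == "C92.0")
    persons, visits, diagnoses, phenotypes, genotypes = [], [], [], [], []
    labs, medications, procedures = [], [], []
    loincs = catalog.domain_codes_of_kind("hematology", "loinc")
    atcs = catalog.domain_codes_of_kind("hematology", "atc")
    opss = catalog.domain_codes_of_kind("hematology", "ops")
    wide_rows: list[dict[str, object]] = []

    for i in range(n_patients):
        pid = f"HEMA-{i:06d}"
        vid = f"{pid}-V1"
        birth, admission, discharge = _random_visit(rng, criteria, min_age)
        persons.append(PersonRec(
            person_id=pid, gender=rng.choice(("female", "male")),
            birth_date=birth,
            age_at_diagnosis=(admission - birth).days // 366,
            postal_code=f"{rng.randint(10000, 99999)}",
            race=rng.choice(_RACES), ethnicity=rng.choice(_ETHNICITIES)))
        visits.append(VisitRec(
            visit_id=vid, person_id=pid, admission_date=admission,
            discharge_date=discharge, visit_kind="inpatient_full"))
        diagnoses.append(DiagnosisRec(
            person_id=pid, visit_id=vid, icd10gm_code=aml.icd10gm_code,
            orpha_code=aml.orpha_code, diagnosis_date=admission))
        if rng.random() < 0.6:
            phenotypes.append(PhenotypeRec(
                person_id=pid, visit_id=vid, hpo_code="HP:0001945",
                observed=True, noted_at=admission))
        for lab in rng.sample(loincs, k=min(2, len(loincs))):
            labs.append(LabRec(
                person_id=pid, visit_id=vid, loinc_code=lab.code,
                value=round(rng.uniform(0.1, 300.0), 2),
                ucum_unit=lab.unit or "1", measured_at=admission))
        if atcs and rng.random() < 0.8:
            med = rng.choice(atcs)
            medications.append(MedicationRec(
                person_id=pid, visit_id=vid, atc_code=med.code,
                start_date=admission))
        if opss and rng.random() < 0.7:
            procedures.append(ProcedureRec(
                person_id=pid, visit_id=vid, ops_code=rng.choice(opss).code,
                procedure_date=admission))

        wide: dict[str, object] = {"person_id": pid, "visit_id": vid}
        for feat in features:
            row_def = by_feature[feat]
            value: str | float
            if row_def.value_kind == "binary":
                value = ("positive" if rng.random() < config.mutation_prob
                         else "negative")
            else:
                value = round(rng.uniform(0.1, 500.0), 2)
            wide[feat] = value
            genotypes.append(GenotypeRec(
                person_id=pid, visit_id=vid, feature_name=feat, value=value,
                assayed_at=admission))
        wide_rows.append(wide)

    frame = pd.DataFrame(wide_rows, columns=["person_id", "visit_id"] + features)
    bundle = RDCDMBundle(
        persons=tuple(persons), visits=tuple(visits),
        diagnoses=tuple(diagnoses), procedures=tuple(procedures),
        labs=tuple(labs), medications=tuple(medications),
        phenotypes=tuple(phenotypes), genotypes=tuple(genotypes),
        domain="hematology", site=site, seed=seed).canonical()
    return bundle, frame
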