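# rdcdm

A customizable rare-disease common data model (RD-CDM) with two ETL routes into
an OMOP CDM-shaped relational store, bundled reference catalogs, and a seeded
synthetic cohort generator.

The package models seven RD-CDM modules (Person, Case/Visit, Diagnosis,
Procedure, Laboratory findings, Medication, Genotype, Phenotype) across four
clinical domains (endocrinology, gastroenterology, pneumonology, hematology).
Records are transformed into a minimal OMOP v5.4 target in two stages:

1. **Core ETL** — persons/visits first, then diagnoses, procedures, labs and
   medications, routed by the bundled module→table map. Codes without a known
   standard concept load with `concept_id 0` and the source code preserved in
   the `*_source_value` column.
2. **Genotype/Phenotype ETL** — distinct HPO codes are registered in
   `SOURCE_TO_CONCEPT_MAP` as individual source codes (HPO is not a standard
   OMOP vocabulary), phenotypes become `observation` rows, and genotype
   features are mapped through the bundled genotype concept map into
   `measurement` rows (many features may share one concept id, e.g. the four
   CEBPA-derived features). This stage refuses to run before the core ETL so
   referential integrity between person and visit ids is guaranteed; the
   per-record `MappingReport` yields the mapping success rate.

The synthetic generator emits fully validated bundles whose diagnosis codes,
symptoms (linked per disease) and genotype features are drawn exclusively from
the bundled catalogs, so a clean cohort maps with 100% success by construction.
A configurable dirty mode injects malformed HPO codes and unmapped features for
negative-path testing.

## CLI

```sh
# seeded synthetic AML-style cohort: 1,674 patients x 124 feature columns
rdcdm generate --domain hematology --n 1674 --features 124 --seed 42 --out cohort/

rdcdm validate cohort/
rdcdm etl-core cohort/ --store omop.db
rdcdm etl-genopheno cohort/ --store omop.db --report-out mapping.csv
rdcdm report --store omop.db --mapping-report mapping.csv --threshold 100
rdcdm catalog --what overlap        # symptom-overlap report across groups
```

`generate` also accepts a YAML config (`--config`) with `symptom_prob`,
`dirty_fraction`, `mutation_prob`, `min_age_years`.

## Library

```python
from rdcdm import (load_catalogs, generate_hematology, init_store,
                   run_core_etl, run_genopheno_etl)

catalog = load_catalogs()
bundle, wide = generate_hematology(catalog, seed=42)   # 1674 x 124 by default
store = init_store()                                    # in-memory sqlite
run_core_etl(bundle, catalog, store)
report = run_genopheno_etl(bundle, catalog, store)
print(report.success_rate)                              # 100.0
```

## Layout

- `src/rdcdm/catalogs.py` — bundled catalogs (diseases, symptoms, routes,
  genotype concept map, criteria) with validation and query helpers
- `src/rdcdm/model.py`, `bundle_io.py` — record types, bundle validation,
  cohort selection, deterministic CSV layout
- `src/rdcdm/omop.py` — sqlite-backed OMOP store with eager PK/FK enforcement
- `src/rdcdm/etl_core.py`, `etl_genopheno.py` — the two ETL routes
- `src/rdcdm/synth.py` — seeded synthetic cohort generator
- `src/rdcdm/qa.py`, `cli.py` — summaries, overlap reports, CLI
- `src/rdcdm/resources/` — the catalog CSV files
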