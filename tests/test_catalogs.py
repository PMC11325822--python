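"""Catalog loading, ICD matching, symptom intersections, module routing."""

import csv
from pathlib import Path

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rdcdm.catalogs import (
    DOMAINS, ICD10GM_RE, RDCDM_MODULES, load_catalogs, match_icd10,
    route_for_module, shared_symptoms,
)
from rdcdm.errors import CatalogValidationError, ConfigurationError

RESOURCE_DIR = Path(__file__).parents[1] / "src" / "rdcdm" / "resources"


# ---------------------------------------------------------------------------
# loading

class TestLoadCatalogs:
    def test_graves_disease_entry(self, catalog):
        graves = [d for d in catalog.diseases if d.disease_name == "Graves' disease"]
        assert len(graves) == 1
        assert graves[0].icd10gm_code == "E05.0"
        assert graves[0].orpha_code == "ORPHA:525,731"
        assert graves[0].orpha_number == 525731

    def test_fever_symptom_entry(self, catalog):
        fevers = [s for s in catalog.symptoms if s.symptom_name == "Fever"]
        assert fevers and all(s.hpo_code == "HP:0001945" for s in fevers)

    def test_empty_dir_is_configuration_error(self, tmp_path):
        with pytest.raises(ConfigurationError):
            load_catalogs(tmp_path)

    def test_completeness(self, catalog):
        assert len(catalog.diseases) >= 28
        assert {d.domain for d in catalog.diseases} == set(DOMAINS)

    def test_all_codes_syntactically_valid(self, catalog):
        for d in catalog.diseases:
            assert ICD10GM_RE.match(d.icd10gm_code), d

    def test_malformed_code_names_row_and_field(self, catalog, tmp_path):
        for f in RESOURCE_DIR.glob("*.csv"):
            (tmp_path / f.name).write_text(f.read_text())
        path = tmp_path / "diseases.csv"
        rows = path.read_text().splitlines()
        rows[3] = rows[3].replace("E05.9", "5E.99")
        path.write_text("\n".join(rows) + "\n")
        with pytest.raises(CatalogValidationError) as exc:
            load_catalogs(tmp_path)
        assert exc.value.row == 4
        assert exc.value.field == "icd10gm_code"

    def test_genotype_map_cebpa_rows(self, catalog):
        cebpa = [g for g in catalog.genotype_map
                 if g.target_concept_id == 35948202]
        assert {g.source_feature for g in cebpa} == {
            "CEBPA.bZIP", "CEBPA.bZIP.inframe", "CEBPA.TAD", "CEBPASTAT"}
        assert all(not g.placeholder for g in cebpa)

    def test_placeholder_ids_in_reserved_range(self, catalog):
        for g in catalog.genotype_map:
            if g.placeholder:
                assert g.target_concept_id >= 2_000_000_000

    def test_map_has_124_unique_features(self, catalog):
        feats = [g.source_feature for g in catalog.genotype_map]
        assert len(feats) == len(set(feats)) == 124


# ---------------------------------------------------------------------------
# match_icd10

class TestMatchIcd10:
    @pytest.mark.parametrize("pattern,code,expected", [
        ("E05.-", "E05.8", True),
        ("E05.0", "E05.0", True),
        ("C34.-", "C92.0", False),
        ("D86.-", "D86", True),   # bare stem included in the wildcard
        ("E05.0", "E05.8", False),
    ])
    def test_examples(self, pattern, code, expected):
        assert match_icd10(pattern, code) is expected

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            match_icd10("e05.-", "E05.0")
        with pytest.raises(ValueError):
            match_icd10("E05.-", "E05.123")

    def test_agrees_with_stem_oracle_on_full_catalog_cross_product(self, catalog):
        # independent oracle: plain string comparison on the 3-char stem
        def oracle(pattern, code):
            if pattern.endswith(".-"):
                return code[:3] == pattern[:3]
            return code == pattern

        codes = sorted({d.icd10gm_code for d in catalog.diseases})
        for pattern in codes:
            for code in codes:
                assert match_icd10(pattern, code) == oracle(pattern, code)

    @given(st.sampled_from(["A15", "C34", "E05", "J10"]),
           st.integers(0, 9))
    def test_wildcard_accepts_every_subcode(self, stem, sub):
        assert match_icd10(f"{stem}.-", f"{stem}.{sub}")


# ---------------------------------------------------------------------------
# shared_symptoms

class TestSharedSymptoms:
    def test_single_group_is_identity(self, catalog):
        full = {s.hpo_code for s in catalog.symptoms
                if s.group == "Gastroenterology"}
        assert shared_symptoms(catalog, {"Gastroenterology"}) == full

    def test_gastro_pneumo_contains_fever_and_fatigue(self, catalog):
        got = shared_symptoms(catalog, {"Gastroenterology", "Pneumonology"})
        assert {"HP:0001945", "HP:0012378"} <= got

    def test_three_development_domains(self, catalog):
        """Frozen from the brute-force oracle over the bundled transcription."""
        hyper = {s.hpo_code for s in catalog.symptoms
                 if s.group == "Endocrinology: Hyperthyroidism"}
        hypo = {s.hpo_code for s in catalog.symptoms
                if s.group == "Endocrinology: Hypothyroidism"}
        gastro = shared_symptoms(catalog, {"Gastroenterology"})
        pneumo = shared_symptoms(catalog, {"Pneumonology"})
        oracle = gastro & pneumo & (hyper | hypo)
        assert oracle == {"HP:0012378"}

    def test_unknown_group_raises(self, catalog):
        with pytest.raises(ValueError):
            shared_symptoms(catalog, {"Cardiology"})

    def test_commutative_idempotent_monotone(self, catalog):
        groups = list(catalog.symptom_groups())
        a, b = groups[0], groups[1]
        assert shared_symptoms(catalog, [a, b]) == shared_symptoms(catalog, [b, a])
        assert shared_symptoms(catalog, [a, a]) == shared_symptoms(catalog, [a])
        prev = shared_symptoms(catalog, groups[:1])
        for k in range(2, len(groups) + 1):
            cur = shared_symptoms(catalog, groups[:k])
            assert cur <= prev
            prev = cur


# ---------------------------------------------------------------------------
# routing

class TestRouteForModule:
    def test_every_module_routes(self, catalog):
        for module in RDCDM_MODULES:
            route = route_for_module(catalog, module)
            assert route.rdcdm_module == module

    def test_phenotype_route(self, catalog):
        r = route_for_module(catalog, "Phenotype")
        assert set(r.omop_tables) == {"observation", "measurement"}
        assert set(r.vocabularies) == {"HPO", "SNOMED", "LOINC"}

    def test_medication_route(self, catalog):
        r = route_for_module(catalog, "Medication")
        assert set(r.omop_tables) == {"drug_exposure", "observation"}
        assert set(r.vocabularies) == {"RxNorm", "ATC"}
        assert r.default_table == "drug_exposure"

    def test_person_route_vocabularies(self, catalog):
        assert set(route_for_module(catalog, "Person").vocabularies) == {
            "SNOMED", "Gender"}

    def test_genotype_route(self, catalog):
        r = route_for_module(catalog, "Genotype")
        assert set(r.omop_tables) == {"observation", "measurement"}
        assert r.vocabularies == ("OMOP Genomic",)

    def test_unknown_module_raises(self, catalog):
        with pytest.raises(ValueError):
            route_for_module(catalog, "Imaging")
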