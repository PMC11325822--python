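"""Genotype/Phenotype-to-OMOP ETL: registration, mapping, ordering, reports."""

from dataclasses import replace
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdcdm.errors import EtlOrderingError
from rdcdm.etl_core import run_core_etl
from rdcdm.etl_genopheno import (
    hpo_placeholder_concept_id, melt_wide_genotypes, register_hpo_codes,
    run_genopheno_etl, transform_genotypes, transform_phenotypes,
)
from rdcdm.model import GenotypeRec, PhenotypeRec
from rdcdm.omop import init_store
from rdcdm.synth import GeneratorConfig, generate_domain_cohort


@pytest.fixture()
def loaded_store(tiny_bundle, catalog):
    store = init_store()
    run_core_etl(tiny_bundle, catalog, store)
    yield store
    store.close()


class TestRegisterHpoCodes:
    def test_duplicates_register_once(self, loaded_store):
        phenos = [
            PhenotypeRec("p1", "v1", "HP:0001945", True, date(2016, 3, 1)),
            PhenotypeRec("p1", "v1", "HP:0001945", False, date(2016, 3, 2)),
        ]
        assert register_hpo_codes(phenos, loaded_store) == 1
        rows = loaded_store.fetch_rows("source_to_concept_map")
        assert rows[0]["source_code"] == "HP:0001945"
        assert rows[0]["source_vocabulary_id"] == "HPO"

    def test_empty_input(self, loaded_store):
        assert register_hpo_codes([], loaded_store) == 0

    def test_rerun_is_idempotent(self, loaded_store):
        codes = ["HP:0001945", "HP:0012378"]
        assert register_hpo_codes(codes, loaded_store) == 2
        assert register_hpo_codes(codes, loaded_store) == 0
        assert loaded_store.count_rows("source_to_concept_map") == 2

    def test_placeholder_ids_are_deterministic_and_reserved(self):
        cid = hpo_placeholder_concept_id("HP:0001945")
        assert cid == 2_100_001_945
        assert cid >= 2_000_000_000


class TestTransformPhenotypes:
    def test_catalog_symptom_maps(self, catalog, loaded_store):
        phenos = [PhenotypeRec("p1", "v1", "HP:0012378", True, date(2016, 3, 1))]
        register_hpo_codes(phenos, loaded_store)
        report = transform_phenotypes(phenos, catalog, loaded_store)
        assert report.mapped == 1 and report.success_rate == 100.0
        rows = loaded_store.fetch_rows(
            "observation", "observation_source_value = ?", ("HP:0012378",))
        assert len(rows) == 1
        assert rows[0]["observation_concept_id"] == hpo_placeholder_concept_id(
            "HP:0012378")

    def test_malformed_code_rejected_without_row(self, catalog, loaded_store):
        phenos = [PhenotypeRec("p1", "v1", "HP:12", True, date(2016, 3, 1))]
        report = transform_phenotypes(phenos, catalog, loaded_store)
        assert report.rejected == 1 and report.mapped == 0
        assert loaded_store.count_rows("observation") == 0
        assert "malformed" in report.outcomes[0].reason

    def test_before_core_etl_is_ordering_error(self, catalog):
        store = init_store()
        phenos = [PhenotypeRec("p1", "v1", "HP:0001945", True, date(2016, 3, 1))]
        with pytest.raises(EtlOrderingError, match="referential integrity"):
            transform_phenotypes(phenos, catalog, store)
        assert store.count_rows("observation") == 0
        store.close()


class TestTransformGenotypes:
    def _rec(self, feature, value):
        return GenotypeRec("p2", "v2", feature, value, date(2020, 7, 1))

    def test_cebpa_bzip_concept_id(self, catalog, loaded_store):
        report = transform_genotypes([self._rec("CEBPA.bZIP", "positive")],
                                     catalog, loaded_store)
        assert report.mapped == 1
        rows = loaded_store.fetch_rows(
            "measurement", "measurement_source_value = ?", ("CEBPA.bZIP",))
        assert rows[0]["measurement_concept_id"] == 35948202
        assert rows[0]["value_as_concept_id"] == 9191  # positive

    def test_four_cebpa_features_share_one_concept(self, catalog, loaded_store):
        feats = ["CEBPA.bZIP", "CEBPA.bZIP.inframe", "CEBPA.TAD", "CEBPASTAT"]
        report = transform_genotypes(
            [self._rec(f, "positive") for f in feats], catalog, loaded_store)
        assert report.mapped == 4
        rows = loaded_store.fetch_rows(
            "measurement", "measurement_concept_id = ?", (35948202,))
        # many-to-one is never collapsed: four rows, one concept id
        assert len(rows) == 4
        assert {r["measurement_source_value"] for r in rows} == set(feats)

    def test_unknown_feature_unmapped_no_row(self, catalog, loaded_store):
        report = transform_genotypes([self._rec("NOT_IN_MAP", "positive")],
                                     catalog, loaded_store)
        assert report.unmapped == 1
        assert loaded_store.count_rows("measurement") == 0

    def test_numeric_value_goes_to_value_as_number(self, catalog, loaded_store):
        report = transform_genotypes([self._rec("WBC", 13.4)],
                                     catalog, loaded_store)
        assert report.mapped == 1
        rows = loaded_store.fetch_rows(
            "measurement", "measurement_source_value = ?", ("WBC",))
        assert rows[0]["value_as_number"] == 13.4

    def test_unencodable_value_rejected(self, catalog, loaded_store):
        report = transform_genotypes([self._rec("CEBPA.TAD", "maybe")],
                                     catalog, loaded_store)
        assert report.rejected == 1
        assert loaded_store.count_rows("measurement") == 0

    def test_negative_rows_can_be_suppressed(self, catalog, loaded_store):
        report = transform_genotypes(
            [self._rec("CEBPA.TAD", "negative")], catalog, loaded_store,
            emit_negative_rows=False)
        assert report.mapped == 1
        assert loaded_store.count_rows("measurement") == 0


class TestRunGenophenoEtl:
    def test_success_rate_with_one_unmapped(self, catalog, tiny_bundle):
        store = init_store()
        run_core_etl(tiny_bundle, catalog, store)
        genos = tuple(
            GenotypeRec("p2", "v2", "CEBPA.bZIP", "positive", date(2020, 7, 1))
            for _ in range(99)) + (
            GenotypeRec("p2", "v2", "NOPE", "positive", date(2020, 7, 1)),)
        bundle = replace(tiny_bundle, phenotypes=(), genotypes=genos)
        report = run_genopheno_etl(bundle, catalog, store)
        assert report.mapped == 99 and report.unmapped == 1
        assert report.success_rate == pytest.approx(99.0)
        store.close()

    def test_empty_input_is_vacuously_100(self, catalog, tiny_bundle):
        store = init_store()
        run_core_etl(tiny_bundle, catalog, store)
        bundle = replace(tiny_bundle, phenotypes=(), genotypes=())
        report = run_genopheno_etl(bundle, catalog, store)
        assert report.records_in == 0
        assert report.success_rate == 100.0
        store.close()

    def test_ordering_violation_writes_nothing(self, catalog, tiny_bundle):
        store = init_store()  # core ETL never ran
        with pytest.raises(EtlOrderingError):
            run_genopheno_etl(tiny_bundle, catalog, store)
        for table in ("observation", "measurement", "source_to_concept_map"):
            assert store.count_rows(table) == 0
        store.close()

    def test_conservation_one_status_per_record(self, catalog, gastro_bundle):
        store = init_store()
        run_core_etl(gastro_bundle, catalog, store)
        report = run_genopheno_etl(gastro_bundle, catalog, store)
        n_in = len(gastro_bundle.phenotypes) + len(gastro_bundle.genotypes)
        assert report.records_in == n_in
        assert report.mapped + report.unmapped + report.rejected == n_in
        store.close()

    @settings(max_examples=8, deadline=None)
    @given(dirty=st.floats(0.0, 1.0))
    def test_conservation_under_dirty_generation(self, catalog, dirty):
        """input records = mapped + unmapped + rejected at any dirty fraction."""
        bundle = generate_domain_cohort(
            catalog, "pneumonology", 15, seed=3,
            config=GeneratorConfig(dirty_fraction=dirty))
        store = init_store()
        run_core_etl(bundle, catalog, store)
        report = run_genopheno_etl(bundle, catalog, store)
        assert (report.mapped + report.unmapped + report.rejected
                == len(bundle.phenotypes) + len(bundle.genotypes))
        store.close()


class TestMeltWideGenotypes:
    def test_melt_and_transform(self, catalog, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text(
            "person_id,visit_id,CEBPA.bZIP,WBC\n"
            "p1,v1,positive,12.5\n"
            "p2,v2,negative,3.1\n")
        records = melt_wide_genotypes(path, assayed_at=date(2020, 1, 1))
        assert len(records) == 4
        by_feat = {(r.person_id, r.feature_name): r.value for r in records}
        assert by_feat[("p1", "CEBPA.bZIP")] == "positive"
        assert by_feat[("p2", "WBC")] == 3.1

    def test_missing_identifier_column_raises(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text("person_id,CEBPA.bZIP\np1,positive\n")
        with pytest.raises(ValueError, match="visit_id"):
            melt_wide_genotypes(path, assayed_at=date(2020, 1, 1))
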