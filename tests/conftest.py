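from datetime import date

import pytest

from rdcdm import generate_domain_cohort, init_store, load_catalogs
from rdcdm.model import (
    DiagnosisRec, GenotypeRec, PersonRec, PhenotypeRec, RDCDMBundle, VisitRec,
)


@pytest.fixture(scope="session")
def catalog():
    return load_catalogs()


@pytest.fixture()
def store():
    s = init_store()
    yield s
    s.close()


@pytest.fixture()
def tiny_bundle():
    """Two persons, two visits, hand-built and referentially closed."""
    return RDCDMBundle(
        persons=(
            PersonRec("p1", "female", date(1980, 5, 4), 35, "01067"),
            PersonRec("p2", "male", date(1990, 1, 1), 30, "60311"),
        ),
        visits=(
            VisitRec("v1", "p1", date(2016, 3, 1), date(2016, 3, 9),
                     "inpatient_full"),
            VisitRec("v2", "p2", date(2020, 7, 1), date(2020, 7, 2),
                     "inpatient_partial"),
        ),
        diagnoses=(
            DiagnosisRec("p1", "v1", "E05.0", date(2016, 3, 1),
                         "ORPHA:525,731"),
            DiagnosisRec("p2", "v2", "C92.0", date(2020, 7, 1)),
        ),
        phenotypes=(
            PhenotypeRec("p1", "v1", "HP:0001945", True, date(2016, 3, 1)),
        ),
        genotypes=(
            GenotypeRec("p2", "v2", "CEBPA.bZIP", "positive", date(2020, 7, 1)),
        ),
        domain="endocrinology",
    )


@pytest.fixture(scope="session")
def gastro_bundle(catalog):
    return generate_domain_cohort(catalog, "gastroenterology", 40, seed=11)
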