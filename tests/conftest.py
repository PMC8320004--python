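import logging

import pytest

from mhcoverage.atlas_ingest import AtlasRecord, Disorder
from mhcoverage.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_logs():
    # the screens and the ratio cap log loudly by design; keep test output
    # readable
    logging.disable(logging.WARNING)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture()
def complete_record():
    return AtlasRecord(
        country_code="AAA", disorder=Disorder.PSYCHOSIS,
        inpatient_cases=100, outpatient_cases=500,
        inpatient_visits=400, outpatient_visits=2000,
        representativeness=0.8, followup_category=2,
        reported_population=5_000_000)


@pytest.fixture(scope="session")
def default_cohort():
    """A mixed-quality synthetic world shared by read-only tests."""
    return generate_cohort(60, GeneratorConfig(), seed=20_17)
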