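import pytest

from usherdx.fixtures import load_fixture_tables
from usherdx.pipeline import run_fixture_pipeline


@pytest.fixture(scope="session")
def tables():
    """The packaged 17-patient cohort, loaded once per session."""
    return load_fixture_tables()


@pytest.fixture(scope="session")
def fixture_result():
    """Full pipeline run on the packaged cohort."""
    return run_fixture_pipeline()


@pytest.fixture(scope="session")
def diagnoses_by_id(fixture_result):
    return {d.patient_id: d for d in fixture_result.diagnoses}
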