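import pytest

from vpquant import SIEMENS_SYMBIA
from vpquant.synthetic_data import CohortSpec, generate_cohort, generate_study_fixtures


@pytest.fixture(scope="session")
def small_cohort():
    """Four synthetic training-profile studies with a fixed seed."""
    return generate_cohort(CohortSpec(n=4, seed=7))


@pytest.fixture(scope="session")
def fixture_manifest(small_cohort, tmp_path_factory):
    """DICOM fixtures for the small cohort, written once per session."""
    out = tmp_path_factory.mktemp("dicom_fixtures")
    return generate_study_fixtures(small_cohort, out)


@pytest.fixture(scope="session")
def camera():
    return SIEMENS_SYMBIA
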