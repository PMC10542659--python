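import io

import pytest
from hypothesis import HealthCheck, settings

from varhits import build_index, read_vcf, table_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_data():
    """The worked-example fixture: records, VCF text, expected TSV."""
    return table_fixture()


@pytest.fixture(scope="session")
def fixture_db(fixture_data):
    return build_index(fixture_data.records)


@pytest.fixture
def fixture_variants(fixture_data):
    return list(read_vcf(io.StringIO(fixture_data.vcf_text)))
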