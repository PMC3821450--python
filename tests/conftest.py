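import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from phenostream import load_fixture  # noqa: E402


@pytest.fixture(scope="session")
def unamuno():
    return load_fixture("unamuno_journal")


@pytest.fixture(scope="session")
def joyce():
    return load_fixture("joyce_penelope")
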