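import pytest

from claimforge import load_reference_bundle, serialize_interchange, worked_example_claim


@pytest.fixture(scope="session")
def bundle():
    return load_reference_bundle()


@pytest.fixture()
def worked_claim():
    return worked_example_claim()


@pytest.fixture()
def worked_text(worked_claim):
    return serialize_interchange([worked_claim])
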