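import pytest

from maml2rwe.synthetic import reference_cohort, screening_cohort


@pytest.fixture(scope="session")
def cohort55():
    """The deterministic 55-case test-order reference cohort."""
    return reference_cohort()


@pytest.fixture(scope="session")
def screening():
    """The deterministic 8106-sample pan-tumor screening cohort."""
    return screening_cohort()
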