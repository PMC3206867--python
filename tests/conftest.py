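import pytest
from hypothesis import settings

from ebcm.datasets import default_model

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model():
    """Default physiology model on the packaged fixture curves (alpha=499)."""
    return default_model()
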