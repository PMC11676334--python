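import pytest
from hypothesis import settings

from algatrait.datasets import load_reference_fame_profile

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def reference_profile():
    """The published 11-component FAME profile (0.5 M NaCl, total 85.74%)."""
    return load_reference_fame_profile()
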