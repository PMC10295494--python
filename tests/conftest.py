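import pytest
from hypothesis import settings

from aortastat import default_spec, derive_frame, generate

settings.register_profile("default", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort_frame():
    """One study-calibrated synthetic cohort (n = 97, fixed seed)."""
    return generate(default_spec(seed=1)).frame


@pytest.fixture(scope="session")
def derived(cohort_frame):
    return derive_frame(cohort_frame)
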