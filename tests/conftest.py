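import numpy as np
import pytest

from aphidcascade.profiles import default_profiles


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def control(profiles):
    return profiles["Control"]


@pytest.fixture(scope="session")
def control_cohort(control):
    """A mid-sized control cohort shared across read-only tests."""
    from aphidcascade.simulate import gen_cohort

    return gen_cohort(control, n=400, seed=2024)
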