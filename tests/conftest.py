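import numpy as np
import pytest
from hypothesis import settings

from circaphen import PhaseSchedule, SyntheticDesign

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def design():
    """Default study-scale synthetic design, fixed seed."""
    return SyntheticDesign(seed=42)


@pytest.fixture
def small_design():
    """Down-scaled design (2 animals/group, 48 h) for fast end-to-end runs."""
    return SyntheticDesign(
        seed=7, groups=(("CNT", 2), ("IVF35", 2), ("IVF37", 2)), duration=48.0
    )


@pytest.fixture
def schedule():
    return PhaseSchedule()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
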