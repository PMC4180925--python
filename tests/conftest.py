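import numpy as np
import pytest

from homecage.arena import default_layout, default_schedule
from homecage.simulate import StrainProfile, simulate_animal


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def short_animal(layout):
    """A rendered 6 h animal with ground truth (track-level tests)."""
    profile = StrainProfile(name="FIX", duration_h=6.0)
    stream, truth = simulate_animal(profile, seed=101, layout=layout)
    return stream, truth


@pytest.fixture(scope="session")
def full_animal():
    """An event-level 3-day animal with known circadian structure."""
    profile = StrainProfile(name="FULL", dark_activity=0.60,
                            light_activity=0.10, habituation=0.85)
    _, truth = simulate_animal(profile, seed=202, render=False)
    return truth


@pytest.fixture(scope="session")
def full_record(full_animal):
    from homecage.parameters import record_from_truth
    return record_from_truth(full_animal)
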