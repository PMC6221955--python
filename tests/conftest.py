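import numpy as np
import pytest

from emobio.montage import Montage, default_montage, load_montage
from emobio.recording import Recording
from emobio.schedule import make_imagery_schedule
from emobio.synth import CohortSpec, GroupEffect, simulate_subject


@pytest.fixture(scope="session")
def montage64() -> Montage:
    return default_montage()


@pytest.fixture(scope="session")
def mini_montage() -> Montage:
    """Four channels, two tiny clusters, for cheap preprocessing tests."""
    return load_montage(
        {
            "channels": ["Fz", "Cz", "Pz", "Oz"],
            "clusters": {"A": ["Fz", "Cz"], "B": ["Pz"]},
        }
    )


def make_recording(
    montage: Montage,
    data: np.ndarray,
    rate_hz: float = 250.0,
    events=None,
) -> Recording:
    return Recording(
        data=np.asarray(data, dtype=float),
        rate_hz=rate_hz,
        montage=montage,
        events=list(events or []),
    )


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    return CohortSpec(
        n_per_group=2,
        sampling_rate_hz=125.0,
        group_effects=(GroupEffect("theta", "C4", "emotion", 3.0),),
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_subject(tiny_spec, montage64) -> Recording:
    """One affected-group subject on a 4-trial imagery schedule."""
    sched = make_imagery_schedule(3, n_per_condition_per_block=1)
    return simulate_subject(tiny_spec, "asd", sched, seed=99, montage=montage64)
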