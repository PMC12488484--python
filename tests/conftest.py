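import numpy as np
import pytest

from boutondyn.config import SimConfig
from boutondyn.synthgen import generate_activity, generate_behavior


@pytest.fixture(scope="session")
def small_task_config() -> SimConfig:
    """A small task session: 4 axons x 4 boutons, 24 trials, 4.5 min."""
    return SimConfig(
        seed=11,
        n_axons_per_mouse=4,
        boutons_per_axon=4,
        n_trials=24,
        p_rm=0.5,
        segment_s=300.0,
        snr=8.0,
    )


@pytest.fixture(scope="session")
def small_session(small_task_config):
    """Generated behaviour + fluorescence + truth for the small task session."""
    behavior = generate_behavior(small_task_config)
    fluor, truth = generate_activity(behavior, small_task_config)
    return {"config": small_task_config, "behavior": behavior,
            "fluor": fluor, "truth": truth}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
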