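import logging

import numpy as np
import pytest

from unfoldkit.events import EventConfig
from unfoldkit.processing import ProcessingConfig
from unfoldkit.simulate import SimulationConfig, simulate_curve

# The simulator logs a coarse-dt warning on some curves; keep test output tidy.
logging.getLogger("unfoldkit.simulate").setLevel(logging.ERROR)
logging.getLogger("unfoldkit.events").setLevel(logging.ERROR)


@pytest.fixture
def processing_config():
    return ProcessingConfig()


@pytest.fixture
def event_config():
    return EventConfig()


@pytest.fixture
def clean_sim_config():
    """Noiseless 9-domain pull (default detachment): the cleanest saw-tooth."""
    return SimulationConfig(force_noise_sd=0.0, pulling_speed=1600.0)


@pytest.fixture
def clean_curve(clean_sim_config):
    """One noiseless simulated curve plus its ground truth."""
    rng = np.random.default_rng(1234)
    return simulate_curve(clean_sim_config, rng, curve_id="clean-0")
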