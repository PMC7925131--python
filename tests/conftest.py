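import numpy as np
import pytest

from colonyscreen import (
    CalibrationFit,
    NoiseModel,
    RDParams,
    run_simulation,
    simulate_plate,
)

SCALE = 10.0  # px/mm used throughout the image tests


@pytest.fixture(scope="session")
def default_cal():
    return CalibrationFit(alpha=2.0, beta=0.5)


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseModel(background_level=100.0, background_sd=0.0, multiplicative_cv=0.0)


@pytest.fixture(scope="session")
def zero_noise_plate(quiet_noise):
    """A full 8x12 plate rendered without noise: (layout, truth, gfp, rfp)."""
    return simulate_plate(noise=quiet_noise, seed=7)


@pytest.fixture(scope="session")
def rd_default_traj():
    """Default-parameter (M2/M1 = 0.8) run to 16 hr, recorded every 2 hr."""
    return run_simulation(RDParams(), duration=960.0, record_every=120.0)


@pytest.fixture(scope="session")
def rd_symmetric_traj():
    """Equal-growth-rate (M2 = M1) run to 16 hr."""
    params = RDParams().with_growth_ratio(1.0)
    return run_simulation(params, duration=960.0, record_every=120.0)


@pytest.fixture(scope="session")
def rd_coarse_traj():
    """The default run on a grid with doubled spacing (dx 0.1 vs 0.05)."""
    return run_simulation(RDParams(dx=0.1, dt=0.4), duration=960.0, record_every=120.0)
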