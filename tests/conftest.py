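import dataclasses

import numpy as np
import pytest

from nirsnet import (
    BlockAverage,
    SimulationConfig,
    build_default_montage,
    generate_schedule,
)


@pytest.fixture(scope="session")
def montage():
    return build_default_montage()


@pytest.fixture(scope="session")
def schedule_small():
    """One session of 8 tasks (2 per condition), seeded."""
    return generate_schedule(1, 8, rng_seed=11)


@pytest.fixture()
def quiet_config():
    """No noise, no variability, no couplings: deterministic forward model."""
    return SimulationConfig().quiet()


@pytest.fixture()
def right_only_config(quiet_config):
    """Zero-noise config with activation exclusively in the right hemisphere."""
    return dataclasses.replace(
        quiet_config,
        condition_amplitudes={
            "Rest": (0.0, 0.0),
            "MV": (0.0, 0.3),
            "MO": (0.0, 0.3),
            "MOV": (0.0, 0.3),
        },
    )


def make_block_average(data, montage, fs=10.0, tmin=-5.0, condition="MV", n_blocks=1):
    """Wrap a (24, n) array as a BlockAverage on the default montage grid."""
    data = np.asarray(data, dtype=float)
    return BlockAverage(
        data=data,
        sd=np.zeros_like(data),
        n_blocks=n_blocks,
        condition=condition,
        tmin=tmin,
        fs=fs,
        channels=montage.channel_names,
        hemispheres=montage.hemispheres,
    )
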