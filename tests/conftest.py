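import numpy as np
import pytest

from thiodyn.synthetic import TASGenConfig
from thiodyn.vibronic import load_2tc_model, load_toy_model


@pytest.fixture(scope="session")
def model_2tc():
    return load_2tc_model()


@pytest.fixture(scope="session")
def lz_toy():
    return load_toy_model("avoided_crossing")


@pytest.fixture(scope="session")
def harmonic_toy():
    return load_toy_model("harmonic_crossing")


@pytest.fixture()
def small_tas_config():
    """A reduced synthetic-map configuration for fast fitting tests:
    coarser wavelength grid, same kinetics."""
    return TASGenConfig(
        wl_min=330.0,
        wl_max=650.0,
        wl_step=8.0,
        delays=np.unique(
            np.concatenate(
                [np.arange(-800.0, 1000.0, 25.0), np.geomspace(1000.0, 4000.0, 25)]
            )
        ),
        seed=1,
    )
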