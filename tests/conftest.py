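import numpy as np
import pytest

from v1bright import ModelParams
from dataclasses import replace


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def quiet_params():
    """Deterministic parameters (noise off) for invariance checks."""
    return replace(ModelParams(), noise_amp=0.0)


@pytest.fixture()
def small_params():
    """Noise-free parameters with short runs for fast unit tests."""
    return replace(
        ModelParams(),
        noise_amp=0.0,
        settle_time=10.0,
        avg_window=6.0,
        conn_radius=4,
        max_reach_px=8,
    )
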