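import numpy as np
import pytest

from sfsc import Measurement, SimulationParams, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def second_realization(gt, seed_offset=1000):
    """Same signal as ``gt`` with an independently drawn noise field."""
    p = gt.params
    other = simulate(
        SimulationParams(p.shape, p.voxel_size, p.b_signal, p.b_noise,
                         p.snr, p.seed + seed_offset)
    )
    return Measurement(gt.signal.data + other.noise.data, p.voxel_size)


@pytest.fixture
def small_phantom():
    """2-D phantom in the well-behaved regime (white noise, rapid decay)."""
    return simulate(SimulationParams((64, 64), 0.81, 100.0, 0.0, 15.0, 7))
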