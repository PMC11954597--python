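import numpy as np
import pytest

from pafpdd import (ABY029_PIF, IRDYE680LT_PIF, DEFAULT_KINETICS,
                    ExperimentConfig, FingerGeometry, PulsatileConfig,
                    TimeSeries, build_geometry)


@pytest.fixture(scope="session")
def minute_grid():
    """The 1-min tumor-study grid over 300 min."""
    return np.arange(0.0, 301.0, 1.0)


@pytest.fixture(scope="session")
def pifs():
    return ABY029_PIF, IRDYE680LT_PIF


@pytest.fixture(scope="session")
def kinetics():
    return DEFAULT_KINETICS


@pytest.fixture()
def short_pulsatile():
    """A 10-min pulsatile configuration for fast signal tests."""
    return PulsatileConfig(duration_min=10.0)


@pytest.fixture(scope="session")
def small_geometry():
    """Coarse finger voxelisation for fast Monte Carlo tests."""
    return FingerGeometry(voxel_size=0.04)


@pytest.fixture(scope="session")
def small_labels(small_geometry):
    return build_geometry(small_geometry)


def sine_series(freq_hz, fs=20.0, duration_s=300.0, amp=1.0, offset=0.0,
                amp_env=None):
    """Helper: a sinusoidal TimeSeries in seconds."""
    t = np.arange(int(duration_s * fs) + 1) / fs
    a = amp if amp_env is None else amp_env(t)
    return TimeSeries(t0=0.0, dt=1.0 / fs,
                      values=offset + a * np.sin(2 * np.pi * freq_hz * t),
                      label="sine", time_unit="s")
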