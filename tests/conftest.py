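import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nddsleep.params import PipelineParams
from nddsleep.synthetic import _band_shape, _pink_shape, _shaped_noise, \
    _spindle_wave

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params() -> PipelineParams:
    return PipelineParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def make_background():
    """NREM-like (1/f^2 power) background noise, unit seedable."""

    def _make(n: int, fs: float = 200.0, rms: float = 15.0,
              seed: int = 0) -> np.ndarray:
        g = np.random.default_rng(seed)
        return _shaped_noise(g, n, fs, _pink_shape) * rms

    return _make


@pytest.fixture(scope="session")
def make_burst():
    """Gaussian-envelope sigma-band burst, the generator's spindle shape."""

    def _make(fs: float, dur: float, freq: float = 13.0,
              amp: float = 45.0, phase: float = 0.0) -> np.ndarray:
        return _spindle_wave(fs, dur, freq, phase, amp)

    return _make


@pytest.fixture(scope="session")
def band_noise():
    def _make(n: int, fs: float, lo: float, hi: float,
              rms: float = 1.0, seed: int = 0) -> np.ndarray:
        g = np.random.default_rng(seed)
        return _shaped_noise(g, n, fs, _band_shape(lo, hi)) * rms

    return _make
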