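import numpy as np
import pytest

from semgfusion.synthetic import AcquisitionSpec, NoiseSpec, default_profiles


@pytest.fixture
def acq():
    return AcquisitionSpec()


@pytest.fixture
def short_acq():
    """1 s trials keep spectral tests fast while preserving resolution."""
    return AcquisitionSpec(duration=1.0)


@pytest.fixture
def noise():
    return NoiseSpec()


@pytest.fixture
def quiet():
    return NoiseSpec(baseline_rms=0.0, powerline_amplitude=0.0, drift_amplitude=0.0)


@pytest.fixture
def profiles():
    return default_profiles(12, 4, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
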