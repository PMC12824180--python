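import numpy as np
import pytest

from sersml.synthetic import PeakSpec, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A light simulation config for fast unit tests."""
    return SimConfig(n_points=120, seed=99)


@pytest.fixture
def quiet_config():
    """No noise, no replicate variability: generators become deterministic maps."""
    return SimConfig(
        n_points=120,
        noise_sd=0.0,
        within_strip_cv=0.0,
        across_strip_cv=0.0,
        seed=5,
    )


@pytest.fixture
def single_band_config():
    """One strongly differential band at 900 cm^-1 on a clean background."""
    return SimConfig(
        n_points=200,
        peak_table=[PeakSpec(900.0, 8.0, 0.2, 2.0)],
        patient_cv=0.1,
        seed=11,
    )
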