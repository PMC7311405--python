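import numpy as np
import pytest

from adcaqp import PhantomSpec, generate_adc_phantom, generate_dwi_series


@pytest.fixture(scope="session")
def noiseless_phantom():
    """A heterogeneous noiseless phantom: (spec, truth, mask, series)."""
    spec = PhantomSpec(grid_shape=(24, 24, 8), lesion_radius_mm=8.0,
                       adc_mean=0.39, adc_spread=0.06, noise_sigma=0.0, seed=7)
    truth, mask = generate_adc_phantom(spec)
    series = generate_dwi_series(truth, mask, spec)
    return spec, truth, mask, series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
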