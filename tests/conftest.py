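import numpy as np
import pytest

from tspoquant.input_function import default_dense_grid
from tspoquant.synthetic_data import simulate_input_function
from tspoquant.tac_io import default_feppa_schedule


@pytest.fixture(scope="session")
def schedule():
    return default_feppa_schedule()


@pytest.fixture(scope="session")
def clean_input_fn():
    """Noise-free ground-truth plasma input on a 2 s grid (fast to
    convolve, accurate enough for sub-0.1% frame averages)."""
    pif, _ = simulate_input_function(
        seed=0,
        auto_noise_pct=0.0,
        manual_noise_pct=0.0,
        grid=default_dense_grid(step_min=2.0 / 60.0),
    )
    return pif


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
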