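import numpy as np
import pytest

from spatocc import DetectionMatrix, ModelSpec, fit_model
from spatocc.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def medium_dataset():
    """One simulated survey big enough for stable intercept-only fits."""
    return simulate_dataset(SimulationConfig(n_sites=400, n_segments=20, seed=11))


@pytest.fixture(scope="session")
def medium_fit(medium_dataset):
    fit = fit_model(medium_dataset.y, None, ModelSpec(), n_starts=3, seed=0)
    assert fit.converged
    return fit


@pytest.fixture()
def tiny_matrix():
    return DetectionMatrix(
        ["a", "b", "c"],
        np.array([[1, 0, -1], [0, 0, 0], [1, 1, 0]], dtype=np.int8),
    )
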