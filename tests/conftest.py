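import numpy as np
import pytest

from permwalk.domain import build_domain
from permwalk.eigen import find_eigenvalues


@pytest.fixture(scope="session")
def benchmark_domain():
    """Two 20 µm compartments, D = 0.5 / 2.5 µm²/ms, κ = 0.05 µm/ms."""
    return build_domain([20.0, 20.0], [0.5, 2.5], [0.05])


@pytest.fixture(scope="session")
def benchmark_spectrum(benchmark_domain):
    return find_eigenvalues(benchmark_domain, lam_max=500.0, n_max=1000,
                            scan_points=100_000)


@pytest.fixture(scope="session")
def single_compartment():
    return build_domain([40.0], [0.5], [])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
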