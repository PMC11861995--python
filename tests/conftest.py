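import numpy as np
import pytest

from connectogcn.synthetic import SyntheticConfig, generate_dataset


def random_symmetric_graph(rng: np.random.Generator, n: int, density: float = 0.6) -> np.ndarray:
    """Random symmetric non-negative zero-diagonal adjacency."""
    A = rng.random((n, n)) * (rng.random((n, n)) < density)
    A = np.triu(A, k=1)
    return A + A.T


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small two-cohort dataset for structural tests (12 regions, 40 + 20)."""
    cfg = SyntheticConfig(n_regions=12, n_adult=40, n_pediatric=20, n_blocks=3, seed=42)
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
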