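import numpy as np
import pytest

from nanoquant.simulate import (
    CompactionConfig,
    NBConfig,
    simulate_compaction_movie,
    simulate_nb_stack,
)


@pytest.fixture(scope="session")
def clean_compaction():
    """Noise-free, jitter-free compaction movie with a fixed anchor."""
    cfg = CompactionConfig(
        seed=1, noise=None, jitter_sigma_px=0.0, anchor_col=100, cluster_sigma_px=1.5
    )
    return simulate_compaction_movie(cfg)


@pytest.fixture(scope="session")
def noisy_compaction():
    """Poisson-noise compaction movie at default SNR."""
    cfg = CompactionConfig(seed=2, anchor_col=100)
    return simulate_compaction_movie(cfg)


@pytest.fixture(scope="session")
def nb_stack_015():
    """Compound-Poisson stack, epsilon = 0.15, 64x64x500, fixed seed."""
    return simulate_nb_stack(NBConfig(seed=7, epsilon=0.15, mean_emitters=20.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
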