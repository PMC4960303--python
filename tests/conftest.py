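import numpy as np
import pytest

from isfc import GroupDataset, SimConfig, simulate_group
from isfc.simulate import uniform_correlation


def random_correlation(p: int, rng: np.random.Generator, strength: float = 0.7) -> np.ndarray:
    """A random well-conditioned correlation matrix (Wishart, shrunk to I)."""
    A = rng.standard_normal((p, p))
    C = A @ A.T
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    return strength * C + (1.0 - strength) * np.eye(p)


@pytest.fixture
def rng():
    return np.random.default_rng(20160718)


@pytest.fixture
def toy_dataset(rng):
    """k=3 subjects, p=4 regions, n=8 timepoints of arbitrary real values."""
    return GroupDataset([rng.normal(5, 3, size=(4, 8)) for _ in range(3)],
                        tr_seconds=1.5)


@pytest.fixture
def white_noise_dataset(rng):
    return GroupDataset([rng.standard_normal((10, 300)) for _ in range(6)])


@pytest.fixture
def shared_signal_dataset():
    cfg = SimConfig(k=8, p=6, n=400, stimulus_share=0.6, noise_share=0.1,
                    stimulus_corr=uniform_correlation(6, 0.6),
                    intrinsic_corr=uniform_correlation(6, 0.3), seed=7)
    ds, _ = simulate_group(cfg)
    return ds
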