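import numpy as np
import pytest

from ppidvm import PSSM, synth_pair_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset():
    """120 labelled pairs with a strong texture contrast (effect=3)."""
    return synth_pair_dataset(n_pairs=120, length_range=(25, 50), effect=3.0, seed=42)


@pytest.fixture(scope="session")
def gaussian_task(rng):
    """Two well-separated 2-D Gaussian classes: 100 train / 50 test each."""
    Xtr = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(5, 1, (100, 2))])
    ytr = np.array([1] * 100 + [2] * 100)
    Xte = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(5, 1, (50, 2))])
    yte = np.array([1] * 50 + [2] * 50)
    return Xtr, ytr, Xte, yte


def random_pssm(rng, length=30):
    scores = rng.integers(-16, 14, size=(length, 20))
    return PSSM(protein_id="rand", scores=scores)
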