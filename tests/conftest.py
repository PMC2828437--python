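import numpy as np
import pytest

from rtamhc.alphabet import AMINO_ACIDS
from rtamhc.synthetic import SyntheticSpec, generate_beta, generate_dataset


def aa_index(residue: str) -> int:
    return AMINO_ACIDS.index(residue)


def random_beta(rng: np.random.Generator, scale: float = 1.0) -> np.ndarray:
    return rng.standard_normal((9, 20)) * scale


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[j] for j in rng.integers(0, 20, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_noisy_dataset():
    """A small seeded dataset with noise, shared across training tests."""
    spec = SyntheticSpec(n_peptides=120, noise_sd=1.0, seed=7)
    beta = generate_beta(spec)
    dataset, truth = generate_dataset(beta, spec)
    return beta, dataset, truth
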