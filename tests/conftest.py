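import numpy as np
import pytest

from protseg.synthetic import SyntheticSpec, make_corpus
from protseg.types import ResidueEmbeddingMatrix


@pytest.fixture(scope="session")
def small_noisy_corpus():
    """20 noisy block proteins with planted boundaries (default conditions)."""
    spec = SyntheticSpec(n_proteins=20, seed=11)
    matrices, boundaries, labels = make_corpus(spec)
    return spec, matrices, boundaries, labels


@pytest.fixture(scope="session")
def small_clean_corpus():
    """Noise-free variant of the block corpus: rows equal their block mean."""
    spec = SyntheticSpec(n_proteins=10, seed=11, noise_sd=0.0)
    matrices, boundaries, labels = make_corpus(spec)
    return spec, matrices, boundaries, labels


@pytest.fixture
def two_block_matrix():
    """A clean two-block protein with its single change point at 60."""
    rng = np.random.default_rng(3)
    mu1 = rng.standard_normal(8) * 3
    mu2 = rng.standard_normal(8) * 3
    rows = np.r_[np.tile(mu1, (60, 1)), np.tile(mu2, (60, 1))]
    return ResidueEmbeddingMatrix(protein_id="P2B", values=rows)
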