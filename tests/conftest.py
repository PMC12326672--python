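import numpy as np
import pytest

from gbadti.config import RunConfig
from gbadti.featurize import SimilarityMatrix, KIND_DRUG_DICE, feature_similarity_matrix
from gbadti.io import InteractionSet
from gbadti.simulate import BlockModelSpec, generate_block_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """2x2-block dataset, 12 drugs x 10 proteins, noiseless labels."""
    spec = BlockModelSpec(
        n_drug_clusters=2, n_protein_clusters=2,
        drugs_per_cluster=6, proteins_per_cluster=5,
        d_m=32, d_t=16, bit_flip_rate=0.02, feature_noise=0.05,
        label_noise=0.0, seed=42,
    )
    return generate_block_dataset(spec)


def dice_matrix_from_bits(X, ids):
    """Dice similarity of stacked bit vectors (shared test helper)."""
    B = (np.asarray(X) > 0).astype(np.int64)
    counts = B.sum(1).astype(float)
    inter = (B @ B.T).astype(float)
    denom = counts[:, None] + counts[None, :]
    S = np.where(denom > 0, 2 * inter / np.where(denom > 0, denom, 1), 0.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(S, list(ids), KIND_DRUG_DICE)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
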