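import numpy as np
import pytest

from promoterbench.dataset_builder import RegionSpec
from promoterbench.seqio import GenomeSequence
from promoterbench.synthetic import (
    SyntheticGenomeConfig,
    generate_synthetic_genome,
    planted_motif_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20404)


@pytest.fixture(scope="session")
def synthetic_bundle():
    """A mid-sized synthetic genome with planted promoters on both strands."""
    cfg = SyntheticGenomeConfig(length=50_000, n_promoters=10, seed=1)
    return generate_synthetic_genome(cfg)


@pytest.fixture(scope="session")
def tiny_planted_train():
    """Short planted-TATA windows for fast learnability checks."""
    return planted_motif_dataset(
        150, 150, length=100, region=RegionSpec(79, 20),
        motifs=(("TATAAA", -31),), seed=3,
    )


@pytest.fixture(scope="session")
def tiny_planted_test():
    return planted_motif_dataset(
        80, 80, length=100, region=RegionSpec(79, 20),
        motifs=(("TATAAA", -31),), seed=4,
    )


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
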