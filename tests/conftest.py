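import numpy as np
import pytest

from homclust import ScoringScheme
from homclust._alphabet import CANONICAL_AA
from homclust.io_formats import GenomeSet, ProteinSequence
from homclust.synthdata import EvolutionParams, generate_dataset


@pytest.fixture(scope="session")
def scheme() -> ScoringScheme:
    """Default PAM-224 scheme with the classic thresholds."""
    return ScoringScheme.default()


def random_protein(rng: np.random.Generator, length: int, seq_id="s", genome_id="g"):
    residues = "".join(rng.choice(list(CANONICAL_AA), size=length))
    return ProteinSequence(seq_id, genome_id, residues)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def mini_params(seed: int = 7, **overrides) -> EvolutionParams:
    """A small simulation preset that still exercises fusions, singletons
    and deep divergence, for fast unit tests."""
    defaults = dict(
        n_genomes=3,
        proteins_per_genome=20,
        n_families=8,
        family_size_min=2,
        family_size_max=8,
        length_min=120,
        length_max=250,
        seed=seed,
    )
    defaults.update(overrides)
    return EvolutionParams(**defaults)


@pytest.fixture(scope="session")
def mini_dataset():
    """60-protein simulated dataset shared by cluster/allvsall tests."""
    return generate_dataset(mini_params())


def as_single_genome(seqs, gid="g1") -> GenomeSet:
    return GenomeSet([(gid, list(seqs))])
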