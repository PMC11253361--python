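import numpy as np
import pytest

from afitbin import CommunitySpec, compute_afit_matrix, generate_community
from afitbin.binning import combined_distance_matrix, run_afitbin
from afitbin.coverage import coverage_matrix_from_depth


@pytest.fixture(scope="session")
def default_community():
    """The study-condition community: 8 genomes, 4 samples, ~400 contigs."""
    return generate_community(CommunitySpec())


@pytest.fixture(scope="session")
def default_binning(default_community):
    """Full pipeline run on the default community (seed 1)."""
    com = default_community
    return run_afitbin(list(com.contigs), com.depth, seed=1)


@pytest.fixture(scope="session")
def default_distance(default_community):
    """Combined composition+coverage distance matrix of the default community."""
    com = default_community
    A = compute_afit_matrix(list(com.contigs))
    C = coverage_matrix_from_depth(com.depth.means, com.depth.variances)
    return combined_distance_matrix(A, C)


@pytest.fixture(scope="session")
def small_community():
    """A fast 3-genome community for CLI and IO round-trip tests."""
    return generate_community(
        CommunitySpec(num_genomes=3, num_samples=2, contigs_per_genome=15,
                      genome_length=20_000, seed=7)
    )


def random_sequence(rng: np.random.Generator, length: int, alphabet="ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
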