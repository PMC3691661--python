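import numpy as np
import pytest

from archnuc.simulate import SimConfig, simulate
from archnuc.types import GenomeSequence, MappedRead


@pytest.fixture
def toy_genome() -> GenomeSequence:
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=400))
    return GenomeSequence({"c1": seq})


@pytest.fixture(scope="session")
def small_sim():
    """A compact planted-code simulation reused across tests.

    30 kb keeps individual tests fast while leaving ~380 planted
    dyads, enough for every positional statistic to resolve.
    """
    config = SimConfig(genome_length=30_000, n_genes=25, n_nucleosomes=500,
                       n_reads=30_000, seed=11)
    return simulate(config)


def random_reads(rng: np.random.Generator, contig: str, n_bp: int, n_reads: int,
                 lengths=(55, 65)) -> list[MappedRead]:
    reads = []
    for _ in range(n_reads):
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        start = int(rng.integers(0, n_bp - length))
        reads.append(MappedRead(contig, start, start + length))
    return reads
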