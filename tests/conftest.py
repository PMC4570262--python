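import numpy as np
import pytest

from leon import build_graph, count_kmers, solid_kmers
from leon.simulate import SimulationSpec, generate_genome, simulate_reads

K_TOY = 21


def revcomp_str(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def canon_str(s: str) -> str:
    r = revcomp_str(s)
    return s if s <= r else r


class ExactDBG:
    """Independent set-based de Bruijn graph oracle (no Bloom filter)."""

    def __init__(self, sequences, k: int):
        self.k = k
        self.nodes = set()
        for seq in sequences:
            for i in range(len(seq) - k + 1):
                self.nodes.add(canon_str(seq[i:i + k]))

    def __contains__(self, kmer: str) -> bool:
        return canon_str(kmer) in self.nodes

    def successors_of(self, kmer: str):
        return [b for b in "ACGT" if (kmer[1:] + b) in self]

    def predecessors_of(self, kmer: str):
        return [b for b in "ACGT" if (b + kmer[:-1]) in self]


@pytest.fixture(scope="session")
def toy_genome():
    return generate_genome(5000, seed=11)


@pytest.fixture(scope="session")
def toy_graph(toy_genome):
    """Near-exact graph of the toy genome's kmers (b=16 keeps FPs ~5e-4)."""
    table = count_kmers([toy_genome], K_TOY)
    return build_graph(solid_kmers(table, 1), b=16, k=K_TOY)


@pytest.fixture(scope="session")
def toy_oracle(toy_genome):
    return ExactDBG([toy_genome], K_TOY)


@pytest.fixture(scope="session")
def small_sim():
    """20 kb genome, 50x, 1% substitutions: genome, spec, simulated records."""
    spec = SimulationSpec(genome_length=20_000, coverage=50.0, read_length=100,
                          substitution_rate=0.01, seed=7)
    genome = generate_genome(spec.genome_length, spec.seed)
    return genome, spec, simulate_reads(genome, spec)


@pytest.fixture(scope="session")
def small_sim_fastq(small_sim, tmp_path_factory):
    from leon import write_fastq
    path = tmp_path_factory.mktemp("sim") / "small.fastq"
    write_fastq(small_sim[2], path)
    return path
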