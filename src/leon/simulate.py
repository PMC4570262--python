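"""Deterministic synthetic genomes and read sets with known ground truth.

Reads are sampled uniformly from both strands of a random genome, with
per-base substitution errors and a simple position-dependent quality profile;
erroneous bases draw their quality from a low tail so that tests can reason
about the lossy quality transform.  Headers carry the ground truth:
``sim.<i> <pos>/<strand>``.  Identical spec + seed always produces a
byte-identical FASTQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._util import seq_to_codes
from .container import ReadRecord, write_fastq

_BASES = np.frombuffer(b"ACGT", np.uint8)


@dataclass
class SimulationSpec:
    genome_length: int = 100_000
    coverage: float = 50.0
    read_length: int = 100
    substitution_rate: float = 0.01
    mean_quality_start: float = 38.0
    mean_quality_end: float = 33.0
    quality_noise_sd: float = 2.0
    error_quality_mean: float = 12.0
    error_quality_sd: float = 3.0
    seed: int = 0


def generate_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. ACGT string from a seeded generator."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, length)].tobytes().decode("ascii")


def inject_repeat(genome: str, src: int, length: int, dest: int) -> str:
    """Copy a segment elsewhere to plant true graph branch points."""
    seg = genome[src:src + length]
    return genome[:dest] + seg + genome[dest + length:]


def simulate_read_arrays(genome: str, spec: SimulationSpec):
    """Vectorized core; returns (seq_codes n*l, qual_codes n*l, pos, strand,
    err_mask)."""
    g = seq_to_codes(genome)
    gl = g.size
    l = spec.read_length
    if l > gl:
        raise ValueError("read length exceeds genome length")
    n = math.ceil(spec.coverage * gl / l)
    rng = np.random.default_rng(spec.seed)
    pos = rng.integers(0, gl - l + 1, n)
    strand = rng.integers(0, 2, n)
    mat = g[pos[:, None] + np.arange(l)[None, :]]
    rev = strand == 1
    mat[rev] = 3 - mat[rev][:, ::-1]
    err = rng.random((n, l), dtype=np.float32) < spec.substitution_rate
    shift = rng.integers(1, 4, (n, l), dtype=np.uint8)
    mat[err] = (mat[err] + shift[err]) % 4
    # qualities
    meanq = np.linspace(spec.mean_quality_start, spec.mean_quality_end, l,
                        dtype=np.float32)
    q = meanq[None, :] + rng.standard_normal((n, l), dtype=np.float32) \
        * spec.quality_noise_sd
    ne = int(err.sum())
    q[err] = (spec.error_quality_mean
              + rng.standard_normal(ne, dtype=np.float32) * spec.error_quality_sd)
    q = np.clip(np.rint(q), 2, 41).astype(np.uint8) + 33
    return mat, q, pos, strand, err


def simulate_reads(genome: str, spec: SimulationSpec) -> list[ReadRecord]:
    """ceil(coverage * G / read_length) FASTQ records with ground-truth
    headers ``sim.<i> <pos>/<strand>``."""
    mat, q, pos, strand, _ = simulate_read_arrays(genome, spec)
    seqs = _BASES[mat]
    records = []
    for i in range(mat.shape[0]):
        records.append(ReadRecord(
            header=f"sim.{i} {pos[i]}/{strand[i]}",
            sequence=seqs[i].tobytes().decode("ascii"),
            quality=q[i].tobytes().decode("ascii")))
    return records


def simulate_fastq(path, spec: SimulationSpec, genome: str | None = None) -> str:
    """Generate (or reuse) a genome, simulate reads and write a FASTQ file.
    Returns the genome so callers keep the ground truth."""
    if genome is None:
        genome = generate_genome(spec.genome_length, spec.seed)
    write_fastq(simulate_reads(genome, spec), path)
    return genome
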