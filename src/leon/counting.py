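"""Canonical kmer counting, abundance histogram and solidity threshold.

Counting is fully in memory (arrays of packed kmers sorted by ``numpy``),
which is adequate up to ~1e8 distinct kmers; the disk-based partitioned
counters used by large-scale tools are deliberately out of scope.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from ._util import flatten_seqs
from .kmer_model import Kmer, canonical, encode

DEFAULT_FALLBACK_T_SOL = 3
T_SOL_MIN, T_SOL_MAX = 2, 20


class KmerCountTable:
    """Occurrence counts of canonical kmers, stored as parallel sorted arrays."""

    def __init__(self, kmers: np.ndarray, counts: np.ndarray, k: int):
        self.kmers = kmers          # uint64, sorted ascending
        self.counts = counts        # int64
        self.k = k

    def __len__(self) -> int:
        return int(self.kmers.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count_of(self, kmer: Kmer | str) -> int:
        if isinstance(kmer, str):
            kmer = encode(kmer)
        key = np.uint64(canonical(kmer).value)
        i = int(np.searchsorted(self.kmers, key))
        if i < self.kmers.size and self.kmers[i] == key:
            return int(self.counts[i])
        return 0

    def items(self):
        for v, c in zip(self.kmers, self.counts):
            yield Kmer(int(v), self.k), int(c)

    def as_dict(self) -> dict[str, int]:
        return {str(km): c for km, c in self.items()}


class AbundanceHistogram:
    """Map abundance -> number of distinct canonical kmers at that abundance."""

    def __init__(self, h: dict[int, int]):
        self.h = dict(sorted(h.items()))

    def __getitem__(self, a: int) -> int:
        return self.h.get(a, 0)

    def __len__(self) -> int:
        return len(self.h)

    def __eq__(self, other) -> bool:
        if isinstance(other, AbundanceHistogram):
            return self.h == other.h
        return self.h == other

    def total_distinct(self) -> int:
        return sum(self.h.values())


def count_kmers(reads, k: int) -> KmerCountTable:
    """Count canonical kmers over all reads; windows touching an N are skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    reads = list(reads)
    if not reads:
        return KmerCountTable(np.empty(0, np.uint64), np.empty(0, np.int64), k)
    codes, starts, ends = flatten_seqs(reads)
    out = np.empty(codes.size, np.uint64)
    n = _kernels.extract_canonical(codes, starts, ends, k, out)
    kmers, counts = np.unique(out[:n], return_counts=True)
    return KmerCountTable(kmers, counts.astype(np.int64), k)


def histogram(table: KmerCountTable) -> AbundanceHistogram:
    if len(table) == 0:
        return AbundanceHistogram({})
    abund, ndistinct = np.unique(table.counts, return_counts=True)
    return AbundanceHistogram({int(a): int(c) for a, c in zip(abund, ndistinct)})


def infer_solidity_threshold(h: AbundanceHistogram) -> int:
    """Abundance of the valley between the low-abundance error peak and the
    genomic coverage peak.

    The scan runs over the abundances actually present, in increasing order:
    the genomic peak is the most populated abundance after the first entry,
    and the threshold is the first abundance attaining the minimum between
    the start and that peak.  A histogram with no such valley (monotonically
    decreasing counts, e.g. very low coverage data) falls back to 3.  The
    result is clamped to [2, 20].
    """
    if len(h) == 0:
        raise ValueError("empty abundance histogram")
    abund = list(h.h.keys())
    counts = list(h.h.values())
    if len(abund) < 3:
        return DEFAULT_FALLBACK_T_SOL
    # genomic peak: most populated abundance, excluding the first (error) entry
    peak = 1 + int(np.argmax(counts[1:]))
    if peak <= 1:
        return DEFAULT_FALLBACK_T_SOL  # unimodal: counts decrease from the start
    valley_slice = counts[1:peak + 1]
    valley = 1 + int(np.argmin(valley_slice))
    if counts[valley] >= counts[peak]:
        return DEFAULT_FALLBACK_T_SOL
    return int(min(max(abund[valley], T_SOL_MIN), T_SOL_MAX))


def solid_kmers(table: KmerCountTable, t_sol: int) -> np.ndarray:
    """Canonical kmers with count >= ``t_sol`` (t_sol is the minimum solid
    abundance), as a sorted uint64 array."""
    if t_sol < 1:
        raise ValueError("t_sol must be >= 1")
    return table.kmers[table.counts >= t_sol]


def solid_kmer_set(table: KmerCountTable, t_sol: int) -> set[Kmer]:
    """Set-of-:class:`Kmer` view of :func:`solid_kmers` (test-friendly)."""
    return {Kmer(int(v), table.k) for v in solid_kmers(table, t_sol)}
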