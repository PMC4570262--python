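"""Probabilistic de Bruijn graph: solid kmers held in a Bloom filter.

The node set is approximate (one-sided error): every solid kmer answers
present, non-members answer present with probability ~(1 - e^{-h n/m})^h.
False positives only cost extra bifurcation symbols downstream, so no
exactness structure is layered on top.
"""

from __future__ import annotations

import math
import struct

import numpy as np

from . import _kernels
from .kmer_model import Kmer, canonical, successors

DEFAULT_BITS_PER_KMER = 12
DEFAULT_SEED1 = 0x5555DEADBEEF1234
DEFAULT_SEED2 = 0x8BADF00DCAFE9876

_MAGIC = b"LBLM"
_HEADER = struct.Struct("<4sQBBQQQ")  # magic, m, h, k, seed1, seed2, n_inserted

_M64 = (1 << 64) - 1


def _hash64_py(x: int, seed: int) -> int:
    """Python mirror of the compiled splitmix64-style hash (bit-exact)."""
    z = ((x + seed) * 0x9E3779B97F4A7C15) & _M64
    z ^= z >> 30
    z = (z * 0xBF58476D1CE4E5B9) & _M64
    z ^= z >> 27
    z = (z * 0x94D049BB133111EB) & _M64
    z ^= z >> 31
    return z


class BloomFilter:
    """Bit array + h hash positions per key (Kirsch-Mitzenmacher combination)."""

    def __init__(self, m: int, h: int, seed1: int = DEFAULT_SEED1,
                 seed2: int = DEFAULT_SEED2):
        if m < 8:
            m = 8
        self.m = int(m)
        self.h = int(h)
        self.seed1 = seed1
        self.seed2 = seed2
        self.n_inserted = 0
        self.bits = np.zeros((self.m + 7) // 8, dtype=np.uint8)

    def add_many(self, keys: np.ndarray) -> None:
        keys = np.ascontiguousarray(keys, dtype=np.uint64)
        _kernels.bloom_insert_many(self.bits, np.uint64(self.m), self.h,
                                   np.uint64(self.seed1), np.uint64(self.seed2), keys)
        self.n_inserted += int(keys.size)

    def __contains__(self, key: int) -> bool:
        p = _hash64_py(key, self.seed1) % self.m
        step = _hash64_py(key, self.seed2) % self.m or 1
        for _ in range(self.h):
            if not (self.bits[p >> 3] >> (p & 7)) & 1:
                return False
            p = (p + step) % self.m
        return True

    def contains_many(self, keys: np.ndarray) -> np.ndarray:
        keys = np.ascontiguousarray(keys, dtype=np.uint64)
        return _kernels.bloom_contains_many(
            self.bits, np.uint64(self.m), self.h,
            np.uint64(self.seed1), np.uint64(self.seed2), keys).astype(bool)


class ProbabilisticDBG:
    """Bloom-backed de Bruijn graph over canonical solid kmers."""

    def __init__(self, bloom: BloomFilter, k: int):
        self.bloom = bloom
        self.k = k

    def serialize(self) -> bytes:
        b = self.bloom
        header = _HEADER.pack(_MAGIC, b.m, b.h, self.k, b.seed1, b.seed2, b.n_inserted)
        return header + b.bits.tobytes()

    @classmethod
    def deserialize(cls, data: bytes) -> "ProbabilisticDBG":
        if len(data) < _HEADER.size:
            raise FormatError("truncated graph section")
        magic, m, h, k, s1, s2, n = _HEADER.unpack_from(data)
        if magic != _MAGIC:
            raise FormatError("bad graph magic")
        if len(data) != _HEADER.size + (m + 7) // 8:
            raise FormatError("graph section length mismatch")
        bloom = BloomFilter(m, h, s1, s2)
        bloom.n_inserted = n
        bloom.bits = np.frombuffer(data, dtype=np.uint8, offset=_HEADER.size).copy()
        return cls(bloom, k)


class FormatError(ValueError):
    """Raised on malformed serialized graph / container sections."""


def build_graph(solid, b: int = DEFAULT_BITS_PER_KMER, k: int | None = None,
                seed1: int = DEFAULT_SEED1, seed2: int = DEFAULT_SEED2) -> ProbabilisticDBG:
    """Insert the canonical solid kmers into a fresh Bloom filter.

    ``m`` is b bits per solid kmer rounded up to a byte multiple and
    ``h = round(b ln 2)`` (at the default b=12 this gives 8 hash functions).
    """
    if b < 1:
        raise ValueError("bits per kmer must be >= 1")
    if isinstance(solid, np.ndarray):
        keys = np.ascontiguousarray(solid, dtype=np.uint64)
        if k is None:
            raise ValueError("k required when passing a raw kmer array")
    else:
        solid = list(solid)
        if not solid:
            raise ValueError("no solid kmers: lower the solidity threshold (T_sol)")
        ks = {x.k for x in solid}
        if len(ks) != 1:
            raise ValueError("mixed kmer lengths")
        k = ks.pop()
        keys = np.array([canonical(x).value for x in solid], dtype=np.uint64)
    if keys.size == 0:
        raise ValueError("no solid kmers: lower the solidity threshold (T_sol)")
    m = ((int(keys.size) * int(b) + 7) // 8) * 8
    h = max(1, round(b * math.log(2)))
    bloom = BloomFilter(m, h, seed1, seed2)
    bloom.add_many(keys)
    return ProbabilisticDBG(bloom, k)


def contains(g: ProbabilisticDBG, x: Kmer) -> bool:
    """Canonical-kmer membership; true for every inserted kmer (no false
    negatives) and for either strand of it."""
    return canonical(x).value in g.bloom


def graph_successors(g: ProbabilisticDBG, x: Kmer) -> list[Kmer]:
    """Those of the 4 successor kmers whose canonical form is present,
    in A < C < G < T order (may include Bloom false positives)."""
    return [y for y in successors(x) if contains(g, y)]
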