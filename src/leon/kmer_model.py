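"""2-bit packed kmers and the de Bruijn edge relation.

Bases are encoded A=0, C=1, G=2, T=3 with the leftmost base occupying the
most-significant bit pair, so the integer order of two equal-length kmers is
their lexicographic order under A < C < G < T.  ``k`` may range from 1 to 63
(values above 31 are supported by this module but not by the compiled
compression pipeline, which packs a kmer into a single 64-bit word).
"""

from __future__ import annotations

from dataclasses import dataclass

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

MAX_K = 63


@dataclass(frozen=True, order=True)
class Kmer:
    """A DNA word of length ``k`` packed 2 bits per base."""

    value: int
    k: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")
        if not 0 <= self.value < (1 << (2 * self.k)):
            raise ValueError("kmer value out of range for k")

    @classmethod
    def from_string(cls, seq: str) -> "Kmer":
        return encode(seq)

    def __str__(self) -> str:
        return decode(self)


def encode(seq: str) -> Kmer:
    """Pack a string over {A,C,G,T} into a :class:`Kmer`.

    Raises ``ValueError`` on any other character; callers are expected to have
    masked N's beforehand (the sequence codec records their positions in a
    side stream).
    """
    v = 0
    for ch in seq:
        try:
            v = (v << 2) | _CODE[ch]
        except KeyError:
            raise ValueError(f"non-ACGT character {ch!r} in kmer") from None
    return Kmer(v, len(seq))


def decode(x: Kmer) -> str:
    return "".join(_BASES[(x.value >> (2 * (x.k - 1 - i))) & 3] for i in range(x.k))


def reverse_complement(x: Kmer) -> Kmer:
    """Involution: base i of the result is the complement of base k-1-i."""
    v = x.value
    out = 0
    for _ in range(x.k):
        out = (out << 2) | (3 - (v & 3))
        v >>= 2
    return Kmer(out, x.k)


def canonical(x: Kmer) -> Kmer:
    """The smaller of ``x`` and its reverse complement in 2-bit integer order.

    This is the strand-neutral identity used for graph membership; the class
    {x, rc(x)} always maps to the same representative.
    """
    y = reverse_complement(x)
    return x if x.value <= y.value else y


def kmerize(seq: str, k: int) -> list[Kmer]:
    """The l-k+1 consecutive kmers of ``seq``; empty when the read is shorter
    than k (such reads fall back to raw encoding)."""
    if len(seq) < k:
        return []
    return [encode(seq[i:i + k]) for i in range(len(seq) - k + 1)]


def successors(x: Kmer) -> list[Kmer]:
    """The 4 kmers whose (k-1)-prefix is the (k-1)-suffix of ``x``, in
    A < C < G < T order."""
    base = (x.value << 2) & ((1 << (2 * x.k)) - 1)
    return [Kmer(base | b, x.k) for b in range(4)]


def predecessors(x: Kmer) -> list[Kmer]:
    """The 4 kmers whose (k-1)-suffix is the (k-1)-prefix of ``x``."""
    low = x.value >> 2
    return [Kmer((b << (2 * (x.k - 1))) | low, x.k) for b in range(4)]
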