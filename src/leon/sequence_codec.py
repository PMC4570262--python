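"""Read <-> graph-path codec.

Each read is represented by an anchor (a solid kmer shared across reads via
an insertion-ordered dictionary), its position, the read length, and two
bifurcation lists describing the walk right and left of the anchor.  Reads
with no dictionary hit and no solid kmer — or shorter than k — fall back to
raw 2-bit sequence.

Two routes exist on purpose: the per-read functions here are a plain-Python
reference implementation, and :func:`encode_block_streams` /
:func:`decode_block_streams` drive the compiled block kernels used by the
CLI.  The test suite checks that both produce identical streams.

Walk rules at each step (S = graph-present successors of the current kmer,
c = the read's next base):

* c in S and |S| == 1 — simple path, nothing emitted;
* c in S and |S| >= 2 — true bifurcation: emit c;
* c not in S — emit c together with its read position (sequencing-error
  case).  The walk then continues on the unique graph successor when there
  is exactly one (the "corrected" path, so an isolated substitution costs a
  single event), otherwise on the read's own kmer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import types
from numba.typed import Dict as NumbaDict

from . import _kernels
from .kmer_model import Kmer, kmerize, predecessors, successors
from .probabilistic_dbg import ProbabilisticDBG, contains

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def mask_n(seq: str) -> tuple[str, list[int]]:
    """Replace N by A, returning the masked read and the N offsets."""
    if "N" not in seq:
        return seq, []
    positions = [i for i, ch in enumerate(seq) if ch == "N"]
    return seq.replace("N", "A"), positions


def unmask_n(seq: str, positions: list[int]) -> str:
    if not positions:
        return seq
    out = list(seq)
    for p in positions:
        out[p] = "N"
    return "".join(out)


class AnchorDictionary:
    """Insertion-ordered set of oriented anchor kmers with integer indices.

    Anchors are stored in the read's forward orientation (not canonical) so
    decoding needs no orientation flag.
    """

    def __init__(self, k: int):
        self.k = k
        self._entries: list[int] = []
        self._index: dict[int, int] = {}
        self._ndict = NumbaDict.empty(types.uint64, types.int64)

    def __len__(self) -> int:
        return len(self._entries)

    def get(self, kmer: Kmer) -> int | None:
        return self._index.get(kmer.value)

    def add(self, kmer: Kmer) -> int:
        """Append a new anchor; returns its index (entries stay unique)."""
        v = kmer.value
        existing = self._index.get(v)
        if existing is not None:
            return existing
        idx = len(self._entries)
        self._entries.append(v)
        self._index[v] = idx
        self._ndict[np.uint64(v)] = idx
        return idx

    def entry(self, idx: int) -> Kmer:
        return Kmer(self._entries[idx], self.k)

    def values_array(self) -> np.ndarray:
        return np.array(self._entries, dtype=np.uint64)

    def extend_from_array(self, kmers: np.ndarray) -> None:
        """Sync python-side state after the block kernel inserted new anchors."""
        for v in kmers:
            v = int(v)
            if v not in self._index:
                idx = len(self._entries)
                self._entries.append(v)
                self._index[v] = idx

    @classmethod
    def from_array(cls, kmers: np.ndarray, k: int) -> "AnchorDictionary":
        d = cls(k)
        for v in kmers:
            d.add(Kmer(int(v), k))
        return d


@dataclass
class BifurcationEvent:
    nucleotide: str
    position: int | None = None  # set only for error-type (graph-absent) events


@dataclass
class EncodedRead:
    mode: str  # "anchored" | "raw"
    read_length: int
    anchor_index: int = 0
    anchor_position: int = 0
    left_events: list[BifurcationEvent] = field(default_factory=list)
    right_events: list[BifurcationEvent] = field(default_factory=list)
    n_positions: list[int] = field(default_factory=list)
    raw_seq: str = ""


def select_anchor(read: str, dictionary: AnchorDictionary,
                  g: ProbabilisticDBG) -> tuple[int, int] | None:
    """Leftmost dictionary hit; otherwise the leftmost solid kmer is appended
    to the dictionary; otherwise None (raw mode).  ``read`` must be N-masked.
    """
    kms = kmerize(read, g.k)
    first_solid = None
    for pos, km in enumerate(kms):
        idx = dictionary.get(km)
        if idx is not None:
            return idx, pos
        if first_solid is None and contains(g, km):
            first_solid = pos
    if first_solid is None:
        return None
    return dictionary.add(kms[first_solid]), first_solid


def _present_successors(g: ProbabilisticDBG, cur: Kmer) -> list[int]:
    return [b for b, y in enumerate(successors(cur)) if contains(g, y)]


def _present_predecessors(g: ProbabilisticDBG, cur: Kmer) -> list[int]:
    return [b for b, y in enumerate(predecessors(cur)) if contains(g, y)]


def encode_read(read: str, anchor: tuple[int, int], g: ProbabilisticDBG,
                n_positions: list[int] | None = None) -> EncodedRead:
    """Walk the graph right then left of the anchor, collecting bifurcation
    events.  ``read`` must be N-masked; always succeeds for an anchored read.
    """
    k = g.k
    anchor_index, a = anchor
    e = EncodedRead(mode="anchored", read_length=len(read),
                    anchor_index=anchor_index, anchor_position=a,
                    n_positions=list(n_positions or []))
    kms = kmerize(read, k)
    # right leg
    cur = kms[a]
    for i in range(a, len(kms) - 1):
        c = _CODE[read[i + k]]
        present = _present_successors(g, cur)
        cand = successors(cur)[c]
        if c in present:
            if len(present) > 1:
                e.right_events.append(BifurcationEvent(_BASES[c]))
            cur = cand
        else:
            e.right_events.append(BifurcationEvent(_BASES[c], i + k))
            cur = successors(cur)[present[0]] if len(present) == 1 else cand
    # left leg
    cur = kms[a]
    for j in range(a, 0, -1):
        c = _CODE[read[j - 1]]
        present = _present_predecessors(g, cur)
        cand = predecessors(cur)[c]
        if c in present:
            if len(present) > 1:
                e.left_events.append(BifurcationEvent(_BASES[c]))
            cur = cand
        else:
            e.left_events.append(BifurcationEvent(_BASES[c], j - 1))
            cur = predecessors(cur)[present[0]] if len(present) == 1 else cand
    return e


def _decode_leg(out: list, g: ProbabilisticDBG, akm: Kmer, a: int,
                events: list[BifurcationEvent], rightward: bool) -> None:
    neighbors = successors if rightward else predecessors
    err_positions = [ev.position for ev in events if ev.position is not None]
    ev_iter = iter(events)
    err_iter = iter(err_positions)
    pending_err = next(err_iter, None)
    k = g.k
    l = len(out)
    span = range(a, l - k) if rightward else range(a, 0, -1)
    cur = akm
    for i in span:
        pos = i + k if rightward else i - 1
        present = [b for b, y in enumerate(neighbors(cur)) if contains(g, y)]
        if pending_err is not None and pending_err == pos:
            ev = next(ev_iter)
            c = _CODE[ev.nucleotide]
            pending_err = next(err_iter, None)
            cur = neighbors(cur)[present[0] if len(present) == 1 else c]
        elif len(present) == 1:
            c = present[0]
            cur = neighbors(cur)[c]
        elif len(present) > 1:
            ev = next(ev_iter, None)
            if ev is None:
                raise ValueError("bifurcation list exhausted while graph ambiguous")
            c = _CODE[ev.nucleotide]
            cur = neighbors(cur)[c]
        else:
            raise ValueError("graph dead end without recorded error event")
        out[pos] = _BASES[c]


def decode_read(e: EncodedRead, dictionary: AnchorDictionary,
                g: ProbabilisticDBG) -> str:
    """Reconstruct a read from its encoding; exact inverse of
    :func:`encode_read` against the same graph and dictionary."""
    if e.mode == "raw":
        return unmask_n(e.raw_seq, e.n_positions)
    a = e.anchor_position
    out = [""] * e.read_length
    akm = dictionary.entry(e.anchor_index)
    for j, ch in enumerate(str(akm)):
        out[a + j] = ch
    _decode_leg(out, g, akm, a, e.right_events, rightward=True)
    _decode_leg(out, g, akm, a, e.left_events, rightward=False)
    return unmask_n("".join(out), e.n_positions)


@dataclass
class BlockStreams:
    """Flat per-block component streams produced by the block kernel."""

    n_reads: int
    lengths: np.ndarray        # int64 per read
    mode: np.ndarray           # uint8 per read: 0 anchored, 1 raw
    anchor_idx: np.ndarray     # int64 per anchored slot (dense per read)
    anchor_pos: np.ndarray
    re_counts: np.ndarray      # error events per read, right leg
    le_counts: np.ndarray
    right_nucs: np.ndarray     # uint8 2-bit symbols, walk order
    right_errs: np.ndarray     # int64 absolute read offsets, walk order
    left_nucs: np.ndarray
    left_errs: np.ndarray
    raw_codes: np.ndarray      # uint8 2-bit symbols of raw-mode reads
    new_anchors: np.ndarray    # uint64 kmers appended to the dictionary


def encode_block_streams(codes: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                         g: ProbabilisticDBG, dictionary: AnchorDictionary) -> BlockStreams:
    """Kernel-backed encoder for a block of reads (codes may contain 4 = N;
    the caller records N positions separately)."""
    nr = starts.size
    total = int(codes.size)
    lengths = ends - starts
    max_l = int(lengths.max()) if nr else 0
    km = np.empty(max(max_l, 1), np.uint64)
    mode = np.zeros(nr, np.uint8)
    anchor_idx = np.zeros(nr, np.int64)
    anchor_pos = np.zeros(nr, np.int64)
    rn_counts = np.zeros(nr, np.int64)
    re_counts = np.zeros(nr, np.int64)
    ln_counts = np.zeros(nr, np.int64)
    le_counts = np.zeros(nr, np.int64)
    right_nucs = np.empty(total, np.uint8)
    right_errs = np.empty(total, np.int64)
    left_nucs = np.empty(total, np.uint8)
    left_errs = np.empty(total, np.int64)
    raw_codes = np.empty(total, np.uint8)
    new_anchors = np.empty(max(nr, 1), np.uint64)
    b = g.bloom
    _, n_rn, n_re, n_ln, n_le, n_raw, n_new = _kernels.encode_block(
        codes, starts, ends, g.k, b.bits, np.uint64(b.m), b.h,
        np.uint64(b.seed1), np.uint64(b.seed2),
        dictionary._ndict, len(dictionary), km,
        mode, anchor_idx, anchor_pos,
        rn_counts, re_counts, ln_counts, le_counts,
        right_nucs, right_errs, left_nucs, left_errs,
        raw_codes, new_anchors)
    dictionary.extend_from_array(new_anchors[:n_new])
    return BlockStreams(
        n_reads=nr, lengths=lengths.astype(np.int64), mode=mode,
        anchor_idx=anchor_idx, anchor_pos=anchor_pos,
        re_counts=re_counts, le_counts=le_counts,
        right_nucs=right_nucs[:n_rn].copy(), right_errs=right_errs[:n_re].copy(),
        left_nucs=left_nucs[:n_ln].copy(), left_errs=left_errs[:n_le].copy(),
        raw_codes=raw_codes[:n_raw].copy(), new_anchors=new_anchors[:n_new].copy())


def decode_block_streams(streams: BlockStreams, dict_entries: np.ndarray,
                         g: ProbabilisticDBG) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kernel-backed inverse of :func:`encode_block_streams`; returns
    (codes, starts, ends).  Raises on container corruption."""
    lengths = streams.lengths
    ends = np.cumsum(lengths)
    starts = ends - lengths
    out_codes = np.zeros(int(ends[-1]) if lengths.size else 0, np.uint8)
    b = g.bloom
    rc = _kernels.decode_block(
        out_codes, starts, ends, g.k, b.bits, np.uint64(b.m), b.h,
        np.uint64(b.seed1), np.uint64(b.seed2),
        np.ascontiguousarray(dict_entries, dtype=np.uint64),
        streams.mode, streams.anchor_idx, streams.anchor_pos,
        streams.re_counts, streams.le_counts,
        streams.right_nucs, streams.right_errs,
        streams.left_nucs, streams.left_errs,
        streams.raw_codes)
    if rc != 0:
        raise ValueError(f"corrupt sequence streams (decode error {rc})")
    return out_codes, starts, ends
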