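"""Lossy (default) or lossless quality-score compression.

Lossy mode uses the solid-kmer evidence already computed for the sequences:
(1) every quality above the cap character '@' (Phred+33 score 31) is replaced
by '@'; (2) every position covered by at least sigma solid kmers is replaced
by '@', where sigma depends on how far below the cap the original quality
was: with delta = code('@') - code(q), sigma = 2 if delta <= 10 and
delta - 5 otherwise (upgrading a low quality needs more evidence).  The
resulting stream is DEFLATE-compressed with zlib, per-read strings joined by
newlines.
"""

from __future__ import annotations

import zlib

import numpy as np

from . import _kernels
from ._util import seq_to_codes
from .probabilistic_dbg import ProbabilisticDBG

CAP_CHAR = "@"
CAP_CODE = ord(CAP_CHAR)  # ASCII 64, Phred+33 score 31
ZLIB_LEVEL = 9


def sigma(original_quality) -> int:
    """Required solid-kmer coverage for smoothing a position with this
    original (pre-truncation) quality.  delta <= 10 (including qualities at
    or above the cap) gives 2; lower qualities give delta - 5."""
    code = ord(original_quality) if isinstance(original_quality, str) else int(original_quality)
    delta = CAP_CODE - code
    return 2 if delta <= 10 else delta - 5


def _sigma_vec(qcodes: np.ndarray) -> np.ndarray:
    delta = CAP_CODE - qcodes.astype(np.int32)
    return np.where(delta <= 10, 2, delta - 5)


def solid_coverage(read: str, g: ProbabilisticDBG) -> np.ndarray:
    """Per-position count of graph-member kmers overlapping each base of the
    (N-masked) read; all zeros when the read is shorter than k."""
    codes = seq_to_codes(read)
    l = codes.size
    cov = np.zeros(l, np.int32)
    if l < g.k:
        return cov
    starts = np.zeros(1, np.int64)
    ends = np.array([l], np.int64)
    wbuf = np.zeros(l + 2, np.int64)
    b = g.bloom
    _kernels.solid_coverage_block(codes, starts, ends, g.k, b.bits,
                                  np.uint64(b.m), b.h,
                                  np.uint64(b.seed1), np.uint64(b.seed2),
                                  wbuf, cov)
    return cov


def smooth_block(qcodes: np.ndarray, coverage: np.ndarray) -> np.ndarray:
    """Vectorized lossy transform of a flat block of quality codes."""
    sig = _sigma_vec(qcodes)
    out = np.minimum(qcodes, CAP_CODE).astype(np.uint8)
    out[coverage >= sig] = CAP_CODE
    return out


def smooth_qualities(quals: str, read: str, g: ProbabilisticDBG) -> str:
    """Lossy smoothing of one read's quality string (see module docstring)."""
    qcodes = np.frombuffer(quals.encode("ascii"), np.uint8)
    cov = solid_coverage(read, g)
    return smooth_block(qcodes, cov).tobytes().decode("ascii")


def compress_quality_stream(quals, mode: str = "lossy",
                            reads=None, g: ProbabilisticDBG | None = None) -> bytes:
    """DEFLATE the concatenated (newline-delimited) quality strings.

    ``mode="lossy"`` smooths each string against the graph first (``reads``
    and ``g`` required); ``mode="lossless"`` skips smoothing entirely.
    """
    quals = list(quals)
    if mode == "lossy":
        if reads is None or g is None:
            raise ValueError("lossy mode needs the reads and the graph")
        quals = [smooth_qualities(q, r, g) for q, r in zip(quals, list(reads))]
    elif mode != "lossless":
        raise ValueError(f"unknown quality mode {mode!r}")
    payload = "\n".join(quals).encode("ascii")
    return zlib.compress(payload, ZLIB_LEVEL)


def decompress_quality_stream(data: bytes, lengths) -> list[str]:
    """Inverse of :func:`compress_quality_stream`; validates per-read lengths."""
    lengths = list(lengths)
    payload = zlib.decompress(data).decode("ascii")
    quals = payload.split("\n") if (payload or lengths) else []
    if len(quals) != len(lengths) or any(len(q) != l for q, l in zip(quals, lengths)):
        raise ValueError("quality stream does not match read lengths")
    return quals
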