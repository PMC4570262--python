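"""Order-0 adaptive arithmetic (range) coding.

A 32-bit range coder with LZMA-style carry handling; the model is a flat
frequency table initialized to 1 per symbol, incremented after each coded
symbol and halved (floor 1) when the total passes 2^16.  Encoder and decoder
evolve the model identically symbol by symbol, so a fresh model instance with
the same alphabet is all that is needed to decode.
"""

from __future__ import annotations

import numpy as np

from . import _kernels

MODEL_INCREMENT = 16
RESCALE_LIMIT = 1 << 16


class CorruptStreamError(ValueError):
    """Raised when a coded stream cannot be decoded (e.g. truncation)."""


class FrequencyModel:
    """Adaptive per-symbol counts for one component stream."""

    def __init__(self, alphabet_size: int, increment: int = MODEL_INCREMENT,
                 rescale_limit: int = RESCALE_LIMIT):
        if alphabet_size < 1:
            raise ValueError("alphabet size must be >= 1")
        self.alphabet_size = alphabet_size
        self.increment = increment
        self.rescale_limit = rescale_limit
        self.counts = np.ones(alphabet_size, dtype=np.uint32)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def probability(self, symbol: int) -> float:
        return float(self.counts[symbol]) / self.total

    def update(self, symbol: int) -> None:
        """Advance the model past one symbol (what the coder does internally)."""
        self.counts[symbol] += self.increment
        if self.counts.sum() >= self.rescale_limit:
            self.counts = (self.counts + 1) >> 1


def arith_encode(symbols, model: FrequencyModel) -> bytes:
    """Encode a symbol sequence; the model is mutated (adapted) in place."""
    arr = np.ascontiguousarray(symbols, dtype=np.uint32)
    if arr.size == 0:
        return b""
    if arr.max() >= model.alphabet_size:
        raise ValueError("symbol out of alphabet range")
    out = _kernels.rc_encode(arr, model.counts, model.increment, model.rescale_limit)
    return out.tobytes()


def arith_decode(data: bytes, n: int, model: FrequencyModel) -> np.ndarray:
    """Decode ``n`` symbols; inverse of :func:`arith_encode` for a model
    initialized identically to the encoder's."""
    if n == 0:
        return np.empty(0, dtype=np.uint32)
    buf = np.frombuffer(data, dtype=np.uint8)
    symbols, consumed = _kernels.rc_decode(buf, n, model.counts,
                                           model.increment, model.rescale_limit)
    # The decoder legitimately reads up to ~5 virtual zero bytes past the end
    # (mirror of the encoder's flush); anything beyond that is truncation.
    if consumed > buf.size + 5:
        raise CorruptStreamError(
            f"arithmetic stream truncated ({buf.size} bytes, needed {consumed})")
    return symbols


def pack_varints(values) -> bytes:
    """LEB128-encode non-negative integers (byte stream for an order-0 model)."""
    arr = np.ascontiguousarray(values, dtype=np.int64)
    if arr.size == 0:
        return b""
    if arr.min() < 0:
        raise ValueError("varints must be non-negative")
    return _kernels.varint_encode(arr).tobytes()


def unpack_varints(data: bytes | np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    buf = np.frombuffer(data, dtype=np.uint8) if isinstance(data, (bytes, bytearray)) else data
    values, consumed, ok = _kernels.varint_decode(np.ascontiguousarray(buf, dtype=np.uint8), n)
    if not ok:
        raise CorruptStreamError("truncated varint stream")
    return values


def zigzag(values) -> np.ndarray:
    arr = np.ascontiguousarray(values, dtype=np.int64)
    return np.where(arr >= 0, arr * 2, -arr * 2 - 1).astype(np.int64)


def unzigzag(values) -> np.ndarray:
    arr = np.ascontiguousarray(values, dtype=np.int64)
    return np.where(arr % 2 == 0, arr // 2, -(arr + 1) // 2).astype(np.int64)
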