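"""Byte-level helpers: DNA <-> 2-bit code buffers."""

from __future__ import annotations

import numpy as np

# A,C,G,T -> 0..3; N -> 4; everything else -> 255 (rejected upstream)
_TRANS = bytearray([255]) * 256
for i, ch in enumerate(b"ACGT"):
    _TRANS[ch] = i
_TRANS[ord("N")] = 4
SEQ_TRANS = bytes(_TRANS)

_BASE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def seq_to_codes(seq: bytes | str) -> np.ndarray:
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    codes = np.frombuffer(seq.translate(SEQ_TRANS), dtype=np.uint8)
    if codes.size and codes.max() == 255:
        bad = chr(seq[int(np.argmax(codes == 255))])
        raise ValueError(f"unsupported sequence character {bad!r} (expected A/C/G/T/N)")
    return codes.copy()


def codes_to_seq(codes: np.ndarray) -> bytes:
    return _BASE_LUT[codes].tobytes()


def flatten_seqs(seqs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concatenate sequences into one code buffer with per-read offsets."""
    buf = bytearray()
    ends = np.empty(len(seqs), dtype=np.int64)
    for i, s in enumerate(seqs):
        if isinstance(s, str):
            s = s.encode("ascii")
        buf += s
        ends[i] = len(buf)
    codes = np.frombuffer(bytes(buf).translate(SEQ_TRANS), dtype=np.uint8)
    if codes.size and codes.max() == 255:
        raise ValueError("unsupported sequence character (expected A/C/G/T/N)")
    starts = np.empty(len(seqs), dtype=np.int64)
    starts[0:1] = 0
    starts[1:] = ends[:-1]
    return codes.copy(), starts, ends
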