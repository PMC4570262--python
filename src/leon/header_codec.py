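"""Tokenized delta coding of read headers.

A header is split into fields (maximal runs of ASCII alphanumerics, possibly
empty) separated by single non-alphanumeric characters; re-joining fields and
separators reproduces the header byte-exactly.  Each header is coded against
the previous one, field by field: identical (field, separator) pairs cost one
MATCH symbol, numeric fields close in value cost a small signed delta, and
everything else falls back to longest-common-prefix + suffix literals.  The
resulting op/side streams are fed to dedicated order-0 arithmetic models by
the container layer.

Numeric fields with leading zeros are treated as alpha so the exact text is
always preserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

NUMERIC = "numeric"
ALPHA = "alpha"

OP_MATCH = 0
OP_NUM_DELTA = 1
OP_LIT = 2
OP_ALPHABET = 3

MAX_NUM_DELTA = 1 << 15

_SPLIT = re.compile(rb"([^0-9A-Za-z])")


def _kind(text: bytes) -> str:
    if text.isdigit() and (len(text) == 1 or not text.startswith(b"0")):
        return NUMERIC
    return ALPHA


@dataclass
class TokenizedHeader:
    fields: list[tuple[bytes, str]] = field(default_factory=list)
    separators: list[int] = field(default_factory=list)  # byte values


def tokenize(header: bytes | str) -> TokenizedHeader:
    if isinstance(header, str):
        header = header.encode("ascii")
    if not header:
        return TokenizedHeader()
    parts = _SPLIT.split(header)
    fields = [(t, _kind(t)) for t in parts[0::2]]
    separators = [p[0] for p in parts[1::2]]
    return TokenizedHeader(fields, separators)


def detokenize(t: TokenizedHeader) -> bytes:
    out = bytearray()
    for i, (text, _) in enumerate(t.fields):
        out += text
        if i < len(t.separators):
            out.append(t.separators[i])
    return bytes(out)


def _common_prefix_len(a: bytes, b: bytes) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def delta_encode(h: TokenizedHeader, prev: TokenizedHeader) -> list[tuple]:
    """Per-field ops: ("MATCH",) | ("NUM_DELTA", d) | ("LIT", plen, suffix, sep).

    MATCH and NUM_DELTA copy the following separator from ``prev`` and are
    only used when that separator matches; LIT carries its separator
    explicitly (None for the last field).
    """
    ops: list[tuple] = []
    n = len(h.fields)
    for i, (text, kind) in enumerate(h.fields):
        ptext, pkind = prev.fields[i] if i < len(prev.fields) else (b"", ALPHA)
        has_sep = i < n - 1
        sep_ok = (not has_sep) or (
            i < len(prev.separators) and prev.separators[i] == h.separators[i])
        if sep_ok and i < len(prev.fields) and text == ptext:
            ops.append(("MATCH",))
            continue
        if (sep_ok and kind == NUMERIC and pkind == NUMERIC
                and abs(int(text) - int(ptext)) < MAX_NUM_DELTA):
            ops.append(("NUM_DELTA", int(text) - int(ptext)))
            continue
        plen = _common_prefix_len(text, ptext)
        sep = h.separators[i] if has_sep else None
        ops.append(("LIT", plen, text[plen:], sep))
    return ops


def delta_decode(ops: list[tuple], prev: TokenizedHeader) -> bytes:
    """Inverse of :func:`delta_encode`: rebuild the header byte-exactly."""
    fields: list[tuple[bytes, str]] = []
    separators: list[int] = []
    n = len(ops)
    for i, op in enumerate(ops):
        ptext = prev.fields[i][0] if i < len(prev.fields) else b""
        if op[0] == "MATCH":
            text = ptext
            if i < n - 1:
                separators.append(prev.separators[i])
        elif op[0] == "NUM_DELTA":
            text = str(int(ptext) + op[1]).encode("ascii")
            if i < n - 1:
                separators.append(prev.separators[i])
        elif op[0] == "LIT":
            _, plen, suffix, sep = op
            text = ptext[:plen] + suffix
            if i < n - 1:
                if sep is None:
                    raise ValueError("corrupt header ops: missing separator")
                separators.append(sep)
        else:
            raise ValueError(f"corrupt header ops: unknown op {op[0]!r}")
        fields.append((text, _kind(text)))
    return detokenize(TokenizedHeader(fields, separators))


@dataclass
class HeaderStreams:
    """Flattened per-block header op streams (one symbol alphabet each)."""

    nfields: list[int] = field(default_factory=list)
    ops: list[int] = field(default_factory=list)
    deltas: list[int] = field(default_factory=list)      # zigzagged
    lit_lens: list[int] = field(default_factory=list)    # prefix,suffix pairs
    lit_bytes: bytearray = field(default_factory=bytearray)
    seps: bytearray = field(default_factory=bytearray)


def _is_canonical_number(text: bytes) -> bool:
    return text.isdigit() and (len(text) == 1 or text[0] != 0x30)


def encode_headers(headers: list[bytes]) -> HeaderStreams:
    """Delta-encode a block of headers (first one against the empty header).

    Inlined hot path equivalent to tokenize + :func:`delta_encode` per header
    (the test suite cross-checks the two routes).
    """
    s = HeaderStreams()
    nfields = s.nfields
    ops = s.ops
    deltas = s.deltas
    lit_lens = s.lit_lens
    lit_bytes = s.lit_bytes
    seps_out = s.seps
    split = _SPLIT.split
    pfields: list[bytes] = []
    pseps: list[bytes] = []
    for header in headers:
        if header:
            parts = split(header)
            fields = parts[0::2]
            seps = parts[1::2]
        else:
            fields = []
            seps = []
        n = len(fields)
        npf = len(pfields)
        nps = len(pseps)
        nfields.append(n)
        last = n - 1
        for i in range(n):
            text = fields[i]
            sep_ok = i >= last or (i < nps and pseps[i] == seps[i])
            if sep_ok and i < npf:
                ptext = pfields[i]
                if text == ptext:
                    ops.append(OP_MATCH)
                    continue
                if (_is_canonical_number(text) and _is_canonical_number(ptext)):
                    d = int(text) - int(ptext)
                    if -MAX_NUM_DELTA < d < MAX_NUM_DELTA:
                        ops.append(OP_NUM_DELTA)
                        deltas.append(d * 2 if d >= 0 else -d * 2 - 1)
                        continue
            else:
                ptext = pfields[i] if i < npf else b""
            ops.append(OP_LIT)
            plen = _common_prefix_len(text, ptext)
            lit_lens.append(plen)
            lit_lens.append(len(text) - plen)
            lit_bytes += text[plen:]
            if i < last:
                seps_out.append(seps[i][0])
        pfields = fields
        pseps = seps
    return s


def decode_headers(n: int, s: HeaderStreams) -> list[bytes]:
    """Inverse of :func:`encode_headers`."""
    headers: list[bytes] = []
    prev = TokenizedHeader()
    oi = di = li = bi = si = 0
    for _ in range(n):
        nf = s.nfields[len(headers)]
        ops: list[tuple] = []
        for j in range(nf):
            code = s.ops[oi]
            oi += 1
            if code == OP_MATCH:
                ops.append(("MATCH",))
            elif code == OP_NUM_DELTA:
                z = s.deltas[di]
                di += 1
                ops.append(("NUM_DELTA", z // 2 if z % 2 == 0 else -(z + 1) // 2))
            elif code == OP_LIT:
                plen = s.lit_lens[li]
                slen = s.lit_lens[li + 1]
                li += 2
                suffix = bytes(s.lit_bytes[bi:bi + slen])
                bi += slen
                sep = None
                if j < nf - 1:
                    sep = s.seps[si]
                    si += 1
                ops.append(("LIT", plen, suffix, sep))
            else:
                raise ValueError("corrupt header op stream")
        header = delta_decode(ops, prev)
        headers.append(header)
        prev = tokenize(header)
    return headers
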