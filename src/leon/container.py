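"""On-disk container, FASTQ/FASTA readers/writers and the compress/decompress
entry points.

Compression makes two passes: pass 1 counts canonical kmers, infers the
solidity threshold and builds the Bloom-filter graph; pass 2 encodes blocks
of reads independently (anchors, bifurcation lists, headers, qualities).
The output file is self-contained: it bundles the serialized graph and the
anchor dictionary, so decompression needs nothing else.  Byte-level layout is
documented in docs/FORMAT.md.
"""

from __future__ import annotations

import gzip
import os
import struct
import zlib
from dataclasses import dataclass

import numpy as np

from . import _kernels, counting, header_codec, quality_codec
from ._util import SEQ_TRANS, codes_to_seq
from .entropy_coding import (CorruptStreamError, FrequencyModel, arith_decode,
                             arith_encode, pack_varints, unpack_varints)
from .probabilistic_dbg import (DEFAULT_BITS_PER_KMER, BloomFilter, FormatError,
                                ProbabilisticDBG, build_graph)
from .sequence_codec import (AnchorDictionary, BlockStreams,
                             decode_block_streams, encode_block_streams)

MAGIC = b"LEONC001"
_HEADER = struct.Struct("<8sBBBIIIQ")  # magic, flags, k, b, t_sol, block, nblocks, nreads

FLAG_HAS_QUALITY = 1
FLAG_LOSSLESS_QUAL = 2
FLAG_SEQ_ONLY = 4
FLAG_FASTA = 8
FLAG_FINAL_NEWLINE = 16

DEFAULT_K = 31
DEFAULT_BLOCK_SIZE = 50_000
MAX_K = 31  # single 64-bit word on the compiled fast path

# (name, alphabet size); alphabet 0 marks a raw (zlib or varint-free) section
_STREAMS = [
    ("modes", 2), ("lengths", 256), ("anchor_idx", 256), ("anchor_pos", 256),
    ("right_nucs", 4), ("re_counts", 256), ("right_errs", 256),
    ("left_nucs", 4), ("le_counts", 256), ("left_errs", 256),
    ("n_counts", 256), ("n_offsets", 256), ("raw_seq", 4),
    ("hdr_nfields", 256), ("hdr_ops", header_codec.OP_ALPHABET),
    ("hdr_deltas", 256), ("hdr_lit_lens", 256), ("hdr_lit_bytes", 256),
    ("hdr_seps", 256), ("plus_flags", 2), ("plus_extra", 256),
    ("quality", 0),
]
_STREAM_INDEX = {name: i for i, (name, _) in enumerate(_STREAMS)}


class InputError(ValueError):
    """Malformed FASTQ/FASTA input."""


class ContainerError(ValueError):
    """Malformed or corrupt container file."""


@dataclass
class ReadRecord:
    header: str
    sequence: str
    quality: str | None = None  # absent for FASTA
    plus: str = "+"


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rb")
    return open(path, "rb")


@dataclass
class _ParsedInput:
    headers: list[bytes]
    seqs: list[bytes]
    quals: list[bytes] | None
    plus: list[bytes] | None
    is_fastq: bool
    final_newline: bool


def _parse_fastx(path) -> _ParsedInput:
    with _open_maybe_gzip(path) as fh:
        data = fh.read()
    if not data:
        raise InputError(f"{path}: empty input file")
    final_newline = data.endswith(b"\n")
    lines = data.split(b"\n")
    if final_newline:
        lines.pop()
    first = lines[0][:1] if lines else b""
    if first == b"@":
        if len(lines) % 4 == 3 and final_newline:
            # ambiguous tail: an empty final quality line with no newline after
            lines.append(b"")
            final_newline = False
        if len(lines) % 4 != 0:
            raise InputError(f"{path}: truncated FASTQ record "
                             f"at record {len(lines) // 4}")
        headers, seqs, quals, plus = [], [], [], []
        for i in range(0, len(lines), 4):
            h, s, p, q = lines[i], lines[i + 1], lines[i + 2], lines[i + 3]
            rec = i // 4
            if not h.startswith(b"@"):
                raise InputError(f"{path}: record {rec}: header does not start with '@'")
            if not p.startswith(b"+"):
                raise InputError(f"{path}: record {rec}: missing '+' line")
            if len(s) != len(q):
                raise InputError(
                    f"{path}: record {rec}: sequence/quality length mismatch "
                    f"({len(s)} vs {len(q)})")
            headers.append(h[1:])
            seqs.append(s)
            plus.append(p[1:])
            quals.append(q)
        return _ParsedInput(headers, seqs, quals, plus, True, final_newline)
    if first == b">":
        headers, seqs = [], []
        cur: list[bytes] = []
        for ln in lines:
            if ln.startswith(b">"):
                if headers:
                    seqs.append(b"".join(cur))
                headers.append(ln[1:])
                cur = []
            elif headers:
                cur.append(ln)
            else:
                raise InputError(f"{path}: sequence before first FASTA header")
        seqs.append(b"".join(cur))
        return _ParsedInput(headers, seqs, None, None, False, final_newline)
    raise InputError(f"{path}: not FASTA or FASTQ (first byte {first!r})")


def read_fastx(path):
    """Stream :class:`ReadRecord` objects from a FASTQ/FASTA file (gzip OK)."""
    p = _parse_fastx(path)
    for i in range(len(p.headers)):
        yield ReadRecord(
            header=p.headers[i].decode("ascii"),
            sequence=p.seqs[i].decode("ascii"),
            quality=p.quals[i].decode("ascii") if p.is_fastq else None,
            plus=("+" + p.plus[i].decode("ascii")) if p.is_fastq else "+")


def write_fastq(records, path) -> None:
    with open(path, "wb") as fh:
        for r in records:
            q = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.header}\n{r.sequence}\n{r.plus}\n{q}\n".encode("ascii"))


def _flatten(seqs: list[bytes]):
    buf = b"".join(seqs)
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    ends = np.cumsum(lengths)
    starts = ends - lengths
    codes = np.frombuffer(buf.translate(SEQ_TRANS), dtype=np.uint8).copy()
    if codes.size and codes.max() == 255:
        bad = int(np.flatnonzero(codes == 255)[0])
        rec = int(np.searchsorted(ends, bad, side="right"))
        raise InputError(f"record {rec}: unsupported sequence character "
                         f"{chr(buf[bad])!r} (expected A/C/G/T/N)")
    return codes, starts, ends


def _write_stream(parts: list[bytes], name: str, payload: bytes, n_symbols: int,
                  stats: dict) -> None:
    parts.append(struct.pack("<QQ", n_symbols, len(payload)))
    parts.append(payload)
    stats[name] = stats.get(name, 0) + len(payload) + 16


def _encode_stream(parts, name, symbols, stats) -> None:
    alphabet = _STREAMS[_STREAM_INDEX[name]][1]
    arr = np.ascontiguousarray(symbols, dtype=np.uint32)
    payload = arith_encode(arr, FrequencyModel(alphabet))
    _write_stream(parts, name, payload, arr.size, stats)


def _encode_varint_stream(parts, name, values, stats) -> None:
    raw = pack_varints(values)
    _encode_stream(parts, name, np.frombuffer(raw, dtype=np.uint8), stats)


class _BlockReader:
    def __init__(self, data: bytes, pos: int):
        self.data = data
        self.pos = pos

    def read_stream(self, name: str):
        if self.pos + 16 > len(self.data):
            raise ContainerError("truncated container (stream header)")
        n_symbols, n_bytes = struct.unpack_from("<QQ", self.data, self.pos)
        self.pos += 16
        payload = self.data[self.pos:self.pos + n_bytes]
        if len(payload) != n_bytes:
            raise ContainerError("truncated container (stream payload)")
        self.pos += n_bytes
        alphabet = _STREAMS[_STREAM_INDEX[name]][1]
        if alphabet == 0:
            return payload, n_symbols
        try:
            return arith_decode(payload, int(n_symbols), FrequencyModel(alphabet)), n_symbols
        except CorruptStreamError as exc:
            raise ContainerError(str(exc)) from exc

    def read_varint_stream(self, name: str, n_values: int) -> np.ndarray:
        symbols, _ = self.read_stream(name)
        try:
            return unpack_varints(symbols.astype(np.uint8), n_values)
        except CorruptStreamError as exc:
            raise ContainerError(str(exc)) from exc


def _empty_graph(k: int) -> ProbabilisticDBG:
    return ProbabilisticDBG(BloomFilter(8, 1), k)


def compress_file(in_path, out_path, k: int = DEFAULT_K, t_sol="auto",
                  b: int = DEFAULT_BITS_PER_KMER, lossless_qual: bool = False,
                  seq_only: bool = False,
                  block_size: int = DEFAULT_BLOCK_SIZE) -> dict:
    """Compress a FASTQ/FASTA file into the container format.

    Returns summary stats: per-stream compressed sizes, the inferred
    solidity threshold and the overall ratio (original size / compressed
    size, the conventional definition).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}]")
    inp = _parse_fastx(in_path)
    n_reads = len(inp.headers)
    codes, starts, ends = _flatten(inp.seqs)

    # pass 1: count kmers, pick the threshold, build the graph
    cnt_out = np.empty(codes.size, np.uint64)
    n_kmers = _kernels.extract_canonical(codes, starts, ends, k, cnt_out)
    kmers, kcounts = np.unique(cnt_out[:n_kmers], return_counts=True)
    del cnt_out
    if t_sol == "auto":
        if kmers.size:
            abund, ndist = np.unique(kcounts, return_counts=True)
            hist = counting.AbundanceHistogram(
                {int(a): int(c) for a, c in zip(abund, ndist)})
            t_sol_val = counting.infer_solidity_threshold(hist)
        else:
            t_sol_val = counting.DEFAULT_FALLBACK_T_SOL
    else:
        t_sol_val = int(t_sol)
        if t_sol_val < 1:
            raise ValueError("t_sol must be >= 1")
    solid = kmers[kcounts >= t_sol_val]
    del kmers, kcounts
    g = build_graph(solid, b=b, k=k) if solid.size else _empty_graph(k)
    del solid

    adict = AnchorDictionary(k)
    stats: dict = {}
    block_parts: list[bytes] = []
    n_blocks = 0
    n_unanchored = 0
    lossy = inp.is_fastq and not lossless_qual and not seq_only
    for lo in range(0, n_reads, block_size):
        hi = min(lo + block_size, n_reads)
        n_blocks += 1
        bstarts = starts[lo:hi]
        bends = ends[lo:hi]
        s = encode_block_streams(codes, bstarts, bends, g, adict)
        n_unanchored += int(s.mode.sum())
        parts: list[bytes] = [struct.pack("<I", hi - lo)]
        _encode_stream(parts, "modes", s.mode, stats)
        _encode_varint_stream(parts, "lengths", s.lengths, stats)
        anchored = s.mode == 0
        _encode_varint_stream(parts, "anchor_idx", s.anchor_idx[anchored], stats)
        _encode_varint_stream(parts, "anchor_pos", s.anchor_pos[anchored], stats)
        _encode_stream(parts, "right_nucs", s.right_nucs, stats)
        _encode_varint_stream(parts, "re_counts", s.re_counts[anchored], stats)
        _encode_varint_stream(parts, "right_errs", s.right_errs, stats)
        _encode_stream(parts, "left_nucs", s.left_nucs, stats)
        _encode_varint_stream(parts, "le_counts", s.le_counts[anchored], stats)
        _encode_varint_stream(parts, "left_errs", s.left_errs, stats)
        # N positions (per read count + offsets within the read)
        span0 = int(bstarts[0])
        bcodes = codes[span0:int(bends[-1])]
        npos = np.flatnonzero(bcodes == 4) + span0
        rid = np.searchsorted(bends, npos, side="right")
        ncounts = np.bincount(rid, minlength=hi - lo)
        _encode_varint_stream(parts, "n_counts", ncounts, stats)
        _encode_varint_stream(parts, "n_offsets", npos - bstarts[rid], stats)
        _encode_stream(parts, "raw_seq", s.raw_codes, stats)
        # headers / plus lines
        if seq_only:
            for name in ("hdr_nfields", "hdr_ops", "hdr_deltas", "hdr_lit_lens",
                         "hdr_lit_bytes", "hdr_seps", "plus_flags", "plus_extra"):
                _write_stream(parts, name, b"", 0, stats)
        else:
            hs = header_codec.encode_headers(inp.headers[lo:hi])
            _encode_varint_stream(parts, "hdr_nfields", hs.nfields, stats)
            _encode_stream(parts, "hdr_ops", hs.ops, stats)
            _encode_varint_stream(parts, "hdr_deltas", hs.deltas, stats)
            _encode_varint_stream(parts, "hdr_lit_lens", hs.lit_lens, stats)
            _encode_stream(parts, "hdr_lit_bytes",
                           np.frombuffer(bytes(hs.lit_bytes), np.uint8), stats)
            _encode_stream(parts, "hdr_seps",
                           np.frombuffer(bytes(hs.seps), np.uint8), stats)
            if inp.is_fastq:
                pflags = np.fromiter((1 if p else 0 for p in inp.plus[lo:hi]),
                                     np.uint32, hi - lo)
                extra = bytearray()
                for p in inp.plus[lo:hi]:
                    if p:
                        extra += pack_varints([len(p)])
                        extra += p
                _encode_stream(parts, "plus_flags", pflags, stats)
                _encode_stream(parts, "plus_extra",
                               np.frombuffer(bytes(extra), np.uint8), stats)
            else:
                _write_stream(parts, "plus_flags", b"", 0, stats)
                _write_stream(parts, "plus_extra", b"", 0, stats)
        # qualities
        if inp.is_fastq and not seq_only:
            qflat = np.frombuffer(b"".join(inp.quals[lo:hi]), np.uint8)
            if lossy and g.bloom.n_inserted:
                rel_starts = (bstarts - span0).copy()
                rel_ends = (bends - span0).copy()
                cov = np.zeros(qflat.size, np.int32)
                maxl = int((bends - bstarts).max()) if hi > lo else 0
                wbuf = np.zeros(maxl + 2, np.int64)
                bl = g.bloom
                _kernels.solid_coverage_block(
                    bcodes, rel_starts, rel_ends, k, bl.bits, np.uint64(bl.m),
                    bl.h, np.uint64(bl.seed1), np.uint64(bl.seed2), wbuf, cov)
                qflat = quality_codec.smooth_block(qflat, cov)
            elif lossy:
                qflat = np.minimum(qflat, quality_codec.CAP_CODE).astype(np.uint8)
            # rebuild newline-delimited per-read strings
            qlens = bends - bstarts
            qsplit = (np.insert(qflat, np.cumsum(qlens)[:-1], 10)
                      if qlens.size > 1 else qflat)
            payload = zlib.compress(qsplit.tobytes(), quality_codec.ZLIB_LEVEL)
            _write_stream(parts, "quality", payload, qflat.size, stats)
        else:
            _write_stream(parts, "quality", b"", 0, stats)
        block_parts.append(b"".join(parts))

    flags = 0
    if inp.is_fastq and not seq_only:
        flags |= FLAG_HAS_QUALITY
    if lossless_qual:
        flags |= FLAG_LOSSLESS_QUAL
    if seq_only:
        flags |= FLAG_SEQ_ONLY
    if not inp.is_fastq:
        flags |= FLAG_FASTA
    if inp.final_newline:
        flags |= FLAG_FINAL_NEWLINE

    head = [_HEADER.pack(MAGIC, flags, k, b, t_sol_val, block_size, n_blocks, n_reads)]
    gbytes = g.serialize()
    head.append(struct.pack("<Q", len(gbytes)))
    head.append(gbytes)
    stats["graph"] = len(gbytes) + 8
    anchors = adict.values_array()
    shifts = (2 * (k - 1 - np.arange(k))).astype(np.uint64)
    dsym = ((anchors[:, None] >> shifts[None, :]) & np.uint64(3)).astype(np.uint32).ravel()
    dpayload = arith_encode(dsym, FrequencyModel(4))
    head.append(struct.pack("<QQ", anchors.size, len(dpayload)))
    head.append(dpayload)
    stats["anchor_dict"] = len(dpayload) + 16

    payload = b"".join(head) + b"".join(block_parts)
    crc = zlib.crc32(payload)
    with open(out_path, "wb") as fh:
        fh.write(payload)
        fh.write(struct.pack("<I", crc))

    original = os.path.getsize(in_path)
    compressed = len(payload) + 4
    stats.update(
        original_size=original, compressed_size=compressed,
        ratio=original / compressed, k=k, t_sol=t_sol_val, bits_per_kmer=b,
        n_reads=n_reads, n_anchors=int(anchors.size), n_unanchored=n_unanchored,
    )
    return stats


def read_container_header(path) -> dict:
    """Parse only the fixed container header (parameters)."""
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
    if len(head) < _HEADER.size:
        raise ContainerError(f"{path}: truncated container header")
    magic, flags, k, b, t_sol, block_size, n_blocks, n_reads = _HEADER.unpack(head)
    if magic != MAGIC:
        raise ContainerError(f"{path}: not a leon container")
    return dict(flags=flags, k=k, bits_per_kmer=b, t_sol=t_sol,
                block_size=block_size, n_blocks=n_blocks, n_reads=n_reads)


def decompress_file(in_path, out_path) -> dict:
    """Reconstruct the FASTQ/FASTA file from a container.

    Headers and sequences are always byte-exact; qualities are byte-exact in
    lossless mode.  No kmer counting happens here — the graph and anchor
    dictionary are loaded from the container.
    """
    with open(in_path, "rb") as fh:
        data = fh.read()
    if len(data) < _HEADER.size + 4:
        raise ContainerError(f"{in_path}: truncated container")
    payload, crc_stored = data[:-4], struct.unpack("<I", data[-4:])[0]
    if zlib.crc32(payload) != crc_stored:
        raise ContainerError(f"{in_path}: checksum mismatch (corrupt container)")
    magic, flags, k, b, t_sol, block_size, n_blocks, n_reads = \
        _HEADER.unpack_from(payload)
    if magic != MAGIC:
        raise ContainerError(f"{in_path}: not a leon container")
    pos = _HEADER.size
    (glen,) = struct.unpack_from("<Q", payload, pos)
    pos += 8
    try:
        g = ProbabilisticDBG.deserialize(payload[pos:pos + glen])
    except FormatError as exc:
        raise ContainerError(str(exc)) from exc
    pos += glen
    n_anchors, dlen = struct.unpack_from("<QQ", payload, pos)
    pos += 16
    dsym = arith_decode(payload[pos:pos + dlen], int(n_anchors) * k, FrequencyModel(4))
    pos += dlen
    shifts = (2 * (k - 1 - np.arange(k))).astype(np.uint64)
    dict_entries = (dsym.astype(np.uint64).reshape(-1, k) << shifts[None, :]).sum(
        axis=1, dtype=np.uint64) if n_anchors else np.empty(0, np.uint64)

    has_quality = bool(flags & FLAG_HAS_QUALITY)
    seq_only = bool(flags & FLAG_SEQ_ONLY)
    is_fasta = bool(flags & FLAG_FASTA)

    out_lines: list[bytes] = []
    rd = _BlockReader(payload, pos)
    for _ in range(n_blocks):
        if rd.pos + 4 > len(payload):
            raise ContainerError("truncated container (block header)")
        (nb,) = struct.unpack_from("<I", payload, rd.pos)
        rd.pos += 4
        modes, _ = rd.read_stream("modes")
        modes = modes.astype(np.uint8)
        lengths = rd.read_varint_stream("lengths", nb)
        anchored = modes == 0
        n_anch = int(anchored.sum())
        aidx = rd.read_varint_stream("anchor_idx", n_anch)
        apos = rd.read_varint_stream("anchor_pos", n_anch)
        rnuc, _ = rd.read_stream("right_nucs")
        rec = rd.read_varint_stream("re_counts", n_anch)
        rerr = rd.read_varint_stream("right_errs", int(rec.sum()))
        lnuc, _ = rd.read_stream("left_nucs")
        lec = rd.read_varint_stream("le_counts", n_anch)
        lerr = rd.read_varint_stream("left_errs", int(lec.sum()))
        ncnt = rd.read_varint_stream("n_counts", nb)
        noff = rd.read_varint_stream("n_offsets", int(ncnt.sum()))
        raw, _ = rd.read_stream("raw_seq")
        # expand per-anchored-read values to dense per-read arrays
        full_aidx = np.zeros(nb, np.int64)
        full_apos = np.zeros(nb, np.int64)
        full_rec = np.zeros(nb, np.int64)
        full_lec = np.zeros(nb, np.int64)
        full_aidx[anchored] = aidx
        full_apos[anchored] = apos
        full_rec[anchored] = rec
        full_lec[anchored] = lec
        streams = BlockStreams(
            n_reads=nb, lengths=lengths, mode=modes,
            anchor_idx=full_aidx, anchor_pos=full_apos,
            re_counts=full_rec, le_counts=full_lec,
            right_nucs=rnuc.astype(np.uint8), right_errs=rerr,
            left_nucs=lnuc.astype(np.uint8), left_errs=lerr,
            raw_codes=raw.astype(np.uint8),
            new_anchors=np.empty(0, np.uint64))
        try:
            bcodes, bstarts, bends = decode_block_streams(streams, dict_entries, g)
        except ValueError as exc:
            raise ContainerError(str(exc)) from exc
        # restore N's
        if ncnt.sum():
            rid = np.repeat(np.arange(nb), ncnt)
            bcodes[bstarts[rid] + noff] = 4
        seqs = codes_to_seq(bcodes)
        # headers + plus + quality
        if seq_only:
            for name in ("hdr_nfields", "hdr_ops", "hdr_deltas", "hdr_lit_lens",
                         "hdr_lit_bytes", "hdr_seps", "plus_flags", "plus_extra",
                         "quality"):
                rd.read_stream(name)
            headers = [b"" for _ in range(nb)]
            plus_lines = [b""] * nb
            quals = None
        else:
            nfields = rd.read_varint_stream("hdr_nfields", nb)
            ops, _ = rd.read_stream("hdr_ops")
            n_delta = int((ops == header_codec.OP_NUM_DELTA).sum())
            n_lit = int((ops == header_codec.OP_LIT).sum())
            deltas = rd.read_varint_stream("hdr_deltas", n_delta)
            lit_lens = rd.read_varint_stream("hdr_lit_lens", 2 * n_lit)
            lit_bytes, _ = rd.read_stream("hdr_lit_bytes")
            seps, _ = rd.read_stream("hdr_seps")
            hs = header_codec.HeaderStreams(
                nfields=list(nfields), ops=list(ops.astype(int)),
                deltas=list(deltas),
                lit_lens=list(lit_lens),
                lit_bytes=bytearray(lit_bytes.astype(np.uint8).tobytes()),
                seps=bytearray(seps.astype(np.uint8).tobytes()))
            try:
                headers = header_codec.decode_headers(nb, hs)
            except (ValueError, IndexError) as exc:
                raise ContainerError(f"corrupt header streams: {exc}") from exc
            pflags, _ = rd.read_stream("plus_flags")
            pextra, _ = rd.read_stream("plus_extra")
            plus_lines = [b""] * nb
            if has_quality and pflags.size:
                buf = pextra.astype(np.uint8).tobytes()
                off = 0
                for i in np.flatnonzero(pflags):
                    ln = 0
                    shift = 0
                    while True:
                        bt = buf[off]
                        off += 1
                        ln |= (bt & 0x7F) << shift
                        if not bt & 0x80:
                            break
                        shift += 7
                    plus_lines[i] = buf[off:off + ln]
                    off += ln
            qpayload, qn = rd.read_stream("quality")
            quals = None
            if has_quality:
                try:
                    qtext = zlib.decompress(qpayload)
                except zlib.error as exc:
                    raise ContainerError(f"corrupt quality stream: {exc}") from exc
                quals = qtext.split(b"\n")
                if len(quals) != nb or any(len(q) != l for q, l in zip(quals, lengths)):
                    raise ContainerError("quality stream does not match read lengths")
        for i in range(nb):
            s = seqs[int(bstarts[i]):int(bends[i])]
            if is_fasta or seq_only:
                out_lines.append(b">" + headers[i] + b"\n" + s + b"\n")
            else:
                q = quals[i] if quals is not None else b""
                out_lines.append(b"@" + headers[i] + b"\n" + s + b"\n+"
                                 + plus_lines[i] + b"\n" + q + b"\n")
    if seq_only and not is_fasta:
        # no headers were stored; emit sequential ids
        renum = []
        idx = 0
        for ln in out_lines:
            body = ln.split(b"\n", 2)[1]
            renum.append(b">read_" + str(idx).encode() + b"\n" + body + b"\n")
            idx += 1
        out_lines = renum
    blob = b"".join(out_lines)
    if not flags & FLAG_FINAL_NEWLINE and blob.endswith(b"\n"):
        blob = blob[:-1]
    with open(out_path, "wb") as fh:
        fh.write(blob)
    return dict(n_reads=int(n_reads), k=k, bits_per_kmer=b, t_sol=t_sol,
                output_size=len(blob))
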