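# Container format (`LEONC001`)

All integers are little-endian.  The file is self-contained: it bundles the
serialized graph and the anchor dictionary, so decompression needs nothing
but this file.

## Fixed header

| field | type | meaning |
|---|---|---|
| magic | 8 bytes | `LEONC001` |
| flags | u8 | bit 0 has-quality, bit 1 lossless-quality, bit 2 seq-only, bit 3 FASTA input, bit 4 input ended with a newline |
| k | u8 | kmer length (1..31) |
| b | u8 | Bloom bits per solid kmer |
| t_sol | u32 | solidity threshold used (minimum solid abundance, count >= t_sol) |
| block_size | u32 | reads per block |
| n_blocks | u32 | |
| n_reads | u64 | |

## Graph section

`u64 length` followed by the serialized Bloom filter:
`LBLM` magic, `m` (u64, bits), `h` (u8, hash count), `k` (u8),
`seed1`/`seed2` (u64, base-hash seeds), `n_inserted` (u64), then the raw bit
array (`m/8` bytes, bit *i* at byte `i>>3`, mask `1<<(i&7)`).  Hash positions
for a canonical kmer key are `g_i = (h1 + i*h2) mod m` where `h1`, `h2` are
splitmix64-style hashes of the key under the two seeds.

Bases are 2-bit coded A=0, C=1, G=2, T=3, leftmost base in the
most-significant pair (so integer order = lexicographic order).

## Anchor dictionary section

`u64 n_entries`, `u64 payload_length`, then `n_entries * k` base symbols
(alphabet 4) arithmetic-coded.  Entries are oriented (not canonical) kmers in
insertion order; reads reference them by index.

## Blocks

Each block starts with `u32 n_reads_in_block` followed by 22 streams in a
fixed order.  Every stream is `u64 n_symbols`, `u64 n_bytes`, payload.
All streams except `quality` are order-0 adaptive arithmetic coded with a
fresh model per stream per block (counts initialized to 1, increment 16,
rescale at 2^16; 32-bit LZMA-style range coder).  Streams whose alphabet is
256 carry LEB128 varint bytes.

| # | stream | alphabet | content |
|---|---|---|---|
| 0 | modes | 2 | per read: 0 anchored, 1 raw |
| 1 | lengths | 256 | per read: read length (varint) |
| 2 | anchor_idx | 256 | per anchored read: dictionary index |
| 3 | anchor_pos | 256 | per anchored read: anchor offset |
| 4 | right_nucs | 4 | right-leg bifurcation nucleotides, walk order |
| 5 | re_counts | 256 | per anchored read: number of right error events |
| 6 | right_errs | 256 | absolute read offsets of right error events |
| 7-9 | left_nucs / le_counts / left_errs | | left leg, mirrored |
| 10 | n_counts | 256 | per read: number of N positions |
| 11 | n_offsets | 256 | N offsets within each read |
| 12 | raw_seq | 4 | concatenated bases of raw-mode reads |
| 13 | hdr_nfields | 256 | per read: header field count |
| 14 | hdr_ops | 3 | per field: 0 MATCH, 1 NUM_DELTA, 2 LIT |
| 15 | hdr_deltas | 256 | zigzag varints for NUM_DELTA ops |
| 16 | hdr_lit_lens | 256 | (prefix_len, suffix_len) varint pairs for LIT ops |
| 17 | hdr_lit_bytes | 256 | literal suffix bytes |
| 18 | hdr_seps | 256 | separator byte per non-final LIT field |
| 19 | plus_flags | 2 | per read: 1 if the '+' line carries extra text |
| 20 | plus_extra | 256 | varint length + bytes per flagged read |
| 21 | quality | raw | zlib (level 9) of newline-joined quality strings |

A bifurcation event carries a position (stream 6/9) exactly when the read's
base was absent from the graph's successor set; nucleotide-only events are
consumed at graph ambiguities, so the decoder needs no count for them.

In seq-only mode streams 13-21 are empty; for FASTA input streams 19-21 are
empty.

## Footer

`u32` CRC-32 (zlib) of every preceding byte.
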