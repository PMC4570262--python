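import numpy as np
import pytest

from leon._util import flatten_seqs
from leon.kmer_model import encode
from leon.sequence_codec import (AnchorDictionary, decode_block_streams,
                                 decode_read, encode_block_streams,
                                 encode_read, mask_n, select_anchor, unmask_n)

from conftest import K_TOY


def fresh_dict():
    return AnchorDictionary(K_TOY)


# ---------------------------------------------------------------------------
# anchor selection
# ---------------------------------------------------------------------------

def test_select_anchor_fresh_dict_appends_leftmost_solid(toy_graph, toy_genome):
    d = fresh_dict()
    read = toy_genome[50:150]
    idx, pos = select_anchor(read, d, toy_graph)
    assert (idx, pos) == (0, 0)
    assert len(d) == 1


def test_select_anchor_prefers_existing_dict_entry(toy_graph, toy_genome):
    d = fresh_dict()
    inner = encode(toy_genome[55:55 + K_TOY])
    d.add(inner)
    read = toy_genome[50:150]
    idx, pos = select_anchor(read, d, toy_graph)
    # kmer at offset 5 is the only dictionary member -> returned over the
    # (solid) kmer at offset 0
    assert (idx, pos) == (0, 5)
    assert len(d) == 1


def test_unanchorable_read_returns_none(toy_graph):
    # a read sharing no kmer with the graph: errors denser than every k bases
    rng = np.random.default_rng(0)
    read = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
    d = fresh_dict()
    assert select_anchor(read, d, toy_graph) is None
    assert len(d) == 0


def test_error_every_k_bases_is_unanchorable(toy_genome):
    from leon import build_graph, count_kmers, solid_kmers
    # b=32 makes Bloom false positives negligible for this construction
    table = count_kmers([toy_genome], K_TOY)
    g = build_graph(solid_kmers(table, 1), b=32, k=K_TOY)
    read = list(toy_genome[100:200])
    for p in range(10, 100, K_TOY - 1):
        read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
    assert select_anchor("".join(read), fresh_dict(), g) is None


# ---------------------------------------------------------------------------
# per-read encode/decode against the exact-set oracle graph
# ---------------------------------------------------------------------------

def test_clean_read_on_simple_path_has_no_events(toy_graph, toy_genome):
    read = toy_genome[300:400]
    e = encode_read(read, (0, 0), toy_graph)
    assert e.right_events == [] and e.left_events == []


def test_single_substitution_yields_one_positional_event(toy_graph, toy_genome):
    read = list(toy_genome[300:400])
    p = 60
    read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
    e = encode_read("".join(read), (0, 0), toy_graph)
    positional = [(ev.nucleotide, ev.position) for ev in e.right_events
                  if ev.position is not None]
    assert positional == [(read[p], p)]
    # the corrected-path continuation keeps the rest of the read event-free
    assert len(e.right_events) <= 2


def test_true_branch_yields_nucleotide_only_event(toy_genome):
    from leon import build_graph, count_kmers, solid_kmers
    # plant a second edge: both variants of one site are in the graph
    core = toy_genome[1000:1100]
    p = 50
    alt = core[:p] + {"A": "C", "C": "G", "G": "T", "T": "A"}[core[p]] + core[p + 1:]
    table = count_kmers([core, alt], K_TOY)
    g = build_graph(solid_kmers(table, 1), b=16, k=K_TOY)
    e = encode_read(core, (0, 0), g)
    branch = [ev for ev in e.right_events if ev.position is None]
    errors = [ev for ev in e.right_events if ev.position is not None]
    assert errors == []
    assert len(branch) == 1 and branch[0].nucleotide == core[p]


def test_left_walk_mirrors(toy_graph, toy_genome):
    read = toy_genome[500:600]
    d = fresh_dict()
    d.add(encode(read[40:40 + K_TOY]))
    e = encode_read(read, (0, 40), toy_graph)
    assert decode_read(e, d, toy_graph) == read


def test_decode_inverts_encode_with_errors(toy_graph, toy_genome):
    rng = np.random.default_rng(5)
    d = fresh_dict()
    for _ in range(150):
        start = int(rng.integers(0, len(toy_genome) - 120))
        read = list(toy_genome[start:start + 100])
        for p in rng.integers(0, 100, rng.integers(0, 4)):
            read[p] = "ACGT"[int(rng.integers(0, 4))]
        read = "".join(read)
        masked, npos = mask_n(read)
        anchor = select_anchor(masked, d, toy_graph)
        if anchor is None:
            continue
        e = encode_read(masked, anchor, toy_graph, n_positions=npos)
        assert decode_read(e, d, toy_graph) == read


def test_raw_mode_read_emitted_verbatim(toy_graph):
    from leon.sequence_codec import EncodedRead
    e = EncodedRead(mode="raw", read_length=7, raw_seq="ACGTACG")
    assert decode_read(e, fresh_dict(), toy_graph) == "ACGTACG"


def test_mask_unmask_round_trip():
    masked, pos = mask_n("ANGNT")
    assert masked == "AAGAT" and pos == [1, 3]
    assert unmask_n(masked, pos) == "ANGNT"
    assert mask_n("ACGT") == ("ACGT", [])


# ---------------------------------------------------------------------------
# block kernel vs per-read reference implementation
# ---------------------------------------------------------------------------

def _events_to_streams(encoded_reads):
    rn, re_, ln, le = [], [], [], []
    for e in encoded_reads:
        for ev in e.right_events:
            rn.append("ACGT".index(ev.nucleotide))
            if ev.position is not None:
                re_.append(ev.position)
        for ev in e.left_events:
            ln.append("ACGT".index(ev.nucleotide))
            if ev.position is not None:
                le.append(ev.position)
    return rn, re_, ln, le


def test_block_kernel_matches_reference_implementation(toy_graph, toy_genome):
    rng = np.random.default_rng(8)
    reads = []
    for _ in range(300):
        start = int(rng.integers(0, len(toy_genome) - 110))
        read = list(toy_genome[start:start + int(rng.integers(K_TOY, 105))])
        for p in rng.integers(0, len(read), rng.integers(0, 3)):
            read[p] = "ACGT"[int(rng.integers(0, 4))]
        reads.append("".join(read))

    # reference route
    ref_dict = fresh_dict()
    encoded = []
    for r in reads:
        anchor = select_anchor(r, ref_dict, toy_graph)
        if anchor is None:
            encoded.append(None)
        else:
            encoded.append(encode_read(r, anchor, toy_graph))

    # kernel route
    kd = fresh_dict()
    codes, starts, ends = flatten_seqs(reads)
    s = encode_block_streams(codes, starts, ends, toy_graph, kd)

    assert [int(m) for m in s.mode] == [1 if e is None else 0 for e in encoded]
    anchored = [e for e in encoded if e is not None]
    assert list(s.anchor_idx[s.mode == 0]) == [e.anchor_index for e in anchored]
    assert list(s.anchor_pos[s.mode == 0]) == [e.anchor_position for e in anchored]
    rn, re_, ln, le = _events_to_streams(anchored)
    assert list(s.right_nucs) == rn
    assert list(s.right_errs) == re_
    assert list(s.left_nucs) == ln
    assert list(s.left_errs) == le
    assert len(kd) == len(ref_dict)
    assert (kd.values_array() == ref_dict.values_array()).all()

    # and the kernel decoder inverts it
    out_codes, dstarts, dends = decode_block_streams(s, kd.values_array(), toy_graph)
    assert (out_codes == np.where(codes == 4, 0, codes)).all()


def test_block_round_trip_with_ns_and_short_reads(toy_graph, toy_genome):
    reads = [toy_genome[0:100],
             "ACGT",                      # shorter than k -> raw
             toy_genome[40:90] + "N" * 5,
             "N" * 30,
             toy_genome[200:300]]
    d = fresh_dict()
    codes, starts, ends = flatten_seqs(reads)
    s = encode_block_streams(codes, starts, ends, toy_graph, d)
    out_codes, _, _ = decode_block_streams(s, d.values_array(), toy_graph)
    assert (out_codes == np.where(codes == 4, 0, codes)).all()


def test_positional_events_coincide_with_planted_errors(small_sim):
    """>= 95% of emitted error events sit on planted substitution positions."""
    from leon import build_graph, count_kmers, solid_kmers
    from leon.counting import histogram, infer_solidity_threshold
    from leon.simulate import simulate_read_arrays

    genome, spec, _ = small_sim
    mat, _, pos, strand, err = simulate_read_arrays(genome, spec)
    all_reads = ["".join("ACGT"[c] for c in row) for row in mat]
    reads = all_reads[:1500]
    k = 21
    table = count_kmers(all_reads, k)  # full 50x coverage for the graph
    t = infer_solidity_threshold(histogram(table))
    g = build_graph(solid_kmers(table, t), b=16, k=k)
    d = AnchorDictionary(k)
    codes, starts, ends = flatten_seqs(reads)
    s = encode_block_streams(codes, starts, ends, g, d)
    planted = {(r, p) for r, p in zip(*np.nonzero(err[:1500]))}
    # clean-region scope: reads whose planted errors are isolated (> k apart);
    # clustered errors legitimately cascade into extra positional events
    clean = set()
    for r in range(len(reads)):
        ep = np.flatnonzero(err[r])
        if ep.size == 0 or np.diff(ep).min(initial=k + 1) > k:
            clean.add(r)
    offs = np.concatenate([s.right_errs, s.left_errs])
    anch = np.arange(len(reads))[s.mode == 0]
    rids = np.concatenate([np.repeat(anch, s.re_counts[s.mode == 0]),
                           np.repeat(anch, s.le_counts[s.mode == 0])])
    hits = total = 0
    for rid, off in zip(rids, offs):
        if int(rid) not in clean:
            continue
        total += 1
        if (int(rid), int(off)) in planted:
            hits += 1
    assert total > 50
    assert hits / total >= 0.95


def test_anchor_dictionary_invariants(toy_graph, toy_genome):
    d = fresh_dict()
    k1 = encode(toy_genome[0:K_TOY])
    k2 = encode(toy_genome[100:100 + K_TOY])
    assert d.add(k1) == 0
    assert d.add(k2) == 1
    assert d.add(k1) == 0  # entries stay unique
    assert len(d) == 2
    assert d.entry(0) == k1 and d.entry(1) == k2
    assert d.get(k2) == 1
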