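import gzip
import os
import shutil

import numpy as np
import pytest
from click.testing import CliRunner

from leon import cli, container
from leon.container import (ContainerError, InputError, ReadRecord,
                            compress_file, decompress_file,
                            read_container_header, read_fastx, write_fastq)


def make_fastq(path, records):
    with open(path, "w") as fh:
        for h, s, q in records:
            fh.write(f"@{h}\n{s}\n+\n{q}\n")


# ---------------------------------------------------------------------------
# FASTQ / FASTA reading
# ---------------------------------------------------------------------------

def test_read_fastx_two_records(tmp_path):
    p = tmp_path / "a.fastq"
    make_fastq(p, [("r1 x/1", "ACGT", "IIII"), ("r2", "GGNTA", "!!!!!")])
    recs = list(read_fastx(p))
    assert len(recs) == 2
    assert recs[0] == ReadRecord("r1 x/1", "ACGT", "IIII", "+")
    assert recs[1].sequence == "GGNTA" and recs[1].quality == "!!!!!"


def test_read_fasta_wrapped_lines(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">chr1 desc\nACGTACGT\nACGT\n>chr2\nTTTT\n")
    recs = list(read_fastx(p))
    assert recs[0].sequence == "ACGTACGTACGT"
    assert recs[0].quality is None
    assert recs[1].header == "chr2"


def test_truncated_fastq_errors_with_record_index(tmp_path):
    p = tmp_path / "bad.fastq"
    p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\n")
    with pytest.raises(InputError, match="record 1"):
        list(read_fastx(p))


def test_length_mismatch_errors_with_record_index(tmp_path):
    p = tmp_path / "bad.fastq"
    p.write_text("@r1\nACGT\n+\nIIII\n@r2\nACGT\n+\nIII\n")
    with pytest.raises(InputError, match="record 1"):
        list(read_fastx(p))


def test_empty_input_rejected(tmp_path):
    p = tmp_path / "empty.fastq"
    p.write_text("")
    with pytest.raises(InputError):
        compress_file(p, tmp_path / "o.leon")


def test_gzip_input_transparent(tmp_path, small_sim_fastq):
    gz = tmp_path / "in.fastq.gz"
    with open(small_sim_fastq, "rb") as src, gzip.open(gz, "wb") as dst:
        shutil.copyfileobj(src, dst)
    out = tmp_path / "o.leon"
    compress_file(gz, out, lossless_qual=True)
    decompress_file(out, tmp_path / "back.fastq")
    assert (tmp_path / "back.fastq").read_bytes() == small_sim_fastq.read_bytes()


# ---------------------------------------------------------------------------
# round trips
# ---------------------------------------------------------------------------

def test_lossless_round_trip_byte_identical(tmp_path, small_sim_fastq):
    out = tmp_path / "o.leon"
    compress_file(small_sim_fastq, out, lossless_qual=True)
    back = tmp_path / "back.fastq"
    decompress_file(out, back)
    assert back.read_bytes() == small_sim_fastq.read_bytes()


def test_lossy_round_trip_headers_sequences_identical(tmp_path, small_sim_fastq):
    out = tmp_path / "o.leon"
    compress_file(small_sim_fastq, out)
    back = tmp_path / "back.fastq"
    decompress_file(out, back)
    a = small_sim_fastq.read_text().splitlines()
    b = back.read_text().splitlines()
    assert a[0::4] == b[0::4]  # headers
    assert a[1::4] == b[1::4]  # sequences
    assert a[2::4] == b[2::4]  # plus lines
    # qualities only change by truncation-to-cap or smoothing-to-cap
    for qa, qb in zip(a[3::4], b[3::4]):
        for ca, cb in zip(qa, qb):
            assert cb == "@" or cb == min(ca, "@")


def test_edge_case_reads_round_trip(tmp_path):
    p = tmp_path / "edge.fastq"
    recs = [("short", "AC", "II"),
            ("has n", "ACGTNNACGTACGTACGTACGTACGTACGTACGTACGTA", "I" * 39),
            ("empty", "", ""),
            ("all n", "N" * 40, "#" * 40),
            ("mixed len", "ACGT" * 30, "J" * 120)]
    make_fastq(p, recs)
    out = tmp_path / "o.leon"
    compress_file(p, out, lossless_qual=True)
    decompress_file(out, tmp_path / "back.fastq")
    assert (tmp_path / "back.fastq").read_bytes() == p.read_bytes()


def test_no_trailing_newline_preserved(tmp_path):
    p = tmp_path / "n.fastq"
    p.write_bytes(b"@r\nACGT\n+\nIIII")
    compress_file(p, tmp_path / "o.leon", lossless_qual=True)
    decompress_file(tmp_path / "o.leon", tmp_path / "back.fastq")
    assert (tmp_path / "back.fastq").read_bytes() == p.read_bytes()


def test_fasta_round_trip_no_quality_section(tmp_path, small_sim):
    genome, _, records = small_sim
    p = tmp_path / "in.fa"
    with open(p, "w") as fh:
        for r in records[:500]:
            fh.write(f">{r.header}\n{r.sequence}\n")
    stats = compress_file(p, tmp_path / "o.leon")
    assert stats["quality"] == 16  # empty section header only (one block)
    decompress_file(tmp_path / "o.leon", tmp_path / "back.fa")
    assert (tmp_path / "back.fa").read_bytes() == p.read_bytes()


def test_self_contained_decompression(tmp_path, small_sim_fastq):
    out = tmp_path / "o.leon"
    compress_file(small_sim_fastq, out, lossless_qual=True)
    elsewhere = tmp_path / "elsewhere"
    elsewhere.mkdir()
    moved = elsewhere / "copy.leon"
    shutil.copy(out, moved)
    decompress_file(moved, elsewhere / "back.fastq")
    assert (elsewhere / "back.fastq").read_bytes() == small_sim_fastq.read_bytes()


def test_multi_block_round_trip(tmp_path, small_sim_fastq):
    out = tmp_path / "o.leon"
    compress_file(small_sim_fastq, out, lossless_qual=True, block_size=700)
    hdr = read_container_header(out)
    assert hdr["n_blocks"] > 10
    decompress_file(out, tmp_path / "back.fastq")
    assert (tmp_path / "back.fastq").read_bytes() == small_sim_fastq.read_bytes()


def test_seq_only_mode(tmp_path, small_sim_fastq):
    out = tmp_path / "o.leon"
    compress_file(small_sim_fastq, out, seq_only=True)
    decompress_file(out, tmp_path / "back.fa")
    seqs = [l for l in (tmp_path / "back.fa").read_text().splitlines()
            if not l.startswith(">")]
    orig = small_sim_fastq.read_text().splitlines()[1::4]
    assert seqs == orig


# ---------------------------------------------------------------------------
# corruption and integrity
# ---------------------------------------------------------------------------

def test_checksum_detects_corruption(tmp_path, small_sim_fastq):
    out = tmp_path / "o.leon"
    compress_file(small_sim_fastq, out)
    data = bytearray(out.read_bytes())
    data[len(data) // 2] ^= 0xFF
    bad = tmp_path / "bad.leon"
    bad.write_bytes(bytes(data))
    with pytest.raises(ContainerError, match="checksum|corrupt"):
        decompress_file(bad, tmp_path / "x.fastq")


def test_truncated_container_rejected(tmp_path, small_sim_fastq):
    out = tmp_path / "o.leon"
    compress_file(small_sim_fastq, out)
    bad = tmp_path / "bad.leon"
    bad.write_bytes(out.read_bytes()[:100])
    with pytest.raises(ContainerError):
        decompress_file(bad, tmp_path / "x.fastq")


def test_not_a_container_rejected(tmp_path, small_sim_fastq):
    with pytest.raises(ContainerError):
        decompress_file(small_sim_fastq, tmp_path / "x.fastq")


def test_decompression_performs_no_kmer_counting(tmp_path, small_sim_fastq,
                                                 monkeypatch):
    out = tmp_path / "o.leon"
    compress_file(small_sim_fastq, out, lossless_qual=True)

    def boom(*a, **k):
        raise AssertionError("counting invoked during decompression")

    import leon.counting
    monkeypatch.setattr(leon.counting, "count_kmers", boom)
    monkeypatch.setattr(container._kernels, "extract_canonical", boom)
    decompress_file(out, tmp_path / "back.fastq")
    assert (tmp_path / "back.fastq").read_bytes() == small_sim_fastq.read_bytes()


# ---------------------------------------------------------------------------
# behavior of the whole pipeline
# ---------------------------------------------------------------------------

def test_beats_gzip_on_high_coverage_dataset(tmp_path):
    from leon.simulate import SimulationSpec, simulate_fastq
    p = tmp_path / "cov.fastq"
    simulate_fastq(p, SimulationSpec(genome_length=200_000, coverage=70,
                                     read_length=100, substitution_rate=0.01,
                                     seed=3))
    stats = compress_file(p, tmp_path / "o.leon")
    gz = gzip.compress(p.read_bytes(), 6)
    gzip_ratio = os.path.getsize(p) / len(gz)
    assert stats["ratio"] > gzip_ratio


def test_graph_size_independent_of_file_size(tmp_path, small_sim):
    # same genome kmer content, 10x more data: Bloom + dictionary stay put
    genome, _, _ = small_sim
    tiles = [(f"t{i}", genome[p:p + 100], "I" * 100)
             for i, p in enumerate(range(0, len(genome) - 100, 10))]
    sizes = {}
    anchors = {}
    for mult in (1, 10):
        p = tmp_path / f"m{mult}.fastq"
        make_fastq(p, tiles * mult)
        st = compress_file(p, tmp_path / f"m{mult}.leon", t_sol=1)
        sizes[mult] = st["graph"]
        anchors[mult] = st["n_anchors"]
    assert sizes[1] == sizes[10]
    n_genome_kmers = len(genome) - 31 + 1
    assert anchors[1] <= n_genome_kmers and anchors[10] <= n_genome_kmers


def test_unanchored_fraction_small_on_high_coverage(tmp_path, small_sim_fastq):
    stats = compress_file(small_sim_fastq, tmp_path / "o.leon")
    assert stats["n_unanchored"] / stats["n_reads"] < 0.05


def test_identical_reads_have_constant_tiny_streams(tmp_path):
    rng = np.random.default_rng(4)
    read = "".join("ACGT"[b] for b in rng.integers(0, 4, 80))
    p = tmp_path / "same.fastq"
    make_fastq(p, [("r", read, "I" * 80)] * 500)
    stats = compress_file(p, tmp_path / "o.leon", lossless_qual=True)
    assert stats["n_anchors"] == 1
    # constant anchor-index stream compresses to (almost) nothing
    assert stats["anchor_idx"] <= 16 + 32   # section header + a few bytes
    decompress_file(tmp_path / "o.leon", tmp_path / "back.fastq")
    assert (tmp_path / "back.fastq").read_bytes() == p.read_bytes()


def test_low_complexity_input_all_raw(tmp_path):
    # random unrelated reads: nothing solid, every read raw, still lossless
    rng = np.random.default_rng(0)
    p = tmp_path / "rand.fastq"
    make_fastq(p, [(f"r{i}", "".join("ACGT"[b] for b in rng.integers(0, 4, 60)),
                    "I" * 60) for i in range(50)])
    stats = compress_file(p, tmp_path / "o.leon", lossless_qual=True)
    assert stats["n_unanchored"] == 50
    decompress_file(tmp_path / "o.leon", tmp_path / "back.fastq")
    assert (tmp_path / "back.fastq").read_bytes() == p.read_bytes()


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def test_cli_round_trip(tmp_path, small_sim_fastq):
    runner = CliRunner()
    out = str(tmp_path / "o.leon")
    back = str(tmp_path / "back.fastq")
    r = runner.invoke(cli.main, ["compress", "-i", str(small_sim_fastq),
                                 "-o", out, "--lossless-qual"])
    assert r.exit_code == 0, r.output
    assert "ratio" in r.output
    r = runner.invoke(cli.main, ["decompress", "-i", out, "-o", back])
    assert r.exit_code == 0, r.output
    assert open(back, "rb").read() == small_sim_fastq.read_bytes()


def test_cli_simulate(tmp_path):
    runner = CliRunner()
    p = str(tmp_path / "sim.fastq")
    r = runner.invoke(cli.main, ["simulate", "-o", p, "--genome-length", "5000",
                                 "--coverage", "5", "--seed", "1"])
    assert r.exit_code == 0, r.output
    recs = list(read_fastx(p))
    assert len(recs) == 250


def test_cli_defaults_recorded_in_container(tmp_path, small_sim_fastq):
    runner = CliRunner()
    out = tmp_path / "o.leon"
    r = runner.invoke(cli.main, ["compress", "-i", str(small_sim_fastq),
                                 "-o", str(out)])
    assert r.exit_code == 0, r.output
    hdr = read_container_header(out)
    assert hdr["k"] == 31
    assert hdr["bits_per_kmer"] == 12
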