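# leon

Reference-free compressor for FASTQ/FASTA short-read files.

Instead of mapping reads to an external reference, the compressor builds a
probabilistic de Bruijn graph *de novo* from the reads themselves: canonical
kmers are counted, a solidity threshold is inferred from the abundance
histogram, and the solid kmers are inserted into a Bloom filter (default 12
bits per solid kmer, 8 hash functions).  Each read is then stored as

* an **anchor**: a solid kmer shared across reads via an insertion-ordered
  dictionary (an index, not a sequence),
* its position, the read length, and
* two **bifurcation lists** describing the graph walk right and left of the
  anchor — empty whenever the read follows a simple path.

Reads with no solid kmer fall back to raw 2-bit sequence.  All component
streams are entropy-coded with an adaptive order-0 range coder; headers are
tokenized and delta-coded against the previous header.  Qualities are either
kept byte-exact (`--lossless-qual`) or lossily smoothed: positions supported
by enough solid kmers are rewritten to `'@'`, with the required support
growing for lower original scores (`sigma = 2` if the score is within 10
code points of `'@'`, else `delta - 5`); the quality stream is DEFLATEd.

Headers and sequences always round-trip byte-exactly; the container is
self-contained (graph + dictionary travel inside it).  Memory scales with
the genome, not the file: doubling coverage leaves the graph size unchanged.
The byte-level container layout is specified in `docs/FORMAT.md`.

## CLI

```sh
# compress (lossy qualities by default)
leon compress -i reads.fastq -o reads.leon \
    [-k 31] [--abundance auto|INT] [--bits-per-kmer 12] \
    [--lossless-qual] [--seq-only] [--block-size 50000]

# decompress
leon decompress -i reads.leon -o reads.fastq

# generate a synthetic dataset with ground-truth headers
leon simulate -o sim.fastq --genome-length 1000000 --coverage 70 \
    --error-rate 0.01 --seed 42
```

gzip-compressed input is detected automatically.  `--abundance` is the
minimum solid abundance (a kmer is solid when its count is `>=` the
threshold); `auto` infers it from the valley of the abundance histogram.
FASTA output is normalized to one sequence per line.  Sequences may contain
`A/C/G/T/N` (uppercase); `N` positions are stored in a side stream.

## Library

One module per concern: `kmer_model` (2-bit kmers), `counting` (abundance
histogram, threshold), `probabilistic_dbg` (Bloom graph), `sequence_codec`
(anchors + bifurcation lists), `entropy_coding` (range coder),
`quality_codec`, `header_codec`, `container` (I/O + pipeline), `simulate`
(synthetic data).  Hot paths are numba kernels in `_kernels`; the sequence
codec also ships a plain-Python per-read reference implementation that the
tests cross-check against the kernels.

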