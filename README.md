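# cdbganno

Dynamic compression of colored de Bruijn graph annotations.

A colored de Bruijn graph attaches metadata labels (*colors*) to the k-mers
of a sequence collection: formally an n × m binary annotation matrix A with
one row per graph edge e_i and one column per color j, A_ji = 1{e_i has
color j}. At pan-genome scale (hundreds of millions of edges, thousands of
colors) this matrix dominates the index size, and it keeps changing as new
samples arrive. `cdbganno` implements two dynamic codecs for it:

- **Wavelet trie (lossless).** Rows are encoded in a compact binary prefix
  tree of (α, β) nodes — α the longest common prefix of the vectors at a
  node, β the assignment vector routing each vector to a child by its next
  significant bit. Querying row i costs one root-to-leaf traversal using
  rank0/rank1 on the β's. Construction is exact under batching: tries built
  from consecutive row batches merge (Align/Merge/Repeat) into precisely the
  trie of the concatenated rows, and rows can be inserted, deleted, and
  updated in place. Prepending *class indicator bits* (one column per group
  of similar colors) steers the top of the trie into a by-class partition
  and can improve compression severalfold.
- **Bloom filters (lossy, one-sided).** Each color becomes one Bloom filter
  over edge k-mers, sized per column via d = ⌈−log2 p⌉,
  b = ⌈−s·log2(p)/ln 2⌉ for target false-positive probability p, with
  FPP(b,d,s) ≈ (1 − e^{−ds/b})^d. There are never false negatives. Because
  edges along a linear graph path share their coloring (guaranteed by
  wrapping inputs in a `$` sentinel), raw queries are corrected by
  intersecting them along the path, dropping the effective FPP to
  ≈ FPP^ℓ for a window of ℓ edges — large accuracy at a fraction of the
  bits.

Both codecs treat colors as independent modules and survive graph growth.
A synthetic genome-family generator (classes of related strains with
controllable divergence) makes the whole pipeline testable offline.

## Worked example

```bash
# simulate 2 classes x 2 genomes of 300 bp
cdbganno simulate --classes 2 --genomes-per-class 2 --length 300 --seed 7 \
    --out-prefix fam

# lossless wavelet-trie archive (k = 11 for this toy)
cdbganno compress fam.fasta --labels fam.labels.tsv --k 11 \
    --codec wtrie -o fam.wtr
cdbganno stats fam.wtr
```

```
k	11
sentinels	0
n_edges	1172
m_colors	4
codec	wtrie
trie_nodes	15
payload_bits	5155
overhead_bits	42
bits_per_edge	4.4343
compression_ratio	0.9021
```

1172 edges × 4 colors compress to 15 trie nodes and ≈ 4.4 bits per edge
(this toy matrix is nearly incompressible — only 4 colors and near-unique
rows; compression ratios grow with color count and row redundancy). Querying
a sequence decodes one row per k-mer along its edge path:

```bash
cdbganno query fam.wtr "GCTTGCAGTCAGG..."
```

```
query	kmer	edge_id	coloring
query	GCTTGCAGTCA	1	1100
query	CTTGCAGTCAG	2	1100
...
```

Each `coloring` is the decoded matrix row: this k-mer occurs in the first
two genomes (both class-0) and not in the others. The Bloom codec prints a
`raw_coloring` column next to the corrected one:

```bash
cdbganno compress fam.fasta --labels fam.labels.tsv --k 11 \
    --codec bloom --fpp 0.01 -o fam.blm
cdbganno query fam.blm "GCTTGCAGTCAGG..."
```

The sweep and permutation experiments are available as `cdbganno eval sweep`
and `cdbganno eval permtest`; `merge` and `insert` update existing archives.

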