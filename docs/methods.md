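# Methods

`cdbganno` compresses the annotation of a colored de Bruijn graph: the n × m
binary matrix A with one row per graph edge (k-mer) and one column per color
(metadata label), A_ji = 1 iff edge e_i carries color j. Two codecs are
provided — a lossless wavelet-trie row codec and a lossy Bloom-filter column
codec corrected through graph topology — together with a synthetic genome
family generator so every claim can be tested end to end without external
data.

## Graph and annotation model

The graph is node-centric: every observed k-mer of the input sequences *and
of their reverse complements* is an edge, stored in a hash table with dense
ids 1..n assigned in first-insertion order. That insertion order is the row
order of A. We deliberately do **not** canonicalize strand pairs: forward and
reverse-complement k-mers are distinct edges, which roughly doubles n
relative to canonical-k-mer tools but keeps the coloring semantics a direct
read-off of the inputs. `N` is part of the alphabet and is its own
complement; likewise the sentinel `$`.

When duplicate k-mers arise (within a sequence, between strands, or between
differently labeled sequences), their coloring vectors are combined by
bitwise OR. Whether the duplicates came from different strands of different
colors makes no difference — all duplicates are OR-merged.

Sequences may be wrapped in `$` before k-mer extraction (`add_sentinels`).
Sentinel k-mers bound *linear paths* (directed paths whose interior nodes
have exactly one incoming and one outgoing edge), which guarantees that every
edge inside a linear path derives from the same set of input sequences and
hence carries an identical coloring. The Bloom correction relies on exactly
this property, so sentinels default to on for the Bloom codec and off for the
wavelet trie.

Default k is 63, the common order for pan-genome-scale colored graphs; it is
overridable everywhere.

## Wavelet-trie codec

Rows are encoded into a compact binary prefix tree. Each node holds a longest
common prefix α and an assignment vector β; construction strips the LCP of
the vectors assigned to a node into α, records each vector's next bit in β,
and recurses left (0) and right (1) on the stripped suffixes. A node whose
vectors are all equal is a leaf (β an all-zero run recording multiplicity).
Query of row i walks the tree, concatenating α's and branch bits while
renumbering i with rank0/rank1 on β.

Key design points:

- **Fixed width.** All rows are right-padded with 0s to the matrix width m.
  Equal-width vectors are never strict prefixes of one another, so the merge
  procedure needs no prefix-freeness assumption.
- **Canonicality.** For a given row tuple the compact trie is unique: a
  node's β always mixes 0s and 1s (otherwise its α was not the LCP). All
  editing operations preserve this, so batched construction can assert
  *structural* equality with direct construction, a much stronger check than
  decode equality.
- **Merge.** Two tries are merged top-down. At each node pair, α̂ =
  LCP(α′, α″); a node whose α extends past α̂ is split: the remainder (after
  the branch bit at position |α̂|+1) moves into a fresh child that inherits
  the old β and children, and the parent's new β is the constant vector of
  that branch bit. After alignment both nodes expose equal α's, the β's are
  concatenated (more generally spliced, which is what row insertion at an
  arbitrary position uses), and the children merge recursively with positions
  renumbered through rank0/rank1. A leaf whose α equals the full remaining
  suffix can only meet another such leaf, so the align step is total.
- **Edits.** `insert_rows` is a positional merge against a trie built from
  the inserted rows. `delete_row` removes one β entry along the row's path;
  an emptied branch causes the surviving child to be absorbed into its
  parent (α ← α · branch-bit · child.α), keeping the trie compact.
  `update_row` is delete + insert at the same position. Adding columns later
  is supported by extending leaf α's with zeros (`pad_width`).
- **Node bound.** After every operation the suite asserts
  |V_T| ≤ min(2n−1, 2^(m+1)−1): at most n leaves in a full binary tree, and
  a complete trie over width-m vectors (all 2^m distinct rows present) has
  2^(m+1)−1 nodes. Height is at most m+1 nodes, bounding query cost.
- **Construction cost.** The implementation deduplicates rows first and
  recurses over unique rows, so the cost is O(u·m) on the unique rows u plus
  O(n · branching-depth) to assemble the β vectors — in colored-graph data u
  (the number of distinct colorings) is typically orders of magnitude smaller
  than n.
- **Serialization.** Pre-order bitstream: per node a leaf flag, an
  Elias-gamma code of |α|+1, the α bits, and the β bits (β lengths are
  implied by the parent's rank counts, so they are not stored).
  `compressed_size()` reports payload (Σ|α|+|β|) and structural overhead
  (flags + length codes) separately; all bits-per-edge figures use their sum.

Rank/select is served by an immutable numpy-backed bit vector with a blocked
popcount index (1-based positions, inclusive slices — the succinct-structure
convention). Entropy-coded (RRR) bit-vector storage would shrink the β's
further but only changes the storage constant, not the interface; we
deliberately ship the plain blocked-index structure.

### Class indicator columns

The trie compresses well when rows share long prefixes. Given a mapping from
colors to similarity classes (e.g. species), one indicator column per class
is **prepended** to the matrix: the indicator for class C is set on a row iff
any of the row's colors belongs to C. Low-index indicators make the first few
branchings of the trie partition the rows by class, after which each subtree
sees long constant runs (the other classes' columns are all zero there). The
indicator block is recorded in the matrix metadata so it can be stripped
exactly. Indicator columns are ordered by class name; re-application is
rejected.

## Bloom-filter codec

Each column j becomes one Bloom filter keyed by the edge k-mer strings
(including `$`/`N` characters verbatim). With b bits, d hashes, and s
insertions the false-positive probability is approximately
FPP(b,d,s) = (1 − e^{−ds/b})^d; given a target p the filter is sized
d = ⌈−log2 p⌉, b = ⌈−s·log2(p)/ln 2⌉, with s taken from the exact column
count. Membership errors are one-sided: no false negatives, ever.

Hashing is double hashing h_i(x) = (u(x) + i·v(x)) mod b with u, v two
independent 64-bit FNV-1a-style hashes under fixed library-wide seeds (v is
forced odd). This is deterministic across runs and platforms and vectorizes
over numpy arrays, so whole columns are inserted and whole graphs decoded in
a handful of array operations.

### Neighborhood correction

Under the shared-coloring-per-linear-path assumption, the corrected
annotation of edge e is the bitwise AND of raw queries over a neighborhood
N(e) inside e's linear path. A surviving false positive then requires every
edge in the window to be a false positive independently, so for a window of
cardinality ℓ the corrected FPP is approximately (1 − e^{−ds/b})^{dℓ}.

`query_corrected` implements the bounded bidirectional walk: up to `l_max`
steps in each direction, stopping early at branchings or sentinel k-mers
(this is the bounded, restartable form of fixed-point propagation along the
path; on a linear path the two coincide). The default budget is 100 steps per
direction, consistent with the typical traversal counts needed to push
accuracy above 95–99% on pan-genome-like data. The Monte-Carlo calibration
test compares against the ℓ-exponent model using windows of exactly ℓ
consecutive path edges, so the exponent is compared like for like.

`decode_corrected_all` computes the same quantity for every edge at once: the
graph is decomposed into maximal linear paths, and within each path the
windowed AND is evaluated with prefix sums over the raw membership bits
(window clamped at path ends). The walk-based and vectorized routes are
cross-checked against each other in the tests.

Bits-per-edge for this codec is Σ_j b_j / n, excluding seeds and per-filter
metadata (a few dozen bytes total). Corrected queries need the graph section
of the archive; the filters alone cannot be corrected.

## Synthetic families and evaluation

`SyntheticFamilySpec` models a pan-genome collection with class structure:
one global ancestor (uniform ACGT), one ancestor per class at the
between-class substitution rate, and each genome derived from its class
ancestor at the within-class rate. Substitutions always change the base; a
single seed drives everything, and identical specs are byte-identical.

Defaults — 5 classes × 10 genomes × 20 kb, 0.5% within-class and 10%
between-class divergence — model species-level classes of closely related
strains: at k = 63, a substitution rate r kills a fraction ≈ 1 − (1−r)^{2k}
of shared k-mers between two genomes, so 0.5% leaves roughly half of k-mers
shared within a class while 10% makes classes essentially k-mer-disjoint.
The model has **no indels, no repeats, no sequencing error**; real data has
all three. Passing tests therefore demonstrate correctness of the codecs and
of the calibration model, and the *direction* of the topology effects — not
the absolute compression ratios achievable on real pan-genomes, which depend
on row-coloring redundancy far beyond this generator.

Evaluation procedures:

- **Accuracy** is the fraction of edges whose decoded row equals the truth
  exactly. Sentinel-containing edges are excluded from the denominator in
  graph sweeps (their paths are degenerate singletons by construction); the
  wavelet trie is exact everywhere by design.
- **Column-permutation experiment**: the matrix is trie-compressed under the
  original column order and under N random orders of *all* columns; the
  empirical p-value uses the add-one estimator
  (1 + #{null ≤ original}) / (1 + N), so it is never zero. When class
  indicators are present, the null also moves them away from the prefix:
  what the experiment measures is precisely whether the prefix placement of
  the indicator block (plus the induced color order) is optimal. The
  alternative convention — pinning the indicator prefix and permuting only
  the color columns — is available via ``fix_indicators=True`` but carries
  almost no signal, for a structural reason: once the indicators sit at the
  prefix, the class partition happens at the top of the trie under *any*
  order of the remaining columns, and the other class's all-zero columns are
  absorbed into shared α's wherever they land, leaving only second-order
  size differences. A related pitfall found while designing the fixture:
  within-class *correlated* column structure (interval or nested-run rows)
  makes random orders compress better than the sorted order, because a
  random order splits a nested family like balanced binary search while the
  sorted order peels it linearly. The shipped two-class fixture therefore
  uses uniform within-block columns, where the block-versus-scattered
  contrast is what the null detects.
- **Bloom sweep**: full factorial target-FPP × correction-budget grid,
  reporting achieved bits-per-edge and accuracy; from it we read off the
  smallest bits-per-edge reaching a target accuracy with and without
  correction.

## Problem sizes and numerical choices

The shipped test-suite and acceptance-script runs use the default family
(≈ 7.4 × 10^5 edges, 50 colors), 10^5 probes for Bloom calibration (3
binomial standard errors as the agreement band), 100 permutations for the
column-order test, and exhaustive enumeration of all matrices with
n·m ≤ 12 plus 10^3 random matrices up to 512 × 64 for losslessness. Bloom
correction calibration uses disjoint (non-overlapping) windows so the
binomial error model is valid. Degenerate inputs are defined, not special
cases: empty record lists give empty graphs, empty row tuples give empty
tries, zero-count columns give minimal always-negative filters, and density
and ratio metrics raise on n = 0 rather than returning NaN.

## Known limitations

- No strand canonicalization (doubles n; documented above).
- The CLI `merge` requires identical color dictionaries; archives with
  different dictionaries must go through `insert`.
- Bloom filters are not deletable or counting; removing a color means
  rebuilding that one filter (each color is an independent module).
- The permutation experiment recompresses the matrix once per permutation;
  it is meant for evaluation-sized matrices, not full pan-genomes.
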