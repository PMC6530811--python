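"""Synthetic genome families and the evaluation procedures.

The generator emulates a pan-genome collection with class structure, like a
set of viral or bacterial strains grouped by species: a global ancestral
sequence gives rise to one ancestor per class (substitutions at the
between-class rate), and each genome in a class derives from its class
ancestor by i.i.d. substitutions at the within-class rate.  There are no
indels, so k-mer sharing between genomes is analytically predictable.  All
randomness flows from the single seed in the spec; identical specs produce
byte-identical families.

Evaluation covers the three study procedures: decoding accuracy (fraction of
edges whose decoded coloring equals the truth exactly), the column-permutation
null experiment for wavelet-trie sizes, and the Bloom filter size/accuracy
sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import bloom as bloom_mod
from .annotation import (
    AnnotationMatrix,
    add_class_indicators,
    build_annotation,
    permute_columns,
)
from .graph import KmerGraph, build_graph
from .wtrie import WaveletTrie

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of a synthetic genome family.

    Defaults model five species-level classes of ten closely related strains
    each: 20 kb genomes, 0.5% within-class and 10% between-class divergence
    (at k = 63, a 10% rate makes k-mer sharing between classes negligible
    while 0.5% leaves roughly half of all k-mers shared within a class).
    """

    n_classes: int = 5
    genomes_per_class: int = 10
    genome_length: int = 20_000
    within_class_divergence: float = 0.005
    between_class_divergence: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if min(self.n_classes, self.genomes_per_class, self.genome_length) < 1:
            raise ValueError("all counts must be >= 1")
        for r in (self.within_class_divergence, self.between_class_divergence):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"divergence rate {r} outside [0, 1]")


@dataclass(frozen=True)
class FamilyRecord:
    sequence: str
    label: str
    class_name: str


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position independently with the given rate; a substituted
    base always changes (shift by 1..3 mod 4)."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def generate_family(spec: SyntheticFamilySpec) -> List[FamilyRecord]:
    """Generate the genome family described by ``spec`` (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    root = rng.integers(0, 4, size=spec.genome_length, dtype=np.int8)
    records: List[FamilyRecord] = []
    for c in range(spec.n_classes):
        cname = f"class{c:02d}"
        ancestor = _mutate(root, spec.between_class_divergence, rng)
        for g in range(spec.genomes_per_class):
            genome = _mutate(ancestor, spec.within_class_divergence, rng)
            records.append(
                FamilyRecord(_to_str(genome), f"{cname}_g{g:02d}", cname)
            )
    return records


def class_assignment(records: Sequence[FamilyRecord]) -> Dict[str, str]:
    """Color-name -> class-name mapping for a generated family."""
    return {r.label: r.class_name for r in records}


def family_graph(
    records: Sequence[FamilyRecord], k: int, add_sentinels: bool = True
) -> Tuple[KmerGraph, AnnotationMatrix]:
    """Convenience: build graph + annotation matrix from a family."""
    g, colorings = build_graph([(r.sequence, r.label) for r in records], k,
                               add_sentinels=add_sentinels)
    labels = [r.label for r in records]
    return g, build_annotation(g, colorings, color_names=labels)


# -- accuracy ---------------------------------------------------------------

def accuracy(
    truth: AnnotationMatrix,
    decoded_rows: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Average fraction of edges whose decoded coloring equals the true row
    exactly; ``mask`` restricts the denominator (e.g. to non-sentinel edges)."""
    decoded = np.asarray(decoded_rows, dtype=np.uint8)
    if decoded.shape != truth.matrix.shape:
        raise ValueError(
            f"shape mismatch: decoded {decoded.shape} vs truth {truth.matrix.shape}"
        )
    correct = (decoded == truth.matrix).all(axis=1)
    if mask is not None:
        correct = correct[mask]
    if correct.size == 0:
        raise ValueError("no edges in accuracy denominator")
    return float(correct.mean())


# -- column-permutation experiment ------------------------------------------

@dataclass
class EvalReport:
    """Result of the column-permutation null experiment."""

    original_size_bits: int
    permutation_null: List[int]
    empirical_p: float
    compression_ratio: float
    bits_per_edge: float


def wtrie_size_bits(a: AnnotationMatrix) -> int:
    """Serialized wavelet-trie size (payload + structural overhead) in bits."""
    return WaveletTrie.construct(a.matrix).compressed_size().total_bits


def permutation_experiment(
    a: AnnotationMatrix,
    n_permutations: int = 100,
    seed: int = 0,
    fix_indicators: bool = False,
) -> EvalReport:
    """Compare the original column order against a permutation null.

    The matrix is trie-compressed under the original order and under
    ``n_permutations`` uniformly random orders of *all* columns — when class
    indicators are present, the null therefore also moves them away from the
    prefix, so the experiment tests the placement of the indicator columns
    together with the ordering of the color columns.  (With the prefix
    pinned, the class partition at the top of the trie survives any
    permutation of the remaining columns and the null carries almost no
    signal; see the methods note.)  ``fix_indicators`` restores the pinned
    variant.  The add-one estimator gives the empirical p-value of the
    hypothesis that the original order is no better than random, so p is
    never exactly zero.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    original = wtrie_size_bits(a)
    width = a.m - a.indicator_count if fix_indicators else a.m
    null: List[int] = []
    for _ in range(n_permutations):
        order = rng.permutation(width)
        null.append(
            wtrie_size_bits(permute_columns(a, order, fix_indicators=fix_indicators))
        )
    p = (1 + sum(1 for s in null if s <= original)) / (1 + n_permutations)
    return EvalReport(
        original_size_bits=original,
        permutation_null=null,
        empirical_p=p,
        compression_ratio=(a.n * a.m) / original if a.n else float("nan"),
        bits_per_edge=original / a.n if a.n else float("nan"),
    )


def two_class_block_matrix(
    n_rows: int = 512,
    colors_per_class: int = 16,
    density: float = 0.4,
    seed: int = 0,
    with_indicators: bool = True,
) -> AnnotationMatrix:
    """A synthetic two-class matrix with block column structure.

    Rows belong to one of two classes; a row's colors are drawn only from its
    class's contiguous column block, so under the original column order rows
    of one class share long zero runs over the other class's block.  With
    ``with_indicators`` two class-indicator columns are prepended.
    """
    rng = np.random.default_rng(seed)
    m = 2 * colors_per_class
    mat = np.zeros((n_rows, m), dtype=np.uint8)
    cls = rng.integers(0, 2, size=n_rows)
    for i in range(n_rows):
        lo = cls[i] * colors_per_class
        block = rng.random(colors_per_class) < density
        if not block.any():
            block[rng.integers(colors_per_class)] = True
        mat[i, lo : lo + colors_per_class] = block
    names = [f"P{j:02d}" for j in range(colors_per_class)] + [
        f"Q{j:02d}" for j in range(colors_per_class)
    ]
    a = AnnotationMatrix(mat, names, 0)
    if with_indicators:
        classes = {n: ("P" if n.startswith("P") else "Q") for n in names}
        a = add_class_indicators(a, classes)
    return a


# -- Bloom sweep ------------------------------------------------------------

def sweep_bloom(
    g: KmerGraph,
    a: AnnotationMatrix,
    fpp_grid: Sequence[float],
    lmax_grid: Sequence[int],
    exclude_sentinel_edges: bool = True,
) -> pd.DataFrame:
    """Full factorial sweep of target FPP x correction budget.

    For each target FPP the matrix is Bloom-compressed once; for each
    ``l_max`` the whole graph is decoded with that correction budget and the
    exact-row accuracy is measured.  Sentinel-containing edges are excluded
    from the accuracy denominator by default (their neighborhoods are
    degenerate by construction).  Returns a tidy table with columns
    fpp, l_max, bits_per_edge, accuracy.
    """
    if not len(fpp_grid) or not len(lmax_grid):
        raise ValueError("grids must be non-empty")
    mask = ~g.sentinel_mask() if exclude_sentinel_edges else None
    rows = []
    for p in fpp_grid:
        ba = bloom_mod.compress(a, g, p)
        bpe = ba.bits_per_edge()
        for lmax in lmax_grid:
            dec = ba.decode_corrected_all(lmax)
            rows.append(
                {
                    "fpp": p,
                    "l_max": lmax,
                    "bits_per_edge": bpe,
                    "accuracy": accuracy(a, dec, mask),
                }
            )
    return pd.DataFrame(rows)


def min_bits_per_edge_at_accuracy(
    sweep: pd.DataFrame, l_max: int, target: float
) -> Optional[float]:
    """Smallest bits-per-edge in the sweep reaching the target accuracy at the
    given correction budget, or None if never reached."""
    sub = sweep[(sweep["l_max"] == l_max) & (sweep["accuracy"] >= target)]
    if sub.empty:
        return None
    return float(sub["bits_per_edge"].min())
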