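"""The binary annotation matrix of a colored de Bruijn graph.

Rows correspond to graph edges (in edge-id order), columns to colors; entry
(i, j) is 1 iff edge e_i carries color j.  The matrix may carry a prefix of
*class indicator columns*: one extra column per similarity class of colors,
set for a row whenever any of its colors belongs to that class.  Placing the
indicators at low column indices steers the wavelet-trie partition so that
rows from the same class are grouped near the root, which is what makes them
improve compression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .bitvec import RankBitVector
from .graph import KmerGraph

INDICATOR_PREFIX = "class:"


class ColorDictionaryError(KeyError):
    pass


class ClassAssignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationMatrix:
    """n x m binary matrix over graph edges x colors.

    ``matrix`` is a read-only uint8 array of 0/1; ``color_names`` has one
    unique name per column; the first ``indicator_count`` columns are class
    indicators (0 when none were added).
    """

    matrix: np.ndarray
    color_names: List[str]
    indicator_count: int = 0

    def __post_init__(self):
        m = np.ascontiguousarray(np.asarray(self.matrix, dtype=np.uint8))
        if m.ndim != 2:
            raise ValueError("annotation matrix must be two-dimensional")
        if m.size and m.max() > 1:
            raise ValueError("annotation matrix entries must be 0/1")
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)
        if len(self.color_names) != m.shape[1]:
            raise ValueError(
                f"{len(self.color_names)} color names for {m.shape[1]} columns"
            )
        if len(set(self.color_names)) != len(self.color_names):
            raise ValueError("duplicate color names")
        if not 0 <= self.indicator_count <= m.shape[1]:
            raise ValueError("indicator_count out of range")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    @property
    def set_bits(self) -> int:
        return int(self.matrix.sum())

    def row(self, i: int) -> RankBitVector:
        """Row of edge e_i (1-based)."""
        if not 1 <= i <= self.n:
            raise IndexError(f"row {i} out of range 1..{self.n}")
        return RankBitVector(self.matrix[i - 1])

    def rows(self) -> Iterable[RankBitVector]:
        return (RankBitVector(r) for r in self.matrix)

    # -- text round trip (test fixtures, CLI inspection) --------------------

    def to_text(self) -> str:
        header = "#indicators=%d\tcolors=%s\n" % (
            self.indicator_count,
            ",".join(self.color_names),
        )
        body = "\n".join((r + ord("0")).tobytes().decode() for r in self.matrix)
        return header + body + ("\n" if self.n else "")

    @classmethod
    def from_text(cls, text: str) -> "AnnotationMatrix":
        lines = [ln for ln in text.splitlines() if ln]
        if not lines or not lines[0].startswith("#indicators="):
            raise ValueError("missing annotation-matrix header")
        head, colors_field = lines[0].split("\t", 1)
        indicator_count = int(head[len("#indicators="):])
        tail = colors_field[len("colors="):]
        names = tail.split(",") if tail else []
        rows = lines[1:]
        if rows:
            mat = np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)
        else:
            mat = np.zeros((0, len(names)), dtype=np.uint8)
        return cls(mat, names, indicator_count)


def build_annotation(
    g: KmerGraph,
    colorings: Sequence[set],
    color_names: Optional[Sequence[str]] = None,
) -> AnnotationMatrix:
    """Assemble the annotation matrix from per-edge label sets.

    Column order follows ``color_names`` when given, otherwise first
    observation order over edges.  Every label in ``colorings`` must appear in
    the dictionary.
    """
    if len(colorings) != g.n_edges:
        raise ValueError(
            f"{len(colorings)} colorings for {g.n_edges} edges"
        )
    if color_names is None:
        names: List[str] = []
        seen = set()
        for labels in colorings:
            for lab in sorted(labels):
                if lab not in seen:
                    seen.add(lab)
                    names.append(lab)
    else:
        names = list(color_names)
    index = {name: j for j, name in enumerate(names)}
    mat = np.zeros((g.n_edges, len(names)), dtype=np.uint8)
    for i, labels in enumerate(colorings):
        for lab in labels:
            j = index.get(lab)
            if j is None:
                raise ColorDictionaryError(f"label {lab!r} not in color dictionary")
            mat[i, j] = 1
    return AnnotationMatrix(mat, names, 0)


def add_class_indicators(
    a: AnnotationMatrix, classes: Mapping[str, str]
) -> AnnotationMatrix:
    """Prepend one indicator column per distinct class (low-index placement).

    ``classes`` maps every color name to its class; the indicator bit for
    class C is set on row i iff any color of row i belongs to C.  Indicator
    columns are ordered by class name.  Re-application is rejected.
    """
    if a.indicator_count:
        raise ClassAssignmentError("matrix already carries class indicators")
    missing = [c for c in a.color_names if c not in classes]
    if missing:
        raise ClassAssignmentError(f"colors without class assignment: {missing[:5]}")
    class_names = sorted(set(classes[c] for c in a.color_names))
    cols = np.zeros((a.n, len(class_names)), dtype=np.uint8)
    cidx = {name: j for j, name in enumerate(class_names)}
    for j, color in enumerate(a.color_names):
        k = cidx[classes[color]]
        np.maximum(cols[:, k], a.matrix[:, j], out=cols[:, k])
    mat = np.concatenate([cols, a.matrix], axis=1)
    names = [INDICATOR_PREFIX + c for c in class_names] + list(a.color_names)
    return AnnotationMatrix(mat, names, len(class_names))


def strip_class_indicators(a: AnnotationMatrix) -> AnnotationMatrix:
    """Drop the indicator prefix, recovering the original matrix exactly."""
    c = a.indicator_count
    if c == 0:
        return a
    return AnnotationMatrix(a.matrix[:, c:], a.color_names[c:], 0)


def permute_columns(
    a: AnnotationMatrix,
    order: Sequence[int],
    fix_indicators: bool = True,
) -> AnnotationMatrix:
    """Reorder columns; with ``fix_indicators`` the indicator prefix stays put
    and ``order`` permutes only the non-indicator columns (0-based, relative
    to the non-indicator block)."""
    c = a.indicator_count if fix_indicators else 0
    order = np.asarray(order, dtype=np.int64)
    width = a.m - c
    if sorted(order.tolist()) != list(range(width)):
        raise ValueError("order must be a permutation of the permutable columns")
    full = np.concatenate([np.arange(c), order + c])
    return AnnotationMatrix(
        a.matrix[:, full],
        [a.color_names[j] for j in full],
        a.indicator_count if fix_indicators else 0,
    )


# -- size metrics -----------------------------------------------------------

def density(a: AnnotationMatrix) -> float:
    """Fraction of set bits, s / (n*m)."""
    if a.n == 0 or a.m == 0:
        raise ValueError("density undefined for an empty matrix")
    return a.set_bits / (a.n * a.m)


def bits_per_edge(compressed_size_bits: int, n: int) -> float:
    if n == 0:
        raise ValueError("bits per edge undefined for n = 0")
    return compressed_size_bits / n


def compression_ratio(a: AnnotationMatrix, compressed_size_bits: int) -> float:
    """Uncompressed matrix bits divided by compressed-representation bits."""
    if a.n == 0:
        raise ValueError("compression ratio undefined for n = 0")
    return (a.n * a.m) / compressed_size_bits
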