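"""Node-centric de Bruijn graph over a k-mer hash table.

The graph stores every observed k-mer of the input sequences *and of their
reverse complements* as an edge.  Edges receive dense integer ids 1..n in
first-insertion order; this ordering fixes the row order of the annotation
matrix.  Forward and reverse-complement k-mers are kept as distinct edges (no
canonicalization), which doubles n relative to canonical-k-mer tools but keeps
the coloring semantics direct.

Sequences may optionally be wrapped in a sentinel character ``$`` before k-mer
extraction.  Sentinel k-mers bound linear paths, which guarantees that all
edges inside a linear path originate from the same set of input sequences and
hence share an identical coloring — the assumption the Bloom-filter
neighborhood correction relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

SENTINEL = "$"
ALPHABET = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTN$acgtn", "TGCAN$tgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N,$}; N and $ are self-complementary."""
    return seq.translate(_COMPLEMENT)[::-1]


class GraphConfigError(ValueError):
    pass


class UnknownEdgeError(KeyError):
    pass


@dataclass
class LinearNeighborhood:
    """A contiguous window of edges along the linear path through ``center``.

    ``members`` runs upstream-to-downstream and always contains the center.
    ``truncated_left``/``truncated_right`` record whether the walk stopped at a
    structural boundary (a branching node or a sentinel k-mer) rather than at
    the step budget.
    """

    center: int
    members: List[int]
    truncated_left: bool
    truncated_right: bool


class KmerGraph:
    """Hash-backed de Bruijn graph of order k with stable edge ordering."""

    def __init__(self, k: int, sentinels: bool = False):
        if k < 2:
            raise GraphConfigError(f"k must be >= 2, got {k}")
        self.k = int(k)
        self.sentinels = bool(sentinels)
        self._id: Dict[str, int] = {}
        self._kmers: List[str] = []
        self._succ_index: Optional[Dict[str, List[int]]] = None
        self._pred_index: Optional[Dict[str, List[int]]] = None

    # -- construction -------------------------------------------------------

    def add_kmer(self, kmer: str) -> int:
        """Insert a k-mer (idempotent) and return its edge id."""
        eid = self._id.get(kmer)
        if eid is None:
            eid = len(self._kmers) + 1
            self._id[kmer] = eid
            self._kmers.append(kmer)
            self._succ_index = None
            self._pred_index = None
        return eid

    # -- lookups ------------------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self._kmers)

    def __len__(self) -> int:
        return len(self._kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self._id

    def edge_id(self, kmer: str) -> Optional[int]:
        return self._id.get(kmer)

    def kmer(self, eid: int) -> str:
        if not 1 <= eid <= len(self._kmers):
            raise UnknownEdgeError(f"edge id {eid} out of range 1..{len(self._kmers)}")
        return self._kmers[eid - 1]

    @property
    def kmers(self) -> Sequence[str]:
        """All k-mers in edge-id order (index 0 holds edge 1)."""
        return self._kmers

    # -- adjacency ----------------------------------------------------------

    def _indexes(self) -> Tuple[Dict[str, List[int]], Dict[str, List[int]]]:
        if self._succ_index is None:
            succ: Dict[str, List[int]] = {}
            pred: Dict[str, List[int]] = {}
            for i, km in enumerate(self._kmers, start=1):
                succ.setdefault(km[:-1], []).append(i)
                pred.setdefault(km[1:], []).append(i)
            self._succ_index = succ
            self._pred_index = pred
        return self._succ_index, self._pred_index

    def successors(self, eid: int) -> List[int]:
        """Edges whose (k-1)-prefix equals this edge's (k-1)-suffix."""
        succ, _ = self._indexes()
        return succ.get(self.kmer(eid)[1:], [])

    def predecessors(self, eid: int) -> List[int]:
        _, pred = self._indexes()
        return pred.get(self.kmer(eid)[:-1], [])

    def outdegree(self, eid: int) -> int:
        return len(self.successors(eid))

    def indegree(self, eid: int) -> int:
        return len(self.predecessors(eid))

    # -- linear-path machinery ----------------------------------------------

    def _linked_successor(self, eid: int) -> Optional[int]:
        """The unique linear continuation of ``eid``, or None at a boundary.

        A link e -> f requires that f is the only successor of e, e is the
        only predecessor of f, and neither k-mer contains the sentinel.
        """
        if SENTINEL in self.kmer(eid):
            return None
        succ = self.successors(eid)
        if len(succ) != 1:
            return None
        nxt = succ[0]
        if SENTINEL in self.kmer(nxt):
            return None
        if len(self.predecessors(nxt)) != 1:
            return None
        return nxt

    def _linked_predecessor(self, eid: int) -> Optional[int]:
        if SENTINEL in self.kmer(eid):
            return None
        pred = self.predecessors(eid)
        if len(pred) != 1:
            return None
        prv = pred[0]
        if SENTINEL in self.kmer(prv):
            return None
        if len(self.successors(prv)) != 1:
            return None
        return prv

    def neighborhood(self, eid: int, max_steps: int) -> LinearNeighborhood:
        """Bounded bidirectional walk along the linear path through ``eid``.

        Stops in each direction at a branching node, at a sentinel k-mer, or
        after ``max_steps`` steps; |members| <= 2*max_steps + 1.
        """
        self.kmer(eid)  # validates the id
        back: List[int] = []
        cur = eid
        truncated_left = False
        for _ in range(max_steps):
            prv = self._linked_predecessor(cur)
            if prv is None:
                truncated_left = True
                break
            back.append(prv)
            cur = prv
        else:
            # ran out of budget; boundary status unknown -> not truncated
            truncated_left = max_steps == 0 and self._linked_predecessor(eid) is None
        fwd: List[int] = []
        cur = eid
        truncated_right = False
        for _ in range(max_steps):
            nxt = self._linked_successor(cur)
            if nxt is None:
                truncated_right = True
                break
            fwd.append(nxt)
            cur = nxt
        else:
            truncated_right = max_steps == 0 and self._linked_successor(eid) is None
        return LinearNeighborhood(
            center=eid,
            members=back[::-1] + [eid] + fwd,
            truncated_left=truncated_left,
            truncated_right=truncated_right,
        )

    def linear_paths(self) -> List[np.ndarray]:
        """Partition all edges into maximal linear paths (edge-id arrays).

        Sentinel k-mers and isolated/branching edges form singleton paths.
        Every edge appears in exactly one path; a rare fully-cyclic component
        is broken at an arbitrary edge.
        """
        n = len(self._kmers)
        nxt = np.zeros(n + 1, dtype=np.int64)
        has_prev = np.zeros(n + 1, dtype=bool)
        for e in range(1, n + 1):
            f = self._linked_successor(e)
            if f is not None:
                nxt[e] = f
                has_prev[f] = True
        paths: List[np.ndarray] = []
        seen = np.zeros(n + 1, dtype=bool)
        for e in range(1, n + 1):
            if has_prev[e] or seen[e]:
                continue
            path = []
            cur = e
            while cur and not seen[cur]:
                seen[cur] = True
                path.append(cur)
                cur = int(nxt[cur])
            paths.append(np.asarray(path, dtype=np.int64))
        for e in range(1, n + 1):  # leftover cycles
            if seen[e]:
                continue
            path = []
            cur = e
            while not seen[cur]:
                seen[cur] = True
                path.append(cur)
                cur = int(nxt[cur])
            paths.append(np.asarray(path, dtype=np.int64))
        return paths

    def sentinel_mask(self) -> np.ndarray:
        """Boolean array (index 0 = edge 1): True where the k-mer contains $."""
        return np.array([SENTINEL in km for km in self._kmers], dtype=bool)


def build_graph(
    records: Iterable[Tuple[str, str]],
    k: int,
    add_sentinels: bool = False,
) -> Tuple[KmerGraph, List[set]]:
    """Build a KmerGraph and per-edge raw colorings from (sequence, label) pairs.

    Every length-k substring of each sequence and of its reverse complement
    becomes an edge; duplicate k-mers have their label sets combined by union
    (the bitwise OR of their coloring vectors).  With ``add_sentinels`` each
    sequence is wrapped as ``$seq$`` before extraction (the reverse complement
    is wrapped likewise; $ is its own complement).

    Returns the graph and a list ``colorings`` aligned with edge ids:
    ``colorings[eid - 1]`` is the set of labels of edge ``eid``.
    """
    g = KmerGraph(k, sentinels=add_sentinels)
    colorings: List[set] = []
    for seq, label in records:
        seq = seq.upper()
        bad = set(seq) - set(ALPHABET)
        if bad:
            raise ValueError(f"sequence contains characters outside ACGTN: {sorted(bad)}")
        for strand in (seq, reverse_complement(seq)):
            if add_sentinels:
                strand = SENTINEL + strand + SENTINEL
            if len(strand) < k:
                logger.warning(
                    "skipping sequence of length %d < k=%d (label %r)",
                    len(strand), k, label,
                )
                continue
            for i in range(len(strand) - k + 1):
                eid = g.add_kmer(strand[i : i + k])
                if eid > len(colorings):
                    colorings.append(set())
                colorings[eid - 1].add(label)
    return g, colorings
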