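"""Probabilistic per-color annotation compression with Bloom filters.

Each color (matrix column) is stored as one Bloom filter keyed by the edge
k-mer strings.  Membership errors are one-sided: an edge that truly carries a
color always tests positive, while an absent color tests positive with
probability approximately

    FPP(b, d, s) = (1 - e^{-ds/b})^d

for a filter of b bits, d hash functions and s inserted keys.  Given a target
false-positive probability p the filter is sized by

    d = ceil(-log2 p),   b = ceil(-s * log2(p) / ln 2).

Because edges along a linear graph path share their coloring (guaranteed when
input sequences are sentinel-wrapped), raw per-edge queries can be corrected
by intersecting them across a path neighborhood: a surviving false positive
then requires l independent filter errors, dropping the rate to roughly
FPP^l.  Correction needs the graph at decode time; the filters alone do not
suffice.

Hashing is double hashing h_i(x) = (u(x) + i*v(x)) mod b where u, v are two
independent 64-bit FNV-1a-style hashes of the k-mer byte string with fixed
library-wide seeds — deterministic across runs and platforms, and vectorized
over numpy arrays so whole columns are inserted and probed at once.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .annotation import AnnotationMatrix
from .bitvec import RankBitVector
from .graph import KmerGraph

#: Library-wide hash seeds (64-bit FNV offset basis and a second fixed basis).
HASH_SEEDS = (0xCBF29CE484222325, 0x9E3779B97F4A7C15)
_FNV_PRIME = np.uint64(0x100000001B3)

_U64 = np.uint64


class BloomConfigError(ValueError):
    pass


def _fnv1a(keys: np.ndarray, seed: int) -> np.ndarray:
    """Vectorized FNV-1a over an (n, L) uint8 array of key bytes."""
    h = np.full(keys.shape[0], seed, dtype=np.uint64)
    for col in range(keys.shape[1]):
        h ^= keys[:, col].astype(np.uint64)
        h *= _FNV_PRIME
    return h


def encode_keys(kmers: Sequence[str]) -> np.ndarray:
    """Encode equal-length k-mer strings as an (n, k) uint8 byte array."""
    if len(kmers) == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    joined = "".join(kmers).encode("ascii")
    k = len(kmers[0])
    return np.frombuffer(joined, dtype=np.uint8).reshape(len(kmers), k)


def hash_pair(keys: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Two independent 64-bit hashes per key; v is forced odd so the double
    hashing probe sequence cycles through all b positions."""
    with np.errstate(over="ignore"):
        u = _fnv1a(keys, HASH_SEEDS[0])
        v = _fnv1a(keys, HASH_SEEDS[1]) | _U64(1)
    return u, v


def fit_parameters(p: float, s: int) -> Tuple[int, int]:
    """Optimal (d, b) for target false-positive probability p and s insertions:
    d = ceil(-log2 p), b = ceil(-s log2(p) / ln 2)."""
    if not 0.0 < p < 1.0:
        raise BloomConfigError(f"target FPP must be in (0, 1), got {p}")
    if s < 1:
        raise BloomConfigError(f"expected insertions must be >= 1, got {s}")
    log2p = math.log2(p)
    d = math.ceil(-log2p)
    b = math.ceil(-s * log2p / math.log(2))
    return d, max(b, 1)


def predicted_fpp(b: int, d: int, s: int) -> float:
    """Approximate false-positive probability (1 - e^{-ds/b})^d."""
    return (1.0 - math.exp(-d * s / b)) ** d


def predicted_fpp_corrected(b: int, d: int, s: int, ell: int) -> float:
    """FPP after intersecting over a neighborhood of cardinality ell:
    (1 - e^{-ds/b})^{d*ell} — ell independent filter errors must coincide."""
    if ell < 1:
        raise BloomConfigError(f"neighborhood cardinality must be >= 1, got {ell}")
    return (1.0 - math.exp(-d * s / b)) ** (d * ell)


class BloomFilter:
    """A single Bloom filter over k-mer keys (no false negatives)."""

    def __init__(self, b: int, d: int):
        if b < 1 or d < 1:
            raise BloomConfigError(f"need b >= 1 and d >= 1, got b={b}, d={d}")
        self.b = int(b)
        self.d = int(d)
        self._bits = np.zeros(self.b, dtype=np.uint8)
        self.inserted = 0

    @classmethod
    def for_target(cls, p: float, s: int) -> "BloomFilter":
        d, b = fit_parameters(p, s)
        return cls(b, d)

    @property
    def bits(self) -> RankBitVector:
        return RankBitVector(self._bits.copy())

    @property
    def popcount(self) -> int:
        return int(self._bits.sum())

    def _positions(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        b = _U64(self.b)
        with np.errstate(over="ignore"):
            return np.stack(
                [((u + _U64(i) * v) % b).astype(np.int64) for i in range(self.d)]
            )

    def insert_hashed(self, u: np.ndarray, v: np.ndarray) -> None:
        self._bits[self._positions(u, v).ravel()] = 1
        self.inserted += int(u.size)

    def contains_hashed(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        pos = self._positions(u, v)
        return self._bits[pos].all(axis=0)

    def insert(self, key: str) -> "BloomFilter":
        u, v = hash_pair(encode_keys([key]))
        self.insert_hashed(u, v)
        return self

    def insert_many(self, keys: Sequence[str]) -> "BloomFilter":
        if len(keys):
            u, v = hash_pair(encode_keys(keys))
            self.insert_hashed(u, v)
        return self

    def __contains__(self, key: str) -> bool:
        u, v = hash_pair(encode_keys([key]))
        return bool(self.contains_hashed(u, v)[0])

    def contains_many(self, keys: Sequence[str]) -> np.ndarray:
        if not len(keys):
            return np.zeros(0, dtype=bool)
        u, v = hash_pair(encode_keys(keys))
        return self.contains_hashed(u, v)


class BloomAnnotator:
    """m per-color Bloom filters plus the graph used for correction.

    ``correction_steps`` is the default step budget per direction of the
    neighborhood walk used by :meth:`query_corrected`.
    """

    def __init__(
        self,
        filters: List[BloomFilter],
        graph: KmerGraph,
        color_names: Sequence[str],
        target_fpp: float,
        correction_steps: int = 100,
    ):
        if len(filters) != len(color_names):
            raise ValueError("one filter per color required")
        self.filters = filters
        self.graph = graph
        self.color_names = list(color_names)
        self.target_fpp = target_fpp
        self.correction_steps = correction_steps
        self._u: Optional[np.ndarray] = None
        self._v: Optional[np.ndarray] = None

    @property
    def m(self) -> int:
        return len(self.filters)

    @property
    def total_filter_bits(self) -> int:
        return sum(f.b for f in self.filters)

    def bits_per_edge(self) -> float:
        """Total filter bits over the number of graph edges (seeds and
        per-filter metadata excluded)."""
        if self.graph.n_edges == 0:
            raise ValueError("bits per edge undefined for an empty graph")
        return self.total_filter_bits / self.graph.n_edges

    # -- hashing cache ------------------------------------------------------

    def _edge_hashes(self) -> Tuple[np.ndarray, np.ndarray]:
        if self._u is None or self._u.size != self.graph.n_edges:
            keys = encode_keys(list(self.graph.kmers))
            self._u, self._v = hash_pair(keys)
        return self._u, self._v

    # -- queries ------------------------------------------------------------

    def query_raw(self, eid: int) -> RankBitVector:
        """Per-filter membership of edge ``eid`` — the uncorrected coloring."""
        self.graph.kmer(eid)  # validates
        u, v = self._edge_hashes()
        iu, iv = u[eid - 1 : eid], v[eid - 1 : eid]
        return RankBitVector(
            np.array([int(f.contains_hashed(iu, iv)[0]) for f in self.filters],
                     dtype=np.uint8)
        )

    def query_raw_all(self) -> np.ndarray:
        """Raw decoded matrix, one row per edge (vectorized)."""
        u, v = self._edge_hashes()
        out = np.zeros((self.graph.n_edges, self.m), dtype=np.uint8)
        for j, f in enumerate(self.filters):
            out[:, j] = f.contains_hashed(u, v)
        return out

    def query_corrected(self, eid: int, max_steps: Optional[int] = None) -> RankBitVector:
        """Intersection of raw queries over the linear-path neighborhood of
        the edge (``max_steps`` per direction; 0 reproduces the raw query)."""
        steps = self.correction_steps if max_steps is None else max_steps
        hood = self.graph.neighborhood(eid, steps)
        result = self.query_raw(eid)
        for member in hood.members:
            if member != eid:
                result = result & self.query_raw(member)
        return result

    def decode_corrected_all(self, max_steps: Optional[int] = None) -> np.ndarray:
        """Corrected decoded matrix for every edge at once.

        Equivalent to calling :meth:`query_corrected` per edge, computed via
        the maximal-linear-path decomposition with prefix sums: within a path
        the corrected bit is 1 iff all raw bits in the clamped window of
        ``max_steps`` each way are 1.
        """
        steps = self.correction_steps if max_steps is None else max_steps
        raw = self.query_raw_all()
        if steps == 0:
            return raw
        paths = self.graph.linear_paths()
        order = np.concatenate(paths) - 1  # 0-based edge order by path position
        starts = np.zeros(order.size, dtype=np.int64)
        ends = np.zeros(order.size, dtype=np.int64)
        off = 0
        for p in paths:
            starts[off : off + p.size] = off
            ends[off : off + p.size] = off + p.size - 1
            off += p.size
        pos = np.arange(order.size)
        lo = np.maximum(pos - steps, starts)
        hi = np.minimum(pos + steps, ends)
        win = hi - lo + 1
        out = np.zeros_like(raw)
        for j in range(self.m):
            bits = raw[order, j]
            cs = np.concatenate([[0], np.cumsum(bits, dtype=np.int64)])
            out[order, j] = (cs[hi + 1] - cs[lo]) == win
        return out

    # -- serialization ------------------------------------------------------

    def serialize(self) -> bytes:
        parts = [len(self.filters).to_bytes(4, "big"),
                 HASH_SEEDS[0].to_bytes(8, "big"), HASH_SEEDS[1].to_bytes(8, "big")]
        names = "\n".join(self.color_names).encode()
        parts += [len(names).to_bytes(4, "big"), names]
        import struct
        parts.append(struct.pack(">dI", self.target_fpp, self.correction_steps))
        for f in self.filters:
            parts += [
                f.b.to_bytes(8, "big"),
                f.d.to_bytes(4, "big"),
                f.inserted.to_bytes(8, "big"),
                np.packbits(f._bits).tobytes(),
            ]
        return b"".join(parts)

    @classmethod
    def deserialize(cls, data: bytes, graph: KmerGraph) -> "BloomAnnotator":
        import struct
        off = 0
        m = int.from_bytes(data[off : off + 4], "big"); off += 4
        seeds = (
            int.from_bytes(data[off : off + 8], "big"),
            int.from_bytes(data[off + 8 : off + 16], "big"),
        )
        off += 16
        if seeds != HASH_SEEDS:
            raise ValueError("archive was written with different hash seeds")
        nlen = int.from_bytes(data[off : off + 4], "big"); off += 4
        names = data[off : off + nlen].decode().split("\n") if nlen else []
        off += nlen
        target_fpp, steps = struct.unpack(">dI", data[off : off + 12]); off += 12
        filters = []
        for _ in range(m):
            b = int.from_bytes(data[off : off + 8], "big"); off += 8
            d = int.from_bytes(data[off : off + 4], "big"); off += 4
            s = int.from_bytes(data[off : off + 8], "big"); off += 8
            nbytes = (b + 7) // 8
            f = BloomFilter(b, d)
            f._bits = np.unpackbits(
                np.frombuffer(data[off : off + nbytes], dtype=np.uint8), count=b
            ).astype(np.uint8)
            f.inserted = s
            off += nbytes
            filters.append(f)
        return cls(filters, graph, names, target_fpp, steps)


def compress(
    a: AnnotationMatrix,
    g: KmerGraph,
    p: float,
    correction_steps: int = 100,
) -> BloomAnnotator:
    """Compress an annotation matrix into per-color Bloom filters.

    Filter j is sized from the exact column count s_j at target FPP ``p``;
    every edge carrying color j is inserted under its k-mer key.  Empty
    columns get a minimal filter that always answers negative.
    """
    if a.n != g.n_edges:
        raise ValueError(f"matrix has {a.n} rows but graph has {g.n_edges} edges")
    keys = encode_keys(list(g.kmers))
    u, v = hash_pair(keys)
    filters: List[BloomFilter] = []
    for j in range(a.m):
        col = a.matrix[:, j]
        s = int(col.sum())
        if s == 0:
            filters.append(BloomFilter(1, 1))
            continue
        d, b = fit_parameters(p, s)
        f = BloomFilter(b, d)
        idx = np.flatnonzero(col)
        f.insert_hashed(u[idx], v[idx])
        filters.append(f)
    ba = BloomAnnotator(filters, g, a.color_names, p, correction_steps)
    ba._u, ba._v = u, v
    return ba
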