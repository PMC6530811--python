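"""Wavelet-trie codec for annotation-matrix rows.

A wavelet trie encodes a tuple of equal-width bit vectors (the matrix rows) as
a compact binary prefix tree.  Each node carries a longest common prefix α and
an assignment vector β: during construction the LCP of the vectors assigned to
the node is stripped off into α, the next significant bit of each vector is
recorded in β, and the suffixes are routed to the left (bit 0) or right
(bit 1) child.  A node whose vectors are all identical becomes a leaf (β is a
run of zeros recording only the multiplicity).  Querying row i walks from the
root, emitting α, reading the branch bit β[i], and renumbering i by
rank0/rank1 on β.

All rows are kept at a fixed common width m (shorter inputs are right-padded
with 0s), so no row is a strict prefix of another and the merge procedure is
total.  Tries are persistent: merge/insert/delete return new tries, sharing
untouched subtrees.

The structure is canonical: for a given row tuple there is exactly one compact
trie, so merging tries built from consecutive batches reproduces, node for
node, the trie built from the concatenated rows.  This is what makes batched
(parallel) construction exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .bitvec import EMPTY, RankBitVector

MAGIC = b"WTR1"
VERSION = 1


class WTrieFormatError(ValueError):
    pass


class WTrieNode:
    """A single (α, β) node; treated as immutable once built."""

    __slots__ = ("alpha", "beta", "left", "right")

    def __init__(
        self,
        alpha: RankBitVector,
        beta: RankBitVector,
        left: Optional["WTrieNode"] = None,
        right: Optional["WTrieNode"] = None,
    ):
        self.alpha = alpha
        self.beta = beta
        self.left = left
        self.right = right

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    @property
    def count(self) -> int:
        """Number of vectors assigned to this node."""
        return len(self.beta)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WTrieNode):
            return NotImplemented
        return (
            self.alpha == other.alpha
            and self.beta == other.beta
            and self.left == other.left
            and self.right == other.right
        )

    def __repr__(self) -> str:
        kind = "leaf" if self.is_leaf else "node"
        return f"<{kind} α={self.alpha.to01()!r} β={self.beta.to01()!r}>"


RowsLike = Union[np.ndarray, Sequence[RankBitVector], Sequence[Sequence[int]]]


def _rows_to_array(rows: RowsLike, width: Optional[int] = None) -> np.ndarray:
    if isinstance(rows, np.ndarray):
        arr = np.asarray(rows, dtype=np.uint8)
        if arr.ndim != 2:
            raise ValueError("row array must be 2-D")
    else:
        seqs = [
            RankBitVector(r).to_array() if isinstance(r, (RankBitVector, str))
            else np.asarray(r, np.uint8)
            for r in rows
        ]
        if not seqs:
            arr = np.zeros((0, width or 0), dtype=np.uint8)
        else:
            w = width if width is not None else max(len(s) for s in seqs)
            arr = np.zeros((len(seqs), w), dtype=np.uint8)
            for i, s in enumerate(seqs):
                if len(s) > w:
                    raise ValueError(f"row {i} wider ({len(s)}) than width {w}")
                arr[i, : len(s)] = s  # right-pad with 0s
    if width is not None and arr.shape[1] != width:
        if arr.shape[1] > width:
            raise ValueError(f"rows wider ({arr.shape[1]}) than trie width {width}")
        pad = np.zeros((arr.shape[0], width - arr.shape[1]), dtype=np.uint8)
        arr = np.concatenate([arr, pad], axis=1)
    return arr


def _build(arr: np.ndarray) -> Optional[WTrieNode]:
    """Construct the trie; recursion runs over deduplicated rows so the cost
    is O(unique-rows * m) plus O(n * branching-depth) for the β vectors."""
    if arr.shape[0] == 0:
        return None
    uniq, inv = np.unique(arr, axis=0, return_inverse=True)
    return _build_dedup(uniq, np.arange(uniq.shape[0]), inv.ravel(), 0)


def _build_dedup(
    uniq: np.ndarray, uids: np.ndarray, ids: np.ndarray, col: int
) -> WTrieNode:
    if uids.size == 1:
        return WTrieNode(
            RankBitVector(uniq[uids[0], col:]), RankBitVector.zeros(ids.size)
        )
    sub = uniq[uids, col:]
    p = int(np.flatnonzero(~(sub == sub[0:1]).all(axis=0))[0])
    ubits = sub[:, p]
    bit_of = np.zeros(uniq.shape[0], dtype=np.uint8)
    bit_of[uids] = ubits
    beta = bit_of[ids]
    mask = beta == 1
    umask = ubits == 1
    return WTrieNode(
        RankBitVector(sub[0, :p]),
        RankBitVector(beta),
        _build_dedup(uniq, uids[~umask], ids[~mask], col + p + 1),
        _build_dedup(uniq, uids[umask], ids[mask], col + p + 1),
    )


@dataclass(frozen=True)
class SizeReport:
    """Bit accounting of a serialized trie.

    ``payload_bits`` counts the α and β bits of every node (leaf β included);
    ``overhead_bits`` counts the per-node structure (leaf flags and α length
    codes).  The fixed archive header is excluded.
    """

    payload_bits: int
    overhead_bits: int

    @property
    def total_bits(self) -> int:
        return self.payload_bits + self.overhead_bits


class WaveletTrie:
    """A wavelet trie over ``n_rows`` bit vectors of common width ``width``."""

    def __init__(self, root: Optional[WTrieNode], n_rows: int, width: int):
        self.root = root
        self.n_rows = n_rows
        self.width = width

    # -- construction -------------------------------------------------------

    @classmethod
    def construct(cls, rows: RowsLike, width: Optional[int] = None) -> "WaveletTrie":
        arr = _rows_to_array(rows, width)
        return cls(_build(arr), arr.shape[0], arr.shape[1])

    @classmethod
    def empty(cls, width: int = 0) -> "WaveletTrie":
        return cls(None, 0, width)

    @classmethod
    def construct_batched(
        cls, rows: RowsLike, batch_size: int, width: Optional[int] = None
    ) -> "WaveletTrie":
        """Chunk rows into consecutive batches, build per-batch tries, and
        left-fold merge them in batch order.  Decode- and structure-identical
        to direct construction."""
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        arr = _rows_to_array(rows, width)
        t = cls.empty(arr.shape[1])
        for start in range(0, arr.shape[0], batch_size):
            t = merge(t, cls.construct(arr[start : start + batch_size]))
        if arr.shape[0] == 0:
            t = cls(None, 0, arr.shape[1])
        return t

    # -- queries ------------------------------------------------------------

    def query(self, i: int) -> RankBitVector:
        """Decode row i (1-based)."""
        return self._query(i)[0]

    def query_visits(self, i: int) -> Tuple[RankBitVector, int]:
        """Decode row i, also returning the number of nodes touched."""
        return self._query(i)

    def _query(self, i: int) -> Tuple[RankBitVector, int]:
        if not 1 <= i <= self.n_rows:
            raise IndexError(f"row {i} out of range 1..{self.n_rows}")
        parts: List[RankBitVector] = []
        node = self.root
        visits = 0
        while True:
            visits += 1
            parts.append(node.alpha)
            if node.is_leaf:
                break
            bit = node.beta[i]
            if bit:
                i = node.beta.rank1(i)
                parts.append(_ONE)
                node = node.right
            else:
                i = node.beta.rank0(i)
                parts.append(_ZERO)
                node = node.left
        out = np.concatenate([p.to_array() for p in parts]) if parts else np.zeros(0, np.uint8)
        return RankBitVector(out), visits

    def decode_all(self) -> np.ndarray:
        """Decode every row at once (vectorized inverse of construction)."""
        out = np.zeros((self.n_rows, self.width), dtype=np.uint8)
        if self.root is not None:
            _fill(self.root, out, np.arange(self.n_rows), 0)
        return out

    # -- structure ----------------------------------------------------------

    def nodes(self) -> List[WTrieNode]:
        acc: List[WTrieNode] = []
        stack = [self.root] if self.root else []
        while stack:
            nd = stack.pop()
            acc.append(nd)
            if nd.right is not None:
                stack.append(nd.right)
            if nd.left is not None:
                stack.append(nd.left)
        return acc

    def node_count(self) -> int:
        return len(self.nodes())

    def height(self) -> int:
        """Maximum number of nodes on a root-to-leaf path."""
        def h(nd: Optional[WTrieNode]) -> int:
            if nd is None:
                return 0
            return 1 + max(h(nd.left), h(nd.right))
        return h(self.root)

    def node_bound(self) -> int:
        """Upper bound on the node count: min(2n−1, 2^(m+1)−1)."""
        if self.n_rows == 0:
            return 0
        return min(2 * self.n_rows - 1, 2 ** (self.width + 1) - 1)

    def check_node_bound(self) -> None:
        cnt = self.node_count()
        if cnt > self.node_bound():
            raise AssertionError(
                f"node count {cnt} exceeds bound {self.node_bound()} "
                f"(n={self.n_rows}, m={self.width})"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, WaveletTrie):
            return NotImplemented
        return (
            self.n_rows == other.n_rows
            and self.width == other.width
            and self.root == other.root
        )

    # -- size & serialization ----------------------------------------------

    def compressed_size(self) -> SizeReport:
        payload = 0
        overhead = 0
        for nd in self.nodes():
            payload += len(nd.alpha) + len(nd.beta)
            overhead += 1 + _gamma_len(len(nd.alpha) + 1)
        return SizeReport(payload, overhead)

    def serialize(self) -> bytes:
        w = _BitWriter()
        if self.root is not None:
            _write_node(w, self.root)
        stream, nbits = w.finish()
        header = (
            MAGIC
            + bytes([VERSION])
            + int(self.width).to_bytes(4, "big")
            + int(self.n_rows).to_bytes(8, "big")
            + int(nbits).to_bytes(8, "big")
        )
        return header + stream

    @classmethod
    def deserialize(cls, data: bytes) -> "WaveletTrie":
        if len(data) < 25 or data[:4] != MAGIC:
            raise WTrieFormatError("bad wavelet-trie magic")
        if data[4] != VERSION:
            raise WTrieFormatError(f"unsupported wavelet-trie version {data[4]}")
        width = int.from_bytes(data[5:9], "big")
        n_rows = int.from_bytes(data[9:17], "big")
        nbits = int.from_bytes(data[17:25], "big")
        stream = np.unpackbits(
            np.frombuffer(data[25:], dtype=np.uint8), count=nbits
        ) if nbits else np.zeros(0, np.uint8)
        if len(data[25:]) * 8 < nbits:
            raise WTrieFormatError("truncated wavelet-trie stream")
        r = _BitReader(stream)
        root = _read_node(r, n_rows) if n_rows else None
        return cls(root, n_rows, width)


_ZERO = RankBitVector("0")
_ONE = RankBitVector("1")


def _fill(node: WTrieNode, out: np.ndarray, idx: np.ndarray, col: int) -> None:
    a = node.alpha.to_array()
    if a.size:
        out[idx, col : col + a.size] = a
    col += a.size
    if node.is_leaf:
        return
    b = node.beta.to_array()
    out[idx, col] = b
    mask = b == 1
    _fill(node.left, out, idx[~mask], col + 1)
    _fill(node.right, out, idx[mask], col + 1)


def construct(rows: RowsLike, width: Optional[int] = None) -> WaveletTrie:
    """Build a wavelet trie from a tuple of rows (right-padded to equal width)."""
    return WaveletTrie.construct(rows, width)


# -- merge ------------------------------------------------------------------

def _split_at(node: WTrieNode, hat: int) -> WTrieNode:
    """Rewrite ``node`` so its α is exactly the first ``hat`` bits.

    The remainder of α (after its (hat+1)-th bit, which becomes the branch
    bit) moves into a fresh child inheriting the old β and children; the new
    β is constant since all of the node's vectors share that bit.
    """
    if len(node.alpha) == hat:
        return node
    bit = node.alpha[hat + 1]
    child = WTrieNode(node.alpha.suffix_from(hat + 2), node.beta, node.left, node.right)
    beta = RankBitVector.filled(bit, node.count)
    if bit:
        return WTrieNode(node.alpha.prefix(hat), beta, None, child)
    return WTrieNode(node.alpha.prefix(hat), beta, child, None)


def _merge_nodes(
    n1: Optional[WTrieNode], n2: Optional[WTrieNode], pos: int
) -> Optional[WTrieNode]:
    """Merge two subtries over the same remaining width; n2's vectors are
    spliced among n1's starting at 1-based position ``pos``."""
    if n1 is None:
        return n2
    if n2 is None:
        return n1
    hat = n1.alpha.lcp_len(n2.alpha)
    a = _split_at(n1, hat)
    b = _split_at(n2, hat)
    if a.is_leaf and b.is_leaf:
        # identical full suffixes; merged multiplicity
        return WTrieNode(a.alpha, RankBitVector.zeros(a.count + b.count))
    if a.is_leaf or b.is_leaf:
        raise AssertionError("leaf/internal clash after align: width mismatch")
    beta = a.beta.prefix(pos - 1) + b.beta + a.beta.suffix_from(pos)
    pos0 = a.beta.rank0(pos - 1) + 1
    pos1 = a.beta.rank1(pos - 1) + 1
    return WTrieNode(
        a.alpha,
        beta,
        _merge_nodes(a.left, b.left, pos0),
        _merge_nodes(a.right, b.right, pos1),
    )


def merge(t1: WaveletTrie, t2: WaveletTrie) -> WaveletTrie:
    """Merge two tries; t1's rows precede t2's.  Equivalent (and structurally
    identical) to constructing from the concatenated row tuples."""
    if t1.n_rows and t2.n_rows and t1.width != t2.width:
        raise ValueError(f"width mismatch: {t1.width} vs {t2.width}")
    width = t1.width if t1.n_rows or not t2.n_rows else t2.width
    if t1.n_rows == 0:
        return WaveletTrie(t2.root, t2.n_rows, max(width, t2.width))
    if t2.n_rows == 0:
        return t1
    return WaveletTrie(
        _merge_nodes(t1.root, t2.root, t1.n_rows + 1), t1.n_rows + t2.n_rows, width
    )


def insert_rows(t: WaveletTrie, at: int, rows: RowsLike) -> WaveletTrie:
    """Splice ``rows`` into the encoded tuple before position ``at`` (1-based;
    ``at = n+1`` appends, equivalent to a merge)."""
    if not 1 <= at <= t.n_rows + 1:
        raise IndexError(f"insert position {at} out of range 1..{t.n_rows + 1}")
    t2 = WaveletTrie.construct(rows, width=t.width if t.n_rows else None)
    if t2.n_rows == 0:
        return t
    if t.n_rows == 0:
        return t2
    return WaveletTrie(
        _merge_nodes(t.root, t2.root, at), t.n_rows + t2.n_rows, t.width
    )


# -- delete / update --------------------------------------------------------

def _delete(node: WTrieNode, i: int) -> Optional[WTrieNode]:
    if node.is_leaf:
        if node.count == 1:
            return None
        return WTrieNode(node.alpha, RankBitVector.zeros(node.count - 1))
    bit = node.beta[i]
    j = node.beta.rank(bit, i)
    beta = node.beta.prefix(i - 1) + node.beta.suffix_from(i + 1)
    if bit:
        child = _delete(node.right, j)
        other, other_bit = node.left, 0
    else:
        child = _delete(node.left, j)
        other, other_bit = node.right, 1
    if child is None:
        # branch emptied: absorb the surviving child to stay compact
        alpha = node.alpha + RankBitVector([other_bit]) + other.alpha
        return WTrieNode(alpha, other.beta, other.left, other.right)
    if bit:
        return WTrieNode(node.alpha, beta, other, child)
    return WTrieNode(node.alpha, beta, child, other)


def delete_row(t: WaveletTrie, i: int) -> WaveletTrie:
    """Remove row i; the trie is re-compacted so it stays a compact prefix tree."""
    if not 1 <= i <= t.n_rows:
        raise IndexError(f"row {i} out of range 1..{t.n_rows}")
    return WaveletTrie(_delete(t.root, i), t.n_rows - 1, t.width)


def update_row(t: WaveletTrie, i: int, row) -> WaveletTrie:
    """Replace row i: delete it and re-insert the modified row at the same
    position."""
    if not 1 <= i <= t.n_rows:
        raise IndexError(f"row {i} out of range 1..{t.n_rows}")
    return insert_rows(delete_row(t, i), i, [row])


def pad_width(t: WaveletTrie, new_width: int) -> WaveletTrie:
    """Widen the trie by right-padding every encoded row with 0s (used when
    new colors append columns to the matrix)."""
    if new_width < t.width:
        raise ValueError(f"cannot shrink width {t.width} to {new_width}")
    if new_width == t.width or t.root is None:
        return WaveletTrie(t.root, t.n_rows, new_width)
    delta = new_width - t.width

    def extend(nd: WTrieNode) -> WTrieNode:
        if nd.is_leaf:
            return WTrieNode(nd.alpha.pad_to(len(nd.alpha) + delta), nd.beta)
        return WTrieNode(nd.alpha, nd.beta, extend(nd.left), extend(nd.right))

    return WaveletTrie(extend(t.root), t.n_rows, new_width)


# -- bitstream helpers ------------------------------------------------------

def _gamma_len(x: int) -> int:
    return 2 * (x.bit_length() - 1) + 1


class _BitWriter:
    def __init__(self):
        self._chunks: List[np.ndarray] = []
        self._nbits = 0

    def write_bits(self, arr: np.ndarray) -> None:
        self._chunks.append(arr)
        self._nbits += arr.size

    def write_gamma(self, x: int) -> None:
        """Elias-gamma code of a positive integer."""
        nb = x.bit_length()
        bits = np.zeros(2 * nb - 1, dtype=np.uint8)
        for k in range(nb):
            bits[nb - 1 + k] = (x >> (nb - 1 - k)) & 1
        self.write_bits(bits)

    def finish(self) -> Tuple[bytes, int]:
        if self._chunks:
            stream = np.concatenate(self._chunks).astype(np.uint8)
        else:
            stream = np.zeros(0, dtype=np.uint8)
        return np.packbits(stream).tobytes(), self._nbits


class _BitReader:
    def __init__(self, bits: np.ndarray):
        self._bits = bits
        self._pos = 0

    def read_bits(self, n: int) -> np.ndarray:
        if self._pos + n > self._bits.size:
            raise WTrieFormatError("bitstream exhausted")
        out = self._bits[self._pos : self._pos + n]
        self._pos += n
        return out

    def read_gamma(self) -> int:
        zeros = 0
        while True:
            b = self.read_bits(1)
            if b[0]:
                break
            zeros += 1
        x = 1
        for b in self.read_bits(zeros):
            x = (x << 1) | int(b)
        return x


def _write_node(w: _BitWriter, node: WTrieNode) -> None:
    w.write_bits(np.array([1 if node.is_leaf else 0], dtype=np.uint8))
    w.write_gamma(len(node.alpha) + 1)
    w.write_bits(node.alpha.to_array())
    w.write_bits(node.beta.to_array())
    if not node.is_leaf:
        _write_node(w, node.left)
        _write_node(w, node.right)


def _read_node(r: _BitReader, count: int) -> WTrieNode:
    leaf = bool(r.read_bits(1)[0])
    alen = r.read_gamma() - 1
    alpha = RankBitVector(r.read_bits(alen).copy())
    beta = RankBitVector(r.read_bits(count).copy())
    if leaf:
        if beta.popcount:
            raise WTrieFormatError("leaf assignment vector must be all zeros")
        return WTrieNode(alpha, beta)
    left = _read_node(r, beta.rank0(count))
    right = _read_node(r, beta.rank1(count))
    return WTrieNode(alpha, beta, left, right)
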