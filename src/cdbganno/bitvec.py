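"""Immutable bit vectors with rank/select support.

The whole library indexes bit vectors the way the succinct-data-structure
literature does: positions are 1-based and slices ``[j:k]`` are inclusive on
both ends.  ``rank_c(v, j)`` counts occurrences of bit ``c`` in the prefix
``v[1:j]`` and ``select_c(v, j)`` returns the position of the j-th occurrence
of ``c``.  These conventions never leak outside the library: the CLI speaks in
whole rows, never positions.

Vectors are immutable; every operation returns a fresh vector.  Rank is
accelerated by a blocked popcount index built lazily on first use, giving
O(1)-amortized rank after an O(n) preparation pass.  Entropy-coded (RRR)
storage is deliberately out of scope: callers rely only on the rank/select
interface contract.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence, Union

import numpy as np

_BLOCK = 512  # bits per rank superblock


class RankBitVector:
    """An immutable sequence of bits with O(1)-amortized rank and select."""

    __slots__ = ("_bits", "_blk", "_ones", "_zeros")

    def __init__(self, bits: Union[Sequence[int], np.ndarray, str, "RankBitVector"] = ()):
        if isinstance(bits, RankBitVector):
            arr = bits._bits
        elif isinstance(bits, str):
            if bits and set(bits) - {"0", "1"}:
                raise ValueError(f"bit string may contain only 0/1: {bits!r}")
            arr = np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")
        else:
            arr = np.asarray(bits, dtype=np.uint8)
            if arr.ndim != 1:
                raise ValueError("bit vector must be one-dimensional")
            if arr.size and arr.max(initial=0) > 1:
                raise ValueError("bit vector entries must be 0 or 1")
        arr = np.ascontiguousarray(arr, dtype=np.uint8)
        arr.setflags(write=False)
        self._bits = arr
        self._blk = None
        self._ones = None
        self._zeros = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def zeros(cls, n: int) -> "RankBitVector":
        return cls(np.zeros(int(n), dtype=np.uint8))

    @classmethod
    def ones(cls, n: int) -> "RankBitVector":
        return cls(np.ones(int(n), dtype=np.uint8))

    @classmethod
    def filled(cls, bit: int, n: int) -> "RankBitVector":
        return cls.ones(n) if bit else cls.zeros(n)

    # -- basics -------------------------------------------------------------

    def __len__(self) -> int:
        return self._bits.size

    def __bool__(self) -> bool:
        return self._bits.size > 0

    def __iter__(self) -> Iterator[int]:
        return iter(int(b) for b in self._bits)

    def __getitem__(self, i: int) -> int:
        """1-based single-bit access; v[1] is the first bit."""
        if not 1 <= i <= self._bits.size:
            raise IndexError(f"position {i} out of range 1..{self._bits.size}")
        return int(self._bits[i - 1])

    def __eq__(self, other) -> bool:
        if not isinstance(other, RankBitVector):
            return NotImplemented
        return self._bits.size == other._bits.size and bool(
            np.array_equal(self._bits, other._bits)
        )

    def __hash__(self) -> int:
        return hash((self._bits.size, self._bits.tobytes()))

    def __repr__(self) -> str:
        s = self.to01()
        if len(s) > 64:
            s = s[:61] + "..."
        return f"RankBitVector({s!r})"

    def to01(self) -> str:
        return (self._bits + ord("0")).tobytes().decode("ascii")

    def to_array(self) -> np.ndarray:
        """Read-only numpy view of the bits."""
        return self._bits

    @property
    def popcount(self) -> int:
        return int(self._bits.sum())

    # -- rank / select ------------------------------------------------------

    def _rank_index(self) -> np.ndarray:
        if self._blk is None:
            nblk = self._bits.size // _BLOCK
            if nblk:
                sums = self._bits[: nblk * _BLOCK].reshape(nblk, _BLOCK).sum(
                    axis=1, dtype=np.int64
                )
                self._blk = np.concatenate(([0], np.cumsum(sums)))
            else:
                self._blk = np.zeros(1, dtype=np.int64)
        return self._blk

    def rank(self, c: int, j: int) -> int:
        """Count occurrences of bit ``c`` in the prefix v[1:j]; rank(c, 0) = 0."""
        if not 0 <= j <= self._bits.size:
            raise IndexError(f"rank position {j} out of range 0..{self._bits.size}")
        blk = self._rank_index()
        q, r = divmod(j, _BLOCK)
        ones = int(blk[q]) + int(self._bits[q * _BLOCK : q * _BLOCK + r].sum())
        return ones if c else j - ones

    def rank1(self, j: int) -> int:
        return self.rank(1, j)

    def rank0(self, j: int) -> int:
        return self.rank(0, j)

    def _positions(self, c: int) -> np.ndarray:
        if c:
            if self._ones is None:
                self._ones = np.flatnonzero(self._bits)
            return self._ones
        if self._zeros is None:
            self._zeros = np.flatnonzero(self._bits == 0)
        return self._zeros

    def select(self, c: int, j: int) -> int:
        """Position of the j-th occurrence of bit ``c`` (1-based on both sides)."""
        pos = self._positions(c)
        if not 1 <= j <= pos.size:
            raise IndexError(f"select index {j} out of range 1..{pos.size}")
        return int(pos[j - 1]) + 1

    def select1(self, j: int) -> int:
        return self.select(1, j)

    def select0(self, j: int) -> int:
        return self.select(0, j)

    # -- slicing / concatenation / bitwise ----------------------------------

    def slice(self, j: int = 1, k: int = None) -> "RankBitVector":
        """Inclusive 1-based slice v[j:k]; k defaults to |v|.  Empty if j > k."""
        n = self._bits.size
        if k is None:
            k = n
        if j < 1 or k > n:
            raise IndexError(f"slice [{j}:{k}] out of range for length {n}")
        if j > k:
            return RankBitVector(np.empty(0, dtype=np.uint8))
        return RankBitVector(self._bits[j - 1 : k])

    def prefix(self, k: int) -> "RankBitVector":
        """v[:k] — the first k bits."""
        return self.slice(1, k) if k else EMPTY

    def suffix_from(self, j: int) -> "RankBitVector":
        """v[j:] — bits from position j to the end (empty when j = |v|+1)."""
        if j == self._bits.size + 1:
            return EMPTY
        return self.slice(j, self._bits.size)

    def concat(self, *others: "RankBitVector") -> "RankBitVector":
        arrs = [self._bits] + [o._bits for o in others]
        return RankBitVector(np.concatenate(arrs))

    def __add__(self, other: "RankBitVector") -> "RankBitVector":
        return self.concat(other)

    def _check_same_length(self, other: "RankBitVector") -> None:
        if self._bits.size != other._bits.size:
            raise ValueError(
                f"length mismatch: {self._bits.size} vs {other._bits.size}"
            )

    def __or__(self, other: "RankBitVector") -> "RankBitVector":
        self._check_same_length(other)
        return RankBitVector(self._bits | other._bits)

    def __and__(self, other: "RankBitVector") -> "RankBitVector":
        self._check_same_length(other)
        return RankBitVector(self._bits & other._bits)

    def lcp_len(self, other: "RankBitVector") -> int:
        """Length of the longest common prefix of two vectors."""
        n = min(self._bits.size, other._bits.size)
        if n == 0:
            return 0
        neq = np.flatnonzero(self._bits[:n] != other._bits[:n])
        return int(neq[0]) if neq.size else n

    def pad_to(self, width: int) -> "RankBitVector":
        """Right-pad with 0s to the given width."""
        n = self._bits.size
        if width < n:
            raise ValueError(f"cannot pad length {n} down to {width}")
        if width == n:
            return self
        return RankBitVector(np.concatenate([self._bits, np.zeros(width - n, np.uint8)]))


#: The empty bit vector ε.
EMPTY = RankBitVector()


def concat(vectors: Iterable[RankBitVector]) -> RankBitVector:
    arrs = [v.to_array() for v in vectors]
    if not arrs:
        return EMPTY
    return RankBitVector(np.concatenate(arrs))
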