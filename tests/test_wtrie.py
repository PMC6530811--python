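"""Wavelet-trie construction, query, merge, editing, and serialization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdbganno import wtrie
from cdbganno.wtrie import WaveletTrie, WTrieFormatError
from conftest import random_matrix


def decode(t: WaveletTrie) -> np.ndarray:
    return t.decode_all()


class TestConstruct:
    def test_hand_worked_recursion(self):
        t = wtrie.construct(["000", "001", "101"])
        r = t.root
        assert r.alpha.to01() == "" and r.beta.to01() == "001"
        assert r.left.alpha.to01() == "0" and r.left.beta.to01() == "01"
        assert r.left.left.is_leaf and r.left.left.alpha.to01() == ""
        assert r.left.right.is_leaf and r.left.right.alpha.to01() == ""
        assert r.right.is_leaf
        assert r.right.alpha.to01() == "01" and r.right.beta.to01() == "0"

    def test_identical_rows_single_leaf(self):
        t = wtrie.construct(["0110"] * 5)
        assert t.root.is_leaf
        assert t.root.alpha.to01() == "0110"
        assert t.root.beta.to01() == "00000"

    def test_all_width3_vectors_saturate_bound(self):
        t = wtrie.construct([format(i, "03b") for i in range(8)])
        # 7 internal nodes with empty alphas plus 8 leaves
        assert t.node_count() == 2 ** (3 + 1) - 1 == t.node_bound()
        assert all(
            nd.alpha.to01() == "" for nd in t.nodes() if not nd.is_leaf
        )

    def test_empty_input(self):
        t = wtrie.construct([])
        assert t.n_rows == 0 and t.root is None
        assert t.node_count() == 0

    def test_ragged_rows_right_padded(self):
        t = wtrie.construct(["1", "10", "100"])
        assert t.width == 3
        assert [t.query(i).to01() for i in (1, 2, 3)] == ["100"] * 3
        assert t.root.is_leaf  # identical after padding


class TestQuery:
    def test_traversal_matches_rows(self):
        t = wtrie.construct(["000", "001", "101"])
        assert t.query(3).to01() == "101"
        assert [t.query(i).to01() for i in (1, 2, 3)] == ["000", "001", "101"]

    def test_single_leaf_any_index(self):
        t = wtrie.construct(["0110"] * 4)
        for i in range(1, 5):
            assert t.query(i).to01() == "0110"

    def test_out_of_range(self):
        t = wtrie.construct(["01"])
        with pytest.raises(IndexError):
            t.query(0)
        with pytest.raises(IndexError):
            t.query(2)

    def test_visit_count_bounded_by_height(self):
        rng = np.random.default_rng(0)
        mat = random_matrix(rng, 50, 9)
        t = WaveletTrie.construct(mat)
        h = t.height()
        assert h <= t.width + 1
        for i in range(1, 51):
            row, visits = t.query_visits(i)
            assert visits <= h
            assert np.array_equal(row.to_array(), mat[i - 1])

    def test_round_trip_random(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            mat = random_matrix(rng, int(rng.integers(1, 64)),
                                int(rng.integers(1, 16)))
            t = WaveletTrie.construct(mat)
            assert np.array_equal(decode(t), mat)


class TestMerge:
    def test_merge_equals_direct_construction(self):
        t = wtrie.merge(wtrie.construct(["000"]), wtrie.construct(["001", "101"]))
        assert t == wtrie.construct(["000", "001", "101"])

    def test_empty_is_identity(self):
        t = wtrie.construct(["0110", "1001"])
        assert wtrie.merge(t, WaveletTrie.empty(4)) == t
        assert wtrie.merge(WaveletTrie.empty(4), t) == t

    def test_order_of_rows_preserved(self):
        a, b = ["110", "010"], ["010", "111"]
        t = wtrie.merge(wtrie.construct(a), wtrie.construct(b))
        assert [r.to01() for r in map(t.query, range(1, 5))] == a + b

    def test_fold_over_random_partitions(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            n, m = int(rng.integers(1, 48)), int(rng.integers(1, 12))
            mat = random_matrix(rng, n, m)
            direct = WaveletTrie.construct(mat)
            nbatch = int(rng.integers(2, 9))
            t = WaveletTrie.construct_batched(mat, max(1, -(-n // nbatch)))
            assert t == direct
            t.check_node_bound()

    def test_merge_width_mismatch(self):
        with pytest.raises(ValueError):
            wtrie.merge(wtrie.construct(["01"]), wtrie.construct(["011"]))


class TestEditing:
    def test_insert_at_end_equals_merge(self):
        rng = np.random.default_rng(3)
        mat = random_matrix(rng, 10, 5)
        extra = random_matrix(rng, 3, 5)
        t = WaveletTrie.construct(mat)
        ti = wtrie.insert_rows(t, 11, extra)
        assert ti == wtrie.merge(t, WaveletTrie.construct(extra))

    def test_insert_at_front(self):
        t = wtrie.construct(["011", "101"])
        ti = wtrie.insert_rows(t, 1, ["110"])
        assert ti.query(1).to01() == "110"
        assert ti == wtrie.construct(["110", "011", "101"])

    def test_insert_then_delete_round_trip(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n, m = int(rng.integers(1, 30)), int(rng.integers(1, 10))
            mat = random_matrix(rng, n, m)
            t = WaveletTrie.construct(mat)
            at = int(rng.integers(1, n + 2))
            row = random_matrix(rng, 1, m)
            assert wtrie.delete_row(wtrie.insert_rows(t, at, row), at) == t

    def test_delete_all_rows_one_by_one(self):
        t = wtrie.construct(["00", "01", "10", "11", "01"])
        rng = np.random.default_rng(5)
        while t.n_rows:
            t = wtrie.delete_row(t, int(rng.integers(1, t.n_rows + 1)))
            t.check_node_bound()
        assert t.root is None

    def test_update_equals_delete_insert(self):
        rng = np.random.default_rng(6)
        mat = random_matrix(rng, 12, 6)
        t = WaveletTrie.construct(mat)
        new = random_matrix(rng, 1, 6)[0]
        tu = wtrie.update_row(t, 5, new)
        td = wtrie.insert_rows(wtrie.delete_row(t, 5), 5, [new])
        assert tu == td
        exp = mat.copy()
        exp[4] = new
        assert np.array_equal(decode(tu), exp)

    def test_pad_width(self):
        t = wtrie.construct(["01", "11"])
        tp = wtrie.pad_width(t, 4)
        assert tp.width == 4
        assert [tp.query(i).to01() for i in (1, 2)] == ["0100", "1100"]
        assert tp == wtrie.construct(["0100", "1100"])

    def test_edit_positions_validated(self):
        t = wtrie.construct(["01"])
        with pytest.raises(IndexError):
            wtrie.insert_rows(t, 3, ["11"])
        with pytest.raises(IndexError):
            wtrie.delete_row(t, 2)


class TestSerialization:
    def test_round_trip_random(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            mat = random_matrix(rng, int(rng.integers(0, 40)),
                                int(rng.integers(1, 12)))
            t = WaveletTrie.construct(mat)
            t2 = WaveletTrie.deserialize(t.serialize())
            assert t2 == t
            assert np.array_equal(decode(t2), mat)

    def test_empty_trie(self):
        t = WaveletTrie.empty(5)
        t2 = WaveletTrie.deserialize(t.serialize())
        assert t2.n_rows == 0 and t2.width == 5

    def test_single_leaf_size_accounting(self):
        n, m = 17, 9
        t = wtrie.construct([[1, 0, 1, 0, 1, 0, 1, 0, 1]] * n)
        size = t.compressed_size()
        assert size.payload_bits == m + n  # alpha bits + leaf multiplicity
        assert size.total_bits == size.payload_bits + size.overhead_bits

    def test_bad_magic_rejected(self):
        t = wtrie.construct(["01"])
        blob = bytearray(t.serialize())
        blob[0] ^= 0xFF
        with pytest.raises(WTrieFormatError):
            WaveletTrie.deserialize(bytes(blob))

    def test_truncated_stream_rejected(self):
        t = wtrie.construct(["0110", "1001", "0101"])
        with pytest.raises(WTrieFormatError):
            WaveletTrie.deserialize(t.serialize()[:-2])


@given(
    st.lists(
        st.lists(st.integers(0, 1), min_size=4, max_size=4),
        min_size=1,
        max_size=24,
    )
)
def test_lossless_property(rows):
    mat = np.array(rows, dtype=np.uint8)
    t = WaveletTrie.construct(mat)
    assert np.array_equal(t.decode_all(), mat)
    t.check_node_bound()


def test_indicator_prefix_shrinks_trie_on_block_data():
    """On two-class block data, prefixed class indicators reduce the
    serialized trie size despite widening the matrix."""
    from cdbganno import synth_eval as se
    from cdbganno.annotation import strip_class_indicators

    a_ci = se.two_class_block_matrix(n_rows=400, colors_per_class=12, seed=0)
    a_plain = strip_class_indicators(a_ci)
    size_ci = WaveletTrie.construct(a_ci.matrix).compressed_size().total_bits
    size_plain = WaveletTrie.construct(a_plain.matrix).compressed_size().total_bits
    assert size_ci <= size_plain
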