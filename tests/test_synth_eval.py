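"""Synthetic family generator and evaluation procedures."""

import numpy as np
import pytest

from cdbganno import synth_eval as se
from cdbganno.annotation import AnnotationMatrix
from cdbganno.graph import build_graph


class TestGenerator:
    def test_fixed_seed_reproducible(self):
        spec = se.SyntheticFamilySpec(n_classes=2, genomes_per_class=2,
                                      genome_length=500, seed=5)
        assert se.generate_family(spec) == se.generate_family(spec)

    def test_zero_within_divergence_identical_genomes(self):
        spec = se.SyntheticFamilySpec(
            n_classes=2, genomes_per_class=3, genome_length=400,
            within_class_divergence=0.0, seed=1,
        )
        recs = se.generate_family(spec)
        by_class = {}
        for r in recs:
            by_class.setdefault(r.class_name, set()).add(r.sequence)
        assert all(len(s) == 1 for s in by_class.values())

    def test_identical_genomes_share_every_edge_coloring(self):
        spec = se.SyntheticFamilySpec(
            n_classes=1, genomes_per_class=3, genome_length=300,
            within_class_divergence=0.0, seed=2,
        )
        g, a = se.family_graph(se.generate_family(spec), k=15)
        assert (a.matrix.sum(axis=1) == 3).all()

    def test_high_between_divergence_near_disjoint_kmers(self):
        spec = se.SyntheticFamilySpec(
            n_classes=2, genomes_per_class=1, genome_length=2000,
            within_class_divergence=0.0, between_class_divergence=1.0, seed=3,
        )
        recs = se.generate_family(spec)
        k = 21
        s0 = {recs[0].sequence[i:i + k] for i in range(2000 - k + 1)}
        s1 = {recs[1].sequence[i:i + k] for i in range(2000 - k + 1)}
        # random 21-mer collision expectation is ~ L^2 / 4^21, essentially 0
        assert len(s0 & s1) <= 2

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            se.SyntheticFamilySpec(within_class_divergence=1.5)
        with pytest.raises(ValueError):
            se.SyntheticFamilySpec(n_classes=0)

    def test_labels_unique_and_classes_consistent(self):
        recs = se.generate_family(
            se.SyntheticFamilySpec(n_classes=3, genomes_per_class=4,
                                   genome_length=100, seed=0)
        )
        labels = [r.label for r in recs]
        assert len(set(labels)) == len(labels)
        assignment = se.class_assignment(recs)
        assert all(assignment[r.label] == r.class_name for r in recs)


class TestAccuracy:
    def test_perfect_decode(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((30, 4)) < 0.4).astype(np.uint8)
        a = AnnotationMatrix(mat, list("abcd"))
        assert se.accuracy(a, mat) == 1.0

    def test_one_wrong_row(self):
        mat = np.zeros((10, 3), np.uint8)
        a = AnnotationMatrix(mat, list("abc"))
        dec = mat.copy()
        dec[4, 1] = 1
        assert se.accuracy(a, dec) == pytest.approx(9 / 10)

    def test_mask_restricts_denominator(self):
        mat = np.zeros((4, 2), np.uint8)
        a = AnnotationMatrix(mat, list("ab"))
        dec = mat.copy()
        dec[0, 0] = 1
        mask = np.array([False, True, True, True])
        assert se.accuracy(a, dec, mask) == 1.0

    def test_shape_mismatch(self):
        a = AnnotationMatrix(np.zeros((2, 2), np.uint8), list("ab"))
        with pytest.raises(ValueError):
            se.accuracy(a, np.zeros((3, 2), np.uint8))

    def test_wtrie_codec_always_exact(self, small_family):
        from cdbganno.wtrie import WaveletTrie

        _, g, a = small_family
        t = WaveletTrie.construct(a.matrix)
        assert se.accuracy(a, t.decode_all()) == 1.0


class TestPermutationExperiment:
    def test_single_column_p_is_one(self):
        rng = np.random.default_rng(1)
        a = AnnotationMatrix((rng.random((40, 1)) < 0.5).astype(np.uint8), ["x"])
        rep = se.permutation_experiment(a, 20, seed=0)
        assert rep.empirical_p == 1.0

    def test_iid_columns_not_systematically_optimal(self):
        ps = []
        for s in range(5):
            rng = np.random.default_rng(s)
            mat = (rng.random((100, 10)) < 0.3).astype(np.uint8)
            a = AnnotationMatrix(mat, [f"c{i}" for i in range(10)])
            ps.append(se.permutation_experiment(a, 20, seed=50 + s).empirical_p)
        assert max(ps) > 0.2

    def test_block_matrix_original_order_in_lower_tail(self):
        a = se.two_class_block_matrix(n_rows=256, colors_per_class=12, seed=4)
        rep = se.permutation_experiment(a, 50, seed=6)
        assert rep.empirical_p <= 0.1

    def test_block_generator_structure(self):
        a = se.two_class_block_matrix(n_rows=50, colors_per_class=5, seed=0)
        assert a.m == 12 and a.indicator_count == 2
        # each row has exactly one indicator set and colors only in its block
        ind = a.matrix[:, :2]
        assert (ind.sum(axis=1) == 1).all()
        body = a.matrix[:, 2:]
        left = body[:, :5].sum(axis=1) > 0
        right = body[:, 5:].sum(axis=1) > 0
        assert not (left & right).any()


class TestSweep:
    def test_sweep_shapes_and_monotonicity(self, small_family):
        _, g, a = small_family
        table = se.sweep_bloom(g, a, [0.001, 0.05, 0.5], [0, 8])
        assert len(table) == 6
        # accuracy non-decreasing in bits-per-edge at fixed l_max
        for lmax in (0, 8):
            sub = table[table.l_max == lmax].sort_values("bits_per_edge")
            assert sub.accuracy.is_monotonic_increasing

    def test_generous_size_near_exact(self, small_family):
        _, g, a = small_family
        table = se.sweep_bloom(g, a, [0.001], [0])
        assert table.accuracy.iloc[0] >= 0.98

    def test_correction_dominates_raw(self, small_family):
        _, g, a = small_family
        table = se.sweep_bloom(g, a, [0.05, 0.3], [0, 8])
        for p in (0.05, 0.3):
            sub = table[table.fpp == p]
            corrected = sub[sub.l_max == 8].accuracy.iloc[0]
            raw = sub[sub.l_max == 0].accuracy.iloc[0]
            assert corrected >= raw

    def test_empty_grid_rejected(self, small_family):
        _, g, a = small_family
        with pytest.raises(ValueError):
            se.sweep_bloom(g, a, [], [0])
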