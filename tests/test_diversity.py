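"""PIC, Jaccard, UPGMA and panel summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from genicmarkers.datasets import MARKER_PANEL
from genicmarkers.diversity import (
    AlleleMatrix,
    jaccard,
    locus_frequencies,
    pic,
    summarize_diversity,
    upgma,
)
from genicmarkers.synthetic import simulate_allele_matrix

from oracles import dendrogram_nodes, naive_upgma


class TestPic:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((1.0,), 0.0),
            ((0.5, 0.5), 0.5),
            ((0.2, 0.2, 0.2, 0.2, 0.2), 0.8),
        ],
    )
    def test_closed_forms(self, freqs, expected):
        assert pic(freqs) == pytest.approx(expected)

    def test_published_panel_mean_and_range(self):
        pics = [p for _, _, p in MARKER_PANEL]
        assert round(float(np.mean(pics)), 2) == 0.54
        assert min(pics) == 0.14 and max(pics) == 0.85
        alleles = [a for _, a, _ in MARKER_PANEL]
        assert round(89 / len(MARKER_PANEL), 1) == 2.9  # printed allele total
        assert len(alleles) == 31

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            pic((0.5, 0.4))
        with pytest.raises(ValueError):
            pic((-0.1, 1.1))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(1, 8), st.integers(0, 2**31 - 1))
    def test_bounded_by_equifrequent_maximum(self, k, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(k))
        value = pic(p / p.sum())
        assert 0.0 <= value <= 1.0 - 1.0 / k + 1e-12

    def test_equality_at_equifrequency(self):
        for k in range(1, 9):
            assert pic(np.full(k, 1.0 / k)) == pytest.approx(1.0 - 1.0 / k)


class TestLocusFrequencies:
    def _matrix(self, scores, bands):
        return AlleleMatrix(
            tuple(f"G{i}" for i in range(len(scores))), bands, np.array(scores)
        )

    def test_single_band_monomorphic(self):
        m = self._matrix([[1]] * 10, (("L1", "A"),))
        assert locus_frequencies(m, "L1").tolist() == [1.0]
        assert pic(locus_frequencies(m, "L1")) == 0.0

    def test_band_count_ratio(self):
        scores = [[1, 0]] * 6 + [[0, 1]] * 4
        m = self._matrix(scores, (("L1", "A"), ("L1", "B")))
        assert locus_frequencies(m, "L1").tolist() == [0.6, 0.4]

    def test_null_genotypes_drop_out_of_denominator(self):
        scores = [[1, 0]] * 3 + [[0, 1]] * 1 + [[0, 0]] * 6
        m = self._matrix(scores, (("L1", "A"), ("L1", "B")))
        assert locus_frequencies(m, "L1").tolist() == [0.75, 0.25]

    def test_all_zero_locus_rejected(self):
        m = self._matrix([[0]] * 3, (("L1", "A"),))
        with pytest.raises(ValueError):
            locus_frequencies(m, "L1")


class TestJaccard:
    def test_identical_nonzero(self):
        assert jaccard([1, 0, 1], [1, 0, 1]) == 1.0

    def test_disjoint(self):
        assert jaccard([1, 0, 0], [0, 1, 1]) == 0.0

    def test_one_shared_of_three(self):
        assert jaccard([1, 1, 0], [1, 0, 1]) == pytest.approx(1 / 3)

    def test_all_zero_pair_defined_as_identical(self):
        assert jaccard([0, 0], [0, 0]) == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jaccard([1, 0], [1, 0, 1])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=30), st.data())
    def test_symmetry_and_bounds(self, x, data):
        y = data.draw(
            st.lists(st.booleans(), min_size=len(x), max_size=len(x))
        )
        s = jaccard(x, y)
        assert 0.0 <= s <= 1.0
        assert s == jaccard(y, x)


class TestUpgma:
    def test_two_taxa(self):
        tree = upgma([[0, 4], [4, 0]], ["A", "B"])
        assert tree.height == pytest.approx(2.0)
        heights = tree.tip_heights()
        assert heights["A"] == heights["B"] == pytest.approx(2.0)

    def test_three_taxa_hand_execution(self):
        d = [[0, 2, 6], [2, 0, 6], [6, 6, 0]]
        tree = upgma(d, ["A", "B", "C"])
        nodes = sorted(dendrogram_nodes(tree), key=lambda n: n[1])
        assert nodes[0] == (frozenset({"A", "B"}), 1.0)
        assert nodes[1] == (frozenset({"A", "B", "C"}), 3.0)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            upgma([[0, 1], [2, 0]], ["A", "B"])

    def _random_distance(self, rng, n):
        x = rng.uniform(0.1, 2.0, size=(n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        return d

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_naive_recomputed_upgma(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        labels = [f"T{i}" for i in range(n)]
        d = self._random_distance(rng, n)
        ours = dendrogram_nodes(upgma(d, labels))
        theirs = naive_upgma(d, labels)
        assert {t for t, _ in ours} == {t for t, _ in theirs}
        ours_h = dict(ours)
        for tips, h in theirs:
            assert ours_h[frozenset(tips)] == pytest.approx(h)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_scipy_average_linkage_cophenet(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        d = self._random_distance(rng, n)
        tree = upgma(d, [str(i) for i in range(n)])
        z = linkage(squareform(d), method="average")
        expected = squareform(cophenet(z))
        heights = {tips: h for tips, h in dendrogram_nodes(tree)}

        def coph(i, j):
            best = None
            for tips, h in heights.items():
                if str(i) in tips and str(j) in tips:
                    if best is None or h < best:
                        best = h
            return 2 * best

        for i in range(n):
            for j in range(i + 1, n):
                assert coph(i, j) == pytest.approx(expected[i, j])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_ultrametric_and_heights_monotone(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        d = self._random_distance(rng, n)
        tree = upgma(d, [f"T{i}" for i in range(n)])
        heights = list(tree.tip_heights().values())
        assert max(heights) - min(heights) < 1e-9

        def check(node):
            children, height, _ = node
            for child in children:
                assert child[1] <= height + 1e-12
                check(child)

        check(tree.root)

    def test_newick_roundtrips_through_dendropy(self):
        import dendropy

        tree = upgma([[0, 2, 6], [2, 0, 6], [6, 6, 0]], ["A", "B", "C"])
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == {"A", "B", "C"}


class TestSummarizeDiversity:
    def test_identical_rows_merge_at_height_zero(self):
        scores = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 0]])
        m = AlleleMatrix(
            ("G1", "G2", "G3"),
            (("L1", "A"), ("L1", "B"), ("L2", "A")),
            scores,
        )
        div = summarize_diversity(m)
        nodes = dict(dendrogram_nodes(div.dendrogram))
        assert nodes[frozenset({"G1", "G2"})] == pytest.approx(0.0)

    def test_estimated_pic_tracks_truth_frequencies(self):
        matrix, truth = simulate_allele_matrix(
            n_loci=8, n_genotypes=400, alleles_per_locus_dist=2, seed=9
        )
        div = summarize_diversity(matrix)
        for stats, t in zip(div.locus_stats, truth):
            assert stats.pic == pytest.approx(pic(t.frequencies), abs=0.08)

    def test_two_equifrequent_alleles_pic_converges_to_half(self):
        # law of large numbers on the band-frequency estimator
        matrix, truth = simulate_allele_matrix(
            n_loci=1, n_genotypes=3000, alleles_per_locus_dist=2,
            equifrequent=True, seed=1,
        )
        assert truth[0].frequencies == (0.5, 0.5)
        est = pic(locus_frequencies(matrix, "L001"))
        assert est == pytest.approx(0.5, abs=0.03)

    def test_single_allele_no_nulls_pic_zero(self):
        matrix, _ = simulate_allele_matrix(
            n_loci=3, n_genotypes=20, alleles_per_locus_dist=1, seed=2
        )
        div = summarize_diversity(matrix)
        assert all(s.pic == 0.0 for s in div.locus_stats)
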