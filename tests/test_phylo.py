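"""p-distances, neighbor joining against independent oracles, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pubclass.io import ValidationError
from pubclass.phylo import (Alignment, DistanceMatrix, bootstrap_support,
                            neighbor_joining, pairwise_pdistance)
from pubclass.synth import random_tree, simulate_alignment


class TestPDistance:
    def test_identical_sequences(self):
        d = pairwise_pdistance(Alignment(["A", "B"], ["ACDE", "ACDE"]))
        assert d.values[0, 1] == 0.0

    def test_one_mismatch_in_four(self):
        d = pairwise_pdistance(Alignment(["A", "B"], ["ACDE", "ACDK"]))
        assert d.values[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_drops_gap_columns(self):
        d = pairwise_pdistance(Alignment(["A", "B"], ["AC-E", "ACDE"]),
                               gap_mode="pairwise_deletion")
        assert d.values[0, 1] == 0.0  # 0 mismatches over 3 compared columns

    def test_complete_deletion_uses_gap_free_columns_only(self):
        aln = Alignment(["A", "B", "C"], ["AC-E", "ACDE", "KCDE"])
        d = pairwise_pdistance(aln, gap_mode="complete_deletion")
        # column 3 (gap in A) removed for ALL pairs: B vs C differ at 1 of 3
        assert d.values[1, 2] == pytest.approx(1 / 3)

    def test_x_treated_as_missing(self):
        d = pairwise_pdistance(Alignment(["A", "B"], ["AXDE", "ACDE"]))
        assert d.values[0, 1] == 0.0

    def test_no_comparable_columns_is_error(self):
        with pytest.raises(ValidationError, match="comparable"):
            pairwise_pdistance(Alignment(["A", "B"], ["A--", "-CD"]))

    def test_poisson_correction(self):
        d = pairwise_pdistance(Alignment(["A", "B"], ["ACDE", "ACDK"]),
                               correction="poisson")
        assert d.values[0, 1] == pytest.approx(-np.log(0.75))

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.text(alphabet="ACDEFG-X", min_size=12, max_size=12),
                    min_size=2, max_size=5, unique=True))
    def test_range_and_symmetry(self, seqs):
        aln = Alignment([f"T{i}" for i in range(len(seqs))], seqs)
        try:
            d = pairwise_pdistance(aln).values
        except ValidationError:
            return  # a pair without comparable columns is a legal rejection
        assert ((d >= 0) & (d <= 1)).all()
        assert np.allclose(d, d.T)


def _four_point_topology(d):
    """Independent oracle: the additive 4-taxon topology by the four-point
    condition (the pairing with the smallest sum of opposite path lengths)."""
    sums = {("AB|CD"): d[0, 1] + d[2, 3],
            ("AC|BD"): d[0, 2] + d[1, 3],
            ("AD|BC"): d[0, 3] + d[1, 2]}
    return min(sums, key=sums.get)


class TestNeighborJoining:
    def test_worked_four_taxon_example(self):
        # additive matrix built from leaf branches 1,2,3,4 and internal branch 1
        labels = list("ABCD")
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert np.allclose(tree.path_length_matrix(labels), d, atol=1e-9)
        assert set(tree.bipartitions()) == {frozenset({"C", "D"})}
        assert _four_point_topology(d) == "AB|CD"
        # leaf branch lengths are exactly 1, 2, 3, 4
        depths = {}
        def walk(node, acc):
            for c, bl in node.children:
                if c.is_leaf:
                    depths[c.name] = bl
                walk(c, acc + bl)
        walk(tree.root, 0.0)
        assert depths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxa_closed_form(self):
        labels = list("ABC")
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        lengths = {c.name: bl for c, bl in tree.root.children}
        assert lengths["A"] == pytest.approx((2 + 3 - 5) / 2)
        assert lengths["B"] == pytest.approx((2 + 5 - 3) / 2)
        assert lengths["C"] == pytest.approx((3 + 5 - 2) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0.0]])))

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValidationError):
            DistanceMatrix(list("ABC"), m)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_random_additive_matrices(self, seed):
        tree = random_tree(int(np.random.default_rng(seed).integers(5, 13)), seed=seed)
        labels = sorted(tree.leaf_names)
        d = tree.path_length_matrix(labels)
        rec = neighbor_joining(DistanceMatrix(labels, d))
        assert rec.bipartitions().keys() == tree.bipartitions().keys()
        assert np.allclose(rec.path_length_matrix(labels), d, atol=1e-9)

    def test_four_point_oracle_on_random_additive_quartets(self):
        for seed in range(25):
            tree = random_tree(list("ABCD"), seed=seed)
            d = tree.path_length_matrix(list("ABCD"))
            rec = neighbor_joining(DistanceMatrix(list("ABCD"), d))
            biparts = set(rec.bipartitions())
            expected = {"AB|CD": frozenset("CD"), "AC|BD": frozenset("BD"),
                        "AD|BC": frozenset("BC")}[_four_point_topology(d)]
            assert biparts == {expected}

    def test_matches_scikit_bio_topology(self):
        """Independent library cross-check on a non-additive matrix."""
        import skbio
        rng = np.random.default_rng(11)
        n = 7
        labels = [f"T{i}" for i in range(n)]
        m = rng.uniform(0.05, 0.9, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        mine = neighbor_joining(DistanceMatrix(labels, m))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(m, ids=labels))
        all_leaves, anchor = frozenset(labels), min(labels)
        sk_biparts = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = all_leaves - side
            if 2 <= len(side) <= n - 2:
                sk_biparts.add(side)
        assert set(mine.bipartitions()) == sk_biparts

    def test_taxon_order_invariance(self):
        tree = random_tree(8, seed=5)
        labels = sorted(tree.leaf_names)
        d = tree.path_length_matrix(labels)
        perm = np.random.default_rng(1).permutation(len(labels))
        t1 = neighbor_joining(DistanceMatrix(labels, d))
        t2 = neighbor_joining(DistanceMatrix(
            [labels[i] for i in perm], d[np.ix_(perm, perm)]))
        assert t1.bipartitions().keys() == t2.bipartitions().keys()

    def test_negative_branch_clamped_preserving_split_distance(self):
        # a decidedly non-additive matrix known to produce a negative NJ branch
        labels = list("ABCDE")
        m = np.array([
            [0.0, 0.1, 0.6, 0.6, 0.6],
            [0.1, 0.0, 0.6, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.05, 0.7],
            [0.6, 0.6, 0.05, 0.0, 0.05],
            [0.6, 0.6, 0.7, 0.05, 0.0]])
        tree = neighbor_joining(DistanceMatrix(labels, m))
        def all_lengths(node):
            out = []
            for c, bl in node.children:
                out.append(bl)
                out.extend(all_lengths(c))
            return out
        assert min(all_lengths(tree.root)) >= 0.0


def _diagnostic_alignment():
    """Two 3-taxon clades separated by 20 fixed diagnostic columns."""
    taxa = ["A1", "A2", "A3", "B1", "B2", "B3"]
    seqs = []
    for i, t in enumerate(taxa):
        diag = ("A" if t.startswith("A") else "C") * 20
        private = "".join("W" if j // 4 == i else "G" for j in range(24))
        seqs.append(diag + private)
    return Alignment(taxa, seqs)


class TestBootstrap:
    def test_fixed_signal_gives_full_support(self):
        tree = bootstrap_support(_diagnostic_alignment(), n_replicates=200, seed=3)
        supports = {frozenset(k): v.support for k, v in tree.bipartitions().items()}
        assert supports[frozenset({"B1", "B2", "B3"})] == 100

    def test_seed_determinism(self):
        aln = _diagnostic_alignment()
        t1 = bootstrap_support(aln, n_replicates=50, seed=9)
        t2 = bootstrap_support(aln, n_replicates=50, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_support_values_in_range(self):
        tree = random_tree(7, seed=2)
        aln = simulate_alignment(tree, 120, 0.8, seed=3)
        bt = bootstrap_support(aln, n_replicates=60, seed=4)
        for node in bt.bipartitions().values():
            assert 0 <= node.support <= 100
        assert bt.n_bootstrap_completed == 60

    def test_default_replicates_is_one_thousand(self):
        import inspect
        assert inspect.signature(bootstrap_support).parameters["n_replicates"].default == 1000
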