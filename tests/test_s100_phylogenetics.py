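import math

import dendropy
import numpy as np
import pytest

from edcscan.s100_phylogenetics import (
    MultipleAlignment,
    _bipartitions,
    all_supported_clades,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    nj_tree_from_alignment,
    pairwise_align_global,
    phylo_groups,
    progressive_align,
    root_with_outgroup,
    sum_of_pairs_score,
    _center_star,
)
from edcscan.synthetic_data import evolve_domain

from oracles import (
    needleman_wunsch_score,
    path_distance_matrix,
    random_binary_tree,
    tree_bipartitions_from_adj,
)

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def tree_biparts(tree):
    return _bipartitions(tree)


class TestPairwiseGlobal:
    def test_identity_alignment_is_gapless(self):
        ga, gb, score = pairwise_align_global("MK", "MK")
        assert (ga, gb) == ("MK", "MK")
        assert score == needleman_wunsch_score("MK", "MK")

    def test_length_difference_forces_terminal_gap(self):
        ga, gb, _ = pairwise_align_global("MK", "M")
        assert ga == "MK"
        assert gb in ("M-", "-M")

    def test_scores_match_affine_dp_oracle(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(AAS, size=int(rng.integers(5, 100))))
            b = "".join(rng.choice(AAS, size=int(rng.integers(5, 100))))
            _, _, score = pairwise_align_global(a, b)
            assert score == pytest.approx(needleman_wunsch_score(a, b))


class TestProgressiveAlign:
    def test_identical_sequences_align_gaplessly(self):
        seqs = [(f"s{i}", "MKWVTFISLL") for i in range(4)]
        aln = progressive_align(seqs)
        assert all(s == "MKWVTFISLL" for _, s in aln.rows)

    def test_single_insertion_gets_one_gap_column(self):
        seqs = [("a", "MKWVTFISLL"), ("b", "MKWVTFISLL"), ("c", "MKWVQTFISLL")]
        aln = progressive_align(seqs)
        assert aln.n_columns == 11
        gaps = {name: s.count("-") for name, s in aln.rows}
        assert gaps == {"a": 1, "b": 1, "c": 0}

    def test_ungapping_recovers_inputs(self, rng):
        seqs = [(f"s{i}", "".join(rng.choice(AAS, size=int(rng.integers(10, 40)))))
                for i in range(5)]
        aln = progressive_align(seqs)
        for name, seq in seqs:
            assert aln.ungapped(name) == seq

    def test_sum_of_pairs_at_least_center_star(self, rng):
        for _ in range(20):
            seqs = [(f"s{i}",
                     "".join(rng.choice(AAS, size=int(rng.integers(15, 60)))))
                    for i in range(3)]
            aln = progressive_align(seqs)
            star = _center_star(seqs, "BLOSUM62")
            assert sum_of_pairs_score(aln) >= sum_of_pairs_score(star) - 1e-9


class TestDistances:
    def test_identical_rows_have_zero_distance(self):
        aln = MultipleAlignment([("a", "MKWV"), ("b", "MKWV")])
        assert distance_matrix(aln)[0, 1] == 0.0

    def test_p_and_poisson_closed_forms(self):
        aln = MultipleAlignment([("a", "AAAA"), ("b", "AAAT")])
        assert distance_matrix(aln, "p")[0, 1] == pytest.approx(0.25)
        assert distance_matrix(aln, "poisson")[0, 1] == \
            pytest.approx(-math.log(0.75))

    def test_poisson_undefined_at_p_one(self):
        aln = MultipleAlignment([("a", "AAAA"), ("b", "TTTT")])
        with pytest.raises(ValueError):
            distance_matrix(aln, "poisson")

    def test_symmetric_zero_diagonal(self, rng):
        rows = [(f"s{i}", "".join(rng.choice(AAS, size=30))) for i in range(5)]
        D = distance_matrix(MultipleAlignment(rows))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_poisson_monotone_in_p(self):
        ps = np.linspace(0.05, 0.9, 10)
        vals = [-math.log(1 - p) for p in ps]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # d(ab)=3, d(ac)=5, d(bc)=6 -> la=1, lb=2, lc=4
        D = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
        tree = neighbor_joining(D, ["a", "b", "c"])
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["a"], taxa["b"]) == pytest.approx(3.0)
        assert pdm.distance(taxa["a"], taxa["c"]) == pytest.approx(5.0)
        assert pdm.distance(taxa["b"], taxa["c"]) == pytest.approx(6.0)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:1,B:1):1,(C:1,D:1):1)
        D = np.array([[0, 2, 3, 3],
                      [2, 0, 3, 3],
                      [3, 3, 0, 2],
                      [3, 3, 2, 0]], dtype=float)
        tree = neighbor_joining(D, list("ABCD"))
        assert tree_biparts(tree) == {frozenset("AB")} or \
            tree_biparts(tree) == {frozenset("CD")}
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, x in enumerate("ABCD"):
            for j, y in enumerate("ABCD"):
                if i < j:
                    assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(D[i, j])

    def test_random_additive_matrices_recover_topology_and_lengths(self, rng):
        for n in (5, 6, 7, 8):
            for _ in range(10):
                labels = [f"t{i}" for i in range(n)]
                adj, _ = random_binary_tree(labels, rng)
                D = path_distance_matrix(adj, labels)
                tree = neighbor_joining(D, labels)
                assert tree_biparts(tree) == tree_bipartitions_from_adj(adj, labels)
                pdm = tree.phylogenetic_distance_matrix()
                taxa = {t.label: t for t in tree.taxon_namespace}
                for i in range(n):
                    for j in range(i + 1, n):
                        assert pdm.distance(taxa[labels[i]], taxa[labels[j]]) == \
                            pytest.approx(D[i, j], abs=1e-9)

    def test_matches_independent_nj_implementation(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj
        labels = [f"t{i}" for i in range(6)]
        adj, _ = random_binary_tree(labels, rng)
        D = path_distance_matrix(adj, labels)
        D = (D + D.T) / 2.0  # symmetrize float round-off from traversal order
        ours = tree_biparts(neighbor_joining(D, labels))
        sk_tree = skbio_nj(DistanceMatrix(D, labels))
        sk = dendropy.Tree.get(data=str(sk_tree), schema="newick")
        theirs = tree_biparts(sk)
        assert ours == theirs

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(D, list("abc"))


class TestBootstrapAndRooting:
    def _strong_alignment(self):
        rows = [("a", "AAAA" * 25), ("b", "AAAC" * 25),
                ("c", "GGGG" * 25), ("d", "GGGT" * 25)]
        return MultipleAlignment(rows)

    def test_invariant_columns_give_full_support(self):
        tree = bootstrap_support(self._strong_alignment(), 100, seed=1)
        supports = [node.annotations.get_value("support")
                    for node in tree.preorder_node_iter()
                    if node.annotations.get_value("support") is not None]
        assert supports and all(s == pytest.approx(1.0) for s in supports)

    def test_same_seed_reproduces_supports(self):
        t1 = bootstrap_support(self._strong_alignment(), 50, seed=9)
        t2 = bootstrap_support(self._strong_alignment(), 50, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_invariant_to_row_permutation(self):
        aln = self._strong_alignment()
        perm = MultipleAlignment(list(reversed(aln.rows)))
        t1 = bootstrap_support(aln, 50, seed=3)
        t2 = bootstrap_support(perm, 50, seed=3)

        def support_map(t):
            out = {}
            for node in t.preorder_node_iter():
                s = node.annotations.get_value("support")
                if s is not None:
                    leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
                    out[leaves] = s
            return out

        m1, m2 = support_map(t1), support_map(t2)
        leafset = frozenset(aln.ids)
        norm = lambda m: {min(k, leafset - k, key=lambda s: (len(s), sorted(s))): v
                          for k, v in m.items()}
        assert norm(m1) == norm(m2)

    def test_outgroup_rooting_bipartition(self):
        aln = self._strong_alignment()
        tree = nj_tree_from_alignment(aln)
        rooted = root_with_outgroup(tree, "d")
        children = rooted.seed_node.child_nodes()
        sides = [frozenset(lf.taxon.label for lf in c.leaf_iter())
                 for c in children]
        assert frozenset(["d"]) in sides
        assert frozenset(["a", "b", "c"]) in sides

    def test_missing_outgroup_rejected(self):
        tree = nj_tree_from_alignment(self._strong_alignment())
        with pytest.raises(ValueError, match="outgroup"):
            root_with_outgroup(tree, "zz")

    def test_rooting_preserves_unrooted_topology(self):
        tree = nj_tree_from_alignment(self._strong_alignment())
        before = tree_biparts(tree)
        rooted = root_with_outgroup(tree, "a")
        assert tree_biparts(rooted) == before


class TestPhyloGroups:
    def _tree_with_supports(self, supports):
        t = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        inner = [n for n in t.preorder_node_iter()
                 if not n.is_leaf() and n.parent_node is not None]
        for node, s in zip(inner, supports):
            node.annotations.add_new("support", s)
        t.is_rooted = True
        return t

    def test_full_support_gives_both_cherries(self):
        groups = phylo_groups(self._tree_with_supports([1.0, 1.0]))
        assert frozenset("ab") in groups and frozenset("cd") in groups

    def test_zero_support_gives_singletons_only(self):
        groups = phylo_groups(self._tree_with_supports([0.0, 0.0]))
        assert all(len(g) == 1 for g in groups)
        assert len(groups) == 4

    def test_bootstrap_separates_two_planted_clades(self, rng):
        ancestor = "".join(rng.choice(AAS, size=200))
        leaves = evolve_domain(
            ancestor, "((a1:0.05,a2:0.05):0.4,(b1:0.05,b2:0.05):0.4);",
            rate=1.0, rng=rng)
        aln = progressive_align(sorted(leaves.items()))
        tree = bootstrap_support(aln, 100, seed=5)
        rooted = root_with_outgroup(tree, "b2")
        clades = all_supported_clades(rooted, 0.9)
        assert frozenset(["a1", "a2"]) in clades


class TestGeneratorBootstrapSanity:
    def test_true_splits_outrank_false_splits(self, rng):
        """Domains evolved along a known 6-taxon tree: true bipartitions
        collect higher mean bootstrap support than false ones."""
        newick = ("(((a:0.12,b:0.12):0.15,c:0.2):0.15,"
                  "((d:0.12,e:0.12):0.15,f:0.2):0.15);")
        truth = dendropy.Tree.get(data=newick, schema="newick")
        true_bp = tree_biparts(truth)
        true_support, false_support = [], []
        for rep in range(10):
            ancestor = "".join(rng.choice(AAS, size=200))
            leaves = evolve_domain(ancestor, newick, rate=1.0, rng=rng)
            aln = MultipleAlignment(sorted(leaves.items()))
            tree = bootstrap_support(aln, 50, seed=100 + rep)
            for node in tree.preorder_node_iter():
                s = node.annotations.get_value("support")
                if s is None:
                    continue
                below = frozenset(lf.taxon.label for lf in node.leaf_iter())
                full = frozenset(aln.ids)
                key = min(below, full - below, key=lambda x: (len(x), sorted(x)))
                (true_support if key in true_bp else false_support).append(s)
        assert np.mean(true_support) > (np.mean(false_support)
                                        if false_support else 0.0)
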