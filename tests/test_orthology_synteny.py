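import pandas as pd
import pytest

from edcscan.orthology_synteny import (
    OrthologyCall,
    apply_segmentation,
    call_orthologs,
    detect_locus_rearrangement,
    local_synteny_score,
    place_events_on_tree,
    reciprocal_best_hits,
    reciprocal_best_hits_from_matrix,
)

from oracles import brute_force_rbh


class TestReciprocalBestHits:
    def test_identical_sets_pair_identically(self):
        prots = [("a", "MKWVTF"), ("b", "GGSSGG"), ("c", "QQEEQQ")]
        pairs, ambiguous = reciprocal_best_hits(prots, prots)
        assert pairs == [("a", "a"), ("b", "b"), ("c", "c")]
        assert ambiguous == []

    def test_tied_best_hits_yield_no_call(self):
        scores = pd.DataFrame([[5.0, 5.0], [1.0, 2.0]],
                              index=["a1", "a2"], columns=["b1", "b2"])
        pairs, ambiguous = reciprocal_best_hits_from_matrix(scores)
        assert all(p[0] != "a1" for p in pairs)
        assert "a1" in ambiguous

    def test_matches_exhaustive_oracle_on_random_matrices(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 50, size=(20, 20)).astype(float)
            ids_a = [f"a{i}" for i in range(20)]
            ids_b = [f"b{i}" for i in range(20)]
            df = pd.DataFrame(scores, index=ids_a, columns=ids_b)
            pairs, _ = reciprocal_best_hits_from_matrix(df)
            assert pairs == brute_force_rbh(scores, ids_a, ids_b)

    def test_symmetry_under_locus_swap(self, rng):
        scores = rng.random((8, 8))
        ids_a = [f"a{i}" for i in range(8)]
        ids_b = [f"b{i}" for i in range(8)]
        p1, _ = reciprocal_best_hits_from_matrix(
            pd.DataFrame(scores, index=ids_a, columns=ids_b))
        p2, _ = reciprocal_best_hits_from_matrix(
            pd.DataFrame(scores.T, index=ids_b, columns=ids_a))
        assert sorted((b, a) for a, b in p1) == p2


class TestLocalSynteny:
    ORDER = [("S100A9", "+"), ("LOR", "+"), ("IVL", "-"), ("KPRP", "+"),
             ("SPRR", "+"), ("S100A11", "+")]

    def test_identical_loci_reach_maximum(self):
        for sym, _ in self.ORDER[1:-1]:
            score = local_synteny_score(sym, sym, self.ORDER, self.ORDER,
                                        window=2)
            left = min(2, self.ORDER.index((sym, dict(self.ORDER)[sym])))
        assert local_synteny_score("IVL", "IVL", self.ORDER, self.ORDER,
                                   window=2) == 4

    def test_no_shared_neighbors_scores_zero(self):
        other = [("X1", "+"), ("IVL", "+"), ("X2", "+")]
        assert local_synteny_score("IVL", "IVL", self.ORDER, other) == 0

    def test_translocated_gene_separated_at_threshold_two(self):
        moved = [("S100A9", "+"), ("LOR", "+"), ("KPRP", "+"),
                 ("SPRR", "+"), ("S100A11", "+"), ("Z1", "+"), ("Z2", "+"),
                 ("IVL", "-"), ("Z3", "+")]
        in_place = local_synteny_score("LOR", "LOR", self.ORDER, moved)
        translocated = local_synteny_score("IVL", "IVL", self.ORDER, moved)
        assert in_place >= 2
        assert translocated < 2


class TestCallOrthologs:
    def test_rbh_plus_synteny_plus_pair_clade_is_one_to_one(self):
        calls = call_orthologs([("a1", "b1")], {("a1", "b1"): 4},
                               [frozenset(["a1", "b1"])], ["a1"], ["b1"])
        [c] = calls
        assert c.relation == "one_to_one"
        assert c.evidence == {"reciprocal_best", "synteny", "phylo_group"}

    def test_rbh_alone_is_insufficient(self):
        [c] = call_orthologs([("a1", "b1")], {("a1", "b1"): 0}, None,
                             ["a1"], ["b1"])
        assert c.relation == "none"

    def test_expanded_family_becomes_co_ortholog_group(self):
        """One gene in A grouping with three in B (the FLG/FLG2/HRNR
        situation): a co-ortholog group, never one_to_one."""
        clades = [frozenset(["a1", "b1", "b2", "b3"]),
                  frozenset(["b2", "b3"]),
                  frozenset(["a2", "b4"])]
        calls = call_orthologs(
            [("a1", "b1"), ("a2", "b4")],
            {("a1", "b1"): 4, ("a2", "b4"): 4},
            clades, ["a1", "a2"], ["b1", "b2", "b3", "b4"])
        by_a = {c.gene_a: c for c in calls}
        assert by_a["a1"].relation == "co_ortholog_group"
        assert set(by_a["a1"].gene_b) == {"b1", "b2", "b3"}
        assert by_a["a2"].relation == "one_to_one"

    def test_never_one_to_one_inside_large_supported_clade(self):
        clades = [frozenset(["a1", "b1", "b2"])]
        calls = call_orthologs([("a1", "b1")], {("a1", "b1"): 6}, clades,
                               ["a1"], ["b1", "b2"])
        assert all(c.relation != "one_to_one" for c in calls)

    def test_one_to_one_requires_two_evidence_streams_by_contract(self):
        with pytest.raises(ValueError):
            OrthologyCall("a", "b", "one_to_one",
                          frozenset({"reciprocal_best"}))

    def test_without_phylo_calls_rest_on_rbh_and_synteny(self):
        calls = call_orthologs([("a1", "b1")], {("a1", "b1"): 3}, None,
                               ["a1"], ["b1"])
        [c] = calls
        assert c.relation == "one_to_one"
        assert c.evidence == {"reciprocal_best", "synteny"}


class TestRearrangement:
    A = [("S100A9", "+"), ("G1", "+"), ("G2", "-"), ("G3", "+"),
         ("G4", "+"), ("G5", "-"), ("S100A11", "+")]

    def test_identical_orders_one_segment_no_events(self):
        rep = detect_locus_rearrangement(self.A, self.A)
        assert len(rep.segments) == 1
        assert rep.events == []
        assert rep.segments[0].orientation == "same"

    def test_split_reports_segments_flanks_and_breakpoints(self):
        b = [("S100A9", "+"), ("G1", "+"), ("G2", "-"), ("N1", "+"),
             ("N2", "+"), ("G3", "+"), ("G4", "+"), ("G5", "-"),
             ("S100A11", "+")]
        rep = detect_locus_rearrangement(self.A, b)
        assert len(rep.segments) == 2
        assert [e["type"] for e in rep.events] == ["split"]
        assert rep.flank_assignment == {"S100A9": 0, "S100A11": 1}
        assert rep.breakpoints_a == [3]  # split before G3 in locus A

    def test_split_plus_inversion_detected_together(self):
        b = [("S100A9", "+"), ("G1", "+"), ("G2", "-"), ("N1", "+"),
             ("S100A11", "-"), ("G5", "+"), ("G4", "-"), ("G3", "-")]
        rep = detect_locus_rearrangement(self.A, b)
        assert len(rep.segments) == 2
        kinds = sorted(e["type"] for e in rep.events)
        assert kinds == ["inversion", "split"]
        inverted = [s for s in rep.segments if s.orientation == "inverted"]
        assert len(inverted) == 1
        assert [a for a, _ in inverted[0].pairs] == ["G3", "G4", "G5", "S100A11"]

    def test_reapplying_events_reproduces_segment_structure(self):
        b = [("S100A9", "+"), ("G1", "+"), ("N1", "+"),
             ("S100A11", "-"), ("G5", "+"), ("G4", "-"), ("G3", "-"),
             ("G2", "+")]
        rep = detect_locus_rearrangement(self.A, b)
        rebuilt = apply_segmentation(self.A, rep)
        shared_b = [s for s, _ in b if any(s == a for a, _ in self.A)]
        segments_in_b = []
        for seg in rebuilt:
            segments_in_b.extend(seg)
        assert sorted(segments_in_b) == sorted(shared_b)

    def test_no_shared_genes_rejected(self):
        with pytest.raises(ValueError):
            detect_locus_rearrangement([("X", "+")], [("Y", "+")])


class TestTreePlacement:
    def test_dollo_placement_on_smallest_containing_clade(self):
        ref = [("S100A9", "+"), ("G1", "+"), ("G2", "+"), ("G3", "+"),
               ("S100A11", "+")]
        split = [("S100A9", "+"), ("G1", "+"), ("N1", "+"), ("G2", "+"),
                 ("G3", "+"), ("S100A11", "+")]
        split_inv = [("S100A9", "+"), ("G1", "+"), ("N1", "+"),
                     ("S100A11", "-"), ("G3", "-"), ("G2", "-")]
        orders = {"platypus": ref, "opossum": split, "wombat": split_inv,
                  "devil": split_inv}
        events = place_events_on_tree(
            orders, "(platypus,(opossum,(wombat,devil)));", "platypus")
        by_kind = {e["type"]: e for e in events}
        assert by_kind["split"]["clade"] == ("devil", "opossum", "wombat")
        assert by_kind["inversion"]["clade"] == ("devil", "wombat")
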