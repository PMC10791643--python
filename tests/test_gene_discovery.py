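import pytest

from edcscan.gene_discovery import (
    GeneModel,
    Query,
    SearchParams,
    classify_gene_type,
    detect_pseudogene,
    iterative_discovery,
    queries_from_fasta_records,
    reverse_complement,
    seeded_search,
    six_frame_translate,
)
from edcscan.locus_io import GenomicRegion, extract_core_region
from edcscan.synthetic_data import random_dna, reverse_translate

from oracles import smith_waterman_score, _mat_dict

AAS = list("ACDEFGHIKLMNPQRSTVWY")

#: guaranteed-seed parameters: the neighborhood threshold is below the
#: minimum word score, so every word of every frame is a seed
GUARANTEED = SearchParams(neighborhood_threshold=-100, min_score=1)


def _self_score(peptide: str) -> float:
    mat = _mat_dict("BLOSUM62")
    return sum(mat[a, a] for a in peptide)


class TestSixFrameTranslate:
    def test_plus_frame_code_table(self):
        assert six_frame_translate("ATGAAATAA")[0] == "MK*"

    def test_minus_frame_uses_reverse_complement(self):
        assert six_frame_translate("TTACATTTTCAT")[3] == "MKM*"

    def test_codons_with_n_translate_to_x(self):
        assert six_frame_translate("ATGANA")[0] == "MX"

    def test_empty_input_gives_six_empty_frames(self):
        assert six_frame_translate("") == [""] * 6


class TestSeededSearch:
    def _region(self, dna):
        return GenomicRegion("t", 0, len(dna), "+", dna.upper())

    def test_exact_encoding_gives_identity_hit_at_self_score(self, rng):
        peptide = "MKWVTFISLLFLFSSAYS"
        dna = random_dna(60, rng) + reverse_translate(peptide, rng) + \
            random_dna(60, rng)
        hits = seeded_search(peptide, self._region(dna),
                            SearchParams(min_score=40))
        assert hits
        top = hits[0]
        assert top.identity_fraction == pytest.approx(1.0)
        assert top.score == pytest.approx(_self_score(peptide))
        assert top.strand == "+"

    def test_reverse_complement_gives_same_score_on_minus_strand(self, rng):
        peptide = "MKWVTFISLLFLFSSAYS"
        dna = random_dna(60, rng) + reverse_translate(peptide, rng) + \
            random_dna(60, rng)
        fwd = seeded_search(peptide, self._region(dna),
                            SearchParams(min_score=40))
        rev = seeded_search(peptide, self._region(reverse_complement(dna)),
                            SearchParams(min_score=40))
        assert rev[0].strand == "-"
        assert rev[0].score == pytest.approx(fwd[0].score)

    def test_low_complexity_query_is_never_masked(self, rng):
        # the defining non-default behavior: poly-S queries still hit
        dna = random_dna(90, rng) + reverse_translate("S" * 10, rng) + \
            random_dna(90, rng)
        hits = seeded_search("SSSSSSSSSS", self._region(dna),
                             SearchParams(min_score=30))
        assert hits
        assert hits[0].identity_fraction == pytest.approx(1.0)

    def test_query_shorter_than_seed_rejected(self, rng):
        with pytest.raises(ValueError, match="seed"):
            seeded_search("MK", self._region(random_dna(100, rng)))

    def test_scores_equal_quadratic_oracle_under_guaranteed_seeds(self, rng):
        for _ in range(10):
            q = "".join(rng.choice(AAS, size=int(rng.integers(30, 120))))
            dna = random_dna(int(rng.integers(120, 360)), rng)
            region = self._region(dna)
            hits = seeded_search(q, region, GUARANTEED)
            oracle = max(smith_waterman_score(q, frame)
                         for frame in six_frame_translate(dna))
            if hits:
                assert hits[0].score == pytest.approx(oracle)
            else:
                assert oracle < GUARANTEED.min_score

    def test_default_scores_never_exceed_oracle(self, rng):
        for _ in range(6):
            q = "".join(rng.choice(AAS, size=60))
            dna = random_dna(240, rng)
            region = self._region(dna)
            hits = seeded_search(q, region, SearchParams(min_score=1))
            oracle = max(smith_waterman_score(q, frame)
                         for frame in six_frame_translate(dna))
            for h in hits:
                assert h.score <= oracle + 1e-9


class TestModelsOnSyntheticLocus:
    @pytest.fixture(scope="class")
    def discovered(self, mini_truth):
        loc = mini_truth.loci["sp1"]
        core = extract_core_region(loc.annotations, sequence=loc.dna)
        models = iterative_discovery(mini_truth.queries, core.region,
                                     max_rounds=2)
        return mini_truth, loc, core, models

    def test_every_planted_gene_recovered(self, discovered):
        truth, loc, core, models = discovered
        off = core.region.start
        for ann in loc.annotations:
            if ann.gene_symbol in ("S100A9", "S100A11"):
                continue
            tce = [(s, e) for (s, e), c in zip(ann.exons, ann.coding_flags) if c]
            span = (tce[0][0], tce[-1][1])
            assert any(m.strand == ann.region.strand and
                       m.cds_span[0] + off < span[1] and
                       span[0] < m.cds_span[1] + off
                       for m in models), ann.gene_symbol

    def test_intact_gene_cds_boundaries_exact(self, discovered):
        truth, loc, core, models = discovered
        off = core.region.start
        flags = truth.pseudogene_flags["sp1"]
        for ann in loc.annotations:
            if ann.gene_symbol in ("S100A9", "S100A11") or flags[ann.gene_id]:
                continue
            tce = [(s, e) for (s, e), c in zip(ann.exons, ann.coding_flags) if c]
            assert any([(s + off, e + off) for s, e in m.coding_exons] == tce
                       for m in models), ann.gene_symbol

    def test_sftp_model_has_two_coding_exons_and_planted_protein(self, discovered):
        truth, loc, core, models = discovered
        sftp = [m for m in models if m.gene_class == "SFTP"]
        assert len(sftp) == 1
        assert sum(sftp[0].coding_flags) == 2
        assert sftp[0].protein == truth.proteins["sp1"]["sp1|SFTP1"]

    def test_pseudogene_flags_match_planted_truth(self, discovered):
        truth, loc, core, models = discovered
        off = core.region.start
        flags = truth.pseudogene_flags["sp1"]
        for ann in loc.annotations:
            if ann.gene_symbol in ("S100A9", "S100A11"):
                continue
            tce = [(s, e) for (s, e), c in zip(ann.exons, ann.coding_flags) if c]
            span = (tce[0][0], tce[-1][1])
            overl = [m for m in models if m.strand == ann.region.strand and
                     m.cds_span[0] + off < span[1] and span[0] < m.cds_span[1] + off]
            best = max(overl, key=lambda m: m.score)
            assert set(best.pseudogene_flags) == set(flags[ann.gene_id]), \
                ann.gene_symbol

    def test_discovery_is_deterministic(self, mini_truth):
        loc = mini_truth.loci["sp1"]
        core = extract_core_region(loc.annotations, sequence=loc.dna)
        a = iterative_discovery(mini_truth.queries, core.region, max_rounds=2)
        b = iterative_discovery(mini_truth.queries, core.region, max_rounds=2)
        assert [(m.gene_id, m.exons, m.protein) for m in a] == \
            [(m.gene_id, m.exons, m.protein) for m in b]

    def test_models_never_overlap_on_same_strand(self, discovered):
        _, _, _, models = discovered
        for i, a in enumerate(models):
            for b in models[i + 1:]:
                if a.strand != b.strand:
                    continue
                (s1, e1), (s2, e2) = a.cds_span, b.cds_span
                assert not (s1 < e2 and s2 < e1)


class TestClassification:
    def _model(self, n_coding, protein, junction=None):
        exons = [(i * 1000, i * 1000 + 300) for i in range(n_coding)]
        return GeneModel(gene_id="m", exons=exons,
                         coding_flags=[True] * n_coding, strand="+",
                         gene_class="unknown", protein=protein,
                         junctions=(junction,) if junction else ())

    def test_single_coding_exon_is_sedc(self):
        assert classify_gene_type(self._model(1, "A" * 312)) == "SEDC"

    def test_two_exons_short_tail_is_s100a(self):
        assert classify_gene_type(self._model(2, "A" * 105, junction=93)) == "S100A"

    def test_two_exons_long_cterm_is_sftp(self):
        assert classify_gene_type(self._model(2, "A" * 2800, junction=93)) == "SFTP"

    def test_four_plus_exons_is_pglyrp_three_unknown(self):
        assert classify_gene_type(self._model(4, "A" * 400)) == "PGLYRP"
        assert classify_gene_type(self._model(3, "A" * 400)) == "unknown"


class TestPseudogeneDetection:
    def _planted(self, rng, disruption=None):
        protein = "M" + "".join(rng.choice(AAS, size=199))
        cds = reverse_translate(protein, rng) + "TAA"
        if disruption == "premature_stop":
            cds = cds[:40 * 3] + "TAA" + cds[40 * 3 + 3:]
        elif disruption == "frameshift":
            cds = cds[:90 * 3 + 1] + cds[90 * 3 + 2:]
        dna = random_dna(150, rng) + cds + random_dna(400, rng)
        start = 150
        end = 150 + len(cds)
        region = GenomicRegion("t", 0, len(dna), "+", dna)
        model = GeneModel(gene_id="m", exons=[(start, end)],
                          coding_flags=[True], strand="+",
                          gene_class="SEDC", protein=protein, region=region)
        return model, protein

    def test_intact_gene_has_no_flags(self, rng):
        model, ref = self._planted(rng)
        assert detect_pseudogene(model, ref) == set()

    def test_planted_premature_stop_flagged(self, rng):
        model, ref = self._planted(rng, "premature_stop")
        assert detect_pseudogene(model, ref) == {"premature_stop"}

    def test_planted_single_nt_deletion_flagged_as_frameshift(self, rng):
        model, ref = self._planted(rng, "frameshift")
        assert detect_pseudogene(model, ref) == {"frameshift"}

    def test_empty_reference_rejected(self, rng):
        model, _ = self._planted(rng)
        with pytest.raises(ValueError):
            detect_pseudogene(model, "")


class TestIterativeDiscovery:
    def test_two_step_chain_needs_second_round(self, rng):
        """Gene B is within reach of the initial query; diverged gene C is
        only detectable from B's protein, hence only in round 2."""
        from edcscan.synthetic_data import mutate_protein

        a = "M" + "".join(rng.choice(AAS, size=180))
        b = mutate_protein(a, 0.62, rng, protected={0})
        c = mutate_protein(b, 0.62, rng, protected={0})
        dna = (random_dna(400, rng) + reverse_translate(b, rng) + "TAA" +
               random_dna(800, rng) + reverse_translate(c, rng) + "TGA" +
               random_dna(400, rng))
        region = GenomicRegion("t", 0, len(dna), "+", dna)
        query = [Query(id="A", sequence=a)]
        one = iterative_discovery(query, region, max_rounds=1)
        two = iterative_discovery(query, region, max_rounds=3)
        assert len(one) == 1
        assert len(two) == 2

    def test_empty_query_set_rejected(self, rng):
        region = GenomicRegion("t", 0, 100, "+", random_dna(100, rng))
        with pytest.raises(ValueError):
            iterative_discovery([], region)


class TestQueryMetadata:
    def test_class_and_junction_parsed_from_description(self):
        queries = queries_from_fasta_records(
            [("q1", "MKWV"), ("q2", "MKWV")],
            {"q1": "class=SFTP junction=93", "q2": ""})
        assert queries[0].gene_class == "SFTP"
        assert queries[0].junctions == (93,)
        assert queries[1].gene_class == "unknown"
        assert queries[1].junctions == ()
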