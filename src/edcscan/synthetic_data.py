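"""Simulation of EDC-like loci with full ground truth.

The generator emulates the study system this package targets: a gene
cluster bounded by two conserved S100A marker genes (S100A9, S100A11),
populated by single-coding-exon (SEDC) genes with strongly biased
amino-acid compositions, a few S100 fused-type (SFTP) genes combining a
conserved ~90-residue S100 domain with a long quasi-repetitive
low-complexity C-terminal domain, occasional pseudogenizing mutations
(premature stops, frameshifts), tandem duplications, and locus split /
inversion events on a species tree.  Every build returns the emitted
sequences together with the planted truth (annotations, proteins,
orthology map, disruption flags, rearrangement events), so each pipeline
stage can be scored against known answers.

Structural conventions match the discovery module: SEDC genes have one
non-coding exon and one coding exon; SFTP/S100A genes have a non-coding
exon and two coding exons separated by a phase-0 GT..AG intron at the
conserved domain junction; coding-exon coordinates are trimmed to the CDS
with the stop codon included.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio.Data import CodonTable

from edcscan.gene_discovery import Query, _translate_frame, reverse_complement
from edcscan.locus_io import Annotation, GenomicRegion

AA = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# Composition profiles (the four SEDC groups plus folded-domain background)

def make_profile(enriched: dict[str, float]) -> dict[str, float]:
    """A 20-residue composition with given enrichments, remainder uniform."""
    total = sum(enriched.values())
    if total >= 1.0:
        raise ValueError("enriched fractions must sum to < 1")
    rest = [a for a in AA if a not in enriched]
    out = dict(enriched)
    for a in rest:
        out[a] = (1.0 - total) / len(rest)
    return out


#: Default composition profiles for planted proteins.  The four SEDC groups
#: mirror the classic subdivision of cornified-envelope proteins: GS-rich
#: (loricrin-like), QE-rich (involucrin-like), GSCP-rich (LCE/KPRP-like) and
#: PCQ-rich (SPRR-like); "domain" is a near-uniform background for folded
#: S100 domains.
PROFILES: dict[str, dict[str, float]] = {
    "GS": make_profile({"G": 0.35, "S": 0.30}),
    "QE": make_profile({"Q": 0.30, "E": 0.26}),
    "GSCP": make_profile({"G": 0.18, "S": 0.18, "C": 0.14, "P": 0.14}),
    "PCQ": make_profile({"P": 0.22, "C": 0.16, "Q": 0.20}),
    "domain": make_profile({}),
}


# ---------------------------------------------------------------------------
# Scenario description

@dataclass(frozen=True)
class RepeatSpec:
    """Tandem-repeat plan for an SFTP C-terminal domain."""

    unit_length: int = 10
    copies: int = 50
    mutation_rate: float = 0.1


@dataclass(frozen=True)
class FamilySpec:
    """One gene family in the locus roster."""

    name: str
    gene_class: str                      # SEDC | SFTP | S100A
    profile: str = "GS"
    length: tuple[int, int] = (120, 300)  # protein length range (SEDC tail range)
    strand: str = "+"
    disruption: str | None = None        # premature_stop | frameshift
    copies: dict[str, int] = field(default_factory=dict)  # per-species copy number
    repeat: RepeatSpec | None = None     # SFTP C-terminal domain plan
    domain_length: int = 92              # S100 domain length (SFTP/S100A)


@dataclass(frozen=True)
class RearrangementEvent:
    """A locus split or inversion on a species-tree edge.

    ``clade`` names the species below the event's edge.  For a split,
    ``after_family`` places the breakpoint immediately downstream of that
    family; for an inversion, the segment containing that family is
    inverted.
    """

    kind: str                            # split | inversion
    clade: tuple[str, ...]
    after_family: str


@dataclass(frozen=True)
class LocusScenario:
    name: str
    seed: int
    species: tuple[str, ...]
    families: tuple[FamilySpec, ...]
    events: tuple[RearrangementEvent, ...] = ()
    species_tree: str | None = None      # newick
    query_identity: tuple[float, float] = (0.6, 0.8)
    intergenic_mean: int = 6500
    intergenic_sd: int = 1500
    intergenic_min: int = 400
    utr5: int = 30
    utr3: int = 30
    noncoding_exon: int = 60
    intron1: int = 120
    intron2: int = 150
    n_spacers: int = 3                   # non-EDC genes inserted at a split


@dataclass
class SpeciesLocus:
    species: str
    sequence_id: str
    dna: str
    annotations: list[Annotation]
    gene_order: list[tuple[str, str]]    # (symbol, strand) by coordinate


@dataclass
class GroundTruth:
    scenario: LocusScenario
    loci: dict[str, SpeciesLocus]
    queries: list[Query]
    references: dict[str, str]                       # query id -> intact protein
    proteins: dict[str, dict[str, str]]              # species -> gene id -> protein
    pseudogene_flags: dict[str, dict[str, frozenset]]
    family_genes: dict[str, dict[str, list[str]]]    # species -> family -> gene ids
    s100_domains: dict[str, str]                     # "species:gene_id" -> domain
    events: tuple[RearrangementEvent, ...] = ()


# ---------------------------------------------------------------------------
# Protein sampling and mutation

def sample_lowcomplexity_protein(profile: dict[str, float] | str, length: int,
                                 repeat_spec: RepeatSpec | None = None,
                                 rng: np.random.Generator | None = None) -> str:
    """Sample a low-complexity protein from a composition profile.

    Residues are i.i.d. draws from the profile; with ``repeat_spec`` a unit
    is sampled once and tandem-copied with a per-residue mutation rate,
    emulating the quasi-repetitive organisation of SFTP C-terminal domains.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    rng = rng if rng is not None else np.random.default_rng()
    letters = np.array(list(profile.keys()))
    probs = np.array(list(profile.values()), dtype=float)
    probs = probs / probs.sum()
    if repeat_spec is None:
        if length < 20:
            raise ValueError("length must be >= 20")
        return "".join(rng.choice(letters, size=length, p=probs))
    unit = "".join(rng.choice(letters, size=repeat_spec.unit_length, p=probs))
    out = []
    for _ in range(repeat_spec.copies):
        copy = list(unit)
        for i in range(len(copy)):
            if rng.random() < repeat_spec.mutation_rate:
                copy[i] = str(rng.choice(letters, p=probs))
        out.append("".join(copy))
    return "".join(out)


def mutate_protein(protein: str, identity: float, rng: np.random.Generator,
                   profile: dict[str, float] | str = "domain",
                   protected: Iterable[int] = ()) -> str:
    """Substitute residues to a target identity, sparing protected positions.

    Replacement residues are drawn from the composition profile so that
    mutation preserves the compositional character of the protein.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    letters = np.array(list(profile.keys()))
    probs = np.array(list(profile.values()), dtype=float)
    probs = probs / probs.sum()
    protected = set(protected)
    positions = [i for i in range(len(protein)) if i not in protected]
    n_mut = int(round((1.0 - identity) * len(protein)))
    n_mut = min(n_mut, len(positions))
    chosen = rng.choice(len(positions), size=n_mut, replace=False)
    seq = list(protein)
    for idx in chosen:
        pos = positions[int(idx)]
        new = str(rng.choice(letters, p=probs))
        while new == seq[pos]:
            new = str(rng.choice(letters, p=probs))
        seq[pos] = new
    return "".join(seq)


def evolve_domain(ancestor_protein: str, tree: dendropy.Tree | str, rate: float,
                  rng: np.random.Generator | None = None) -> dict[str, str]:
    """Evolve a protein along a tree by i.i.d. per-site substitution.

    Each site on a branch of length *b* substitutes with probability
    ``1 - exp(-rate * b)``, the replacement drawn uniformly from the other
    19 residues.  Returns the per-leaf sequences keyed by taxon label.
    """
    if len(ancestor_protein) < 50:
        raise ValueError("ancestor must be >= 50 residues")
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    rng = rng if rng is not None else np.random.default_rng()
    seqs: dict[int, str] = {id(tree.seed_node): ancestor_protein}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        b = node.edge.length or 0.0
        p = 1.0 - np.exp(-rate * b)
        seq = list(parent_seq)
        for i in range(len(seq)):
            if rng.random() < p:
                choices = [a for a in AA if a != seq[i]]
                seq[i] = choices[int(rng.integers(len(choices)))]
        seqs[id(node)] = "".join(seq)
        if node.is_leaf():
            out[node.taxon.label] = seqs[id(node)]
    return out


# ---------------------------------------------------------------------------
# DNA encoding

_FWD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS: dict[str, list[str]] = {}
for codon, aa in _FWD_TABLE.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Encode a protein with uniformly chosen synonymous codons."""
    out = []
    for aa in protein:
        codons = _CODONS[aa]
        out.append(codons[int(rng.integers(len(codons)))])
    return "".join(out)


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# Gene cassettes

@dataclass
class _Gene:
    """A laid-out gene before insertion into the locus."""

    gene_id: str
    symbol: str
    family: str
    gene_class: str
    strand: str
    dna: str                             # gene-oriented cassette sequence
    exons: list[tuple[int, int]]         # cassette-local, gene orientation
    coding_flags: list[bool]
    protein: str                         # intact protein (pre-disruption)
    flags: frozenset = frozenset()
    domain: str = ""                     # S100 domain (SFTP / S100A)


def _build_cassette(gene_id: str, symbol: str, family: str, gene_class: str,
                    strand: str, protein: str, junction: int | None,
                    scenario: LocusScenario, rng: np.random.Generator,
                    disruption: str | None = None, domain: str = "") -> _Gene:
    """Encode a protein into an exon-structured DNA cassette.

    Layout: [non-coding exon][intron1 GT..AG][5'UTR + CDS part 1]
    and, for two-coding-exon genes, [intron2 GT..AG][CDS part 2][3'UTR].
    A disruption plants a premature TAA or deletes one CDS nucleotide.
    """
    sc = scenario
    cds = reverse_translate(protein, rng) + _STOPS[int(rng.integers(3))]
    exon1 = random_dna(sc.noncoding_exon, rng)
    intron1 = "GT" + random_dna(sc.intron1 - 4, rng) + "AG"
    utr5 = random_dna(sc.utr5, rng)
    utr3 = random_dna(sc.utr3, rng)
    parts: list[str] = [exon1, intron1, utr5]
    exons: list[tuple[int, int]] = [(0, len(exon1))]
    coding = [False]
    pos = len(exon1) + len(intron1) + len(utr5)
    if junction is None:
        parts.append(cds)
        exons.append((pos, pos + len(cds)))
        coding.append(True)
        pos += len(cds)
    else:
        cds_a, cds_b = cds[: 3 * junction], cds[3 * junction:]
        intron2 = "GT" + random_dna(sc.intron2 - 4, rng) + "AG"
        parts += [cds_a, intron2, cds_b]
        exons.append((pos, pos + len(cds_a)))
        coding.append(True)
        pos += len(cds_a) + len(intron2)
        exons.append((pos, pos + len(cds_b)))
        coding.append(True)
        pos += len(cds_b)
    parts.append(utr3)
    dna = "".join(parts)
    flags: set[str] = set()
    if disruption is not None and junction is not None:
        raise ValueError("disruptions are only modelled in single-coding-exon genes")
    if disruption == "premature_stop":
        # replace an internal codon, ~20% into the CDS, with TAA
        codon_idx = max(20, len(protein) // 5)
        s, e = exons[1]
        off = s + 3 * codon_idx
        dna = dna[:off] + "TAA" + dna[off + 3:]
        flags.add("premature_stop")
    elif disruption == "frameshift":
        # delete one nucleotide mid-CDS; downstream coordinates shift by 1
        s, e = exons[1]
        off = s + 3 * (((e - s) // 3) // 2) + 1
        dna = dna[:off] + dna[off + 1:]
        exons = [(a - 1 if a >= off else a, b - 1 if b > off else b)
                 for a, b in exons]
        flags.add("frameshift")
    elif disruption is not None:
        raise ValueError(f"unknown disruption {disruption!r}")
    return _Gene(gene_id=gene_id, symbol=symbol, family=family,
                 gene_class=gene_class, strand=strand, dna=dna, exons=exons,
                 coding_flags=coding, protein=protein, flags=frozenset(flags),
                 domain=domain)


def _spacer_gene(i: int, scenario: LocusScenario, rng: np.random.Generator) -> _Gene:
    prot = "M" + sample_lowcomplexity_protein("domain", 150, rng=rng)
    return _build_cassette(f"NONEDC{i}", f"NONEDC{i}", f"NONEDC{i}", "unknown",
                           "+", prot, None, scenario, rng)


# ---------------------------------------------------------------------------
# Locus assembly

def _family_proteins(spec: FamilySpec, scenario: LocusScenario,
                     rng: np.random.Generator) -> tuple[str, int | None, str]:
    """(ancestor protein, junction, ancestor domain) for a family."""
    if spec.gene_class == "SEDC":
        length = int(rng.integers(spec.length[0], spec.length[1] + 1))
        prot = "M" + sample_lowcomplexity_protein(spec.profile, length - 1, rng=rng)
        return prot, None, ""
    domain = sample_lowcomplexity_protein("domain", spec.domain_length, rng=rng)
    junction = 1 + spec.domain_length
    if spec.gene_class == "SFTP":
        rep = spec.repeat or RepeatSpec()
        cterm = sample_lowcomplexity_protein(spec.profile, 0, repeat_spec=rep, rng=rng)
    else:  # S100A: short tail after the domain
        tail = int(rng.integers(spec.length[0], spec.length[1] + 1))
        cterm = sample_lowcomplexity_protein(spec.profile, tail, rng=rng)
    return "M" + domain + cterm, junction, domain


def _protected_positions(protein: str, junction: int | None) -> set[int]:
    n = len(protein)
    prot = {0, 1, 2, n - 3, n - 2, n - 1}
    if junction is not None:
        prot |= {junction - 2, junction - 1, junction, junction + 1}
    return prot


def build_locus(scenario: LocusScenario) -> GroundTruth:
    """Assemble per-species loci and ground truth for a scenario.

    Genes are laid out in roster order between the S100A9 and S100A11
    marker genes; copy-number, disruption and rearrangement events are
    applied per species.  A translate-and-compare self-check asserts that
    emitted DNA and truth proteins agree on every build.
    """
    rng = np.random.default_rng(scenario.seed)
    lo_id, hi_id = scenario.query_identity

    # ancestor (query) proteins per family, plus the two flank markers
    flank_specs = [
        FamilySpec("S100A9", "S100A", "domain", length=(20, 24)),
        FamilySpec("S100A11", "S100A", "domain", length=(20, 24)),
    ]
    ancestors: dict[str, tuple[str, int | None, str]] = {}
    for spec in list(scenario.families) + flank_specs:
        ancestors[spec.name] = _family_proteins(spec, scenario, rng)

    queries: list[Query] = []
    references: dict[str, str] = {}
    for spec in scenario.families:
        prot, junction, _dom = ancestors[spec.name]
        qid = f"HS_{spec.name}"
        queries.append(Query(id=qid, sequence=prot, gene_class=spec.gene_class,
                             junctions=(junction,) if junction else ()))
        references[qid] = prot

    loci: dict[str, SpeciesLocus] = {}
    proteins: dict[str, dict[str, str]] = {}
    flags_by_sp: dict[str, dict[str, frozenset]] = {}
    family_genes: dict[str, dict[str, list[str]]] = {}
    domains: dict[str, str] = {}

    for species in scenario.species:
        sp_rng = np.random.default_rng(
            np.random.SeedSequence([scenario.seed,
                                    zlib.crc32(species.encode()) % (2 ** 31)]))
        genes: list[_Gene] = []

        def plant(spec: FamilySpec, symbol: str, gene_id: str,
                  base_protein: str | None = None,
                  disruption: str | None = None) -> _Gene:
            anc, junction, anc_dom = ancestors[spec.name]
            source = base_protein if base_protein is not None else anc
            identity = lo_id + (hi_id - lo_id) * sp_rng.random()
            protein = mutate_protein(
                source, identity, sp_rng, profile=spec.profile,
                protected=_protected_positions(source, junction))
            dom = protein[1:junction] if junction else ""
            return _build_cassette(gene_id, symbol, spec.name, spec.gene_class,
                                   spec.strand, protein, junction, scenario,
                                   sp_rng, disruption=disruption, domain=dom)

        roster_genes: list[_Gene] = []
        for spec in scenario.families:
            n_copies = spec.copies.get(species, 1)
            base = None
            for c in range(n_copies):
                suffix = f"_{c + 1}" if n_copies > 1 else ""
                g = plant(spec, spec.name + suffix, f"{species}|{spec.name}{suffix}",
                          base_protein=base, disruption=spec.disruption)
                if c == 0:
                    base = g.protein  # later tandem copies diverge from copy 1
                roster_genes.append(g)

        flank5 = plant(flank_specs[0], "S100A9", f"{species}|S100A9")
        flank3 = plant(flank_specs[1], "S100A11", f"{species}|S100A11")

        # rearrangement events affecting this species
        layout: list[list[_Gene]] = [[flank5] + roster_genes + [flank3]]
        for ev in scenario.events:
            if species not in ev.clade:
                continue
            if ev.kind == "split":
                seg = layout[-1]
                cut = next(i for i, g in enumerate(seg) if g.family == ev.after_family) + 1
                spacers = [_spacer_gene(i + 1, scenario, sp_rng)
                           for i in range(scenario.n_spacers)]
                layout = layout[:-1] + [seg[:cut], spacers, seg[cut:]]
            elif ev.kind == "inversion":
                # invert the segment containing the named family
                for si, seg in enumerate(layout):
                    if any(g.family == ev.after_family for g in seg):
                        layout[si] = [
                            replace(g, strand="-" if g.strand == "+" else "+")
                            for g in reversed(seg)]
                        break
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")

        ordered = [g for seg in layout for g in seg]

        # lay the genes onto a chromosome with random intergenic spacers
        chrom_parts: list[str] = []
        annotations: list[Annotation] = []
        order: list[tuple[str, str]] = []
        pos = 0
        seqid = f"{species}_chr1"
        sp_prot: dict[str, str] = {}
        sp_flags: dict[str, frozenset] = {}
        fam_map: dict[str, list[str]] = {}
        lead = random_dna(scenario.intergenic_min, sp_rng)
        chrom_parts.append(lead)
        pos += len(lead)
        for g in ordered:
            glen = len(g.dna)
            if g.strand == "+":
                chrom_parts.append(g.dna)
                exons = [(pos + s, pos + e) for s, e in g.exons]
                coding = list(g.coding_flags)
            else:
                chrom_parts.append(reverse_complement(g.dna))
                exons = sorted((pos + glen - e, pos + glen - s) for s, e in g.exons)
                coding = list(g.coding_flags)[::-1]
            annotations.append(Annotation(
                gene_id=g.gene_id,
                region=GenomicRegion(seqid, exons[0][0], exons[-1][1], g.strand),
                exons=exons, coding_flags=coding, gene_symbol=g.symbol,
                gene_class=g.gene_class, pseudogene_evidence=tuple(sorted(g.flags)),
            ))
            order.append((g.symbol, g.strand))
            sp_prot[g.gene_id] = g.protein
            sp_flags[g.gene_id] = g.flags
            fam_map.setdefault(g.family, []).append(g.gene_id)
            if g.domain:
                domains[f"{species}:{g.gene_id}"] = g.domain
            pos += glen
            gap = max(scenario.intergenic_min,
                      int(sp_rng.normal(scenario.intergenic_mean, scenario.intergenic_sd)))
            chrom_parts.append(random_dna(gap, sp_rng))
            pos += gap
        dna = "".join(chrom_parts)

        _self_check(dna, annotations, sp_prot, sp_flags, utr5=scenario.utr5)
        loci[species] = SpeciesLocus(species=species, sequence_id=seqid, dna=dna,
                                     annotations=annotations, gene_order=order)
        proteins[species] = sp_prot
        flags_by_sp[species] = sp_flags
        family_genes[species] = fam_map

    return GroundTruth(scenario=scenario, loci=loci, queries=queries,
                       references=references, proteins=proteins,
                       pseudogene_flags=flags_by_sp, family_genes=family_genes,
                       s100_domains=domains, events=scenario.events)


def _self_check(dna: str, annotations: Sequence[Annotation],
                proteins: dict[str, str], flags: dict[str, frozenset],
                utr5: int = 0) -> None:
    """Structural self-checks on every build: all planted introns are GT..AG,
    and translating the truth CDS of intact genes yields the truth protein.

    Coding-exon coordinates are CDS-trimmed, so the acceptor of the intron
    preceding the first coding exon sits ``utr5`` nucleotides upstream of it.
    """
    for ann in annotations:
        exons = ann.exons if ann.region.strand == "+" else ann.exons[::-1]
        coding = (ann.coding_flags if ann.region.strand == "+"
                  else ann.coding_flags[::-1])
        first_coding = coding.index(True)
        for i, ((s1, e1), (s2, e2)) in enumerate(zip(exons, exons[1:])):
            gap = utr5 if i + 1 == first_coding else 0
            if ann.region.strand == "+":
                donor, acceptor = dna[e1:e1 + 2], dna[s2 - gap - 2:s2 - gap]
            else:
                donor = reverse_complement(dna[s1 - 2:s1])
                acceptor = reverse_complement(dna[e2 + gap:e2 + gap + 2])
            if donor != "GT" or acceptor != "AG":
                raise AssertionError(
                    f"planted intron of {ann.gene_id} is not GT..AG")
        if flags.get(ann.gene_id):
            continue
        segs = [dna[s:e] for (s, e), c in zip(ann.exons, ann.coding_flags) if c]
        cds = "".join(segs)
        if ann.region.strand == "-":
            cds = reverse_complement("".join(
                dna[s:e] for (s, e), c in
                zip(ann.exons, ann.coding_flags) if c))
        prot = _translate_frame(cds, 0)
        if not prot.endswith("*") or prot[:-1] != proteins[ann.gene_id]:
            raise AssertionError(
                f"truth self-check failed for {ann.gene_id}: emitted CDS does "
                f"not translate to the truth protein")


# ---------------------------------------------------------------------------
# Named scenarios

def fig1_locus(seed: int = 20_03) -> LocusScenario:
    """A single-species ~200 kb locus: 20 SEDC + 4 SFTP genes, 5 disrupted."""
    profiles = ["GS", "QE", "GSCP", "PCQ"]
    families: list[FamilySpec] = []
    disruptions = {2: "premature_stop", 7: "frameshift", 11: "premature_stop",
                   15: "frameshift", 18: "premature_stop"}
    for i in range(20):
        families.append(FamilySpec(
            name=f"SEDC{i + 1:02d}",
            gene_class="SEDC",
            profile=profiles[i % 4],
            length=(120, 320),
            strand="+" if i % 3 else "-",
            disruption=disruptions.get(i),
        ))
    for i in range(4):
        families.append(FamilySpec(
            name=f"SFTP{i + 1}",
            gene_class="SFTP",
            profile=["GS", "QE", "GSCP", "PCQ"][i],
            strand="+" if i % 2 else "-",
            repeat=RepeatSpec(unit_length=10, copies=45 + 10 * i, mutation_rate=0.1),
        ))
    return LocusScenario(name="fig1_locus", seed=seed, species=("platypus",),
                         families=tuple(families))


def fig2_rearrangement(seed: int = 20_04) -> LocusScenario:
    """Four species; a locus split on the marsupial stem edge and an
    inversion of the distal segment on a nested edge."""
    families = [FamilySpec(name=f"SEDC{i + 1:02d}", gene_class="SEDC",
                           profile=["GS", "QE", "GSCP", "PCQ"][i % 4],
                           length=(100, 200), strand="+" if i % 2 else "-")
                for i in range(10)]
    families.append(FamilySpec(name="SFTP1", gene_class="SFTP", profile="GS",
                               repeat=RepeatSpec(10, 40, 0.1)))
    return LocusScenario(
        name="fig2_rearrangement", seed=seed,
        species=("platypus", "opossum", "wombat", "devil"),
        species_tree="(platypus,(opossum,(wombat,devil)));",
        families=tuple(families),
        events=(
            RearrangementEvent("split", ("opossum", "wombat", "devil"), "SEDC05"),
            RearrangementEvent("inversion", ("wombat", "devil"), "SEDC06"),
        ),
        intergenic_mean=800, intergenic_sd=200, intergenic_min=200,
    )


def fig5_sftp_expansion(seed: int = 20_05) -> LocusScenario:
    """Two species; one SFTP family expanded to three tandem copies in one
    lineage (the FLG/FLG2/HRNR-like situation), all others unduplicated."""
    families = [
        FamilySpec(name="SEDC01", gene_class="SEDC", profile="GS", length=(120, 200)),
        FamilySpec(name="SEDC02", gene_class="SEDC", profile="QE", length=(120, 200),
                   strand="-"),
        FamilySpec(name="SFTPA", gene_class="SFTP", profile="GSCP",
                   repeat=RepeatSpec(10, 40, 0.1)),
        FamilySpec(name="FLGL", gene_class="SFTP", profile="GS",
                   repeat=RepeatSpec(10, 45, 0.1),
                   copies={"opossum": 3}),
        FamilySpec(name="SFTPB", gene_class="SFTP", profile="PCQ",
                   repeat=RepeatSpec(10, 40, 0.1)),
        FamilySpec(name="SEDC03", gene_class="SEDC", profile="GSCP", length=(120, 200)),
    ]
    return LocusScenario(
        name="fig5_sftp_expansion", seed=seed,
        species=("platypus", "opossum"),
        species_tree="(platypus,opossum);",
        families=tuple(families),
        intergenic_mean=1200, intergenic_sd=300, intergenic_min=300,
    )


_SCENARIOS = {
    "fig1_locus": fig1_locus,
    "fig2_rearrangement": fig2_rearrangement,
    "fig5_sftp_expansion": fig5_sftp_expansion,
}


def named_scenario(name: str, seed: int | None = None) -> LocusScenario:
    """One of the bundled scenarios, optionally reseeded."""
    if name not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"available: {sorted(_SCENARIOS)}")
    return _SCENARIOS[name]() if seed is None else _SCENARIOS[name](seed)


# ---------------------------------------------------------------------------
# Discovery evaluation against truth

def evaluate_discovery(models: Sequence, truth: SpeciesLocus,
                       flags: dict[str, frozenset],
                       core_offset: int = 0) -> dict:
    """Score discovered gene models against planted truth.

    A truth gene counts as recovered when a model's CDS span overlaps it on
    the same strand; a model counts as a true positive when it overlaps any
    truth CDS.  Boundary exactness (coding exons identical) is evaluated on
    intact genes; pseudogene flags are compared per truth gene using its
    best-scoring overlapping model.  ``core_offset`` translates model
    coordinates (region-local) into locus coordinates.
    """
    truth_genes = [a for a in truth.annotations
                   if a.gene_symbol not in ("S100A9", "S100A11")
                   and not a.gene_symbol.startswith("NONEDC")]
    model_spans = []
    for m in models:
        s, e = m.cds_span
        model_spans.append((s + core_offset, e + core_offset, m.strand, m))
    matched_truth = 0
    boundary_exact = 0
    boundary_eligible = 0
    flags_match = 0
    for ann in truth_genes:
        t_ce = [(s, e) for (s, e), c in zip(ann.exons, ann.coding_flags) if c]
        t_span = (t_ce[0][0], t_ce[-1][1])
        overl = [(ms, me, st, m) for ms, me, st, m in model_spans
                 if st == ann.region.strand and ms < t_span[1] and t_span[0] < me]
        if overl:
            matched_truth += 1
            best = max(overl, key=lambda x: x[3].score)[3]
            truth_flags = set(flags.get(ann.gene_id, frozenset()))
            if set(best.pseudogene_flags) == truth_flags:
                flags_match += 1
            if not truth_flags:
                boundary_eligible += 1
                m_ce = [(s + core_offset, e + core_offset)
                        for s, e in best.coding_exons]
                if m_ce == t_ce:
                    boundary_exact += 1
        else:
            if not flags.get(ann.gene_id, frozenset()):
                boundary_eligible += 1
    tp_models = sum(
        1 for ms, me, st, m in model_spans
        if any(st == ann.region.strand and
               ms < max(e for (s, e), c in zip(ann.exons, ann.coding_flags) if c) and
               min(s for (s, e), c in zip(ann.exons, ann.coding_flags) if c) < me
               for ann in truth_genes))
    n_truth = len(truth_genes)
    n_models = len(model_spans)
    return {
        "n_truth": n_truth,
        "n_models": n_models,
        "sensitivity": matched_truth / n_truth if n_truth else 0.0,
        "precision": tp_models / n_models if n_models else 0.0,
        "boundary_exact_fraction":
            boundary_exact / boundary_eligible if boundary_eligible else 0.0,
        "pseudogene_flag_accuracy": flags_match / n_truth if n_truth else 0.0,
    }
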