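"""Orthology calling and locus-rearrangement detection between two loci.

Orthology rests on three evidence streams — reciprocal best sequence
similarity, shared local synteny, and membership in the same supported
phylogenetic group — and no single stream is considered sufficient on its
own: a one-to-one call requires reciprocal best hits plus at least one
concordant second stream, and a supported clade containing one gene from
one locus and several from the other produces a co-ortholog group (the
FLG/FLG2/HRNR-versus-monotreme-SFTP situation), never one-to-one calls.

Gene-order comparison decomposes two loci into maximal common-order
segments (allowing whole-segment reversal), reporting breakpoints, segment
orientations, flank assignment, and — given a species tree — parsimony
placement of split/inversion events on its edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from edcscan.gene_discovery import _aligner


@dataclass(frozen=True)
class OrthologyCall:
    """An evidence-tagged relationship between genes of two loci."""

    gene_a: str
    gene_b: str | tuple[str, ...]
    relation: str                      # one_to_one | co_ortholog_group | none
    evidence: frozenset[str]           # subset of {reciprocal_best, synteny, phylo_group}
    note: str = ""

    def __post_init__(self):
        if self.relation not in ("one_to_one", "co_ortholog_group", "none"):
            raise ValueError(f"bad relation {self.relation!r}")
        if self.relation != "none" and not self.evidence:
            raise ValueError("non-none call requires evidence")
        if self.relation == "one_to_one" and len(self.evidence) < 2:
            raise ValueError("one_to_one requires >= 2 evidence streams")


@dataclass
class SyntenyBlock:
    """A maximal run of genes in common order between two loci."""

    pairs: list[tuple[str, str]]       # (symbol in A, symbol in B), A-ordered
    orientation: str                   # same | inverted
    flank_context: tuple[str, ...] = ()

    def __post_init__(self):
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class RearrangementReport:
    segments: list[SyntenyBlock]
    breakpoints_a: list[int]           # gene-index breakpoints in locus A
    breakpoints_b: list[int]
    events: list[dict]                 # {type, ...} with optional tree placement
    flank_assignment: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reciprocal best hits

def global_alignment_scorer(matrix: str = "BLOSUM62", gap_open: int = 11,
                            gap_extend: int = 1) -> Callable[[str, str], float]:
    al = _aligner(matrix, gap_open, gap_extend, "global")

    def score(a: str, b: str) -> float:
        return float(al.score(a, b))

    return score


def score_matrix(proteins_a: Sequence[tuple[str, str]],
                 proteins_b: Sequence[tuple[str, str]],
                 scorer: Callable[[str, str], float] | None = None) -> pd.DataFrame:
    """All-vs-all similarity scores (rows = A ids, columns = B ids)."""
    scorer = scorer or global_alignment_scorer()
    rows = {}
    for ida, seqa in proteins_a:
        rows[ida] = {idb: scorer(seqa, seqb) for idb, seqb in proteins_b}
    return pd.DataFrame.from_dict(rows, orient="index")


def reciprocal_best_hits_from_matrix(scores: pd.DataFrame,
                                     ) -> tuple[list[tuple[str, str]], list[str]]:
    """RBH pairs from a score matrix; ties yield no call and are logged.

    (a, b) is reported iff b is a's unique best column and a is b's unique
    best row.  Returns (pairs sorted by A id, ids involved in a tie).
    """
    pairs = []
    ambiguous: list[str] = []
    vals = scores.to_numpy(dtype=float)
    best_col = {}
    for i, ida in enumerate(scores.index):
        row = vals[i]
        m = row.max()
        winners = np.flatnonzero(row == m)
        if len(winners) != 1:
            ambiguous.append(str(ida))
            best_col[ida] = None
        else:
            best_col[ida] = scores.columns[winners[0]]
    best_row = {}
    for j, idb in enumerate(scores.columns):
        col = vals[:, j]
        m = col.max()
        winners = np.flatnonzero(col == m)
        if len(winners) != 1:
            ambiguous.append(str(idb))
            best_row[idb] = None
        else:
            best_row[idb] = scores.index[winners[0]]
    for ida, idb in best_col.items():
        if idb is not None and best_row.get(idb) == ida:
            pairs.append((str(ida), str(idb)))
    return sorted(pairs), sorted(set(ambiguous))


def reciprocal_best_hits(proteins_a: Sequence[tuple[str, str]],
                         proteins_b: Sequence[tuple[str, str]],
                         scorer: Callable[[str, str], float] | None = None,
                         ) -> tuple[list[tuple[str, str]], list[str]]:
    """RBH pairs between two protein sets under a similarity scorer
    (default: affine-gap global alignment score)."""
    return reciprocal_best_hits_from_matrix(
        score_matrix(proteins_a, proteins_b, scorer))


# ---------------------------------------------------------------------------
# Local synteny

def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def local_synteny_score(gene_a: str | int, gene_b: str | int,
                        order_a: Sequence[tuple[str, str]],
                        order_b: Sequence[tuple[str, str]],
                        window: int = 3) -> int:
    """Shared gene symbols in the oriented neighborhoods of two genes.

    ``order_*`` are (symbol, strand) lists in locus order; genes may be
    given by symbol or by index (indices disambiguate tandem copies that
    share a family symbol).  Neighborhoods are taken gene-relative (a
    minus-strand gene's upstream side lies to its right), and upstream /
    downstream sides are compared separately, so a maximum of
    ``2 * window`` symbols can be shared.
    """
    def sides(order, gene):
        syms = [_norm(s) for s, _ in order]
        idx = gene if isinstance(gene, int) else syms.index(_norm(gene))
        left = set(syms[max(0, idx - window):idx])
        right = set(syms[idx + 1:idx + 1 + window])
        if order[idx][1] == "-":
            left, right = right, left
        return left, right

    try:
        up_a, down_a = sides(order_a, gene_a)
        up_b, down_b = sides(order_b, gene_b)
    except ValueError as exc:
        raise ValueError("gene not present in its locus order") from exc
    return len(up_a & up_b) + len(down_a & down_b)


# ---------------------------------------------------------------------------
# Orthology calling

def call_orthologs(rbh_pairs: Sequence[tuple[str, str]],
                   synteny_scores: Mapping[tuple[str, str], int],
                   phylo_clades: Sequence[frozenset[str]] | None,
                   genes_a: Sequence[str], genes_b: Sequence[str],
                   synteny_threshold: int = 2) -> list[OrthologyCall]:
    """Combine the three evidence streams into orthology calls.

    One-to-one requires an RBH plus either sufficient local synteny or a
    minimal supported clade containing exactly the two genes.  A supported
    clade whose gene content across the two loci exceeds two members turns
    into a single co-ortholog group call (and vetoes one-to-one for its
    members).  Phylogenetic evidence is optional; without it calls rest on
    RBH + synteny alone.
    """
    genes_a = list(genes_a)
    genes_b = list(genes_b)
    set_a, set_b = set(genes_a), set(genes_b)
    clades = [c for c in (phylo_clades or [])]

    def minimal_clade(members: set[str]) -> frozenset[str] | None:
        containing = [c for c in clades if members <= c]
        if not containing:
            return None
        return min(containing, key=lambda c: (len(c), sorted(c)))

    calls: list[OrthologyCall] = []
    claimed_a: set[str] = set()
    claimed_b: set[str] = set()

    # co-ortholog groups: minimal supported clades mixing the two loci with
    # more than two local members
    for clade in sorted(set(clades), key=lambda c: (len(c), sorted(c))):
        in_a = sorted(set_a & clade - claimed_a)
        in_b = sorted(set_b & clade - claimed_b)
        if not in_a or not in_b or len(in_a) + len(in_b) <= 2:
            continue
        sub = minimal_clade(set(in_a) | set(in_b))
        if sub is None or sub != clade:
            continue
        evidence = {"phylo_group"}
        if any((a, b) in set(rbh_pairs) for a in in_a for b in in_b):
            evidence.add("reciprocal_best")
        for a in in_a:
            calls.append(OrthologyCall(
                gene_a=a, gene_b=tuple(in_b), relation="co_ortholog_group",
                evidence=frozenset(evidence),
                note=f"supported clade of {len(in_a)}+{len(in_b)} genes"))
        claimed_a.update(in_a)
        claimed_b.update(in_b)

    rbh_by_a = {a: b for a, b in rbh_pairs}
    for a in genes_a:
        if a in claimed_a:
            continue
        b = rbh_by_a.get(a)
        if b is None or b in claimed_b:
            calls.append(OrthologyCall(gene_a=a, gene_b="", relation="none",
                                       evidence=frozenset(),
                                       note="no reciprocal best hit"))
            continue
        evidence = {"reciprocal_best"}
        mc = minimal_clade({a, b})
        if mc is not None and len(mc & (set_a | set_b)) > 2:
            # inside a larger supported clade: never one-to-one
            calls.append(OrthologyCall(
                gene_a=a, gene_b=(b,), relation="co_ortholog_group",
                evidence=frozenset({"reciprocal_best", "phylo_group"}),
                note="RBH inside a larger supported clade"))
            claimed_b.add(b)
            continue
        if synteny_scores.get((a, b), 0) >= synteny_threshold:
            evidence.add("synteny")
        if mc is not None and mc & (set_a | set_b) == {a, b}:
            evidence.add("phylo_group")
        if len(evidence) >= 2:
            calls.append(OrthologyCall(gene_a=a, gene_b=b, relation="one_to_one",
                                       evidence=frozenset(evidence)))
            claimed_b.add(b)
        else:
            calls.append(OrthologyCall(
                gene_a=a, gene_b="", relation="none", evidence=frozenset(),
                note="single evidence stream is not sufficient"))
    return calls


# ---------------------------------------------------------------------------
# Gene-order rearrangement

def detect_locus_rearrangement(order_a: Sequence[tuple[str, str]],
                               order_b: Sequence[tuple[str, str]],
                               flanks: tuple[str, str] = ("S100A9", "S100A11"),
                               ) -> RearrangementReport:
    """Decompose two gene orders into maximal common segments.

    Genes shared by both loci are walked in locus-A order; a segment
    extends while the corresponding genes are adjacent in locus B (in
    either direction).  A segment traversed right-to-left in B with
    flipped strands is ``inverted``.  Segments separated in B (by foreign
    genes or relocation) imply split events; inverted segments imply
    inversion events.
    """
    syms_a = [_norm(s) for s, _ in order_a]
    syms_b = [_norm(s) for s, _ in order_b]
    shared = set(syms_a) & set(syms_b)
    if not shared:
        raise ValueError("loci share no gene symbols")
    pos_b = {s: i for i, s in enumerate(syms_b)}
    strand_a = {_norm(s): st for s, st in order_a}
    strand_b = {_norm(s): st for s, st in order_b}
    walk = [s for s in syms_a if s in shared]

    segments: list[list[str]] = [[walk[0]]]
    directions: list[int] = [0]
    for prev, cur in zip(walk, walk[1:]):
        delta = pos_b[cur] - pos_b[prev]
        d = directions[-1]
        if delta in (1, -1) and (d == 0 or d == delta):
            segments[-1].append(cur)
            directions[-1] = delta
        else:
            segments.append([cur])
            directions.append(0)

    blocks: list[SyntenyBlock] = []
    flank_assignment: dict[str, int] = {}
    for i, (seg, d) in enumerate(zip(segments, directions)):
        if d == 0:
            # single-gene segment: orientation from relative strand
            inverted = strand_a[seg[0]] != strand_b[seg[0]]
        else:
            inverted = d == -1
        blocks.append(SyntenyBlock(
            pairs=[(s, s) for s in seg],
            orientation="inverted" if inverted else "same",
            flank_context=tuple(f for f in flanks if _norm(f) in seg)))
        for f in flanks:
            if _norm(f) in seg:
                flank_assignment[f] = i

    breakpoints_a = []
    breakpoints_b = []
    for s1, s2 in zip(segments, segments[1:]):
        breakpoints_a.append(syms_a.index(s2[0]))
        edge = s1[-1] if directions[segments.index(s1)] != -1 else s1[0]
        breakpoints_b.append(pos_b[edge] + 1)

    events: list[dict] = []
    for _ in range(len(segments) - 1):
        events.append({"type": "split"})
    for i, b in enumerate(blocks):
        if b.orientation == "inverted" and len(b.pairs) > 1:
            events.append({"type": "inversion", "segment": i})
    return RearrangementReport(segments=blocks, breakpoints_a=breakpoints_a,
                               breakpoints_b=breakpoints_b, events=events,
                               flank_assignment=flank_assignment)


def apply_segmentation(order_a: Sequence[tuple[str, str]],
                       report: RearrangementReport) -> list[list[str]]:
    """Reconstruct locus B's shared-gene segment structure from locus A
    plus the detected events (consistency check: re-applying the events
    reproduces B's segments)."""
    out = []
    for block in report.segments:
        seg = [a for a, _ in block.pairs]
        if block.orientation == "inverted" and len(seg) > 1:
            seg = list(reversed(seg))
        out.append(seg)
    return out


def place_events_on_tree(orders: Mapping[str, Sequence[tuple[str, str]]],
                         species_tree: dendropy.Tree | str,
                         reference: str,
                         flanks: tuple[str, str] = ("S100A9", "S100A11"),
                         ) -> list[dict]:
    """Infer rearrangement events and place them on species-tree edges.

    Each non-reference species is compared with the reference locus; an
    event type observed in a set of species is assigned, Dollo-style, to
    the edge above the smallest clade containing exactly those species.
    Returns events as ``{type, clade, species}`` dicts.
    """
    if isinstance(species_tree, str):
        species_tree = dendropy.Tree.get(data=species_tree, schema="newick")
    species_tree.is_rooted = True
    species_tree.update_bipartitions(suppress_unifurcations=False)
    ref_order = orders[reference]
    split_species: set[str] = set()
    inverted_species: set[str] = set()
    for sp, order in orders.items():
        if sp == reference:
            continue
        rep = detect_locus_rearrangement(ref_order, order, flanks)
        if len(rep.segments) > 1:
            split_species.add(sp)
        if any(b.orientation == "inverted" and len(b.pairs) > 1
               for b in rep.segments):
            inverted_species.add(sp)
    events = []
    for kind, species in (("split", split_species), ("inversion", inverted_species)):
        if not species:
            continue
        mrca = species_tree.mrca(taxon_labels=sorted(species))
        clade = tuple(sorted(lf.taxon.label for lf in mrca.leaf_iter()))
        events.append({"type": kind, "clade": clade,
                       "species": tuple(sorted(species))})
    return events
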