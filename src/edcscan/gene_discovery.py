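"""Translated homology search and exon-structured gene-model building.

The search is tBLASTn-shaped: protein queries are compared against all six
reading frames of a genomic region via k-mer seeds expanded to a scored
neighborhood, and seed clusters are resolved by optimal local alignment of
the query against a window of the frame translation (Smith-Waterman with
affine gaps, BLOSUM62, existence 11 / extension 1 by default).  No
low-complexity masking is ever applied: EDC proteins are low-complexity by
nature and masking would remove exactly the signal being searched for.

Gene models are then assembled around the best alignments using canonical
GT-AG splice-site rules and the conserved intron position carried by the
query (SFTP and S100A genes interrupt their coding sequence at a homologous
exon junction), classified into the four EDC gene classes by exon
architecture, and screened for pseudogenizing disruptions (premature stop
codons, frameshifts).  :func:`iterative_discovery` repeats the search with
newly found proteins as queries until a fixed point.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from edcscan.locus_io import Annotation, GenomicRegion

STOP = "*"
_CLASSES = ("SEDC", "SFTP", "S100A", "PGLYRP", "unknown")


# ---------------------------------------------------------------------------
# Parameters and data types

@dataclass(frozen=True)
class SearchParams:
    """Seeded-search parameters (tBLASTn-style defaults).

    ``gap_open`` is the gap-existence cost and ``gap_extend`` the per-residue
    cost, i.e. a gap of length L costs ``gap_open + L * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    seed_length: int = 3
    neighborhood_threshold: int = 11
    x_drop: int = 20
    min_score: int = 80
    gap_open: int = 11
    gap_extend: int = 1
    two_hit_window: int = 40  # 0 disables the two-hit seeding requirement
    min_cluster_seeds: int = 6  # non-overlapping seeds to open a window
    max_word_positions: int = 10  # drop seed words matching more query positions


@dataclass(frozen=True)
class ModelParams:
    """Gene-model construction parameters (all lengths in nucleotides)."""

    max_orf_extension: int = 2000
    splice_donor: str = "GT"
    splice_acceptor: str = "AG"
    upstream_scan_window: int = 200
    start_slack_codons: int = 15   # ATG search window around the homology-implied start
    splice_slack: int = 30         # donor search window around the implied junction
    min_intron: int = 40
    max_intron: int = 3000
    probe_length: int = 400        # residues used to validate acceptor candidates
    min_probe_score: int = 15      # minimum probe score to accept an intron
    min_hit_identity: float = 0.5  # model-building filter: hit identity
    min_query_coverage: float = 0.35  # model-building filter: query coverage


@dataclass(frozen=True)
class Query:
    """A protein query with optional class metadata.

    ``junctions`` are amino-acid positions of coding-exon boundaries in the
    query (one entry for the SFTP/S100A exon-2/3 junction); they drive the
    conserved-splice-site search during model building.
    """

    id: str
    sequence: str
    gene_class: str = "unknown"
    junctions: tuple[int, ...] = ()


@dataclass
class TranslatedHit:
    """A gapped local alignment of a protein query to one genomic frame."""

    query_id: str
    region: GenomicRegion          # genomic footprint, forward coordinates
    strand: str
    frame: int                     # 0/1/2 offset in the strand-oriented sequence
    score: float
    query_span: tuple[int, int]
    identity_fraction: float
    t_aa_span: tuple[int, int]     # aa coords within the frame translation
    n_aligned: int = 0


@dataclass
class GeneModel:
    """A located gene model: exons, class, protein, disruption flags.

    Exon coordinates are 0-based half-open on the forward strand of the
    searched region's sequence; coding exons are trimmed to the CDS (the
    stop codon included), and a modelled 5' non-coding exon, when present,
    has approximate coordinates (flag ``utr_exon_approximate``).
    """

    gene_id: str
    exons: list[tuple[int, int]]
    coding_flags: list[bool]
    strand: str
    gene_class: str
    protein: str
    pseudogene_flags: set[str] = field(default_factory=set)
    source_query: str = ""
    source_root: str = ""      # the original query at the root of the chain
    score: float = 0.0
    flags: set[str] = field(default_factory=set)
    region: GenomicRegion | None = None   # the searched region (sequence carrier)
    junctions: tuple[int, ...] = ()       # aa positions of coding-exon boundaries

    @property
    def coding_exons(self) -> list[tuple[int, int]]:
        return [e for e, c in zip(self.exons, self.coding_flags) if c]

    @property
    def cds_span(self) -> tuple[int, int]:
        ce = self.coding_exons
        return (ce[0][0], ce[-1][1])

    def to_annotation(self) -> Annotation:
        seqid = self.region.sequence_id if self.region else "."
        offset = self.region.start if self.region else 0
        exons = [(s + offset, e + offset) for s, e in self.exons]
        start, end = exons[0][0], exons[-1][1]
        return Annotation(
            gene_id=self.gene_id,
            region=GenomicRegion(seqid, start, end, self.strand),
            exons=exons,
            coding_flags=list(self.coding_flags),
            gene_symbol=self.gene_id,
            gene_class=self.gene_class,
            pseudogene_evidence=tuple(sorted(self.pseudogene_flags)),
        )


# ---------------------------------------------------------------------------
# Translation

def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())


def _translate_frame(dna: str, offset: int) -> str:
    sub = dna[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def six_frame_translate(dna: str) -> list[str]:
    """Translate all six reading frames (order +0,+1,+2,-0,-1,-2).

    Codons containing N translate to X; stops are rendered ``*``; minus
    frames read the reverse complement.
    """
    dna = dna.upper()
    rc = reverse_complement(dna)
    return [_translate_frame(dna, f) for f in range(3)] + \
           [_translate_frame(rc, f) for f in range(3)]


# ---------------------------------------------------------------------------
# Alignment kernel

@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _matrix_dict(name: str) -> dict[tuple[str, str], float]:
    """Plain-dict view of a substitution matrix (fast scalar lookups)."""
    mat = substitution_matrices.load(name)
    return {(a, b): float(mat[a, b])
            for a in mat.alphabet for b in mat.alphabet}


@lru_cache(maxsize=32)
def _aligner(matrix: str, gap_open: int, gap_extend: int, mode: str) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _matrix(matrix)
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


def local_align_score(query: str, target: str, params: SearchParams) -> float:
    """Optimal local alignment score only (no traceback; cheaper)."""
    if not query or not target:
        return 0.0
    al = _aligner(params.matrix, params.gap_open, params.gap_extend, "local")
    return float(al.score(query, target))


def local_align(query: str, target: str, params: SearchParams):
    """Optimal local alignment (affine gaps); returns (score, alignment) or None."""
    if not query or not target:
        return None
    al = _aligner(params.matrix, params.gap_open, params.gap_extend, "local")
    result = al.align(query, target)
    if result.score <= 0:
        return None
    return result.score, result[0]


def _alignment_stats(aln) -> tuple[tuple[int, int], tuple[int, int], int, int]:
    """(query_span, target_span, n_identical, n_aligned) from a local alignment."""
    qblocks, tblocks = aln.aligned
    qa, qb = int(qblocks[0][0]), int(qblocks[-1][1])
    ta, tb = int(tblocks[0][0]), int(tblocks[-1][1])
    ident = aligned = 0
    qs, ts = aln.sequences
    for (q0, q1), (t0, t1) in zip(qblocks, tblocks):
        for i in range(q1 - q0):
            aligned += 1
            if qs[q0 + i] == ts[t0 + i]:
                ident += 1
    return (qa, qb), (ta, tb), ident, aligned


# ---------------------------------------------------------------------------
# Seeding

@lru_cache(maxsize=None)
def _neighbors(word: str, matrix_name: str, threshold: int) -> tuple[str, ...]:
    """All words of the same length scoring >= threshold against ``word``."""
    mat = _matrix_dict(matrix_name)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    rows = []
    for ch in word:
        scores = sorted(((mat[ch, a], a) for a in alphabet), reverse=True)
        rows.append(scores)
    best_rest = [0.0] * (len(word) + 1)
    for i in range(len(word) - 1, -1, -1):
        best_rest[i] = best_rest[i + 1] + rows[i][0][0]
    out: list[str] = []

    def rec(i: int, acc: float, prefix: str):
        if i == len(word):
            out.append(prefix)
            return
        for s, a in rows[i]:
            if acc + s + best_rest[i + 1] < threshold:
                break
            rec(i + 1, acc + s, prefix + a)

    rec(0, 0.0, "")
    return tuple(out)


_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CODE = np.full(128, 20, dtype=np.int64)  # non-standard residues -> code 20
for _i, _a in enumerate(_ALPHABET):
    _CODE[ord(_a)] = _i


def _word_codes(prot: str, k: int) -> np.ndarray:
    """Base-21 integer codes of all k-mers; words touching a non-standard
    residue (X, *) get an out-of-range code and never seed."""
    c = _CODE[np.frombuffer(prot.encode("ascii"), dtype=np.uint8)]
    if len(c) < k:
        return np.empty(0, dtype=np.int64)
    w = np.zeros(len(c) - k + 1, dtype=np.int64)
    bad = np.zeros(len(c) - k + 1, dtype=bool)
    for off in range(k):
        w = w * 21 + c[off: len(c) - k + 1 + off]
        bad |= c[off: len(c) - k + 1 + off] == 20
    w[bad] = 21 ** k  # sentinel: excluded from every neighborhood
    return w


class SearchIndex:
    """Six-frame translations of a region plus per-frame k-mer code arrays.

    Built once per region and shared across queries and discovery rounds.
    """

    def __init__(self, region: GenomicRegion, k: int = 3):
        self.region = region
        self.k = k
        self.frames = six_frame_translate(region.sequence)
        self.codes = [_word_codes(prot, k) for prot in self.frames]

    def frame_info(self, fi: int) -> tuple[str, int]:
        """(strand, frame offset) for frame index 0..5."""
        return ("+", fi) if fi < 3 else ("-", fi - 3)


def _oriented_to_forward(a: int, b: int, strand: str, length: int) -> tuple[int, int]:
    if strand == "+":
        return a, b
    return length - b, length - a


def _word_code(word: str) -> int:
    code = 0
    for ch in word:
        code = code * 21 + int(_CODE[ord(ch)])
    return code


class _QuerySeedPlan:
    """Per-query seeding tables: a boolean neighborhood lookup over word
    codes and, per neighborhood word, the query positions it extends.

    Words whose neighborhood maps to more than ``max_word_positions`` query
    positions (ubiquitous words of quasi-repetitive queries) are dropped:
    they carry no positional information, and genuinely homologous regions
    still seed through their rarer word variants.
    """

    def __init__(self, query_seq: str, params: SearchParams):
        k = params.seed_length
        self.k = k
        sentinel = 21 ** k
        qn: dict[int, list[int]] = {}
        for i in range(len(query_seq) - k + 1):
            word = query_seq[i:i + k]
            if any(ch not in _ALPHABET for ch in word):
                continue
            for nw in _neighbors(word, params.matrix,
                                 params.neighborhood_threshold):
                qn.setdefault(_word_code(nw), []).append(i)
        lut = np.zeros(sentinel + 1, dtype=bool)
        kept = {}
        for code, positions in qn.items():
            if len(positions) <= params.max_word_positions:
                lut[code] = True
                kept[code] = np.asarray(positions, dtype=np.int64)
        self.lut = lut
        self.qn = kept


# above this many seed pairs for one word code, skip it: the pairing carries
# no positional information at that density
_DENSE_WORD_CAP = 50_000


def _candidate_windows(plan: _QuerySeedPlan, query_len: int,
                       index: SearchIndex, fi: int,
                       params: SearchParams) -> list[tuple[int, int]]:
    """Seed one frame against a query plan and return merged aa windows."""
    prot = index.frames[fi]
    k = params.seed_length
    if len(prot) < k or query_len < k:
        return []
    min_word_score = k * min(
        _matrix(params.matrix)[a, b] for a in _ALPHABET for b in _ALPHABET)
    if params.neighborhood_threshold <= min_word_score:
        return [(0, len(prot))]  # every word is in every neighborhood
    W = index.codes[fi]
    if W.size == 0:
        return []
    cand = np.flatnonzero(plan.lut[W])
    if cand.size == 0:
        return []
    if params.two_hit_window:
        # verify two non-overlapping seeds on a shared diagonal
        Wc = W[cand]
        order = np.argsort(Wc, kind="stable")
        cand_sorted = cand[order]
        Wc_sorted = Wc[order]
        boundaries = np.flatnonzero(np.diff(Wc_sorted)) + 1
        diag_parts, tpos_parts = [], []
        for grp in np.split(np.arange(cand_sorted.size), boundaries):
            code = int(Wc_sorted[grp[0]])
            P = cand_sorted[grp]
            Q = plan.qn.get(code)
            if Q is None:
                continue
            if P.size * Q.size > _DENSE_WORD_CAP:
                continue
            diag_parts.append((P[:, None] - Q[None, :]).ravel())
            tpos_parts.append(np.repeat(P, Q.size))
        kept = []
        if diag_parts:
            diag_a = np.concatenate(diag_parts)
            tpos_a = np.concatenate(tpos_parts)
            order = np.lexsort((tpos_a, diag_a))
            tpos_a, diag_a = tpos_a[order], diag_a[order]
            # the two hits must not overlap: overlapping word matches are
            # correlated (they share k-1 residues) and carry no new evidence.
            # Runs of consecutive seeds make non-overlapping partners
            # non-adjacent in the sorted order, so compare at lags 1..k.
            for lag in range(1, k + 1):
                same = diag_a[lag:] == diag_a[:-lag]
                dt = tpos_a[lag:] - tpos_a[:-lag]
                keep = same & (dt >= k) & (dt <= params.two_hit_window)
                if keep.any():
                    kept.append(tpos_a[lag:][keep])
                    kept.append(tpos_a[:-lag][keep])
        if not kept:
            return []
        cand = np.unique(np.concatenate(kept))
    if cand.size == 0:
        return []
    # cluster surviving seeds tightly and demand local support before
    # opening an alignment window: isolated chance seeds are discarded,
    # while homologous regions carry dense runs of seeds.  Only seeds that
    # do not overlap the previously counted one add support.
    clusters: list[tuple[int, int, int]] = []   # (start, end, n_nonoverlapping)
    w0 = prev = int(cand[0])
    last_counted = w0
    count = 1
    for t in cand[1:]:
        t = int(t)
        if t - prev > 40:
            clusters.append((w0, prev + k, count))
            w0, count = t, 1
            last_counted = t
        elif t - last_counted >= k:
            count += 1
            last_counted = t
        prev = t
    clusters.append((w0, prev + k, count))
    # short queries cannot produce many non-overlapping seeds; scale the
    # support requirement down so a perfect short match still opens a window
    support = min(params.min_cluster_seeds,
                  max(1, (query_len - k + 1) // (2 * k)))
    strong = [(s, e) for s, e, n in clusters if n >= support]
    if not strong:
        return []
    # merge neighbouring strong clusters into query-sized windows
    gap = max(query_len, 50)
    windows = [list(strong[0])]
    for s, e in strong[1:]:
        if s - windows[-1][1] <= gap:
            windows[-1][1] = e
        else:
            windows.append([s, e])
    return [(s, e) for s, e in windows]


def _hits_in_bounds(query: Query, index: SearchIndex, fi: int, a: int, b: int,
                    params: SearchParams, depth: int = 0,
                    precomputed=None) -> list[TranslatedHit]:
    """All local alignments >= min_score inside hard bounds [a, b)."""
    prot = index.frames[fi]
    if b - a < params.seed_length + 5:
        return []
    if precomputed is None:
        if local_align_score(query.sequence, prot[a:b], params) < params.min_score:
            return []
        precomputed = local_align(query.sequence, prot[a:b], params)
        if precomputed is None:
            return []
    score, aln = precomputed
    (qa, qb), (ta, tb), ident, aligned = _alignment_stats(aln)
    strand, f = index.frame_info(fi)
    aa0, aa1 = a + ta, a + tb
    o0, o1 = f + 3 * aa0, f + 3 * aa1
    L = len(index.region.sequence)
    fwd0, fwd1 = _oriented_to_forward(o0, o1, strand, L)
    hit = TranslatedHit(
        query_id=query.id,
        region=GenomicRegion(index.region.sequence_id,
                             index.region.start + fwd0, index.region.start + fwd1,
                             strand),
        strand=strand, frame=f, score=float(score),
        query_span=(qa, qb), identity_fraction=ident / aligned if aligned else 0.0,
        t_aa_span=(aa0, aa1), n_aligned=aligned,
    )
    hits = [hit]
    if depth < 12:
        hits += _hits_in_bounds(query, index, fi, a, aa0, params, depth + 1)
        hits += _hits_in_bounds(query, index, fi, aa1, b, params, depth + 1)
    return hits


def _window_hits(query: Query, index: SearchIndex, fi: int, w0: int, w1: int,
                 params: SearchParams) -> list[TranslatedHit]:
    """Pad a seed window, expand it while the optimum touches a boundary,
    then collect all qualifying alignments inside it."""
    prot = index.frames[fi]
    qlen = len(query.sequence)
    a = max(0, w0 - 50)
    b = min(len(prot), w1 + 50)
    sc = local_align_score(query.sequence, prot[a:b], params)
    if sc < params.min_score:
        # a tight window can truncate the optimum; retry once, widely padded
        a2, b2 = max(0, w0 - qlen - 30), min(len(prot), w1 + qlen + 30)
        if (a2, b2) != (a, b):
            a, b = a2, b2
            sc = local_align_score(query.sequence, prot[a:b], params)
        if sc < params.min_score:
            return []
    res = None
    pad = qlen + 30
    for _ in range(8):
        res = local_align(query.sequence, prot[a:b], params)
        if res is None:
            return []
        _, (ta, tb), _, _ = _alignment_stats(res[1])
        touches_left = a > 0 and ta == 0
        touches_right = b < len(prot) and tb == b - a
        if not (touches_left or touches_right):
            break
        if touches_left:
            a = max(0, a - pad)
        if touches_right:
            b = min(len(prot), b + pad)
        res = None
    if res is None:
        res = local_align(query.sequence, prot[a:b], params)
        if res is None:
            return []
    return _hits_in_bounds(query, index, fi, a, b, params, precomputed=res)


def _merge_overlapping(hits: list[TranslatedHit]) -> list[TranslatedHit]:
    """Keep the best-scoring hit among same-strand overlapping footprints."""
    hits = sorted(hits, key=lambda h: (-h.score, h.region.start, h.query_id, h.frame))
    kept: list[TranslatedHit] = []
    for h in hits:
        if any(k.strand == h.strand and
               k.region.start < h.region.end and h.region.start < k.region.end
               for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (-h.score, h.region.start, h.query_id))
    return kept


def seeded_search(query: Query | str, region: GenomicRegion,
                  params: SearchParams = SearchParams(),
                  index: SearchIndex | None = None) -> list[TranslatedHit]:
    """Search a protein query against all six frames of a genomic region.

    Returns maximal gapped local alignments of seed clusters scoring at
    least ``params.min_score``, with same-strand overlapping hits from the
    query merged to the best-scoring one, sorted by descending score.
    Low-complexity queries are searched like any other (no masking).
    """
    if isinstance(query, str):
        query = Query(id="query", sequence=query)
    if len(query.sequence) < params.seed_length:
        raise ValueError(
            f"query {query.id!r} shorter than seed length {params.seed_length}")
    if index is None:
        index = SearchIndex(region, k=params.seed_length)
    plan = _QuerySeedPlan(query.sequence, params)
    hits: list[TranslatedHit] = []
    for fi in range(6):
        for w0, w1 in _candidate_windows(plan, len(query.sequence), index,
                                         fi, params):
            hits.extend(_window_hits(query, index, fi, w0, w1, params))
    return _merge_overlapping(hits)


# ---------------------------------------------------------------------------
# Gene-model construction

def _oriented(region: GenomicRegion, strand: str) -> str:
    return region.sequence if strand == "+" else reverse_complement(region.sequence)


def _find_start(ori: str, frame: int, expected_aa: int, anchor_aa: int,
                mp: ModelParams) -> int | None:
    """In-frame ATG nearest the homology-implied start (aa index), or None."""
    lo = max(0, expected_aa - mp.max_orf_extension // 3)
    hi = min((len(ori) - frame) // 3 - 1, max(anchor_aa, expected_aa + mp.start_slack_codons))
    best = None
    for a in range(lo, hi + 1):
        p = frame + 3 * a
        if ori[p:p + 3] == "ATG":
            if best is None or abs(a - expected_aa) < abs(best - expected_aa):
                best = a
    return best


def _find_stop(ori: str, frame: int, from_aa: int, limit_aa: int) -> int | None:
    """First in-frame stop codon at aa index >= from_aa, scanning to limit_aa."""
    n_aa = (len(ori) - frame) // 3
    for a in range(from_aa, min(limit_aa, n_aa)):
        if ori[frame + 3 * a: frame + 3 * a + 3] in ("TAA", "TAG", "TGA"):
            return a
    return None


def _nearest_motif(ori: str, motif: str, center: int, slack: int,
                   phase_anchor: int | None = None) -> int | None:
    """Position of ``motif`` nearest ``center`` within ``+-slack``.

    With a ``phase_anchor``, only positions congruent to the anchor modulo 3
    are considered (phase-0 splice sites).
    """
    for off in range(0, slack + 1):
        for pos in (center - off, center + off) if off else (center,):
            if pos < 0 or pos + len(motif) > len(ori):
                continue
            if phase_anchor is not None and (pos - phase_anchor) % 3:
                continue
            if ori[pos:pos + len(motif)] == motif:
                return pos
    return None


def _best_acceptor(ori: str, donor: int, query_seq: str, junction: int,
                   params: ModelParams, matrix_name: str = "BLOSUM62",
                   cap: int | None = None) -> int | None:
    """Choose the acceptor AG whose downstream translation best matches the
    query just after the conserved exon junction.

    Every AG in the allowed intron-length range is scored by an ungapped
    comparison of up to ``probe_length`` translated residues against
    ``query[junction:]``; a long probe keeps quasi-repetitive downstream
    exons from locking one repeat unit out of phase.  The best-scoring
    candidate wins, ties to the shortest intron.
    """
    mat = _matrix_dict(matrix_name)
    probe = query_seq[junction:junction + params.probe_length]
    if not probe:
        return None
    best_pos, best_score = None, -1e9
    lo = donor + params.min_intron - 2
    hi = min(len(ori) - 2, donor + params.max_intron)
    if cap is not None:
        hi = min(hi, cap)
    for a in range(lo, hi):
        if ori[a:a + 2] != params.splice_acceptor:
            continue
        start = a + 2
        trans = _translate_frame(ori[start:start + 3 * len(probe)], 0)
        score = 0.0
        for qa, ta in zip(probe, trans):
            score += mat.get((qa, ta), -1.0)
        if score > best_score:
            best_pos, best_score = a, score
    if best_pos is None or best_score < params.min_probe_score:
        return None
    return best_pos


def build_gene_model(hit: TranslatedHit, region: GenomicRegion, query: Query,
                     params: ModelParams = ModelParams(),
                     sibling_hits: Sequence[TranslatedHit] = ()) -> GeneModel | None:
    """Assemble an exon-structured gene model around a translated hit.

    Single-coding-exon queries yield an ORF bounded by the nearest in-frame
    start codon upstream and stop codon downstream of the homologous span.
    Queries carrying coding-exon junctions (SFTP/S100A and PGLYRP metadata)
    trigger a search for GT..AG introns at the positions homologous to the
    query's own exon boundaries, anchored by sibling hits covering the
    downstream exons.  A 5' non-coding exon is modelled when an acceptor AG
    lies within ``upstream_scan_window`` of the start codon; models missing a
    start or stop are returned flagged ``incomplete``, never truncated
    silently.
    """
    strand = hit.strand
    junctions = sorted(j for j in query.junctions if 0 < j < len(query.sequence))
    # a hit anchored on a downstream coding exon cannot place the start codon;
    # switch to a same-strand sibling hit covering the first exon if one exists
    if junctions and hit.query_span[0] >= junctions[0] - 5:
        max_shift = ModelParams().max_intron * len(junctions) + 3 * len(query.sequence)
        for sh in sorted(sibling_hits, key=lambda s: -s.score):
            if (sh.strand == strand and sh.query_id == query.id
                    and sh.query_span[0] < junctions[0] - 5
                    and abs(sh.region.start - hit.region.start) <= max_shift):
                hit = sh
                break
    ori = _oriented(region, strand)
    L = len(ori)
    f = hit.frame
    qa, qb = hit.query_span
    ta, tb = hit.t_aa_span
    flags: set[str] = set()

    expected_start = ta - qa
    start_aa = _find_start(ori, f, expected_start, ta, params)
    if start_aa is None:
        flags.add("incomplete_no_start")
        start_aa = max(0, expected_start)
    atg = f + 3 * start_aa

    # --- coding exon boundaries in oriented coordinates
    coding_exons_ori: list[tuple[int, int]] = []
    cds_cursor = atg                      # genomic position of next codon
    codons_done = 0                       # aa already placed in previous exons
    model_junctions: list[int] = []
    ok = True
    for j in junctions:
        exon_len = 3 * (j - codons_done)
        donor_expect = cds_cursor + exon_len
        donor = _nearest_motif(ori, params.splice_donor, donor_expect,
                               params.splice_slack, phase_anchor=cds_cursor)
        if donor is None:
            flags.add("incomplete_missing_intron")
            ok = False
            break
        coding_exons_ori.append((cds_cursor, donor))
        codons_done += (donor - cds_cursor) // 3
        model_junctions.append(codons_done)
        # the gapped hit usually bridges the intron, so its end bounds the
        # gene: keep the acceptor search from jumping into a downstream
        # paralog's exon; fall back to the full intron range if capped
        # search fails (e.g. the hit covered only the upstream exon)
        hit_end_ori = hit.frame + 3 * tb
        acc = _best_acceptor(ori, donor, query.sequence, j, params,
                             cap=hit_end_ori + params.splice_slack)
        if acc is None:
            acc = _best_acceptor(ori, donor, query.sequence, j, params)
        if acc is None:
            flags.add("incomplete_missing_intron")
            ok = False
            break
        cds_cursor = acc + 2
    if not ok:
        junctions = junctions[:len(model_junctions)]

    # --- terminal coding exon: extend to the first in-frame stop
    frame_term = cds_cursor % 3
    from_aa = (cds_cursor - frame_term) // 3
    limit_aa = from_aa + 2 * (len(query.sequence) - codons_done) + \
        params.max_orf_extension // 3 + 10
    stop_aa = _find_stop(ori, frame_term, from_aa, limit_aa)
    if stop_aa is None:
        flags.add("incomplete_no_stop")
        stop_aa = min(limit_aa, (L - frame_term) // 3) - 1
        if stop_aa <= from_aa:
            return None
        end = frame_term + 3 * stop_aa
    else:
        end = frame_term + 3 * stop_aa + 3   # stop codon included in the CDS
    coding_exons_ori.append((cds_cursor, end))

    # --- spliced protein
    cds = "".join(ori[s:e] for s, e in coding_exons_ori)
    protein = _translate_frame(cds, 0)
    if protein.endswith(STOP):
        protein = protein[:-1]
    if len(protein) < 10:
        return None

    # --- 5' non-coding exon via upstream acceptor scan
    exons_ori = list(coding_exons_ori)
    coding = [True] * len(exons_ori)
    acc_pos = None
    scan_lo = max(0, atg - params.upstream_scan_window)
    for p in range(atg - 2, scan_lo - 1, -1):
        if ori[p:p + 2] == params.splice_acceptor:
            acc_pos = p
            break
    if acc_pos is not None and acc_pos > 152:
        # nominal 50 nt UTR exon upstream of a nominal 100 nt intron
        exons_ori = [(acc_pos - 150, acc_pos - 100)] + exons_ori
        coding = [False] + coding
        flags.add("utr_exon_approximate")
    else:
        flags.add("missing_utr_exon")

    # --- convert to forward coordinates
    exons_fwd = sorted(_oriented_to_forward(s, e, strand, L) for s, e in exons_ori)
    if strand == "-":
        coding = coding[::-1]
    model = GeneModel(
        gene_id=f"{query.id}.model",
        exons=[tuple(e) for e in exons_fwd],
        coding_flags=coding,
        strand=strand,
        gene_class="unknown",
        protein=protein,
        source_query=query.id,
        score=hit.score,
        flags=flags,
        region=region,
        junctions=tuple(model_junctions),
    )
    model.gene_class = classify_gene_type(model)
    return model


def classify_gene_type(model: GeneModel, sftp_min_cterm_len: int = 300) -> str:
    """EDC gene class from exon architecture and protein length.

    One coding exon -> SEDC.  Two coding exons -> SFTP when the segment
    after the S100 domain (the first coding exon) is at least
    ``sftp_min_cterm_len`` residues, else S100A.  Four or more coding
    exons -> PGLYRP.  Three -> unknown.
    """
    n = sum(model.coding_flags)
    if n < 1:
        raise ValueError("model has no coding exon")
    if n == 1:
        return "SEDC"
    if n == 2:
        s100_end = model.junctions[0] if model.junctions else min(
            len(model.protein), 100)
        return "SFTP" if len(model.protein) - s100_end >= sftp_min_cterm_len else "S100A"
    if n >= 4:
        return "PGLYRP"
    return "unknown"


# ---------------------------------------------------------------------------
# Pseudogene detection

def _piece_alignment(ref_piece: str, dna: str, frame: int,
                     params: SearchParams) -> dict | None:
    """Best local alignment of a reference piece to one frame translation,
    with '*' positions mapped back to reference coordinates and the
    genomic footprint (nt coordinates in ``dna``) reported."""
    t = _translate_frame(dna, frame)
    res = local_align(ref_piece, t, params)
    if res is None:
        return None
    score, aln = res
    (ra, rb), (ta, tb), _i, _n = _alignment_stats(aln)
    stops = []
    for (q0, q1), (t0, t1) in zip(*aln.aligned):
        for i in range(q1 - q0):
            if t[t0 + i] == STOP:
                stops.append(q0 + i)
    return {"score": score, "ref_span": (ra, rb), "stops": stops,
            "dna_span": (frame + 3 * ta, frame + 3 * tb)}


def detect_pseudogene(model: GeneModel, reference_protein: str,
                      params: SearchParams = SearchParams(),
                      coverage_threshold: float = 0.9,
                      frameshift_margin: float = 30.0,
                      split_step: int = 10) -> set[str]:
    """Flag coding-sequence disruptions relative to an intact reference.

    ``frameshift``: splitting the reference at some breakpoint and aligning
    the two pieces in two different reading frames scores decisively better
    (by ``frameshift_margin``) than the best single-frame alignment — the
    signature of a CDS indel of length not divisible by three.  A plain
    coverage criterion is not reliable here: low-complexity coding sequence
    aligns passably in a wrong frame, so score, not coverage, decides.

    ``premature_stop``: an in-frame stop inside the aligned portion of the
    interpretation chosen above, before ``coverage_threshold`` of the
    reference length.  The scan window extends beyond the model's CDS in
    both directions so disruptions that truncated or displaced the model
    are still visible.
    """
    if not reference_protein:
        raise ValueError("reference protein is empty")
    if model.region is None:
        raise ValueError("model carries no source region")
    strand = model.strand
    ori = _oriented(model.region, strand)
    L = len(ori)
    ce_ori = sorted(_oriented_to_forward(s, e, strand, L)
                    for s, e in model.coding_exons)
    nref = len(reference_protein)
    ext = 3 * nref + 60
    if len(ce_ori) == 1:
        s, e = ce_ori[0]
        lo = max(0, s - ext)
        lo = s - 3 * ((s - lo) // 3)   # keep the model frame at phase 0
        dna = ori[lo:min(L, e + ext)]
    else:
        last_s, last_e = ce_ori[-1]
        dna = "".join(ori[s:e] for s, e in ce_ori[:-1]) + \
            ori[last_s:min(L, last_e + ext)]

    al = _aligner(params.matrix, params.gap_open, params.gap_extend, "local")
    frames = [_translate_frame(dna, f) for f in range(3)]
    single = [float(al.score(reference_protein, t)) if t else 0.0
              for t in frames]
    best_single = max(single)
    if best_single <= 0:
        return set()

    # two-piece interpretation: prefix in one frame, suffix in another.
    # Candidate splits are ranked by score; a candidate is only accepted
    # when its two piece alignments are adjacent in the DNA (within 60 nt):
    # without the adjacency requirement, repetitive sequence lets a piece
    # float to a distant repeat copy and fake a frame change.
    splits = list(range(30, nref - 29, split_step))
    candidates: list[tuple[float, int, int, int]] = []
    if splits:
        prefix = {(x, f): float(al.score(reference_protein[:x], frames[f]))
                  for x in splits for f in range(3) if frames[f]}
        suffix = {(x, f): float(al.score(reference_protein[x:], frames[f]))
                  for x in splits for f in range(3) if frames[f]}
        for x in splits:
            for f1 in range(3):
                for f2 in range(3):
                    if f1 == f2 or (x, f1) not in prefix or (x, f2) not in suffix:
                        continue
                    s = prefix[(x, f1)] + suffix[(x, f2)]
                    if s >= best_single + frameshift_margin:
                        candidates.append((s, x, f1, f2))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))

    flags: set[str] = set()
    segments: list[dict] = []
    for s, x, f1, f2 in candidates[:20]:
        seg1 = _piece_alignment(reference_protein[:x], dna, f1, params)
        seg2 = _piece_alignment(reference_protein[x:], dna, f2, params)
        if seg1 is None or seg2 is None:
            continue
        if abs(seg2["dna_span"][0] - seg1["dna_span"][1]) > 60:
            continue
        flags.add("frameshift")
        for seg, offset in ((seg1, 0), (seg2, x)):
            ra, rb = seg["ref_span"]
            segments.append({"ref_span": (ra + offset, rb + offset),
                             "stops": [p + offset for p in seg["stops"]]})
        break
    if not segments:
        f_best = int(np.argmax(single))
        seg = _piece_alignment(reference_protein, dna, f_best, params)
        if seg:
            segments.append(seg)

    for seg in segments:
        _ra, rb = seg["ref_span"]
        for rpos in seg["stops"]:
            if rpos < coverage_threshold * nref and rpos + 5 < rb:
                flags.add("premature_stop")
    return flags


# ---------------------------------------------------------------------------
# Iterative discovery

def _models_overlap(a: GeneModel, b: GeneModel) -> bool:
    if a.strand != b.strand:
        return False
    (s1, e1), (s2, e2) = a.cds_span, b.cds_span
    return s1 < e2 and s2 < e1


def _resolve_overlaps(models: list[GeneModel]) -> list[GeneModel]:
    """Same-strand overlapping models: highest score wins, ties leftmost."""
    ordered = sorted(models,
                     key=lambda m: (-m.score, m.cds_span[0], m.source_query))
    kept: list[GeneModel] = []
    for m in ordered:
        if any(_models_overlap(m, k) for k in kept):
            continue
        kept.append(m)
    kept.sort(key=lambda m: (m.cds_span[0], m.strand))
    return kept


def iterative_discovery(query_set: Sequence[Query], region: GenomicRegion,
                        search_params: SearchParams = SearchParams(),
                        model_params: ModelParams = ModelParams(),
                        max_rounds: int = 4,
                        references: dict[str, str] | None = None,
                        ) -> list[GeneModel]:
    """Iterate seeded search -> model building with found proteins as queries.

    Each round adds newly discovered proteins (with their inferred class and
    junction metadata) to the query set and re-searches; iteration stops when
    a round adds no new non-overlapping model or ``max_rounds`` is reached.
    Output models are deduplicated by genomic footprint, renamed ``g001..``
    and sorted by coordinate; pseudogene flags are annotated against each
    model's source query (or ``references`` when given).
    """
    if not query_set:
        raise ValueError("query set is empty")
    index = SearchIndex(region, k=search_params.seed_length)
    queries = list(query_set)
    seen_seqs = {q.sequence for q in queries}
    # intact reference for pseudogene screening, per query id: caller-supplied
    # reference, else the query's own sequence (initial queries are presumed
    # intact; proteins found in later rounds reference themselves)
    ref_by_qid = {q.id: (references or {}).get(q.id, q.sequence) for q in queries}
    root_by_qid = {q.id: q.id for q in queries}
    models: list[GeneModel] = []
    for _round in range(max_rounds):
        round_models: list[GeneModel] = []
        for q in queries:
            hits = seeded_search(q, region, search_params, index=index)
            used: list[TranslatedHit] = []
            for h in hits:
                # cross-composition matches between unrelated low-complexity
                # proteins align weakly over short spans; require homolog-like
                # identity and query coverage before building a model
                qa, qb = h.query_span
                if (h.identity_fraction < model_params.min_hit_identity or
                        (qb - qa) / len(q.sequence) < model_params.min_query_coverage):
                    continue
                if any(u.strand == h.strand and
                       u.region.start < h.region.end and h.region.start < u.region.end
                       for u in used):
                    continue
                m = build_gene_model(h, region, q, model_params, sibling_hits=hits)
                if m is None:
                    continue
                used.append(h)
                # mark the hit footprint plus downstream exons as consumed
                for s, e in m.coding_exons:
                    used.append(replace(
                        h, region=GenomicRegion(h.region.sequence_id,
                                                region.start + s, region.start + e,
                                                h.strand)))
                round_models.append(m)
        before = len(models)
        models = _resolve_overlaps(models + round_models)
        new_count = len(models) - before
        queries = []
        for m in models:
            if m.protein not in seen_seqs:
                seen_seqs.add(m.protein)
                qid = f"found.{m.source_query}.{m.cds_span[0]}"
                queries.append(Query(
                    id=qid,
                    sequence=m.protein,
                    gene_class=m.gene_class,
                    junctions=m.junctions,
                ))
                # chain back to the original (intact) query's reference: a
                # found protein may itself be disrupted or junk-extended
                ref_by_qid[qid] = ref_by_qid.get(m.source_query, m.protein)
                root_by_qid[qid] = root_by_qid.get(m.source_query,
                                                   m.source_query)
        if new_count == 0 or not queries:
            break
    models = _resolve_overlaps(models)
    for i, m in enumerate(models, 1):
        m.gene_id = f"g{i:03d}"
        m.source_root = root_by_qid.get(m.source_query, m.source_query)
        ref = ref_by_qid.get(m.source_query, "")
        if ref:
            m.pseudogene_flags = detect_pseudogene(m, ref, search_params)
    return models


# ---------------------------------------------------------------------------
# Query FASTA metadata

_META_RE = re.compile(r"(\w+)=([\w.,-]+)")


def queries_from_fasta_records(records: Iterable[tuple[str, str]],
                               descriptions: dict[str, str] | None = None
                               ) -> list[Query]:
    """Build queries from (id, seq) pairs; descriptions may carry metadata
    tokens like ``class=SFTP junction=93``."""
    descriptions = descriptions or {}
    out = []
    for name, seq in records:
        meta = dict(_META_RE.findall(descriptions.get(name, "")))
        juncs = tuple(int(x) for x in meta.get("junction", "").split(",") if x)
        out.append(Query(id=name, sequence=seq,
                         gene_class=meta.get("class", "unknown"),
                         junctions=juncs))
    return out
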