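"""S100-domain phylogenetics: alignment, distance trees, bootstrap, rooting.

The N-terminal S100 domain is the only globular, alignable part of SFTP
proteins, so phylogenetic grouping evidence comes from a multiple alignment
of the domains, a neighbor-joining tree on p- or Poisson-corrected
distances, nonparametric bootstrap supports, and rooting with an S100A11
outgroup.  Supported clades ("phylo groups") feed the orthology caller.

Trees are dendropy :class:`~dendropy.Tree` objects throughout; Newick
serialization carries branch lengths and bootstrap supports as internal
node labels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np
from edcscan.gene_discovery import _aligner, _matrix


@dataclass
class MultipleAlignment:
    """Rows of equal-length gapped sequences."""

    rows: list[tuple[str, str]]

    def __post_init__(self):
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.rows]

    def ungapped(self, row_id: str) -> str:
        seq = dict(self.rows)[row_id]
        return seq.replace("-", "")

    def column(self, j: int) -> str:
        return "".join(s[j] for _, s in self.rows)


# ---------------------------------------------------------------------------
# Pairwise and progressive alignment

def pairwise_align_global(a: str, b: str, matrix: str = "BLOSUM62",
                          gap_open: int = 11, gap_extend: int = 1,
                          ) -> tuple[str, str, float]:
    """Optimal global alignment under affine gaps (existence+extension).

    Returns the two gapped strings and the score; the traceback is
    deterministic (Biopython's first reported alignment).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    al = _aligner(matrix, gap_open, gap_extend, "global")
    res = al.align(a, b)
    aln = res[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb, float(res.score)


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - fractional common k-mer count (MUSCLE-style guide distance)."""
    if len(a) < k or len(b) < k:
        return 1.0
    ka: dict[str, int] = {}
    kb: dict[str, int] = {}
    for i in range(len(a) - k + 1):
        ka[a[i:i + k]] = ka.get(a[i:i + k], 0) + 1
    for i in range(len(b) - k + 1):
        kb[b[i:i + k]] = kb.get(b[i:i + k], 0) + 1
    common = sum(min(ka[w], kb[w]) for w in ka if w in kb)
    return 1.0 - common / (min(len(a), len(b)) - k + 1)


def _align_profiles(pa: list[str], pb: list[str], matrix: str,
                    gap: float = 8.0) -> list[str]:
    """Global DP over two profiles (lists of equal-length gapped rows).

    Column score is the average substitution score over residue pairs; a
    linear gap cost keeps the profile recursion simple.
    """
    mat = _matrix(matrix)
    na, nb = len(pa[0]), len(pb[0])

    def colscore(i: int, j: int) -> float:
        total = n = 0
        for ra in pa:
            ca = ra[i]
            if ca == "-":
                continue
            for rb in pb:
                cb = rb[j]
                if cb == "-":
                    continue
                total += mat[ca, cb]
                n += 1
        return total / n if n else 0.0

    D = np.zeros((na + 1, nb + 1))
    D[:, 0] = -gap * np.arange(na + 1)
    D[0, :] = -gap * np.arange(nb + 1)
    back = np.zeros((na + 1, nb + 1), dtype=np.int8)
    back[1:, 0] = 1
    back[0, 1:] = 2
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            m = D[i - 1, j - 1] + colscore(i - 1, j - 1)
            up = D[i - 1, j] - gap
            left = D[i, j - 1] - gap
            # tie-break: match > insert(up) > delete(left)
            if m >= up and m >= left:
                D[i, j], back[i, j] = m, 0
            elif up >= left:
                D[i, j], back[i, j] = up, 1
            else:
                D[i, j], back[i, j] = left, 2
    # traceback
    outa = [[] for _ in pa]
    outb = [[] for _ in pb]
    i, j = na, nb
    while i > 0 or j > 0:
        step = back[i, j]
        if step == 0:
            for r, row in enumerate(pa):
                outa[r].append(row[i - 1])
            for r, row in enumerate(pb):
                outb[r].append(row[j - 1])
            i, j = i - 1, j - 1
        elif step == 1:
            for r, row in enumerate(pa):
                outa[r].append(row[i - 1])
            for r in range(len(pb)):
                outb[r].append("-")
            i -= 1
        else:
            for r in range(len(pa)):
                outa[r].append("-")
            for r, row in enumerate(pb):
                outb[r].append(row[j - 1])
            j -= 1
    return ["".join(reversed(r)) for r in outa] + ["".join(reversed(r)) for r in outb]


def sum_of_pairs_score(alignment: MultipleAlignment, matrix: str = "BLOSUM62",
                       gap_penalty: float = 8.0) -> float:
    """Sum-of-pairs score: substitution scores over residue pairs minus a
    linear penalty per residue-gap pair."""
    mat = _matrix(matrix)
    total = 0.0
    seqs = [s for _, s in alignment.rows]
    for x, y in itertools.combinations(seqs, 2):
        for cx, cy in zip(x, y):
            if cx == "-" and cy == "-":
                continue
            if cx == "-" or cy == "-":
                total -= gap_penalty
            else:
                total += mat[cx, cy]
    return total


def _center_star(sequences: list[tuple[str, str]], matrix: str) -> MultipleAlignment:
    """Center-star alignment: align everything to the most central sequence."""
    n = len(sequences)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, s = pairwise_align_global(sequences[i][1], sequences[j][1], matrix)
            scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))
    order = [center] + [i for i in range(n) if i != center]
    rows = [list(sequences[center][1])]
    ids = [sequences[center][0]]
    for i in order[1:]:
        ga, gb, _ = pairwise_align_global("".join(rows[0]).replace("-", ""),
                                          sequences[i][1], matrix)
        # thread the new pairwise alignment through the growing profile
        merged_rows = _merge_into_profile(rows, ga, gb)
        rows = merged_rows
        ids.append(sequences[i][0])
    return MultipleAlignment(rows=list(zip(ids, ["".join(r) for r in rows])))


def _merge_into_profile(rows: list[list[str]], center_gapped: str,
                        new_gapped: str) -> list[list[str]]:
    """'Once a gap, always a gap' merge of a new row into a profile whose
    first row's ungapped sequence matches ``center_gapped``'s."""
    out = [[] for _ in range(len(rows) + 1)]
    pi = 0   # column index into the existing profile
    ci = 0   # index into center_gapped
    ncols = len(rows[0])
    while ci < len(center_gapped) or pi < ncols:
        profile_char = rows[0][pi] if pi < ncols else None
        if profile_char == "-":
            for r, row in enumerate(rows):
                out[r].append(row[pi])
            out[-1].append("-")
            pi += 1
            continue
        ca = center_gapped[ci] if ci < len(center_gapped) else None
        if ca == "-":
            for r in range(len(rows)):
                out[r].append("-")
            out[-1].append(new_gapped[ci])
            ci += 1
            continue
        # both consume a residue column
        for r, row in enumerate(rows):
            out[r].append(row[pi])
        out[-1].append(new_gapped[ci])
        pi += 1
        ci += 1
    return out


def progressive_align(sequences: Sequence[tuple[str, str]],
                      matrix: str = "BLOSUM62") -> MultipleAlignment:
    """Progressive multiple alignment with a k-mer-distance guide tree.

    Profiles are merged in guide-tree order (UPGMA over fractional common
    k-mers); the result is compared against a center-star alignment under
    the sum-of-pairs score and the better of the two is returned, so the
    output is never worse than the center-star baseline.  Deterministic for
    a given input order.
    """
    sequences = list(sequences)
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    n = len(sequences)
    # UPGMA guide tree over k-mer distances
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(sequences[i][1], sequences[j][1])
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    profiles: dict[int, list[str]] = {i: [sequences[i][1]] for i in range(n)}
    ids: dict[int, list[str]] = {i: [sequences[i][0]] for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        (i, j), _ = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        merged = _align_profiles(profiles[i], profiles[j], matrix)
        profiles[next_id] = merged
        ids[next_id] = ids[i] + ids[j]
        clusters[next_id] = clusters[i] + clusters[j]
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        size_i, size_j = len(clusters[i]), len(clusters[j])
        for k in list(clusters):
            if k in (i, j, next_id):
                continue
            dij = []
            for a in clusters[k]:
                for b in clusters[next_id]:
                    dij.append(d[min(a, b), max(a, b)])
            dist[(min(k, next_id), max(k, next_id))] = float(np.mean(dij))
        del clusters[i], clusters[j], profiles[i], profiles[j], ids[i], ids[j]
        next_id += 1
    root = next(iter(clusters))
    rows = list(zip(ids[root], profiles[root]))
    # restore input order
    pos = {name: k for k, (name, _) in enumerate(sequences)}
    rows.sort(key=lambda r: pos[r[0]])
    progressive = MultipleAlignment(rows=rows)
    star = _center_star(sequences, matrix)
    star.rows.sort(key=lambda r: pos[r[0]])
    if sum_of_pairs_score(star) > sum_of_pairs_score(progressive):
        return star
    return progressive


# ---------------------------------------------------------------------------
# Distances and neighbor joining

def distance_matrix(alignment: MultipleAlignment,
                    correction: str = "p") -> np.ndarray:
    """Pairwise distances from an alignment.

    ``p``: mismatches over comparable (both non-gap) columns;
    ``poisson``: -ln(1 - p).  Raises for p >= 1 under Poisson and for pairs
    with no comparable columns.
    """
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    seqs = [s for _, s in alignment.rows]
    n = len(seqs)
    if n < 2:
        raise ValueError("need >= 2 rows")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for ca, cb in zip(seqs[i], seqs[j]):
                if ca == "-" or cb == "-":
                    continue
                comparable += 1
                if ca != cb:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(f"rows {i} and {j} share no comparable columns")
            p = mismatch / comparable
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("p-distance >= 1: Poisson correction undefined")
                p = -math.log(1.0 - p)
            D[i, j] = D[j, i] = p
    return D


def neighbor_joining(matrix: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Neighbor joining on a symmetric distance matrix.

    Ties in the Q-criterion break to the smallest (i, j) index pair;
    negative branch lengths are clamped to zero (the original value is kept
    in each node's annotations).  Returns an unrooted dendropy tree.
    """
    D = np.asarray(matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("matrix is not symmetric")
    labels = list(labels)
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    active = list(range(n))
    D = D.copy()
    Dwork = {(i, j): D[i, j] for i in range(n) for j in range(n)}

    def dget(i, j):
        return Dwork[(min(i, j), max(i, j))] if i != j else 0.0

    next_idx = n
    while len(active) > 2:
        r = len(active)
        sums = {i: sum(dget(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dget(i, j) - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = dget(i, j)
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        for child, ln in ((nodes[i], li), (nodes[j], lj)):
            child.edge.length = max(0.0, ln)
            if ln < 0:
                child.annotations.add_new("raw_branch_length", float(ln))
            parent.add_child(child)
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            Dwork[(min(k, next_idx), max(k, next_idx))] = \
                0.5 * (dget(i, k) + dget(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1
    # join the last two nodes with a single edge
    i, j = active
    a, b = nodes[i], nodes[j]
    final = dget(i, j)
    if a.is_leaf() and not b.is_leaf():
        a, b = b, a
    b.edge.length = max(0.0, final)
    a.add_child(b)
    tree.seed_node = a
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


# ---------------------------------------------------------------------------
# Bootstrap, rooting, groups

def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of leaf labels (smaller side
    normalized by the full leaf set)."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = leaves - below
        if len(below) < 2 or len(other) < 2:
            continue
        out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
    return out


def nj_tree_from_alignment(alignment: MultipleAlignment,
                           correction: str = "p") -> dendropy.Tree:
    D = distance_matrix(alignment, correction)
    return neighbor_joining(D, alignment.ids)


def bootstrap_support(alignment: MultipleAlignment, n_replicates: int = 100,
                      seed: int = 0, correction: str = "p") -> dendropy.Tree:
    """Point-estimate NJ tree with nonparametric bootstrap supports.

    Columns are resampled with replacement ``n_replicates`` times; the
    support of each internal edge of the point tree is the fraction of
    replicate trees containing its bipartition, stored as the node label
    (and in ``annotations['support']``) on the child node of the edge.
    """
    if len(alignment.rows) < 4:
        raise ValueError("bootstrap needs >= 4 rows")
    point = nj_tree_from_alignment(alignment, correction)
    ncol = alignment.n_columns
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rows = [(name, "".join(seq[c] for c in cols))
                for name, seq in alignment.rows]
        try:
            rep_tree = nj_tree_from_alignment(MultipleAlignment(rows), correction)
        except ValueError:
            continue  # e.g. a replicate with no comparable columns for a pair
        for bp in _bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    leaves = frozenset(alignment.ids)
    for node in point.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = min(below, leaves - below, key=lambda s: (len(s), sorted(s)))
        if len(below) < 2 or len(leaves - below) < 2:
            continue
        support = counts.get(key, 0) / n_replicates
        node.label = f"{support:.2f}"
        node.annotations.add_new("support", float(support))
    return point


def _support_of(node) -> float | None:
    s = node.annotations.get_value("support")
    if s is None and node.label:
        try:
            s = float(node.label)
        except ValueError:
            s = None
    return s


def root_with_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root a tree at the midpoint of the outgroup's pendant edge.

    Bootstrap supports are properties of edges (bipartitions), not nodes, so
    they are re-attached by bipartition lookup after rerooting.
    """
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())

    def bipart_key(node) -> frozenset:
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        return min(below, leaves - below, key=lambda s: (len(s), sorted(s)))

    support_by_bipart: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        s = _support_of(node)
        if s is not None:
            support_by_bipart[bipart_key(node)] = s

    rooted = tree.clone(depth=1)
    node = None
    for lf in rooted.leaf_node_iter():
        if lf.taxon.label == outgroup_label:
            node = lf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup_label!r} not found")
    length = node.edge.length or 0.0
    rooted.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0,
                          update_bipartitions=True)
    rooted.is_rooted = True
    for n in rooted.preorder_node_iter():
        n.annotations.drop(name="support")
        if n.is_leaf() or n.parent_node is None:
            continue
        s = support_by_bipart.get(bipart_key(n))
        if s is not None:
            n.annotations.add_new("support", float(s))
            n.label = f"{s:.2f}"
        else:
            n.label = None
    return rooted


def phylo_groups(rooted_tree: dendropy.Tree,
                 support_threshold: float = 0.9) -> list[frozenset[str]]:
    """Maximal clades whose subtending edge support meets the threshold.

    Singletons (leaves) are always trivially supported groups and are
    included for leaves not covered by any supported clade.
    """
    groups: list[frozenset[str]] = []
    covered: set[str] = set()

    def walk(node) -> None:
        if node.is_leaf():
            return
        support = node.annotations.get_value("support")
        if support is None and node.label:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if (support is not None and support >= support_threshold
                and node.parent_node is not None):
            leafset = frozenset(lf.taxon.label for lf in node.leaf_iter())
            groups.append(leafset)
            covered.update(leafset)
            # maximal: do not descend further
            return
        for child in node.child_nodes():
            walk(child)

    for child in rooted_tree.seed_node.child_nodes():
        walk(child)
    for lf in rooted_tree.leaf_node_iter():
        if lf.taxon.label not in covered:
            groups.append(frozenset([lf.taxon.label]))
    return sorted(groups, key=lambda g: (len(g), sorted(g)))


def all_supported_clades(rooted_tree: dendropy.Tree,
                         support_threshold: float = 0.9) -> list[frozenset[str]]:
    """Every clade (not just maximal) with support >= threshold, plus
    singletons; used by the orthology caller to find minimal groups."""
    out: list[frozenset[str]] = []
    for node in rooted_tree.preorder_node_iter():
        if node.is_leaf():
            out.append(frozenset([node.taxon.label]))
            continue
        if node.parent_node is None:
            continue
        support = node.annotations.get_value("support")
        if support is None and node.label:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if support is not None and support >= support_threshold:
            out.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return sorted(set(out), key=lambda g: (len(g), sorted(g)))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
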