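"""Independent brute-force oracles used by the test suite.

These are deliberately simple quadratic / exhaustive implementations,
written without reference to the package's own algorithms, so that
agreement between the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

NEG = -1e18


def _mat_dict(name: str = "BLOSUM62") -> dict:
    mat = substitution_matrices.load(name)
    return {(a, b): float(mat[a, b]) for a in mat.alphabet for b in mat.alphabet}


def smith_waterman_score(a: str, b: str, matrix: str = "BLOSUM62",
                         gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal local alignment score, affine gaps (length-L gap costs
    open + L*extend).  Plain O(nm) Gotoh recursion."""
    mat = _mat_dict(matrix)
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            Ei[j] = max(Hi[j - 1] - first, Ei[j - 1] - gap_extend)
            Fi[j] = max(Hi1[j] - first, Fi1[j] - gap_extend)
            h = max(0.0, Hi1[j - 1] + mat[ai, b[j - 1]], Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best = h
    return best


def needleman_wunsch_score(a: str, b: str, matrix: str = "BLOSUM62",
                           gap_open: int = 11, gap_extend: int = 1) -> float:
    """Optimal global alignment score with affine, end-penalized gaps."""
    mat = _mat_dict(matrix)
    first = gap_open + gap_extend
    n, m = len(a), len(b)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = -(gap_open + j * gap_extend)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -(gap_open + i * gap_extend)
        H[i][0] = F[i][0]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            H[i][j] = max(H[i - 1][j - 1] + mat[a[i - 1], b[j - 1]],
                          E[i][j], F[i][j])
    return H[n][m]


# ---------------------------------------------------------------------------

def average_linkage_merges(vectors: np.ndarray) -> list[float]:
    """Average-linkage agglomeration heights by direct recomputation."""
    clusters = [[i] for i in range(len(vectors))]
    heights = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                ds = [np.linalg.norm(vectors[i] - vectors[j])
                      for i in clusters[x] for j in clusters[y]]
                d = float(np.mean(ds))
                if best is None or d < best[0]:
                    best = (d, x, y)
        d, x, y = best
        heights.append(d)
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)]
        clusters.append(merged)
    return heights


# ---------------------------------------------------------------------------
# Trees

def random_binary_tree(labels: list[str], rng: np.random.Generator,
                       blen_range=(0.1, 1.0)):
    """A random unrooted binary tree as nested tuples with branch lengths.

    Returns (adjacency dict node->list[(node, length)], leaf names).
    Internal nodes are negative integers.
    """
    nodes = list(labels)
    adj: dict = {lab: [] for lab in labels}
    next_internal = -1
    rng_labels = list(labels)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = next_internal
        next_internal -= 1
        adj[parent] = []
        for child in (a, b):
            ln = float(rng.uniform(*blen_range))
            adj[parent].append((child, ln))
            adj[child].append((parent, ln))
        nodes = [n for n in nodes if n not in (a, b)] + [parent]
    center = next_internal
    adj[center] = []
    for child in nodes:
        ln = float(rng.uniform(*blen_range))
        adj[center].append((child, ln))
        adj[child].append((center, ln))
    return adj, rng_labels


def path_distance_matrix(adj: dict, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path lengths by BFS over the adjacency."""
    n = len(labels)
    D = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, ln in adj[node]:
                if nb not in dist:
                    dist[nb] = dist[node] + ln
                    stack.append(nb)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]
    return D


def tree_bipartitions_from_adj(adj: dict, labels: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions (as smaller-side frozensets) of the tree."""
    leafset = frozenset(labels)
    out = set()
    seen_edges = set()
    for node, nbrs in adj.items():
        for nb, _ in nbrs:
            edge = frozenset((node, nb))
            if edge in seen_edges:
                continue
            seen_edges.add(edge)
            # leaves on nb's side of the edge
            side = set()
            stack = [nb]
            visited = {node, nb}
            while stack:
                cur = stack.pop()
                if not isinstance(cur, int) or cur >= 0:
                    side.add(cur)
                for nxt, _ in adj[cur]:
                    if nxt not in visited:
                        visited.add(nxt)
                        stack.append(nxt)
            if isinstance(nb, str):
                side.add(nb)
            side_f = frozenset(s for s in side if s in leafset)
            other = leafset - side_f
            if len(side_f) >= 2 and len(other) >= 2:
                out.add(min(side_f, other, key=lambda s: (len(s), sorted(s))))
    return out


def all_unrooted_topologies(labels: list[str]):
    """Enumerate all unrooted binary topologies by stepwise leaf addition.

    Yields adjacency dicts (unit branch lengths); 3 leaves -> 1 topology,
    6 leaves -> 105.
    """
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def edges_of(adj):
        seen = set()
        for node, nbrs in adj.items():
            for nb, _ in nbrs:
                e = tuple(sorted((node, nb), key=str))
                if e not in seen:
                    seen.add(e)
                    yield e

    base: dict = {-1: [(labels[0], 1.0), (labels[1], 1.0), (labels[2], 1.0)]}
    for lab in labels[:3]:
        base[lab] = [(-1, 1.0)]
    trees = [base]
    next_internal = -2
    for lab in labels[3:]:
        new_trees = []
        for adj in trees:
            for u, v in list(edges_of(adj)):
                new = {k: [x for x in vs] for k, vs in adj.items()}
                mid = next_internal
                new[u] = [(n, l) for n, l in new[u] if n != v] + [(mid, 1.0)]
                new[v] = [(n, l) for n, l in new[v] if n != u] + [(mid, 1.0)]
                new[mid] = [(u, 1.0), (v, 1.0), (lab, 1.0)]
                new[lab] = [(mid, 1.0)]
                new_trees.append(new)
        trees = new_trees
        next_internal -= 1
    return trees


def best_fit_topology(D: np.ndarray, labels: list[str]) -> set[frozenset]:
    """Exhaustive search: bipartitions of the topology whose least-squares
    additive fit to D is best (non-negative edge lengths)."""
    from scipy.optimize import nnls

    best = None
    for adj in all_unrooted_topologies(labels):
        edges = []
        seen = set()
        for node, nbrs in adj.items():
            for nb, _ in nbrs:
                e = tuple(sorted((node, nb), key=str))
                if e not in seen:
                    seen.add(e)
                    edges.append(e)
        eidx = {e: k for k, e in enumerate(edges)}
        rows, y = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                row = np.zeros(len(edges))
                # path between leaves i, j
                src, dst = labels[i], labels[j]
                parent = {src: None}
                stack = [src]
                while stack:
                    cur = stack.pop()
                    for nb, _ in adj[cur]:
                        if nb not in parent:
                            parent[nb] = cur
                            stack.append(nb)
                node = dst
                while parent[node] is not None:
                    e = tuple(sorted((node, parent[node]), key=str))
                    row[eidx[e]] = 1.0
                    node = parent[node]
                rows.append(row)
                y.append(D[i, j])
        A = np.vstack(rows)
        x, _ = nnls(A, np.asarray(y))
        resid = float(np.linalg.norm(A @ x - np.asarray(y)))
        if best is None or resid < best[0] - 1e-12:
            best = (resid, adj)
    return tree_bipartitions_from_adj(best[1], labels)


# ---------------------------------------------------------------------------

def brute_force_rbh(scores: np.ndarray, ids_a: list[str], ids_b: list[str]
                    ) -> list[tuple[str, str]]:
    """Exhaustive reciprocal-best enumeration with strict uniqueness."""
    pairs = []
    for i, ida in enumerate(ids_a):
        for j, idb in enumerate(ids_b):
            row, col = scores[i], scores[:, j]
            if (scores[i, j] > np.max(np.delete(row, j)) if len(row) > 1 else True) \
               and (scores[i, j] > np.max(np.delete(col, i)) if len(col) > 1 else True):
                pairs.append((ida, idb))
    return sorted(pairs)
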