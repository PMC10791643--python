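"""Amino-acid-composition analysis of low-complexity proteins.

Most SEDC proteins (and the C-terminal domains of SFTPs) are too repetitive
and compositionally biased for alignment-based phylogenetics, so they are
characterized by their amino-acid percentages and grouped by hierarchical
clustering of the resulting 20-dimensional vectors.  The module also slices
the post-S100-domain segment out of SFTPs and detects tandem quasi-repeats
by shifted self-comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA)}


@dataclass(frozen=True)
class CompositionVector:
    """Amino-acid percentages of one protein (or protein segment)."""

    protein_id: str
    percentages: tuple[float, ...]   # one per residue of AA, percent units
    length: int

    def __post_init__(self):
        if len(self.percentages) != 20:
            raise ValueError("composition vector must have 20 entries")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        total = sum(self.percentages)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {total}, not 100")
        if any(p < 0 for p in self.percentages):
            raise ValueError("negative percentage")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.percentages, dtype=float)

    def __getitem__(self, residue: str) -> float:
        return self.percentages[_AA_INDEX[residue]]


@dataclass
class Dendrogram:
    """Agglomerative clustering result over composition vectors."""

    linkage: np.ndarray              # scipy linkage matrix (n-1 x 4)
    labels: list[str]                # protein ids, input order
    metric: str = "euclidean"
    method: str = "average"

    @property
    def merges(self) -> list[tuple[int, int, float, int]]:
        return [(int(a), int(b), float(h), int(n)) for a, b, h, n in self.linkage]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels for a k-group cut."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def to_newick(self) -> str:
        """Newick text with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


@dataclass(frozen=True)
class RepeatReport:
    """A detected tandem quasi-repeat in a protein segment."""

    protein_id: str
    period: int
    repeat_span: tuple[int, int]
    mean_identity: float
    method: str = "shifted-self-identity"

    def __post_init__(self):
        if self.period < 2:
            raise ValueError("period must be >= 2")
        s, e = self.repeat_span
        if not 0 <= s < e:
            raise ValueError("invalid repeat span")


# ---------------------------------------------------------------------------

def aa_composition(protein: str, protein_id: str = "") -> CompositionVector:
    """Amino-acid percentages of a protein.

    ``X`` and ``*`` are excluded from both numerator and denominator.
    """
    counts = np.zeros(20)
    denom = 0
    for ch in protein.upper():
        if ch in ("X", STOP_CHAR):
            continue
        if ch not in _AA_INDEX:
            raise ValueError(f"unexpected residue {ch!r}")
        counts[_AA_INDEX[ch]] += 1
        denom += 1
    if denom == 0:
        raise ValueError("protein has no standard residues")
    pct = 100.0 * counts / denom
    # compensate float round-off so the invariant sum==100 holds exactly
    pct[np.argmax(pct)] += 100.0 - pct.sum()
    return CompositionVector(protein_id=protein_id, percentages=tuple(pct),
                             length=denom)


STOP_CHAR = "*"


def sftp_cterm_segment(protein: str, s100_end_position: int) -> str:
    """Residues of an SFTP strictly after its S100 domain.

    ``s100_end_position`` is the index just past the domain's last residue
    (so the segment is ``protein[s100_end_position:]``).
    """
    if not 0 < s100_end_position < len(protein):
        raise ValueError(
            f"S100 boundary {s100_end_position} outside protein of "
            f"length {len(protein)}")
    return protein[s100_end_position:]


def composition_table(vectors: Sequence[CompositionVector]) -> pd.DataFrame:
    """Vectors as a DataFrame (rows = proteins, 20 residue columns + length)."""
    data = {v.protein_id: list(v.percentages) + [v.length] for v in vectors}
    return pd.DataFrame.from_dict(data, orient="index",
                                  columns=list(AA) + ["length"])


def hierarchical_cluster(vectors: Sequence[CompositionVector],
                         metric: str = "euclidean",
                         method: str = "average") -> Dendrogram:
    """Agglomerative clustering of composition vectors.

    Input order does not affect the tree: vectors are sorted by protein id
    before linkage, which also makes tie-breaking deterministic.
    """
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    ordered = sorted(vectors, key=lambda v: v.protein_id)
    X = np.vstack([v.as_array() for v in ordered])
    Z = hierarchy.linkage(X, method=method, metric=metric)
    return Dendrogram(linkage=Z, labels=[v.protein_id for v in ordered],
                      metric=metric, method=method)


#: Default composition-group centroids, percent units: the four recurring
#: SEDC groups (GS-rich loricrin-like, QE-rich involucrin-like, GSCP-rich
#: LCE/KPRP-like, PCQ-rich SPRR-like).  Enriched residues carry the named
#: percentages; the remainder is spread uniformly.
def _centroid(enriched: dict[str, float]) -> tuple[float, ...]:
    rest = (100.0 - sum(enriched.values())) / (20 - len(enriched))
    return tuple(enriched.get(a, rest) for a in AA)


DEFAULT_GROUP_PROFILES: dict[str, tuple[float, ...]] = {
    "GS-rich (loricrin-like)": _centroid({"G": 35.0, "S": 30.0}),
    "QE-rich (involucrin-like)": _centroid({"Q": 30.0, "E": 26.0}),
    "GSCP-rich (LCE/KPRP-like)": _centroid({"G": 18.0, "S": 18.0,
                                            "C": 14.0, "P": 14.0}),
    "PCQ-rich (SPRR-like)": _centroid({"P": 22.0, "C": 16.0, "Q": 20.0}),
}


def assign_composition_group(vector: CompositionVector,
                             profiles: Mapping[str, Sequence[float]] | None = None,
                             ) -> tuple[str, float, bool]:
    """Nearest-centroid composition group for a protein.

    Returns ``(label, distance, tied)``; ties (equal distance within 1e-9)
    are broken lexicographically by label and reported via the flag.
    """
    profiles = profiles if profiles is not None else DEFAULT_GROUP_PROFILES
    x = vector.as_array()
    dists = sorted(
        (float(np.linalg.norm(x - np.asarray(p, dtype=float))), name)
        for name, p in profiles.items())
    (d0, name0), rest = dists[0], dists[1:]
    tied = bool(rest) and abs(rest[0][0] - d0) < 1e-9
    return name0, d0, tied


def detect_tandem_repeats(segment: str, protein_id: str = "",
                          min_period: int = 2, min_copies: int = 3,
                          min_identity: float = 0.8) -> list[RepeatReport]:
    """Detect tandem quasi-repeats by shifted self-comparison.

    For each candidate period *p*, the segment is compared against itself
    shifted by *p*; periods whose mean shifted identity reaches
    ``min_identity`` over at least ``min_copies`` copies are reported,
    shortest period first.
    """
    n = len(segment)
    if n < 2 * min_period:
        raise ValueError("segment shorter than twice the minimum period")
    reports = []
    max_period = n // min_copies
    for p in range(min_period, max_period + 1):
        overlap = n - p
        if overlap < p * (min_copies - 1):
            continue
        same = sum(1 for i in range(overlap) if segment[i] == segment[i + p])
        identity = same / overlap
        if identity >= min_identity:
            reports.append(RepeatReport(protein_id=protein_id, period=p,
                                        repeat_span=(0, n),
                                        mean_identity=identity))
    return reports
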