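"""Genomic regions, annotations and the standard-format I/O around them.

Coordinates are 0-based half-open internally; GFF3 emission converts to the
1-based inclusive convention of the format.  The central locus operation is
:func:`extract_core_region`, which cuts out the interval strictly between two
flanking marker genes (by default *S100A9* and *S100A11*, the conserved
flanks of the EDC core in amniote genomes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class Gff3FormatError(ValueError):
    """Raised for malformed or inconsistent GFF3 input."""


class LocusIncompleteError(ValueError):
    """A required flanking gene is missing from the annotation set."""

    def __init__(self, missing_symbol: str):
        self.missing_symbol = missing_symbol
        super().__init__(f"locus incomplete: flanking gene {missing_symbol!r} not found")


class LocusSplitSignal(Exception):
    """The two flanking genes lie on different sequences: the locus is split.

    Carries both flank annotations so downstream synteny / rearrangement
    analysis can consume the split (the marsupial EDC-A / EDC-B situation,
    where one segment retains S100A9 and the other S100A11).
    """

    def __init__(self, flank5: "Annotation", flank3: "Annotation"):
        self.flank5 = flank5
        self.flank3 = flank3
        super().__init__(
            "locus split: flanks on different sequences "
            f"({flank5.gene_symbol}@{flank5.region.sequence_id}, "
            f"{flank3.gene_symbol}@{flank3.region.sequence_id})"
        )


@dataclass(frozen=True)
class GenomicRegion:
    """A located, stranded stretch of genomic sequence.

    ``start``/``end`` are 0-based half-open on ``sequence_id``;
    ``sequence`` is the forward-strand DNA of the interval (may contain N).
    """

    sequence_id: str
    start: int
    end: int
    strand: str = "+"
    sequence: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != interval "
                f"length {self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Annotation:
    """A gene annotation: exon structure plus classification attributes.

    ``exons`` are (start, end) pairs in the same coordinate system as
    ``region`` (i.e. on ``region.sequence_id``), sorted, non-overlapping;
    ``coding_flags[i]`` says whether exon *i* contains coding sequence.
    """

    gene_id: str
    region: GenomicRegion
    exons: list[tuple[int, int]]
    coding_flags: list[bool]
    gene_symbol: str = ""
    gene_class: str = "unknown"
    pseudogene_evidence: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.exons) != len(self.coding_flags):
            raise ValueError("coding_flags length must match exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise Gff3FormatError(f"exon end {end} <= start {start}")
            if start < self.region.start or end > self.region.end:
                raise Gff3FormatError(
                    f"exon ({start}, {end}) outside gene bounds "
                    f"[{self.region.start}, {self.region.end})"
                )
            if prev_end is not None and start < prev_end:
                raise Gff3FormatError("exons overlap or are unsorted")
            prev_end = end

    @property
    def coding_exons(self) -> list[tuple[int, int]]:
        return [e for e, c in zip(self.exons, self.coding_flags) if c]


@dataclass(frozen=True)
class CoreRegion:
    """The interval strictly between the two flanking marker genes."""

    region: GenomicRegion
    flank5: Annotation
    flank3: Annotation
    reversed_order: bool = False  # flank3 precedes flank5 in coordinates


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, uppercased sequence) pairs.

    The record id is the first whitespace-delimited token of the header.
    Raises :class:`FastaFormatError` (naming the line) for an empty file or
    leading non-header content.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected '>' header, got {line.strip()!r}"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: line {lineno or 1}: empty FASTA file")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                descriptions: dict[str, str] | None = None) -> None:
    """Write (id, sequence) pairs as FASTA, with optional per-id descriptions."""
    descriptions = descriptions or {}
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def write_gff3(annotations: Sequence[Annotation], path: str | Path,
               source: str = "edcscan") -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive coordinates.

    Gene lines carry ``gene_class`` and, when applicable,
    ``pseudogene_evidence`` attributes.
    """
    lines = ["##gff-version 3"]
    for ann in annotations:
        seqid = ann.region.sequence_id
        strand = ann.region.strand
        attrs = [f"ID={ann.gene_id}"]
        if ann.gene_symbol:
            attrs.append(f"Name={ann.gene_symbol}")
        attrs.append(f"gene_class={ann.gene_class}")
        if ann.pseudogene_evidence:
            attrs.append("pseudogene_evidence=" + ",".join(sorted(ann.pseudogene_evidence)))
        lines.append("\t".join([
            seqid, source, "gene",
            str(ann.region.start + 1), str(ann.region.end), ".", strand, ".",
            ";".join(attrs),
        ]))
        mrna_id = f"{ann.gene_id}.t1"
        lines.append("\t".join([
            seqid, source, "mRNA",
            str(ann.region.start + 1), str(ann.region.end), ".", strand, ".",
            f"ID={mrna_id};Parent={ann.gene_id}",
        ]))
        for i, ((start, end), coding) in enumerate(zip(ann.exons, ann.coding_flags), 1):
            lines.append("\t".join([
                seqid, source, "exon", str(start + 1), str(end), ".", strand, ".",
                f"ID={mrna_id}.exon{i};Parent={mrna_id}",
            ]))
            if coding:
                lines.append("\t".join([
                    seqid, source, "CDS", str(start + 1), str(end), ".", strand, "0",
                    f"ID={mrna_id}.cds;Parent={mrna_id}",
                ]))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | Path) -> list[Annotation]:
    """Read the gene/mRNA/exon/CDS feature subset written by :func:`write_gff3`.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    A CDS outside its parent gene's bounds raises :class:`Gff3FormatError`.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise Gff3FormatError(f"{path}: line {lineno}: expected 9 columns")
            seqid, _source, ftype, start1, end1, _score, strand, _phase, attrs = cols
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError as exc:
                raise Gff3FormatError(f"{path}: line {lineno}: bad coordinates") from exc
            if end <= start:
                raise Gff3FormatError(f"{path}: line {lineno}: end < start")
            a = _parse_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID", f"gene{lineno}")
                genes[gid] = {
                    "seqid": seqid, "start": start, "end": end, "strand": strand,
                    "symbol": a.get("Name", ""),
                    "gene_class": a.get("gene_class", "unknown"),
                    "pseudogene_evidence": tuple(
                        x for x in a.get("pseudogene_evidence", "").split(",") if x),
                    "exons": [], "cds": [],
                }
            elif ftype == "mRNA":
                mrna_parent[a.get("ID", "")] = a.get("Parent", "")
            elif ftype in ("exon", "CDS"):
                parent = a.get("Parent", "")
                gid = mrna_parent.get(parent, parent)
                if gid not in genes:
                    raise Gff3FormatError(
                        f"{path}: line {lineno}: {ftype} with unknown parent {parent!r}")
                gene = genes[gid]
                if ftype == "CDS" and not (gene["start"] <= start and end <= gene["end"]):
                    raise Gff3FormatError(
                        f"{path}: line {lineno}: CDS outside parent gene bounds")
                gene["exons" if ftype == "exon" else "cds"].append((start, end))
    annotations = []
    for gid, g in genes.items():
        exons = sorted(g["exons"]) or [(g["start"], g["end"])]
        cds = sorted(g["cds"])
        coding = [any(cs < e and s < ce for cs, ce in cds) for s, e in exons]
        annotations.append(Annotation(
            gene_id=gid,
            region=GenomicRegion(g["seqid"], g["start"], g["end"], g["strand"]),
            exons=exons,
            coding_flags=coding,
            gene_symbol=g["symbol"],
            gene_class=g["gene_class"],
            pseudogene_evidence=g["pseudogene_evidence"],
        ))
    annotations.sort(key=lambda a: (a.region.sequence_id, a.region.start, a.gene_id))
    return annotations


# ---------------------------------------------------------------------------
# Core-region extraction

def extract_core_region(annotations: Sequence[Annotation],
                        flank5_symbol: str = "S100A9",
                        flank3_symbol: str = "S100A11",
                        sequence: str = "") -> CoreRegion:
    """Cut out the interval strictly between two flanking marker genes.

    Returns the region from the end of the upstream flank to the start of the
    downstream flank (in sequence coordinates), excluding both flanks, with
    ``reversed_order`` set when the 3' flank precedes the 5' flank.  Raises
    :class:`LocusIncompleteError` when a flank is absent and
    :class:`LocusSplitSignal` when the flanks lie on different sequences.
    ``sequence`` is the full sequence of the flanks' contig; when given, the
    returned region carries its slice.
    """
    def find(symbol: str) -> Annotation:
        matches = [a for a in annotations if a.gene_symbol.upper() == symbol.upper()]
        if not matches:
            raise LocusIncompleteError(symbol)
        if len(matches) > 1:
            raise ValueError(f"flanking symbol {symbol!r} present more than once")
        return matches[0]

    flank5 = find(flank5_symbol)
    flank3 = find(flank3_symbol)
    if flank5.region.sequence_id != flank3.region.sequence_id:
        raise LocusSplitSignal(flank5, flank3)
    upstream, downstream = sorted([flank5, flank3], key=lambda a: a.region.start)
    start, end = upstream.region.end, downstream.region.start
    if end <= start:
        raise ValueError("flanking genes overlap; no core interval between them")
    region = GenomicRegion(
        sequence_id=flank5.region.sequence_id,
        start=start, end=end, strand="+",
        sequence=sequence[start:end].upper() if sequence else "",
    )
    return CoreRegion(region=region, flank5=flank5, flank3=flank3,
                      reversed_order=flank3.region.start < flank5.region.start)
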