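# Methods

This note documents the models, algorithms and numerical choices behind
`edcscan`, what the bundled simulator does and does not emulate, and the
known limitations.

## Translated homology search

Queries are protein sequences; targets are the six reading-frame
translations of a genomic region (minus-strand frames read the reverse
complement; codons containing N translate to X; stops are `*` and never
seed).  Seeding follows the classic seed-and-extend design:

* **Words and neighborhoods.** All k-mers (default k=3) of the query are
  expanded to their scored neighborhood — every word scoring at least the
  neighborhood threshold T (default 11) against the query word under the
  substitution matrix (default BLOSUM62).  Setting T at or below the
  minimum possible word score makes every word a seed; the search then
  degenerates, by construction, to a full local alignment of the query
  against each frame, which is the regime used for oracle-equivalence
  testing.
* **Low complexity is never masked.** EDC proteins are compositionally
  biased by nature; masking would delete the signal of interest.  Instead,
  two statistical guards replace masking: words whose neighborhood maps to
  more than 10 distinct query positions are dropped from seeding (they
  carry no positional information in quasi-repetitive queries, and
  homologous regions still seed through rarer word variants), and a window
  of the target is only aligned when a cluster of seeds contains at least 6
  mutually non-overlapping seeds that satisfy a two-hit rule (two
  non-overlapping seeds on one diagonal within 40 residues).  Overlapping
  word matches share k−1 residues and are treated as one observation.  The
  support requirement scales down for queries too short to produce it.
* **Extension.** Each surviving seed window, padded and expanded while the
  optimum touches a window boundary, is resolved by optimal affine-gap
  Smith–Waterman (existence 11, extension 1; a gap of length L costs
  11 + L) using Biopython's C aligner; flanking subwindows are searched
  recursively so several genes in one window are all reported.  Hits below
  `min_score` (default 80, raw units) are dropped; same-strand overlapping
  hits of one query are merged to the best-scoring one.  Raw scores are
  reported; E-values are not computed, since database-size statistics are
  meaningless on a single locus.

## Gene models

Gene models are anchored on the best local alignment of the query:

* The start codon is the in-frame ATG nearest the homology-implied
  position (alignment target start minus three times the query offset);
  the CDS ends at the first in-frame stop, which is included in the coding
  exon.  Coding-exon coordinates are therefore CDS-trimmed; UTRs are not
  modelled (a 5' non-coding exon is added with approximate coordinates
  when an acceptor AG lies within 200 nt upstream of the ATG, and flagged
  as approximate).
* Queries carrying coding-exon junction metadata (`class=SFTP junction=93`)
  trigger a conserved-intron search: a phase-0 GT donor at the position
  homologous to the query's junction, and the acceptor AG whose downstream
  translation best matches the query past the junction.  Acceptor
  candidates are scored ungapped over up to 400 residues — a long probe is
  essential because quasi-repetitive C-terminal domains make short probes
  lock one repeat unit out of phase — and the search is capped at the end
  of the anchoring hit (which usually bridges the intron), preventing
  jumps into a downstream paralog; if the capped search fails, the full
  intron-length range (40–3000 nt) is retried.  This logic assumes
  conserved intron position and near-conserved splice-proximal residues,
  which holds for the gene classes modelled; intron-position shifts or
  splice-site turnover would defeat it.
* Classification is a pure function of structure: 1 coding exon → SEDC;
  2 coding exons → SFTP if the segment after the S100 domain is ≥ 300
  residues, else S100A; ≥ 4 → PGLYRP; 3 → unknown.  The 300-residue
  threshold separates the short tails of S100A proteins (tens of residues)
  from SFTP C-terminal domains (hundreds to thousands) with a wide margin
  on either side.
* Iterative discovery re-searches with newly found proteins as queries
  until a round adds no new non-overlapping model.  Models are only built
  from hits with ≥ 0.5 identity and ≥ 0.35 query coverage: unrelated
  low-complexity proteins of similar composition produce genuine but
  non-homolog-like alignments well below this identity, while homologs of
  interest sit well above it.  Overlap resolution keeps the highest score,
  ties broken by leftmost coordinate then query id, so the output is
  independent of discovery order.

## Pseudogene detection

Disruptions are assessed against an intact reference protein (the query
that found the gene, traced back through iterative rounds to the original
query set).  The scan window extends three reference lengths beyond the
model CDS so truncated models still expose the full gene.

* **Frameshift**: the reference is split at candidate breakpoints (every
  10 residues, at least 30 from either end) and the two pieces are aligned
  to two *different* frame translations; a frameshift is called when the
  best two-piece score beats the best single-frame score by ≥ 30 *and* the
  two piece alignments are adjacent in the DNA (within 60 nt) — without
  the adjacency requirement, a piece can float to a distant repeat copy on
  quasi-repetitive sequence and fake a frame change.  Score, not coverage,
  decides: low-complexity coding sequence aligns passably in a wrong
  frame, so coverage-based criteria both over- and under-call.
  Frameshifts within 30 residues of either end are undetectable by design,
  consistent with treating C-terminal length variation as non-disruptive.
* **Premature stop**: an in-frame stop inside the aligned span of the
  chosen interpretation, before 90% of the reference length.  The 90%
  cutoff avoids flagging natural C-terminal length variation, which is
  extensive in SFTPs.

## Composition analysis

Compositions are amino-acid percentages (X and `*` excluded from numerator
and denominator), so proteins of very different lengths are comparable.
Hierarchical clustering uses average linkage on Euclidean distances over
the 20-dimensional percentage vectors; both are configurable and recorded
in output metadata, and input order cannot affect the result because
vectors are sorted by protein id before linkage.  Nearest-centroid group
assignment uses four built-in centroids for the recurring SEDC groups
(GS-, QE-, GSCP- and PCQ-rich); ties are reported and broken
lexicographically.  Tandem repeats are found by shifted self-comparison:
period p is reported when mean identity between the segment and itself
shifted by p reaches the threshold over at least the required copy count
(defaults: period ≥ 2, ≥ 3 copies, identity ≥ 0.8); the method tag is
carried in every report.

## Phylogenetics

Only the folded N-terminal S100 domain of SFTP/S100A proteins is
alignable, so trees are built from a multiple alignment of domains.
The progressive aligner merges profiles in the order of a UPGMA guide tree
over fractional-common-k-mer distances, with a linear gap cost at the
profile level; it additionally computes a center-star alignment and
returns whichever scores better under sum-of-pairs, so the output is never
worse than the center-star baseline.  Distances are p-distances or their
Poisson correction −ln(1−p).  Neighbor joining breaks Q-criterion ties to
the smallest index pair and clamps negative branch lengths to zero
(raw values kept in node annotations).  Bootstrap supports come from
resampling alignment columns with replacement (default 100 replicates,
seeded); the support of an edge is the fraction of replicate trees
containing its bipartition.  Supports are properties of bipartitions, not
nodes, and are re-attached by bipartition lookup after outgroup rooting
(midpoint of the outgroup's pendant edge).  Distance/NJ inference is a
deliberate design choice for a self-contained desk-scale tool; the
downstream contract is supported-clade membership, which is also what the
orthology caller consumes (clades with support ≥ 0.9 by default).

## Orthology and rearrangements

No single evidence stream is sufficient.  One-to-one requires a reciprocal
best hit (strict uniqueness: ties produce no call and are logged) plus
either local synteny ≥ 2 shared oriented neighbors (window 3) or a
supported clade containing exactly the two genes.  A supported clade
containing more than two genes across the two loci turns into one
co-ortholog-group call and vetoes one-to-one for its members.  Phylogenetic
evidence is optional; without it, calls rest on RBH + synteny.

Gene-order comparison walks the shared genes in locus-A order and extends
a segment while the partners are adjacent in locus B in a consistent
direction; a right-to-left segment with flipped strands is inverted.
Breakpoints, per-segment orientation and flank assignment are reported,
and re-applying the detected events to locus A reproduces locus B's
segment structure.  Given gene orders for several species and a species
tree, each event type is placed Dollo-style on the edge above the smallest
clade containing all species that exhibit it.

## The simulator

The generator emulates the study system: a core region between S100A9 and
S100A11; 15–30 single-coding-exon genes drawn from four biased composition
profiles (GS 35/30, QE 30/26, GSCP 18/18/14/14, PCQ 22/16/20 percent on
their diagnostic residues — every pair of profiles differs by at least 15
points on some diagnostic residue); SFTP genes as a near-uniform 92-residue
domain plus a tandem-repeat C-terminal domain (unit 10, per-copy mutation
0.1); planted GT–AG introns at phase-0 junctions; uniform-random intergenic
DNA (mean 6.5 kb in the large locus scenario); species-level divergence by
substitutions drawn from the family profile at 60–80% identity to the
ancestral (query) protein; disruptions as a planted TAA at ~20% of the CDS
or a 1-nt deletion mid-CDS; tandem duplications diverging from copy 1; and
split/inversion events applied to the gene layout of all species below a
tree edge, with three non-EDC spacer genes inserted at a split.

Boundary codons (first/last three) and the four residues around the
SFTP/S100A junction are never mutated, so intact genes have unmutated
boundaries and conserved splice-proximal residues — the regime in which
CDS-exact recovery is a fair requirement and the conserved-splice-site
assumption holds.  What the simulator does *not* emulate: indel evolution,
codon-usage and GC bias, repeat elements in intergenic DNA, intron-length
and intron-position evolution, segmental duplications larger than one
gene, and assembly artifacts.  Passing on synthetic loci therefore
demonstrates the pipeline's logic under its stated assumptions, not
performance on raw assemblies, where masking decisions, fragmented contigs
and non-canonical gene structures add failure modes the tests do not
probe.

Every build self-checks: planted introns must be GT–AG, and translating
the truth CDS of every intact gene must reproduce the truth protein.
Same seed, byte-identical output.

## Problem sizes and reproducibility

The bundled scenarios are: `fig1_locus` (~190 kb, one species, 20 SEDC +
4 SFTP genes, 5 disrupted), `fig2_rearrangement` (four species, split on
the stem of a three-species clade and inversion on a nested two-species
clade) and `fig5_sftp_expansion` (two species, one SFTP family expanded to
three tandem copies in one lineage).  Oracle comparisons use 100 random
query/target pairs (≤ 200 aa) for search scores, 200 random additive
matrices (n ≤ 8) plus exhaustive topology search (n ≤ 6) for NJ, 20
seeded 6-taxon simulations at 200 sites for bootstrap sanity, and 50
random 20×20 matrices with engineered ties for RBH.  All stages and the
acceptance script are deterministic given a seed; run manifests record
inputs, parameters and seeds and omit timestamps so reruns are
byte-identical.

## Known limitations

* Splice-site dialect is canonical GT–AG only; minor spliceosome introns
  are not modelled.
* The acceptor search assumes a conserved, phase-0 intron position;
  intron sliding defeats exact boundary recovery.
* Pseudogene detection assumes substitution-only divergence between gene
  and reference; real indel-rich divergence would require gapped
  frame-aware alignment (e.g. a three-frame DP), which is not implemented.
* The 5' non-coding exon is placed heuristically from the nearest upstream
  acceptor and flagged approximate; transcript evidence would be needed
  for exact UTR structure.
* Composition clustering metric/linkage defaults (Euclidean/average) are a
  documented choice; published clustermaps of real data cannot be matched
  leaf-for-leaf and are not a target.
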