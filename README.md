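# edcscan

Comparative-genomics analysis of the **epidermal differentiation complex
(EDC)** — the gene cluster, flanked in its core by *S100A9* and *S100A11*,
that encodes cornified-envelope precursors and related epidermal proteins
(loricrin, involucrin, LCEs, SPRRs, the S100 fused-type proteins such as
filaggrin, hornerin and trichohyalin).  EDC genes are hard for standard
annotation pipelines: most encode low-complexity, compositionally biased,
internally repetitive proteins that default homology searches mask away and
that resist alignment-based phylogenetics.

`edcscan` is a reusable pipeline for the analysis strategy this niche
requires, aimed at researchers studying the evolution of skin appendage
genes in vertebrate genomes:

* **Gene discovery** — iterative translated homology search (tBLASTn-style
  seed-and-extend over all six reading frames, BLOSUM62, *no*
  low-complexity masking), exon-structured gene-model building with
  canonical GT–AG splice sites and conserved intron positions, and
  classification into the four EDC gene classes by exon architecture:
  SEDC (one coding exon), S100A and SFTP (two coding exons, split at the
  S100-domain junction), PGLYRP (≥4 coding exons).
* **Pseudogene flagging** — premature stop codons and frameshifts detected
  by frame-aware alignment of the genomic translation to an intact
  reference protein.
* **Composition clustering** — amino-acid percentage vectors (the only
  robust descriptor for low-complexity proteins), hierarchical clustering,
  nearest-centroid assignment to the classic SEDC composition groups
  (GS-rich/loricrin-like, QE-rich/involucrin-like, GSCP-rich, PCQ-rich),
  and tandem-repeat detection by shifted self-comparison.
* **S100-domain phylogenetics** — progressive alignment of the conserved
  N-terminal S100 domains, neighbor-joining on p/Poisson distances,
  nonparametric bootstrap (100 replicates by default), outgroup rooting
  with S100A11, and extraction of supported clades.
* **Orthology & synteny** — reciprocal best hits, oriented local-synteny
  scores, and evidence-combining orthology calls where no single criterion
  suffices: one-to-one requires RBH plus concordant synteny or phylogeny,
  and a supported clade mixing one gene of locus A with several of locus B
  yields a co-ortholog group (the FLG/FLG2/HRNR situation), never
  one-to-one.
* **Locus rearrangements** — decomposition of two gene orders into maximal
  common segments (allowing whole-segment reversal), breakpoints, flank
  assignment, and Dollo-style placement of split/inversion events on a
  species tree (the marsupial EDC-A/EDC-B reconstruction).
* **Synthetic loci** — a first-class simulator that generates EDC-like loci
  with full ground truth (planted genes, compositions, disruptions, tandem
  duplications, rearrangements on a species tree), so every stage is
  testable without downloading genome assemblies.

## Worked example

Run the whole pipeline on a bundled synthetic scenario — two species, one
SFTP family expanded to three tandem copies in one lineage:

```bash
edcscan full --scenario fig5_sftp_expansion --seed 123 --out run1
```

```
full: {'platypus': 6, 'opossum': 8} gene models; artifacts in run1
```

`run1/orthology_calls.tsv` then contains (abridged):

```
gene_a          gene_b                                  relation            evidence
platypus:g004   opossum:g004,opossum:g005,opossum:g006  co_ortholog_group   phylo_group+reciprocal_best
platypus:g001   opossum:g001                            one_to_one          reciprocal_best+synteny
platypus:g003   opossum:g003                            one_to_one          phylo_group+reciprocal_best+synteny
```

Reading: the three tandem copies of the expanded SFTP family in the second
lineage form a single co-ortholog group with the one copy in the first
lineage — supported by the S100-domain tree and reciprocal similarity, but
deliberately *not* resolved to a one-to-one pair — while every unduplicated
family is called one-to-one from reciprocal best hits plus shared local
synteny.  Each stage writes a `*.manifest.json` recording inputs,
parameters and seed; rerunning with the same seed reproduces every artifact
byte for byte.

Other stages can be run individually (`edcscan simulate`, `find-genes`,
`classify`, `compose`, `cluster`, `phylo`, `ortho`, `compare-loci`); every
command accepts `--config config.yaml` with keys mirroring its flags.

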