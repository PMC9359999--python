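# Methods

`metaminer` mechanizes a knowledge-driven protocol for annotating
secondary-metabolite biosynthesis genes in a de novo plant transcriptome.
The protocol rests on three checkpoints applied in sequence to homology
hits: presence of the functionally important residues (FIRs) published for
the enzyme, presence of required degenerate motifs, and phylogenetic
co-clustering with a curated "start point" sequence from a close relative.
Candidates that clear all three are ranked by tissue-level TPM abundance.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Knowledge base

A knowledge-base entry holds, per enzyme: one or more reference protein
sequences with a designated **anchor** (the closest-relative sequence whose
published residue numbering the FIRs use, and the taxon the co-clustering
test is anchored on); FIR specifications (1-based position on the anchor,
allowed residue set); degenerate motif patterns; and identity/coverage
thresholds for the homology search. Motif syntax supports single residues,
slash-alternations `(I/V)`, and `x` wildcards, so the β-glucosidase
catalytic-glutamate motifs are written `(I/V)TENG` and `TFNEP`.

FIR `allowed_residues` default to the single published residue (the
protocol checks exact residue presence); conservative-substitution sets are
an opt-in per entry. Positions are validated against the named reference at
load time.

The shipped example KB (`metaminer.examples.example_knowledgebase`) covers
nicotinate N-methyltransferase (NNMT; Asn21, Tyr120, His124, Thr264),
betaine aldehyde dehydrogenase (BADH; Glu260, Trp285, Cys294, Trp456),
choline monooxygenase (CHMO; Rieske 2Fe-2S and non-heme motifs),
sterol-3β-glucosyltransferase (PSBD and PSPG motifs) and β-glucosidase
((I/V)TENG, TFNEP). Its reference *sequences* are synthetic stand-ins:
seeded random proteins with the documented residues and motif windows
installed at the documented coordinates, plus two relatives per enzyme
derived from a common ancestral sequence (88% / 75% / 60% identity to the
ancestor, rule sites preserved) so the reference set has lineage structure.
Motif patterns whose sequences are not published (SAM-binding, PSBD,
Rieske, non-heme) are placeholders flagged in each entry's notes; the PSPG
pattern uses the conserved THCGWNS core. Real analyses should substitute
curated UniProt sequences and literature patterns; nothing in the pipeline
depends on the stand-ins.

## ORF extraction

All six reading frames are scanned. Per maximal stop-free codon run, one
maximal ORF is emitted and labelled `complete` (ATG…stop), `3'-partial`
(ATG, no stop before the transcript end), `5'-partial` (runs off the 5'
edge into a stop) or `internal` (runs off both ends); this guarantees no
reported ORF nests inside another in the same frame. Codons containing N
translate to X and do not split an ORF.

The default minimum length is **100 codons**. The source protocol states a
"100 bases" cut-off, which conflicts with the conventional 100-amino-acid
minimum of coding-region predictors on de novo assemblies; 100 bases (~33
codons) would flood downstream stages with spurious ORFs, so the
conventional unit is the default and the value is a CLI flag
(`--min-length`). No coding-potential scoring is applied — length and
completeness only, a deliberate simplification.

## Homology search

Each ORF is aligned locally (Smith–Waterman, affine gaps) against every
reference of every enzyme; per (enzyme, ORF) pair the best-scoring
reference is retained, and a hit is emitted iff identity ≥ `min_identity`
and reference coverage ≥ `min_coverage`. Defaults are **0.30 / 0.70**, the
explicit criterion the protocol applies (">70% query coverage and >30%
sequence identity"), generalized to all enzymes and overridable per entry.
Identity is counted over all alignment columns (gaps included), BLAST
style; coverage is the aligned span on the *reference*, since references
are the trusted queries. Filtering uses these two statistics rather than
E-values: at desk scale with a handful of curated start points, exhaustive
exact DP replaces heuristic seeding, and the identity/coverage pair is the
stated decision rule.

Scoring defaults to BLOSUM62 with gap open −11 / extend −1 (BLASTP
defaults); a gap run of length *k* costs `open + (k−1)·extend`. Alignments
are computed with Biopython's `PairwiseAligner`; the test suite checks the
scores against an independent explicit three-state affine recursion.
Co-optimal tracebacks are resolved by the aligner's deterministic first
traceback; scores, identity and coverage of reported hits do not depend on
this choice in practice, and output order is fully deterministic (sorted by
score, enzyme, ORF).

## FIR and motif validation

FIR positions are transferred from the anchor onto each candidate through
one optimal **global** alignment; the candidate residue in the FIR's column
must lie in the allowed set. A FIR opposite a gap is a hard fail — the
criterion is exact residue presence, with no ±1 positional tolerance.
Because candidate/reference pairs at these identity levels align without
gaps under affine penalties (two gaps cost ≥ 22, a worst mismatch 4), the
transfer is stable; the suite verifies that 500 mutants sparing the FIRs
all pass and 500 mutants hitting a FIR all fail.

Motifs must each occur at least once anywhere in the candidate (the
protocol states presence only, no position constraint). The scanner is a
compiled regular expression inside a lookahead (overlapping matches
reported); an all-windows brute-force scan is the test oracle.

A candidate with neither FIRs nor motifs passes this stage vacuously and is
flagged as requiring co-clustering, which then becomes its only gate.

## Phylogenetic co-clustering

Multiple alignments are computed with MAFFT (`--auto`); the two-sequence
case reduces to the package's own global aligner. Distances are
**Poisson-corrected** (−ln(1−p), p capped at 0.999 to keep bootstrap
replicates finite) by default, with plain p-distance by flag; the source
protocol does not state its distance model. Neighbor joining is implemented
in-package: the standard Q-criterion with ties broken on the
lexicographically smallest label pair, negative branch lengths clamped to
zero with the deficit moved to the sister branch (count recorded on the
tree). NJ is exact on additive matrices — verified on 100 random trees
(5–8 taxa, branch lengths U(0.01, 1)) with path lengths reproduced to
1e−9.

Bootstrap supports resample alignment columns with replacement; an internal
edge's support is the percentage of replicate trees containing the same
bipartition. Default 100 replicates for pipeline runs (desk scale); 1000 is
available to match the source protocol.

The decision rule: midpoint-root the tree, walk from the candidate tip
toward the root, stop at the first clade containing at least one reference
taxon, and call the candidate co-clustered iff that clade contains the
anchor (and, when `min_support` > 0, the clade's defining edge reaches that
support). Two numerical choices deserve note:

* **`min_support` defaults to 0** (topology-only gate). The innermost
  candidate/anchor edge of a within-family fan carries almost no bootstrap
  signal even for genuine orthologues — sister-to-anchor groupings inside a
  shallow radiation are near-ties by construction — and the source protocol
  states no support threshold (supports were displayed, co-clustering
  assessed topologically). Supports are still computed and written into
  every tree so users can gate on them explicitly.
* **Each candidate is decided on its own subtree.** The pipeline writes a
  joint per-enzyme tree over references plus all surviving candidates as
  the display artifact, but the verdict for each candidate is computed on
  the row subset {references + that candidate} of the joint alignment, with
  its own bootstrap. When several candidates are local derivatives of the
  same anchor (exactly the synthetic benchmark design, and common for
  splice isoforms in real assemblies), they form a polytomy around the
  anchor: after the homolog clades join, the remaining NJ Q-values tie and
  the star resolves by noise, which can interpose one candidate between the
  anchor and the references on the joint tree. On the per-candidate quartet
  the discriminating edge (anchor lineage vs. the rest) is positive and NJ
  is provably consistent.

Rooting uses standard midpoint rooting; for degenerate trees with no
midpoint (zero total length) the existing trifurcation is kept. The
whole-tree "clade" has no defining edge and fails any positive support
threshold.

## Expression

TPM per sample: `TPM_i = 1e6·(c_i/l_i)/Σ_j(c_j/l_j)` from raw counts and
effective lengths (read mapping and count estimation are upstream of the
input contract); all-zero samples give all-zero TPM, otherwise each sample
sums to 1e6 exactly (checked to 1e−6 relative). "Average TPM" is the
arithmetic mean over a tissue's replicates. Per-tissue top-N ranking (N=20
by default) breaks ties lexicographically by transcript id. Heatmap
matrices are `log2(mean TPM + pseudocount)` with pseudocount 1.0 (the
transform offset is not stated in the source protocol). Effective length
falls back to plain length when absent, with a logged warning.

## Synthetic transcriptome generator

The generator emulates the shape of the study's data — a transcriptome
containing true orthologues of the knowledge-base enzymes, near-miss
decoys, and background — with every truth recorded in a manifest:

* **Orthologues**: anchor mutants at target identities (defaults 0.5 / 0.7
  / 0.9) with the initiator Met, all FIR positions and all motif windows
  protected. Substitutions are drawn from a BLOSUM62-weighted proposal
  (`w ∝ 2^(s/2)`), exactly `round((1−t)·L)` of them, so realized identity
  is within rounding (±0.03 audited) of the target.
* **FIR decoys**: a 0.9-identity base mutant whose FIR positions are set to
  the most dissimilar residue outside the allowed set — guaranteed, not
  probabilistic, check failure.
* **Motif decoys**: a base mutant with every occurrence of one motif
  destroyed the same way.
* **Paralogs** (off by default): low-identity mutants with rule sites
  unprotected.
* **Background**: random proteins, length-matched (250–450 aa by default,
  200 of them in the benchmark design).

Proteins are back-translated with uniform synonymous codons (no codon-usage
model — nothing downstream reads codon bias), wrapped in random UTRs
(30–90 nt) with an in-frame stop immediately 5' of the ATG so the planted
complete ORF is exactly the planted protein, and strand-randomized.

Counts are negative-binomial with variance `μ + α·μ²` (α = 0.1 by
default; α < 1e−8 is the noise-free limit where counts equal rounded
means), mean proportional to true TPM × length scaled to a 500,000-read
library, two replicates per tissue over leaf/stem/root. Each tissue gets a
disjoint designated top-20 set boosted strictly above every baseline, so
ranking has a known answer; explicit per-transcript tissue folds (e.g. a
10× leaf-high transcript) can be added. All outputs are bit-exact
reproducible from (design, seed); the pipeline derives per-stage seeds via
`SeedSequence(seed, spawn_key=(stage, …))`.

### What the benchmark shows — and does not

Passing the recovery benchmark shows the pipeline's logic is sound: intact
orthologues down to 50% identity are accepted, single-residue FIR damage
and single-motif loss are always rejected, random background never survives
the coverage filter, and the whole run is deterministic. It does **not**
demonstrate performance on real assemblies: the generator plants
substitution-only mutants (no indels, no domain shuffling), background is
i.i.d. random rather than a real proteome with true paralog families, there
are no assembly artifacts (chimeras, fragmented ORFs), and reference
sequences are synthetic. Real paralogs at ~30–50% identity with conserved
catalytic residues are the hard case this benchmark cannot probe; the
co-clustering stage exists precisely for them.

## Degenerate inputs and failure behaviour

Empty knowledge base: the pipeline succeeds with a warning and an empty
report. Empty local alignment (all-negative scores): score 0, no hit. A
distance pair with zero shared columns is fatal, naming the pair; a
bootstrap replicate with such a pair supports no edge but still counts in
the denominator. Trees need ≥ 3 taxa; an enzyme with fewer leaves its
candidates' co-clustering `not_run`, in which case FIR/motif rules alone
decide (and rule-free candidates are rejected).

## Problem sizes

The shipped verification runs use: 100 additive matrices (5–8 taxa) for NJ;
200 random pairs ≤ 60 aa for the alignment oracles; 1,000 instances for the
motif oracle; 500 + 500 mutants for FIR transfer; 10 generator seeds × (5
enzymes × (3 orthologues + decoys) + 200 background ORFs, 100 bootstrap
replicates) for end-to-end recovery; and 3 tissues × 2 replicates ×
~120 transcripts for the expression checks.
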