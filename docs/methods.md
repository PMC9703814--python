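# Methods

This note documents the models and procedures the package implements, the
defaults it ships, and what its synthetic fixtures do and do not show.

## Eight-cysteine motif detection

A mature nsLTP peptide is modelled as
`X^n0 C X^g1 C X^g2 CC X^g4 C x C X^g6 C X^g7 C X^n8`: eight cysteines
whose third and fourth are adjacent (gap g3 = 0) and whose fifth and sixth
flank exactly one residue (g5 = 1, the CXC core, residue `x`). The scanner
enumerates *every* assignment of eight cysteine positions satisfying the
structural constraints and a per-gap bound set, by depth-first search over
the sorted cysteine positions with pruning (once a candidate gap exceeds
its upper bound, later cysteines only increase it, so the branch is cut).
All placements are reported; `best_match` picks the one closest to a known
subfamily pattern, breaking ties toward the N-terminal-most placement.

Default bounds are the element-wise union of the five subfamily patterns
(n0 ∈ [1,16], g1 ∈ [7,14], g2 ∈ [12,18], g4 ∈ [8,19], g6 ∈ [20,26],
g7 ∈ [6,13], n8 ∈ [0,19]); a `slack` parameter widens every bound
symmetrically to admit near-pattern variants. The scanner operates on the
given (mature) sequence; signal-peptide removal is the caller's
responsibility, and the leading spacer n0 is counted from position 0 of
whatever sequence is supplied.

## Spacing-grammar classification

Each subfamily type is an explicit set of admissible integers per variable
gap; ranges written `13-15` expand to contiguous sets, comma lists
(`2,3,8`) are exact. A match's score against a pattern is the sum over
gaps of the distance to the nearest admissible value; 0 means every gap
is admissible. By default only score-0 matches classify (`max_score = 0`);
ties between different types at the best score are left unclassified, as
are sequences whose best score exceeds the cap. Types III/VII/VIII/IX
occur in other species but have no built-in pattern here; they can be
loaded from a TSV grammar file. The CXC-core residue is classed
hydrophilic ({R,G,E,N,S,T,K}), hydrophobic ({L,I,F,V,M}) or other.

Phylogeny (below) is a cross-check of the grammar, not the classifier:
the grammar is the deterministic, reproducible rule.

## Pairwise alignment

Duplicate and ortholog detection use exact global Needleman–Wunsch
alignment (BLOSUM62, affine gap open 10 / extend 0.5) rather than a
heuristic seeded search: family members are short and homologous, and an
exact optimum is deterministic. Identity is the fraction of equal
residues among both-non-gap columns (columns containing the unknown
residue X always count as mismatches); coverage is the number of aligned
columns over the length of the longer input. The 80 % thresholds are
applied to protein sequences.

Codon alignments are obtained by back-threading each CDS through the
protein alignment: one codon pair per both-non-gap column, with pairs
containing N or a stop dropped and counted.

## Duplication calling

A pair is duplicated when identity and coverage both *strictly* exceed
80 %. Mode assignment uses chromosomal position only: **tandem** when the
genes share a chromosome and either their span gap is ≤ 100 kb or at most
5 annotated genes lie between them; **segmental** otherwise. Both tandem
parameters are configurable — "tightly linked" has no single community
definition, and these are the common conventions in gene-family surveys.
Within each connected component of tandem pairs, only genomically
consecutive neighbours are retained, so an array of k genes counts as
k − 1 duplication events. Segmental calls do not require synteny-block
evidence.

## NG86 Ka/Ks and dating

Synonymous sites per codon: at each position, the fraction of the three
single-base changes that preserve the amino acid, with changes to stop
codons removed from the denominator; nonsynonymous sites are the
complement (s + n = 3). Site totals are averaged over the two sequences.
Differences per codon pair: for k differing positions, all k! orders of
introducing the changes are enumerated; each single-base step is
classified synonymous/nonsynonymous, pathways passing through a stop are
excluded and the average renormalised over the remainder (if every
pathway hits a stop, the unnormalised average over all pathways is used
with a warning — a difference count is always produced). Proportions
ps = Sd/S and pn = Nd/N are Jukes–Cantor corrected,
`K = −(3/4)·ln(1 − (4/3)p)`, undefined at p ≥ 0.75 (saturation error).
The ratio Ka/Ks is flagged undefined when Ks = 0; purifying means
ratio < 1. Only the standard genetic code is wired in.

Divergence age: `t = Ks / (2r)`, reported in million years, with
`r = 6.5 × 10⁻⁹` substitutions per synonymous site per year by default
(a rate commonly adopted for grass nuclear genes). The age is exact
arithmetic in Ks and r.

NG86 is implemented from first principles because it is fully specified
by the counting rules above; maximum-likelihood codon models (GY94,
YN00) and gamma rate corrections are out of scope.

## Orthology

Reciprocal best hit on global alignment score, ties broken toward the
lexicographically smallest id, with an optional minimum-score floor.
Each gene appears in at most one pair. This is the minimal defensible
one-to-one orthology rule; synteny support and tree reconciliation are
not attempted.

## Neighbor joining

Distances are p-distances, `1 − identity/100`, from the same global
pairwise alignments (no multiple-sequence alignment is built). Joining
follows Saitou & Nei's Q-criterion; ties break on the smallest index
pair, making the topology deterministic. Branch lengths use the standard
two-point formulas; a negative length is clamped to zero with the
deficit moved to the sister branch, preserving the joined pair's
distance. On an exactly additive matrix the generating tree (topology
and branch lengths) is recovered exactly. Optional bootstrap support
resamples the aligned columns of each pairwise alignment. Subfamily
monophyly is tested on the tree after pruning unclassified leaves: a
type is monophyletic when its members form one side of some bipartition.

## Promoters

The promoter is the 2000 bp upstream of the annotated gene start:
`[start−2000, start−1]` for plus-strand genes, the reverse complement of
`[end+1, end+2000]` for minus-strand genes, truncated (never padded) at
chromosome ends. Elements are short IUPAC motifs counted with overlaps
on both strands; a palindromic motif counts once per position. The
shipped library (ABRE ACGTG/CACGTG, TGACG/CGTCA, MBS CAACTG, LTR CCGAAA,
WUN-motif AAATTTCCT) is a small documented set of canonical core motifs;
it makes no claim of equivalence to any external prediction database,
whose element inventories and match criteria are not public. Note that
TGACG and CGTCA are reverse complements: every physical site counts for
both names.

## Expression

FPKM matrices carry an explicit transform state (raw → log2(FPKM+1) →
median-collapsed) so a transform cannot be applied twice. Replicates
collapse to per-group medians. Clustering is average-linkage
agglomerative with 1 − Pearson correlation on genes by default
(Euclidean available); constant profiles are rejected by name under the
correlation metric. qPCR quantification: per replicate
ΔCt = Ct_target − Ct_reference (Actin-style internal control), per
condition ΔΔCt = mean ΔCt(condition) − mean ΔCt(control), fold =
2^−ΔΔCt; the control condition folds to exactly 1 by construction.

## Synthetic fixtures

The generators define the study conditions the tests and the acceptance
script run under:

- **Family** (default 14/9/6/5/8 members of Types I/II/IV/V/VI + decoys):
  spacing vectors drawn uniformly from each type's allowed sets, spacer
  residues from a per-type prototype backbone with a 10 % per-residue
  substitution rate (so types show within-type similarity), CXC-core
  residues hydrophilic for Type I and Leu-weighted hydrophobic otherwise,
  decoys with < 8 cysteines. Optional ±1 spacing noise.
- **Codon pairs**: a random stop-free ancestral CDS receives Poisson
  numbers of synonymous and nonsynonymous single-base edits (expected
  counts ps·S and pn·N from the Jukes–Cantor inverses of the target Ka,
  Ks), at most one edit per codon and never creating a stop — so NG86
  classifies every planted difference exactly, synonymous-only specs give
  Ka = 0 identically, and E[recovered Ks] equals the target.
- **Genome layouts**: tandem arrays placed consecutively below the
  tandem threshold, segmental partners on distinct chromosomes, both
  derived from shared ancestors at Ks = 0.2 / Ka = 0.02 over 200 codons
  (≈ 95 % protein identity), plus mutually unrelated filler genes.
- **Promoters**: windows scrubbed of accidental library hits, then exact
  motif copies planted at non-overlapping random positions and strands,
  re-verified against the whole library.
- **Expression**: lognormal FPKM around tissue-block means (Types IV/V
  high in root/stem, VI in panicle, I in stem/leaf) over 7 tissues × 3
  replicates; qPCR Ct tables are back-computed from known folds with
  Gaussian replicate noise.

These fixtures share the *statistical structure* each stage assumes, not
the composition of real genomes: base/codon usage is uniform, chromosome
sizes are arbitrary, and noise models are minimal. Passing tests
therefore demonstrate algorithmic correctness and recovery under the
stated conditions, not performance on real annotation artifacts
(fragmented gene models, alternative isoforms, repetitive DNA).

## Numerical and design choices

- Coordinates are 1-based inclusive throughout (GFF3 convention);
  half-open arithmetic is internal.
- Terminal stop codons are trimmed before CDS/protein checks; internal
  stops are errors.
- Intron phase is cumulative upstream CDS length mod 3, computed in
  transcription order (minus-strand exons descend by coordinate).
- Classification, clustering and NJ all fix their tie-breaking rules, so
  every output is deterministic for identical input.
- The per-gene transcript choice on real inputs is the first (primary)
  model; alternative-transcript selection is out of scope.
- Problem sizes in the shipped tests and acceptance run (10 000-codon
  neutral simulations, 50-seed purifying panels, 200 scanner fixtures,
  50 random additive trees, 30 promoter fixtures) were chosen to make
  sampling error negligible relative to the asserted tolerances while
  keeping a full run fast on one CPU.

## Known limitations

- Table-driven spacing grammars must be supplied for subfamily types not
  built in (III, VII–IX).
- The NG86 estimator can differ from ML codon models on real diverged
  pairs; printed Ka/Ks values produced by other estimators are treated
  as inputs to the ratio/dating arithmetic, not as end-to-end targets.
- BLAST-style heuristic search is not implemented; all-vs-all exact
  alignment is quadratic and intended for family-sized inputs (tens to
  hundreds of sequences), not whole proteomes.
- The promoter element library is deliberately small; genome-scale
  regulatory annotation needs a curated database.
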