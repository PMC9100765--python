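# Methods

`pleioscan` implements a four-phase analysis for discovering *pleiotropic
signatures of regulatory SNPs* (rSNPs) in an association panel of inbred
lines, together with a synthetic-data generator whose planted ground truth
makes every phase testable end to end.

## Phase 1 — allele-aware TFBS scanning

A SNP is a candidate rSNP when it falls inside a gene's promoter window,
defined as −500 bp to +100 bp around the transcription start site *in
transcription direction* (minus-strand genes map to the genomic interval
[TSS − 100, TSS + 500]; both boundaries are inclusive).  SNPs with minor
allele frequency below 0.05 are discarded first (the boundary value is
kept).  For each promoter SNP, two 51-base windows are cut from the genome
(±25 bp, SNP central): one carrying the reference allele, one the
alternate.

Each window is scanned on both strands against a position weight matrix
(PWM) library with an information-weighted similarity score.  For a PWM
with frequencies f(i, b), the per-position information is

    I(i) = Σ_b f(i,b) · ln(4 f(i,b))        (0·ln 0 ≡ 0),

and a motif-length window s scores

    MSS = (Current − Min) / (Max − Min),
    Current = Σ_i I(i) f(i, s_i),  Min/Max = Σ_i I(i) min_b/max_b f(i,b),

clamped to [0, 1]; the *core* score is the same quantity restricted to the
five consecutive positions with the largest summed information.  A matrix
whose positions are all uniform has Max = Min and is excluded as
unscorable.  A TF's site is "present" in a window when at least one offset
passes both cutoffs (defaults MSS ≥ 0.95, core ≥ 0.90; both configurable).
Per (SNP, TF): presence only with the reference allele is a **Loss**, only
with the alternate a **Gain**, anything else **NoStrongEffect**.  A SNP
with at least one Gain or Loss is an rSNP.  Since a motif window that does
not cover the SNP position is identical in both alleles, only
SNP-overlapping sites can produce Gain/Loss — so the sequence-level
presence rule and a SNP-overlap rule coincide.

Published per-matrix cutoff profiles (minFP/minFN) are deliberately out of
scope; a single global cutoff pair is used.

## Phase 2 — Boruta ranking and incremental feature selection

Per phenotype, rSNP dosages (0/1/2 alternate-allele counts; missing values
imputed by the per-SNP mode) feed a Random-Forest regression.  Forest
settings follow the classical regression defaults: 500 trees,
features-per-split = p/3, minimum leaf size 5 (the R `randomForest`
regression `nodesize`), impurity-based importances, one fixed seed per
phenotype.

The Boruta wrapper appends a column-permuted *shadow* copy of every active
feature each iteration, fits the forest, and counts a "hit" for each
undecided feature whose importance exceeds the best shadow importance.
After iteration t, hit counts are tested against Binomial(t, ½), two-sided
at α = 0.01 with Bonferroni correction over the currently undecided
features; significantly-above-half features are Confirmed, significantly
below Rejected (and removed from the design), survivors at `max_iter`
(default 100) stay Tentative.  All original features are ranked by their
median standardized importance Z = (imp − mean shadow)/sd shadow over
their active iterations; ties break on the feature id.

Incremental feature selection (IFS) then walks down that full ranking
(not only the Confirmed set — optimal set sizes may exceed it), refits the
forest on the top-k features for k = 1, 1+stride, …, and records
out-of-bag R².  The optimal rSNP count is the smallest k attaining the
maximum recorded R²; OOB R² was chosen over cross-validation because it is
deterministic per seed and costs a single fit per k.

## Phase 3 — PSI profiles and Markov clustering

Every rSNP appearing in at least one optimal set gets a binary profile row
over phenotype columns (optimal-set membership) and TF columns (a recorded
Gain or Loss for that TF).  Rows are compared with the Proportional
Similarity Index

    A_kl = 2 Σ_j min(M_kj, M_lj) / Σ_j (M_kj + M_lj),

a [0, 1] overlap measure (0/0 for two all-zero rows is defined as 0).  The
association matrix A is clustered with the Markov clustering algorithm:
self-loops equal to each row's maximum are added (standard practice; it
stabilizes convergence), columns are normalized to a stochastic matrix,
and expansion (matrix square) alternates with inflation (entrywise power
2.0, renormalize) and pruning of entries below 1e-6 until the maximum
entry change falls below 1e-8 or 200 iterations.  Attractors (rows with
positive diagonal mass) define clusters; overlapping attractor systems are
merged, every other node joins the attractor holding its largest limit
weight, ties toward the smallest attractor index so output is
deterministic.  Inflation is exposed (higher values → finer clusters).

Finally, rSNPs whose profile marks fewer than two *phenotype* columns are
pruned — TF columns never confer pleiotropy — and emptied clusters are
dropped.

## Phase 4 — hierarchical networks and expression validation

Each pleiotropic cluster becomes a three-layer directed graph
TF → rSNP(gene) → phenotype; TF edges carry the Gain/Loss label, and
edges exist only between adjacent layers.  Counts are normalized with
median-of-ratios size factors (per line: the median over genes with
all-positive counts of count / gene geometric mean).  For each
(pleiotropic rSNP, gene) pair, lines are split by allele — reference
homozygotes vs alternate homozygotes; heterozygotes are excluded by
default on an inbred panel but can be pooled with the alternate group —
and gene expression is compared with a two-sample Wilcoxon rank-sum test.
The p-value is exact by enumeration whenever the pooled data has no ties
and C(n1+n2, n1) ≤ 184 756 (which covers both groups up to 10 lines
each); otherwise a tie-corrected normal approximation with continuity
correction is used.  Groups smaller than 3 lines per side skip validation
(the rank test is degenerate below that).  Significance is raw p < 0.05 by
default; Benjamini–Hochberg correction across all records is available by
flag, since whether any multiple-testing correction belongs here is an
open modelling choice.  rSNPs without a significant validation are removed
from the network along with any TF or phenotype node left unconnected.

## Synthetic data

The generator emulates an inbred association panel:

* **PWMs** — random motifs of length 8–14 with a dominant base per
  position (0.6–0.95) and one near-deterministic anchor position (0.97),
  so every motif has a consensus site that a single-base change destroys.
* **Genome/annotation** — one contig, evenly spaced genes on alternating
  strands.  For each planted rSNP a motif consensus is written into the
  promoter overlapping the SNP; Loss plants the consensus on the reference
  allele and an anti-consensus alternate base at the motif's most
  information-dense position, Gain the converse.  Every planted site is
  re-verified against the Phase-1 scanner at default cutoffs before
  acceptance.
* **Genotypes** — biallelic, homozygous 0/2 dosages (heterozygosity rate
  configurable, default 0), per-SNP alternate frequency drawn from the
  configured MAF range with realized MAF re-checked against the floor.
* **Phenotypes** — each planted pleiotropy cluster assigns a disjoint set
  of rSNPs to a disjoint set of traits; a clustered trait is the sum of
  additive standardized-dosage effects (β = 0.5 per rSNP) plus Gaussian
  noise at a configured variance fraction (default 0.3, i.e. "heritability"
  0.7); unclustered traits are pure noise.  Effects are additive only — no
  epistasis, matching what marginal RF importance can use.
* **Expression** — gamma-Poisson counts (dispersion 0.1) with per-line
  log-normal size factors (so median-of-ratios normalization has real work
  to do); each planted rSNP shifts its gene's alternate-homozygote mean by
  2^shift (default shift 1.0 log2 units, sign +1 for Gain and −1 for
  Loss).

Deliberately **not** emulated: linkage disequilibrium, population
structure, kinship, genotype×environment interaction, read-level noise.
Passing recovery tests therefore demonstrates the pipeline's correctness
under clean marginal signals, not robustness to confounding that real
panels carry.

All generators are pure functions of (config, seed); every stochastic
stage of the pipeline draws from a named substream of the single run seed.

## Reference run and problem sizes

The package's reference study conditions are 400 lines, 2000 SNPs, 60
genes, 30 PWMs, 20 traits and 3 planted clusters of 4 rSNPs × 4 traits.
The reference analysis keeps 500 trees and IFS stride 1 — out-of-bag R²
at smaller forests is noisy enough to let spurious features into the
optimal sets, which can bridge otherwise-distinct profile clusters — and
caps Boruta at 40 shadow iterations: confirm/reject decisions on this
panel fall at iteration 12–16, so the cap only bounds features whose hit
counts hover near one half and would otherwise idle to the 100-iteration
default while changing nothing downstream (they stay Tentative either
way).  At these sizes the full pipeline completes in under ten minutes on
one CPU and recovers the planted structure exactly (cluster ARI 1.0,
optimal-set recall 1.0, full cis-rSNP survival after pruning); a heavier
run at max_iter 100 reproduced the same recovery.

## Numerical and degenerate-input choices

* Coordinates: 1-based inclusive on disk (VCF/GFF3), 0-based half-open
  internally.
* Windows containing ambiguous bases (N) are skipped with a warning;
  frequencies are undefined for N.
* Multi-allelic VCF records are split into biallelic records on load.
* A constant response or an all-missing dosage column is an error (the
  former) or dropped with a warning (the latter).
* Shadow importance sd of a single-shadow design is guarded to a small
  epsilon so Z stays finite.
* MCL on an all-zero row inserts a unit self-loop so the matrix stays
  stochastic; such nodes come out as singletons.

## Known limitations

* Global PWM cutoffs rather than per-matrix calibrated profiles.
* No population-structure or kinship correction in the association phase;
  on stratified panels the optimal sets would absorb confounded markers.
* MCL inflation/expansion defaults are the algorithm's canonical values,
  not tuned to any particular data set.
* The allele-split expression test is a single cis comparison per rSNP,
  not an eQTL model; trans effects and covariates are out of scope.
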