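# Methods

`bcrtme` reimplements the repertoire-analysis layer of a matched-tissue B
cell receptor (BCR) study of solid tumors: bulk heavy-chain AIRR-seq of IgM
and IgG from peripheral blood (PBMC), tumor-adjacent tissue, and tumor;
near-full-length IgG reads resolving the constant-region (IGHC) locus; and
mass-cytometry-derived immune-subset proportion matrices.  Every stage is
exercised on a synthetic cohort with known ground truth; nothing here
requires downloading repository data.

## Data model

Rearrangement tables use the AIRR Community Rearrangement column names.
Region boundaries (FWR1, CDR1, FWR2, CDR2, FWR3, CDR3 start) are stored as
1-based inclusive coordinates on disk and converted to 0-based half-open
intervals in memory by a single tested function pair.  Allele calls collapse
to gene level by stripping the `*NN` suffix and to family level by truncating
at the first hyphen, matching IMGT naming.  Validation is strict by default:
synthetic or user data is never silently repaired; a lenient flag drops
offending rows with one logged warning each.

## Clonal structure

Clones are single-linkage clusters of junction nucleotide sequences at a
normalized Hamming threshold (default 0.15) within each patient x V gene x
J gene x junction-length group.  The threshold and grouping follow the
standard DefineClones-style convention; clones are scoped within a patient
across tissues and isotypes so a clone can be followed between compartments,
and per-sample statistics restrict members by a filter.  Each record counts
once by default (UMI collapse upstream already deduplicates); a flag weights
by `duplicate_count`.

*Polarization* is the minimum number of clones whose sequences cover 80% of
a sample, divided by the clone count; values near 1/n indicate strong clonal
expansion.  *Diversity* is the Hill number of order q over clone frequencies
(q = 2, the inverse Simpson index, is the default) with a 95% CI of the
point estimate plus or minus 1.96 bootstrap standard deviations over 200
resamples of sequences; centering on the estimate avoids the downward
richness bias percentile intervals show when many clones are singletons.  *Top-clone sets* take the largest
ceil(fraction x n_clones) clones, ties broken lexicographically by clone id
so outputs are stable.

## Mutation profiling

Mutations are counted between the gapped observed and germline alignments.
A position is informative when both bases are in {A,C,G,T}; gaps and Ns are
excluded from numerator and denominator, so `shm_frequency =
total/informative` is well defined.  Replacement/silent classification
substitutes the observed base alone into the germline codon (frame anchored
at alignment position 0) and compares translations; multiple mutations in one
codon are classified independently, the common convention.  Positions whose
germline codon is gap-broken count in the total but are tracked as
unclassifiable, so `r + s + unclassifiable = total` always holds.  Region
accounting splits mutations into CDR (CDR1 + CDR2) and FWR (FWR1-FWR3); the
junction/CDR3 is excluded from the region partition by default because it is
not germline-encoded (a flag includes it).  Group summaries are means of
per-sequence frequencies (a pooled-count option exists) to match
per-sequence plotting conventions.

## Gene usage and enrichment

Usage matrices count productive records per gene over each patient x tissue
x isotype sample (sequence-weighted by default; clone weighting by flag).
The tumor-enrichment contrast subtracts each gene's frequency in a patient's
PBMC IgM sample — the circulating, largely antigen-naive baseline — from its
frequency in tumor IgM or tumor IgG; deltas are taken over the union of genes
with absent genes as 0, so each row sums to exactly 0.  Cohort enrichment is
a per-gene one-sample t-test of deltas against zero, Bonferroni-corrected
over the genes actually tested (those used by at least `min_patients = 5`
patients).  Zero-variance nonzero delta vectors cannot yield a finite t; they
are reported deterministically with a degeneracy flag and q = 0 sentinel
rather than NaN.  Per-patient recurrence ranks genes by delta (ties broken by
larger tumor frequency, then name) and counts patients with the gene in the
top k = 5.

CDR3 features: length in amino acids; net charge = (#R + #K) − (#D + #E),
i.e. formal charge at neutral pH; basic fraction counts R, K and H (histidine
is basic but contributes no net charge at pH 7.4); acidic fraction counts D
and E.  The enriched-vs-depleted contrast averages, per patient, normalized
clone size (clone count / productive sequences in the sample), SHM frequency,
R frequency and the CDR3 features over sequences using enriched-gene vs
depleted-gene BCRs, then applies a paired t-test per feature.

## Repertoire geometry

PCA of usage vectors is column-centered and unscaled (frequencies share a
scale; scaling available by flag), matching R's `prcomp` default, with a
deterministic sign convention (largest-magnitude loading positive).  PCA is
run per segment class (IGHV, IGHD, IGHJ).  Two distance summaries are
computed on PC1-PC2 exactly: each sample's Euclidean distance to its nearest
same-tissue neighbor, and the distance between a patient's paired samples
from two tissues.  On spiked synthetic cohorts the paired between-tissue
distance exceeds the within-tissue nearest-neighbor distance, reproducing
the qualitative tissue-separation pattern.

## IGHC genotyping and haplotype-resolved class switching

Near-full-length IgG reads are modelled as co-linear with a per-gene
constant-region reference (substitution-only; indel realignment is out of
scope), replacing the external aligner/phaser/clusterer chain with positional
comparison and in-house minimum-error-correction (MEC) phasing.  Stages:

1. **Length filter** — constant segments outside [900, 1100] bp (inclusive,
   the literal reading of the stated window) are dropped.
2. **Heterozygous SNV calling** — a site is reported when the second-most
   common base reaches an allele fraction inside [0.2, 0.8] at depth >= 10.
   This window is appropriate for genomically balanced alleles; for
   *expressed transcripts* the allele fraction also carries the haplotype
   expression bias that the class-switch analysis itself measures, so the
   switch-ratio analysis widens the window to (0.05, 0.95) — discarding
   low-fraction sites there would discard exactly the biased genes of
   interest.
3. **Phasing** — reads are split into two haplotypes minimizing MEC.  For up
   to 6 het sites the consensus-pair enumeration is provably optimal when
   reads cover the sites (the optimum's majority consensus is one of the
   enumerated pairs, and nearest-assignment can only reduce cost); above
   that, a deterministic multi-start iterative refinement is used.
   Haplotype 1 is the side with more reads (ties: lexicographically smaller
   consensus), anchoring the otherwise arbitrary labels.
4. **Allele calling** — 100% identity clustering is exact string equality
   over the constant segment (bit-exact reproducibility; a trim option
   exists); clusters holding >= 5% of a gene's reads (boundary inclusive)
   are assigned the reference allele with the fewest mismatches, ties
   flagged novel.  The 5% threshold is applied after length filtering.
5. **Class-switch tables** — phased reads are tabulated per haplotype x
   subisotype, overall and per clone; fold ratios with zero denominators are
   reported as undefined, never infinite.  Cross-gene chromosome pairing
   matches each phased side to its called allele; the synthetic locus places
   both reference alleles on haplotype 1.

Per-sample subisotype statistics report IGHG1-4 frequencies and the
(IGHG1+IGHG4)/(IGHG2+IGHG3) ratio, an index of switching toward the distal
constant genes.

## Cohort statistics

Tissue contrasts are paired t-tests per subset on raw proportions with
Bonferroni correction; log2 fold changes (with a 0.01-point
pseudo-proportion) are descriptive only.  Proportions are analyzed
untransformed to match the paired-t convention; arcsine/logit transforms are
available as flags.  Patient grouping is k-means on tumor proportion rows
(k = 4 by default, with a silhouette-scan utility since the choice of k is
otherwise open); group ids are relabeled by size so outputs are stable.
One-vs-rest group enrichment uses intercept + indicator coding, under which
the coefficient equals the group mean minus the rest mean in percentage
points exactly; p-values come from the equivalent equal-variance two-sample
t-test, Bonferroni-corrected over subset x group tests.  B-subset analysis
renormalizes each patient's B-cell subset values to their CD19+ total before
one-way ANOVA per subset and pairwise t-tests for significant subsets.
Clinical associations use Pearson chi-squared without continuity correction
(df = (r−1)(c−1)).  Feature-subset correlations are Pearson by default
(Spearman by flag), sorted by |R|, with zero-variance columns marked
undefined.  Group-enrichment regressions are unadjusted for covariates.

## Synthetic cohort: what it emulates, and what it does not

Defaults mirror the emulated study design: 48 patients in four groups mixed
21:10:3:14; 66 immune subsets (15 B-cell, 15 CD4, 15 CD8, 6 NK, 5 gamma-delta
T, 10 myeloid); a 29-patient subset with matched PBMC/adjacent/tumor IgM and
IgG repertoires.  Sampling depth defaults to 500 sequences per sample, a
deliberate desk-scale choice — relative frequencies, not absolute depth,
drive every statistic tested.

* **Clone sizes** are geometric (weight ratio^i) with per-tissue skew:
  PBMC nearly uniform (ratio 0.995, 300 clones), adjacent intermediate
  (0.97, 200), tumor most skewed (0.93, 150).  The geometric law was chosen
  for its single tunable parameter and closed-form expectations; increasing
  skew provably lowers expected polarization.
* **SHM rates** (substitutions/site): PBMC IgM 0.004 (the near-naive
  peripheral compartment), adjacent/tumor IgM 0.020/0.025, IgG 0.050-0.060,
  reproducing the tissue and isotype ordering of mutation loads.  Mutations
  are independent uniform substitutions over the V region; generated
  germlines N-mask the junction (as germline reconstruction does), so the
  mean SHM frequency is an unbiased estimate of the generating rate.
  Hotspot motifs and indels are not modelled.
* **Gene usage** draws V/D/J genes per clone from fixed baseline vectors; in
  tumor the V vector is spiked (defaults: IGHV3-7 +0.08, IGHV3-74 +0.05,
  IGHV1-24 +0.05) with the unspiked mass rescaled, leaving a valid
  distribution.
* **Subisotypes** are drawn per group: the B-cell-rich group biased toward
  IGHG1/IGHG4 (0.45/0.30), the others toward IGHG2/IGHG3.
* **Proportion matrices** are Dirichlet resamples (concentration 200) around
  per-tissue group means; tumor means add signature effects per group
  (e.g. +6.66 points of resident activated memory B cells in the B-cell-rich
  group, +13 points CD8 resident memory, +25.6 points Th1-like CD4, and a
  myeloid/NK signature in the fourth group), then renormalize to 100.
* **IGHC locus**: a diploid synthetic locus with IGHG1 and IGHG4
  heterozygous at 3 SNVs each; reads mix chromosomes 0.8:0.2 and draw
  subisotypes from per-haplotype bias vectors with a true haplotype-1
  IGHG4:IGHG1 ratio of 4.6 (haplotype 2 minor and evenly split between
  IGHG1 and IGHG4).  This mixture was calibrated by Monte Carlo of the
  read-count model so the ratio is recoverable within 25% relative error
  from 560 reads in >= 90% of seeds.  Read errors are substitutions only.

The germline reference is a small packaged set of synthetic V/D/J and IGHC
allele sequences with IMGT-style names, generated deterministically from the
gene name; it reproduces realistic lengths and region layout but no real
allele sequence, so sequence-content conclusions (e.g. motif biology) cannot
be drawn from it.  One global seed expands into per-stage child seeds via
`numpy.random.SeedSequence`, making each stage individually reproducible.

Passing tests on this generator demonstrate that the statistics, tests and
phasing recover known truth under the stated noise models; they do not
validate upstream read QC, V(D)J annotation accuracy, or biological claims
about real repertoires.

## Numerical choices and degenerate inputs

All probability-vector validations use 1e-9 tolerances.  Deterministic
tie-breaks: clone ids by smallest member sequence id; top-clone ties by
clone id; per-patient gene ranking by delta, then tumor frequency, then
name; k-means group ids by size then smallest member.  Guarded divisions
return NaN/undefined markers with flags (subisotype ratio, correlations on
constant columns) or raise informative errors (empty samples, singleton
tissues).  Bootstrap CIs are SD-based and centered on the point
estimate, so they contain it by construction (and are floored at 1, the
minimum attainable Hill number).  Exhaustive phasing is
limited to 6 het sites (4^6 consensus pairs); larger instances use 10-start
refinement, which matches the exact optimum on separable instances but
carries no optimality guarantee.

## Known limitations

No lineage trees, light chains, rarefaction by default, selection-pressure
statistics (BASELINe-style), CNV/multi-haplotype IGHC models, indel-aware
alignment, or covariate-adjusted group regressions.  Monte-Carlo power
checks simulate the delta-table noise model directly (Gaussian around the
spike) rather than resimulating full sequence-level cohorts per run.
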