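# bcrtme

Analysis of B cell receptor (BCR) repertoires in the tumor microenvironment.

Tumor-infiltrating B cells in solid tumors show signatures of antigen-driven
responses: clonal expansion, somatic hypermutation (SHM), biased heavy-chain
gene usage, and isotype switching toward particular IgG subclasses.  `bcrtme`
implements the statistics used to quantify those signatures from matched
PBMC / adjacent-tissue / tumor AIRR-seq data, resolves IgG subisotypes and
constant-region (IGHC) haplotypes from near-full-length reads, and stratifies
patients by mass-cytometry-derived immune-subset proportions.  It is aimed at
computational immunologists who have annotated rearrangement tables (AIRR
Rearrangement TSV) and subset-proportion matrices and want a tested,
scriptable version of this analysis layer — including a synthetic-cohort
generator with known ground truth for validating every stage.

## The statistics at the core

For a sample with clone sizes n_1 ≥ n_2 ≥ … ≥ n_C (N sequences total):

* **Polarization** = k*/C, where k* = min{k : Σ_{i≤k} n_i ≥ 0.8 N} — the
  minimum number of clones covering 80% of sequences, normalized by the
  clone count.  Lower values mean stronger clonal expansion.
* **Diversity** = Hill number of order q over clone frequencies p_i,
  ^qD = (Σ p_i^q)^{1/(1−q)}; q = 2 gives the inverse Simpson index
  1/Σ p_i², with a 95% CI from 200 bootstrap resamples of sequences.
* **SHM**: per sequence, mutations between the IMGT-gapped observed and
  germline alignments at unambiguous positions; each mutation is classified
  replacement (R) or silent (S) by single-base codon substitution against
  the germline frame, and partitioned into CDR (CDR1+CDR2) vs FWR regions.
* **Tumor enrichment**: per patient and gene g,
  Δ_g = f_g(tumor, isotype) − f_g(PBMC, IgM); cohort-level enrichment is a
  one-sample t-test of Δ_g against 0, Bonferroni-corrected over tested
  genes.
* **IGHC haplotypes**: constant segments of near-full-length IgG reads are
  length-filtered (900–1100 bp), heterozygous SNVs are called from base
  counts, reads are phased into two haplotypes by minimum error correction
  (MEC), exact-identity clusters ≥ 5% of a gene's reads are assigned
  alleles, and class switching is tabulated per haplotype × subisotype
  (e.g. the IGHG4:IGHG1 fold ratio on one chromosome).
* **Cohort stratification**: k-means on tumor subset proportions (k = 4);
  one-vs-rest enrichment per subset and group, whose coefficient equals the
  group-vs-rest mean difference in percentage points; B-subset ANOVA after
  renormalizing to the CD19+ compartment; chi-squared clinical
  associations; Pearson correlations of repertoire features with subsets.

See `docs/methods.md` for assumptions, defaults, and numerical conventions.

## Worked example

Simulate a 29-patient matched cohort (three spiked tumor V genes:
IGHV3-7 +0.08, IGHV3-74 +0.05, IGHV1-24 +0.05), assign clones, and measure
clonality, SHM and tumor enrichment:

```python
from bcrtme import synthetic_cohort as sc, clonal_structure as cl
from bcrtme import mutation_profile as mp, gene_usage as gu

config = sc.CohortConfig(n_patients=29, n_airr_patients=29,
                         sequences_per_sample=300, seed=1)
table, proportions, truth = sc.simulate_cohort(config)
part = cl.assign_clones(table, threshold=0.15)

for tissue in ("PBMC", "tumor"):
    mask = cl.sample_filter(part.table, patient="P001", tissue=tissue, isotype="IGHM")
    pol = cl.polarization(part, mask)
    div = cl.diversity(part, mask, q=2.0, n_boot=200, seed=0)
    print(f"{tissue:8s} IgM  polarization={pol:.3f}  inv. Simpson={div.point:.1f} "
          f"(95% CI {div.ci_low:.1f}-{div.ci_high:.1f})")

_, shm = mp.shm_summary(table[table["patient_id"] == "P001"])
print(shm.round(4).to_string(index=False))

freqs = gu.usage_frequencies(table, segment="v")
tumor = freqs.xs(("tumor", "IGHM"), level=("tissue", "isotype"))
pbmc = freqs.xs(("PBMC", "IGHM"), level=("tissue", "isotype"))
deltas = gu.delta_vs_baseline(tumor, pbmc)
res = gu.cohort_enrichment_test(deltas, tumor, pbmc)
print(res[res["significant"]][["gene", "mean_delta", "t", "q", "direction"]]
      .round(4).to_string(index=False))
```

Output:

```
PBMC     IgM  polarization=0.670  inv. Simpson=137.2 (95% CI 125.8-148.6)
tumor    IgM  polarization=0.426  inv. Simpson=29.1 (95% CI 25.9-32.2)
  tissue isotype  mean_shm_frequency  r_percentage  r_frequency  n_sequences
    PBMC    IGHG              0.0494       76.0973       0.0376          300
    PBMC    IGHM              0.0042       75.5936       0.0032          300
adjacent    IGHG              0.0597       76.1157       0.0454          300
adjacent    IGHM              0.0202       74.7946       0.0151          300
   tumor    IGHG              0.0558       76.6583       0.0428          300
   tumor    IGHM              0.0242       74.6627       0.0182          300
    gene  mean_delta       t      q direction
IGHV1-24      0.0467  3.1610 0.0451  enriched
IGHV1-69     -0.0402 -3.5682 0.0158  depleted
IGHV3-23     -0.0390 -3.6843 0.0117  depleted
 IGHV3-7      0.0660  4.5258 0.0012  enriched
IGHV3-74      0.0409  3.7907 0.0088  enriched
```

Reading this: the tumor IgM repertoire is more polarized (0.426 vs 0.670)
and less diverse (inverse Simpson 29 vs 137) than matched blood; peripheral
IgM is nearly unmutated (SHM 0.004/site) while tissue IgM and all IgG
compartments carry substantial mutation loads; and the per-patient
tumor-minus-PBMC deltas recover exactly the three spiked genes as enriched
(the depleted genes absorb the compensating frequency mass — delta rows sum
to zero by construction).

The same stages are available from the shell:

```bash
bcrtme simulate --out-prefix demo --seed 3
bcrtme clones   --in demo.rearrangements.tsv --out demo.clones.tsv
bcrtme usage    --in demo.rearrangements.tsv --out-prefix demo.v
bcrtme cohort   --tumor demo.proportions.tumor.csv --out-prefix demo
```

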