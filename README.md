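# rareburden

Gene-based rare-variant collapsing burden association testing for stratified
case-control cohorts, with synthetic-data generation for end-to-end testing.

The pipeline covers:

- **Qualifying-variant sets** — nine numbered filters combining variant class
  (pLOF-only vs pLOF+missense/in-frame), gnomAD allele-frequency ceilings
  (1%, 0.1%, 0.01%), and a per-gene CADD ≥ MSC rule for missense/in-frame
  variants; plus bLOF-only restriction and branchpoint inclusion for
  candidate-set analyses (`rareburden.variant_sets`).
- **Collapsing** — per-gene genetic scores under co-dominant (0/1/2),
  heterozygous, recessive, and dominant models, with hemizygous males treated
  as equivalent to homozygous females on X; burden tests require at least
  three carriers (`rareburden.collapse`).
- **Conditional Firth burden test** — ML logistic LRT adjusted for sex, age,
  and principal components; when the ML p-value is below 0.05 the test
  switches to a Firth-penalized (Jeffreys prior) LRT with profile-penalized
  confidence intervals, giving finite odds ratios under separation
  (`rareburden.firth`).
- **Genome-wide scan** — joint analysis plus trans-ethnic and trans-pipeline
  stratified analyses combined by sample-size-weighted Z meta-analysis with
  effect direction; a consistency filter discards results with joint p < 1e-3
  but meta p > 0.05; the effective number of tests (Meff) comes from the
  eigenvalue variance of the cross-gene statistic correlation across variant
  sets, and Bonferroni thresholds are 0.05 / (genes × Meff)
  (`rareburden.scan`).
- **Gene-set enrichment** — pooled super-gene burden tests over candidate
  loci with per-gene rule overrides, an empirical null from random gene sets
  matched on pLI and CoNeS, a zygosity odds-ratio equality test, and
  reporting helpers (`rareburden.enrichment`).
- **Weighted score and power** — Madsen–Browning frequency-weighted
  common+rare burden test, and Monte-Carlo power of the 2×2
  conditional-Firth test (`rareburden.weighted`).
- **QC / PCA** — MAF, call-rate, and Hardy–Weinberg filters, greedy
  sliding-window LD pruning, and genotype PCA for stratification covariates
  (`rareburden.pca`).
- **Synthetic cohorts** — stratified case-control simulation with planted
  per-gene effects (including X-linked recessive), Balding–Nichols common
  background for population structure, and VCF/TSV round-trip I/O
  (`rareburden.simulate`, `rareburden.io`).

## Command line

```sh
rareburden simulate --n-cases 200 --n-controls 200 --seed 1 --out cohort/
rareburden pca   --cohort cohort/ --k 5 --out pca_out/
rareburden scan  --cohort cohort/ --models codominant,recessive --out scan_out/
rareburden power --pd 0.005 --rr 6 --n-case 3269 --n-ctrl 1373 \
                 --alpha 2.5e-6 --reps 1000 --seed 1
```

A cohort directory holds `genotypes.vcf` (VCF v4.2, haploid male-X
genotypes), `annotation.tsv`, `samples.tsv`, `msc.tsv`, and
`gene_features.tsv`.

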