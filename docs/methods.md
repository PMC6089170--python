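# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions a user may need when
comparing against other implementations.

## Data model and identity

All genomic coordinates are 1-based closed intervals internally; BED input is
converted on read. Patient identity is the truncated sample barcode (default:
first 12 characters of a TCGA-style barcode), applied uniformly when reading
mutation, copy-number and lesion tables so that germline and somatic data
join per patient. The truncation length is a parameter of every reader; no
public convention exists for this join, so it is fixed here once and exposed.

Trinucleotide contexts come from explicit context columns in the mutation
table (a `CONTEXT` string centred on the variant). The package never touches
a reference genome; synthetic data emits contexts directly.

## Genotype QC

Variants enter association scans when imputation info ≥ 0.5, folded MAF
≥ 0.01 and Hardy–Weinberg exact P ≥ 0.001 (all inclusive). The HWE test is
the exact conditional test: given the allele counts, every heterozygote count
of matching parity is enumerated, and the two-sided P is the total
probability of configurations no more probable than the observed one. The
exact test rather than the χ² approximation is used because it is stable at
the rare-allele counts a risk-SNP panel can contain. Dosages are rounded to
best-guess genotypes for the HWE test only; association always uses raw
dosages. The implementation enumerates in log space with a normalizing
logsumexp, and ties are detected with a 1e-10 relative tolerance; it agrees
with an exact rational-arithmetic oracle to < 1e-12 over every genotype
configuration with n ≤ 20.

LD pruning of a SNP panel is greedy in ascending GWAS-P order (ties: input
order): a SNP is kept iff its r² with every kept SNP is below 0.8. Keeping
the smallest-P member of each clump is the conventional choice when only
"one SNP per clump" is specified.

Genotype principal components are computed from per-variant standardized
dosages. By default the PCA runs on an LD-pruned variant subset (pairwise
r² < 0.2 within 250-variant windows, with r² estimated from the dosages
themselves); `prune_r2=None` uses all QC-passing variants. Component signs
are fixed by making the largest-magnitude loading positive, so results are
reproducible across runs and platforms.

## Region enrichment

Susceptibility regions are `pos ± flank` (flanks 50, 100, 200, 500 kb;
200 kb is the default for susceptibility-gene assignment), clipped at
position 1. The enrichment statistic is the proportion of **driver genes
among the distinct coding genes resident in the regions** — with this
denominator the observed proportion naturally dilutes as flanks grow, which
is the documented qualitative behaviour; using the driver list as the
denominator would not have that property.

Null SNP sets are matched per target SNP on four features: |ΔMAF| ≤ 0.05
(absolute), and LD-buddy count, distance to nearest gene and gene density
each within ±50% (relative). These windows follow the defaults of the
SNPsnap matched-sampling service; all are configuration keys. A target whose
feature value is at or below a small-value floor (1 LD buddy, 10 kb distance,
1 gene) matches any pool value at or below the floor — a relative window
around a near-zero value would otherwise be empty. Sampling is uniform within
the eligibility window, seeded, and without replacement within a set; a
target with no eligible pool SNP is an error naming the SNP, and fewer than
n_sets/10 eligible matches is an error suggesting wider tolerances.

The permutation P is `#{null ≥ observed} / n_perm` (ties count toward the
numerator). A P of exactly 0 is stored as 0 but displayed as `< 1/n_perm`.
An optional (count+1)/(n+1) estimator is available and off by default.

## Gene-set and pathway enrichment

Fold enrichment of an overlap k between a drawn set of n genes and a category
of K genes in a universe of N is (k/n)/(K/N); significance is the
hypergeometric upper tail P(X ≥ k). The default universe is 56,318 genes
(a full human annotation); it is a parameter because pathway analyses are
sensitive to it and no single value is canonical.

Pathways are prefiltered to those containing at least one driver or
susceptibility gene. Each surviving pathway gets two upper-tail tests
(overlap with the susceptibility-gene list; overlap with the driver list);
BH adjustment runs across pathways separately per list, and key pathways are
those at FDR ≤ 0.1 on both sides. BH is the standard step-up adjustment
(p·m/rank, cumulative minimum from the largest rank, capped at 1, input
order preserved).

## Somatic phenotypes

* **Driver mutation flags** count any mapped call, silent included, because
  the phenotype is defined as "one or more DNA mutations" in the gene; a
  `nonsilent_only` switch excludes Silent.
* **Truncation flags** use the conventional protein-shortening classification
  set {Nonsense, Frame_Shift_Del, Frame_Shift_Ins, Splice_Site, Nonstop};
  the set is a parameter since "truncating" has no single standard.
* **Copy number** is the absolute gene-level value restricted to driver
  genes; lesion flags are 1 when the GISTIC threshold code is ≥ 1.
* **Spectra** accumulate SNVs into the canonical 96 channels
  (substitution-major, then 5' base, then 3' base); purine-reference calls
  are reverse-complemented into the pyrimidine convention. Non-SNV or
  ambiguous-context records are skipped and counted.
* **Signature refitting** normalizes the spectrum to frequencies and solves
  non-negative least squares against the reference matrix, discards weights
  below 0.06, refits on the surviving support, and reports
  `unknown = max(0, 1 − Σw)`. The discard threshold and the `unknown`
  convention follow the deconstructSigs defaults; the solver is exact NNLS
  with support refit rather than iterative forward selection because the two
  coincide at the optimum on well-conditioned inputs and NNLS has a simpler
  determinism contract — the equivalence is property-tested against a
  grid-search oracle. An optional `tri_counts` vector divides the spectrum
  channel-wise before fitting (trinucleotide-abundance correction); default
  is no correction, since the appropriate abundance depends on the capture
  design and is best supplied explicitly.

## Association scans

The additive model codes genotype as risk-allele dosage in [0, 2] entering
the regression linearly. Binary phenotypes use logistic regression (Newton,
gradient tolerance 1e-8 or better), quantitative phenotypes use OLS; both
include an intercept and the covariates (age, gender dummy-coded, clinical
stage as an ordinal 1–4 numeric — cast the column to strings for dummy
coding — and genotype PCs). Missing clinical values are imputed with the
column median (mode for nominal columns) before fitting. P-values are
two-sided Wald tests on the dosage coefficient, the standard reporting choice
for genotype scans; 95% CIs are exp(β ± 1.96·SE) for logistic fits.

Perfect separation or non-convergence flags the result and sets P to missing
rather than raising, so one degenerate phenotype cannot abort a scan; a
logistic fit with fewer than 10 samples in either outcome class is flagged
`small_class`. A constant dosage is an error ("monomorphic").

BH runs within each phenotype family (driver mutations, key pathways, copy
number, lesions, signatures) because each family is reported as its own
analysis; a `global_bh` switch adjusts across all families jointly.
Stratified analyses are re-runs of the scan on sample subsets (a pandas
query on the covariate table via `--subset`); no interaction terms are fit.

The genotype contingency report rounds dosages to best-guess genotypes and
prints counts with within-column percentages for the three genotypes, the
dominant collapse and the additive model, with unadjusted (or, if covariates
are passed, adjusted) logistic ORs; a genotype absent from one outcome column
gets an absent OR.

## Synthetic cohorts and ground truth

The generator emulates, with known ground truth: HWE genotype dosages at
stated MAFs with uniform imputation info scores in [0.3, 1] (so the QC filter
has variants to remove) and optional Gaussian dosage noise; a tiled
protein-coding annotation on 10 synthetic chromosomes; driver genes planted
within ±50 kb of risk SNPs at a configurable rate (default 0 — the null);
key pathways constructed with enough driver and susceptibility genes that
both enrichment tests clear FDR 0.1 with a 20× margin, among uniform
background pathways; per-sample mutation catalogs with negative-binomial
totals (mean 120/sample, shape 5 — exome-scale) whose SNV channels are drawn
from per-sample signature mixtures (Dirichlet over 3 active signatures by
default, or supplied); copy number Gaussian around 0 (σ = 0.3); GISTIC-style
lesions with threshold codes; and clinical covariates with 5% missingness.
Cohort defaults mirror the target study design: 442 samples, 11 risk SNPs,
276 drivers, 8 key pathways, 11 reference signatures. The gene and SNP
universes are scaled (2,000 genes, 5,000–8,000 pool SNPs) so a full analysis
runs in seconds.

Planted genotype→phenotype effects are logistic in dosage for binary
phenotypes — the flag is drawn first and the mutation records are made
consistent with it, so derived phenotypes equal the ground truth exactly —
linear slopes for copy number (planted genes get a baseline of 1.0 so the
absolute-value step does not fold the signal), and per-allele weight shifts
for signatures.

What the generator does **not** emulate: LD structure (every synthetic SNP
has zero LD buddies, and the matching floor makes that feature non-binding),
population stratification, mutation hotspots, gene-length effects on
mutation probability, or correlated copy-number segments. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery, not robustness to those real-data complications.

All generators are deterministic functions of the config seed, with separate
streams per stage.

## Calibration experiments and problem sizes

The permutation-engine calibration uses 200 replicate null cohorts (1,200
genes, 8,000 pool SNPs, 150 drivers, no planting) at n_perm = 1,000, checking
that the P-values are uniform (KS test) and that the fraction at P ≤ .05
stays in [0.02, 0.10]; planted cohorts (drivers beside every risk SNP) must
give median P < .05. n_perm = 1,000 and the scaled genome keep the whole
experiment around a minute while leaving the P-value grid fine enough for
the uniformity check; production runs default to 10,000 sets.

CI coverage is assessed on 100 datasets per planted log-OR in
{−1.35, 0, 0.7} at n = 1,000, MAF 0.3: per-effect mean bias must be < 0.1
and coverage, pooled over the 300 intervals, must lie in [0.92, 0.98] — a
100-interval estimate of a 95% rate has ±2.2% binomial noise, so the band is
checked on the pooled estimate.

Published numbers that require individual-level cohort data (the specific
region-enrichment P trend, the covariate-adjusted OR 0.26 for the pathway
truncation association, the signature and copy-number association P-values,
and the specific eight Reactome pathways) cannot be recomputed from summary
inputs; the pipeline instead reproduces each analysis *form* on synthetic
cohorts with planted effects of the same magnitude and verifies recovery.
The quantities that are computable from printed inputs — the gene-based
enrichment example and the contingency-table margins and unadjusted odds
ratios — are recomputed exactly (the unadjusted additive OR on the printed
genotype rows is ≈ 0.30; the published 0.26 is covariate-adjusted).

## Known limitations

* The signature refit assumes the reference matrix is well-conditioned;
  near-collinear signatures (as some real COSMIC pairs are) make individual
  weights unstable even when the fitted spectrum is accurate.
* The exact HWE test on imputed best-guess genotypes ignores imputation
  uncertainty; poorly imputed variants should be removed by the info filter
  first.
* Matched sampling requires a background pool dense enough that every target
  has ≥ n_sets/10 eligible matches; small pools need wider windows.
* The association layer fits one SNP at a time; no kinship or mixed-model
  adjustment is available, so cryptic relatedness must be handled upstream.
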