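# Methods

`ricegwas` implements an end-to-end pipeline from a rice diversity panel's
genotypes and brown-rice total-flavonoid phenotypes to QTLs and candidate
genes, together with a synthetic-panel generator that reproduces the
statistical structure the analysis assumes. This note documents the models,
the defaults and the design choices that were genuinely open.

## Phenotype quantification

Total flavonoid content (TFC) is measured colorimetrically against a rutin
standard. Absorbance at 500 nm relates linearly to rutin concentration
(mg/mL); the package ships the two per-replication standard curves
(`y = 1.8764x − 0.0054`, `y = 1.8503x − 0.0129`) and fits new curves by OLS.
The conversion from reaction concentration `c = (A − b)/a` to mg rutin
equivalent per 100 g of flour multiplies by

    reaction_volume × (extract_volume / aliquot_volume) × (basis / sample_mass)

With the default extraction bookkeeping (0.5 g flour, 5 mL extract, 1 mL
aliquot, 6.2 mL reaction, per 100 g) the multiplier is 6200. This factor is
not a universal constant — lab conventions differ — so every term is
configurable in `DilutionScheme`. Technical repeats are averaged first,
each field replicate is converted with its own curve, and TFC (not
absorbance) is averaged across replicates. Sub-blank absorbances are
clamped to zero concentration with a warning rather than rejected.
Summary statistics use the adjusted Fisher–Pearson skewness and report the
max/min ratio rounded half away from zero to one decimal.

## Genotype QC and population structure

SNPs are retained when they are biallelic, their missing rate is at most
0.30 and their minor allele frequency is at least 0.05 ("over 30%" and
"less than 5%" read strictly). Missing dosages are mean-imputed per SNP for
kinship, PCA and association — the standard choice that preserves allele
frequencies.

LD pruning uses PLINK-style greedy sliding windows (window 50, step 5,
r² < 0.3). The window unit is SNP count by default; a literal base-pair
reading is available via `window_unit="bp"`. Within a window the member of
the worst pair with the higher missing rate is dropped (ties to the higher
index), which makes pruning deterministic.

Kinship is the VanRaden centered cross-product `ZZ' / 2Σp(1−p)`
(identity-by-state available by flag); PCA is the SVD of the centered
imputed dosage matrix with signs fixed so each component's
largest-magnitude loading is positive. Because dosage centering forces the
row sums of the kinship matrix toward zero, the off-diagonal mean of an
unrelated panel sits at `−mean(diag)/(n−1)` rather than exactly zero; the
tests check this exact null rather than a naive zero.

## Mixed-model association

The scan fits `y = [1,Q]β + gγ + u + e` with `u ~ N(0, σg²K)` and
`e ~ N(0, σe²I)`, where Q holds the first three principal components.
Variance components are estimated once under the null by REML: the model is
rotated into the eigenbasis of K and the restricted likelihood profiled
over `δ = σe²/σg²` on a 100-point log grid in [1e-5, 1e5], refined by
bounded scalar minimization (xatol 1e-6 relative). Each SNP then enters as
a fixed effect with `δ` held fixed (P3D); effect and SE come from GLS in
the whitened space, and the p-value from a t distribution with `n − q − 1`
degrees of freedom (q = null covariates including the intercept). The
residual scale is re-estimated per SNP, so with K = I and no covariates the
scan reduces *exactly* to per-SNP OLS — an identity the tests assert to
1e-8. Exact per-SNP REML (`p3d=False`) exists for small panels.

Kinship compression clusters accessions by average-linkage hierarchical
clustering on `1 − K/max(diag K)` and replaces the kinship with group-pair
means; `select_compression` picks the group count maximizing the REML
likelihood over candidates {1, n/8, n/4, n/2, n} (ties to fewer groups).

The genome-wide threshold is a maxT permutation construction: the phenotype
is permuted (breaking genotype–phenotype links while keeping the phenotype
distribution and the genotype LD intact), `δ` is re-estimated with the
cached eigendecomposition, all SNPs are rescanned, and the maximum
−log10(p) recorded. The threshold is the 95% type-7 (linear-interpolation)
quantile of the permutation maxima. The rotated genotype matrix is cached
across permutations, making each permutation O(n·m).

## QTL definition and co-location

A QTL is a maximal run of at least three significant SNPs on one chromosome
in which every gap between adjacent *significant* SNPs is strictly under
170 kb — an intervening non-significant SNP does not break a run, only a
long gap does (the all-SNPs-consecutive alternative is not implemented as a
flag because only gap distances are constrained). The lead SNP is the
member with the largest −log10(p), ties to the smaller position. Interval
lengths are coordinate differences (`right − left`, not inclusive base
counts); this convention reproduces every printed overlap length of the
reference co-located-QTL table exactly and is used everywhere, including
the whole-kb rounding (nearest integer) of reported interval sizes.

Two QTLs from different population scans co-locate when their intervals
have positive intersection (touching endpoints do not count). The
commonly-significant-SNP count is taken over the union of the two member
intervals, not the overlap — the reference table contains rows with
positive overlap but zero common SNPs, which rules out the overlap-only
reading. Threshold relaxation re-runs significance and clumping on one
chromosome at a lower threshold and returns the relaxed QTL containing the
original lead (error if the lead is orphaned).

## Candidate-gene funnel

For a chosen QTL the local LD interval is the maximal run of significant
SNPs around the lead (within ±1 Mb) in which every SNP has r² ≥ 0.6 to the
lead. A single below-threshold SNP breaks the run by default
(`max_interruptions=0`; a tolerance is configurable). The funnel then
proceeds: genes with positive intersection with the interval → drop
transposons/retrotransposons (and hypothetical proteins by default) → keep
genes with ≥1 significant SNP in the gene region (promoter, exon, intron,
5′/3′UTR) → keep genes with at least moderate peak expression in
grain-related tissues (ovary, embryo, endosperm) → keep genes whose
haplotypes separate the phenotype within a subpopulation. Each gene records
the first stage at which it fell out.

Choices left open by convention and resolved here:

- **Promoter length**: 2,000 bp upstream of the gene span respecting
  strand — the dominant rice-annotation convention; configurable.
- **SNP location precedence**: UTR sub-intervals are recorded as sub-spans
  of terminal exons, so UTR membership is resolved before exon; any other
  in-span position is intronic.
- **Expression classes**: qualitative none/low/moderate/high with linear
  cut points 1 / 5 / 20; the retained floor is "moderate" (configurable to
  include "low"); genes absent from the table are kept with a warning
  rather than silently dropped.
- **Haplotypes**: accessions with complete homozygous calls at all defining
  SNPs are grouped by allele string; groups under 10 members are dropped;
  within each subpopulation all group pairs are compared by two-tailed
  equal-variance Student's t-tests and the minimum p is reported.
  Heterozygous or partially missing accessions are excluded, consistent
  with inbred-panel practice.
- **Utilization**: favorable-haplotype proportions per breeding category
  (landrace vs improved) are whole percentages rounded half away from zero.

## Synthetic panel generator

The generator emulates a two-subpopulation (indica/japonica-like) inbred
panel:

- **Divergence**: ancestral alt-allele frequencies are drawn per LD block
  from the configured MAF range; each subpopulation's frequency comes from
  the Balding–Nichols distribution `Beta(p(1−F)/F, (1−p)(1−F)/F)`, so the
  Hudson-estimator Fst over SNPs is centred on the configured `fst`
  (default 0.4, the indica–japonica scale of divergence).
- **LD**: frequencies are shared (with σ=0.02 jitter) by all SNPs of an LD
  block, and each accession carries a latent uniform per SNP copied from
  the previous SNP with probability `exp(−d/L)` (L = 150 kb by default) or
  drawn fresh. Dosage r² therefore decays roughly as `exp(−2d/L)`; pairs
  more than 5L apart average r² < 0.05. Block-level frequency sharing is
  essential: with per-SNP independent divergence draws the pooled
  two-subpopulation r² never reaches realistic within-block levels.
- **Inbreeding**: dosages are 0/2 (one haplotype draw per accession),
  with configurable residual heterozygosity (default 0).
- **Phenotype**: `y = baseline + Σ effect·dosage + u + e` with `u` drawn
  with covariance proportional to the *realized* kinship and scaled to
  `h2_polygenic` of the total variance; the total variance is set so the
  planted-SNP variance share equals `h2_qtl` (when causal effects exist) or
  to `base_sd²` (default 38 mg/100 g, matching a panel mean of 136 mg/100 g
  with CV ≈ 28%). Two field replicates add independent noise (default
  4 mg/100 g).
- **Causal SNPs**: blocks holding a planted causal SNP redraw their
  frequencies from a mid-range ancestral value until all subpopulation
  frequencies lie in [0.2, 0.8], so the configured effect is actually
  expressed in the panel rather than lost to drift.
- **Annotation/expression**: Poisson gene counts per Mb, non-overlapping
  2–6 kb gene bodies with 1–5 exons, UTR stubs and class labels
  (gene/transposon/retrotransposon/hypothetical); expression levels are
  lognormal with a configurable expressed fraction and designated
  always-high genes.

What the generator does **not** emulate: coalescent-accurate haplotype
mosaics, recombination-rate variation, allele-frequency spectra of real
resequencing data, genotype-calling error structure, or linked selection.
Passing tests therefore demonstrate the pipeline's correctness and
calibration under a controlled two-population block-LD model, not its
behaviour on any particular real panel.

## Problem sizes and numerical choices

Tests and calibration run at desk scale: the default simulated panel is
500 accessions × 3 chromosomes × 2,000 SNPs, large enough to express
population structure and block LD while keeping the permutation loop cheap.
The genome-wide error-rate calibration uses 200 permutations and 50 fresh
null scans; planted-signal recovery uses 20 replicate seeds with
`h2_qtl = 0.15`. All random draws flow from explicit integer seeds through
`numpy.random.default_rng`; every pipeline artifact is byte-reproducible
given the seed. Degenerate inputs fail loudly: zero phenotypic variance,
non-PSD kinship, monomorphic lead SNPs and unformable haplotypes raise
errors rather than returning silent NaNs, while undefined r² (zero
variance or <2 complete observations) returns NaN with a warning because
it occurs routinely inside window scans.

## Known limitations

- The mixed model is single-locus; linked QTLs are not split by
  conditional analysis.
- P3D holds variance components fixed across SNPs; for very strong single
  loci exact per-SNP REML gives slightly different p-values (available but
  slow).
- Compression clustering uses the kinship-derived distance only; it does
  not re-estimate group effects jointly with compression level.
- The haplotype t-test assumes equal variances and ignores kinship within
  haplotype groups, as is conventional for this style of analysis.
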