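# ricegwas

Mixed-model GWAS and candidate-gene screening for total flavonoid content
(TFC) in brown rice, with a matched diversity-panel simulator.

Flavonoids in the rice grain are a breeding target for functional rice.
Mapping the loci that control grain TFC in a diversity panel requires a
pipeline that (i) converts raw colorimetric assay readings into a
phenotype, (ii) controls the strong indica/japonica population structure
in the association scan, (iii) turns per-SNP signals into QTL intervals and
cross-population co-locations, and (iv) narrows each interval to candidate
genes. `ricegwas` implements that pipeline for researchers in rice
quantitative genetics, and ships a synthetic-panel generator so every stage
is testable with planted truth and no external downloads.

## The model

Phenotypes are mg rutin equivalent / 100 g flour via a rutin standard
curve `A = a·c + b` and the extraction bookkeeping (default multiplier
6200). The association scan fits, per SNP,

    y = [1, Q]β + gγ + u + e,   u ~ N(0, σg²K),   e ~ N(0, σe²I)

with Q the first three principal components and K the (optionally
compressed, CMLM-style) VanRaden kinship. Variance components are
estimated once under the null by spectral REML and reused for each SNP
(P3D). Genome-wide significance is the 95% quantile of per-permutation
maximum −log10(p) over phenotype permutations. A QTL is a run of ≥3
significant SNPs with adjacent gaps < 170 kb; its interval spans the
outermost members and lengths are coordinate differences (right − left).
QTLs from two population scans with positively overlapping intervals are
co-located. Candidate screening delimits the local LD interval (r² ≥ 0.6
to the lead SNP), drops transposons, keeps genes with significant SNPs in
the gene region (promoter/exon/intron/UTR), filters on grain-tissue
expression (ovary, embryo, endosperm) and tests haplotype–phenotype
differences by two-tailed Student's t-tests within subpopulations.

See `docs/methods.md` for assumptions, defaults and design choices.

## Worked example

```python
from ricegwas.simdata import SimConfig, CausalSNP, simulate_genotypes, simulate_phenotype
from ricegwas.structure import filter_snps, kinship, pca
from ricegwas import gwas, qtl
from ricegwas.phenotype import summarize_phenotype

cfg = SimConfig(
    n_accessions=500, n_chromosomes=3, snps_per_chromosome=2000,
    causal_snps=[CausalSNP("Chr1", 5_000_000, 15.0)],
    h2_qtl=0.15, h2_polygenic=0.2, seed=1)
G, labels = simulate_genotypes(cfg)
pheno, truth = simulate_phenotype(G, cfg, labels)

s = summarize_phenotype(pheno)
print(f"panel: n={s.n}  mean={s.mean:.1f} mg/100 g  CV={s.cv:.1f}%")

Gq, report = filter_snps(G)
y = pheno["mean_tfc"].to_numpy()
K = kinship(Gq)
Q = pca(Gq, n_components=3).coordinates
assoc = gwas.associate(Gq, y, Q, K, min_maf=0.05)
thr = gwas.permutation_threshold(Gq, y, Q, K, n_perm=200, seed=1, min_maf=0.05)
print(f"permutation threshold (95%): -log10(p) = {thr.threshold:.2f}")

sig = qtl.significant_snps(assoc, thr.threshold)
for q in qtl.call_qtls(sig):
    print(f"{q.name}: {q.chrom}:{q.left}-{q.right} ({q.length} bp, "
          f"{q.n_snps} SNPs), lead {q.lead_pos} at -log10(p)={q.lead_neg_log10_p:.2f}")
```

Output:

```
panel: n=500  mean=150.9 mg/100 g  CV=26.0%
permutation threshold (95%): -log10(p) = 4.91
qTFC-Full-1-1: Chr1:4969198-5032623 (63425 bp, 14 SNPs), lead 5000000 at -log10(p)=12.33
```

The simulated panel has a TFC distribution on the scale of real brown-rice
panels; the permutation threshold lands near −log10(p) ≈ 5; and the scan
recovers the planted causal SNP at Chr1:5,000,000 exactly as the lead SNP
of the single called QTL, whose 63 kb interval reflects the simulated
150 kb LD-block scale.

A command-line interface mirrors the library
(`ricegwas simulate | phenotype | qc | structure | gwas | threshold |
call-qtls | colocate | screen | run-all`); `ricegwas run-all
--config config.yaml --outdir out/` writes association tables, thresholds,
QTL and co-location tables, candidate reports and a manifest.

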