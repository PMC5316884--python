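# meningomics

Integrated genomic, transcriptomic and epigenomic analysis of **primary
(de novo) atypical meningioma** versus benign meningioma, packaged as a
tested, reusable Python library with a synthetic-cohort generator so that
every stage can be exercised end-to-end with planted ground truth.

Meningiomas are mostly benign (WHO grade I) tumours of the meninges; the
5–20% that are atypical (grade II) recur more often and carry worse
prognosis. The pipeline implemented here separates primary atypical from
benign tumours along the axes that distinguish them molecularly:

- **Somatic variants** — a tumour/normal post-calling filter cascade
  (genotype-likelihood somatic score < 20, repeat/segmental-duplication
  overlap, QUAL/QD, mapping-quality-zero reads, strand bias, mutation
  clusters of size > 2, homopolymer runs ≥ 10 bp, clipped-read rank sum,
  > 1% population frequency, > 150 internal cohort alleles), consequence
  severity selection, six-category substitution signatures, mutually
  exclusive driver subgroups (NF2, NF2/SMARCB1, TRAF7/PI3K, TRAF7/KLF4,
  Hedgehog, POLR2A) and cancer-cell-fraction (clonality) estimation
  `CCF = VAF·D/(p·m)` with `D = p·CN + (1−p)·2`.
- **Copy-number instability** — BAF-based false-positive correction
  (heterozygous-SNP BAF must deviate from 0.5 by ≥ 0.05), large-scale
  (> 1/3 arm) / focal (1/10–1/3 arm) / copy-neutral-LOH event classes,
  tumour purity from copy-loss BAF deviation `p = 4d/(1+2d)`, percentage of
  genome altered (PGA) and CNV-high/low status against the cohort mean
  (reference value 4.8%), plus arm-level Fisher and per-gene Wilcoxon
  grade associations.
- **Expression** — quantile normalisation, location/scale batch
  adjustment, an empirical-Bayes moderated t (limma-style variance
  shrinkage, validated against the Bioconductor reference) stratified by
  NF2 status, signature PCA, and a top-25-gene random forest grade
  classifier with out-of-bag error.
- **miRNA networks** — log2-RPM normalisation, moderated differential
  expression, miRNA:mRNA edges requiring negative Spearman correlation
  (p < 0.05) **and** ≥ 3 of 6 target-prediction databases, the chr14q32
  cluster / copy-loss coupling, and let-7–EZH2 anti-correlation.
- **DNA methylation** — detection/SNP/sex-chromosome QC, differential
  sites with the dual threshold (adjusted p < 0.05 and |Δ median β| > 0.1),
  consensus clustering (80% subsampling, Pearson-correlation distance,
  average linkage), hypermethylation–PGA coupling, and GREAT-style
  basal-plus-extension regulatory-domain hypergeometric enrichment.
- **ChIP regulatory state** — super-enhancer stitching (12.5 kb, 2 kb
  promoter exclusion) with the rank-curve tangent cutoff, differential
  H3K27ac/H3K27me3 signal, and concordance with expression changes.
- **TERT promoter screen** — offset↔coordinate mapping of the C228T
  (−124) and C250T (−146) hotspots relative to the minus-strand TSS and a
  recurrence-status frequency report.

## Worked example

```python
from meningomics.synthetic import CohortConfig, generate_cohort
from meningomics.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    input_dir="cohort", output_dir="results", seed=1,
    synthesize={"n_atypical": 8, "n_benign": 8},
    thresholds={"consensus_iterations": 200, "rf_trees": 300},
)
manifest = run_pipeline(cfg)
print(manifest["expression"], manifest["mirna"], manifest["methylation"])
```

prints (seed 1):

```
{'n_signature_genes': 74, 'grade_silhouette': 0.83, 'd0': 88.4, 's0_sq': 0.22, 'rf_oob_error': 0.0}
{'neg_vs_pos_p': 0.00098, 'n_edges': 19, 'let7c_ezh2_rho': -0.75, 'let7c_ezh2_p': 0.00082}
{'qc': {...'retained': 1970}, 'pga_correlation': {'rho': 0.987, 'p': 1.7e-12}, 'mask_ari': 1.0}
```

Reading: 74 genes separate atypical from benign at FDR 0.05 (silhouette
0.83 on the signature PCs; the random forest classifies the training
cohort with 0% out-of-bag error); miRNAs have significantly more
negatively than positively correlated targets (paired Wilcoxon p ≈ 1e−3)
and the planted let-7c loss anti-correlates with EZH2 (ρ = −0.75);
hypermethylation tracks chromosomal instability (ρ = 0.99) and the
methylation clusters are unchanged after masking chr1/14/22 (ARI 1.0).

The `examples/` directory has one short narrative script per capability
(variant cascade, CNV/purity, clonality/subgroups, expression signature,
miRNA network, methylation clustering, super-enhancers, TERT screen); each
generates or builds its own small input and prints what the numbers mean.
The same pipeline is available from the shell as
`meningomics run --config config.yaml` (exit codes: 0 ok, 2 validation,
3 dependency).

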