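# Methods

This note documents the models and procedures implemented in
`meningomics`, the assumptions behind them, the parameters that matter,
and the places where the design was genuinely open.

## Somatic variant cascade

Variant records arrive as caller output (allele depths, genotype log10
likelihood triplets for hom-ref/het/hom-alt, site annotations); alignment
and calling are out of scope.

**Somatic score.** Both likelihood triplets are normalised to posteriors
under a flat genotype prior; assuming tumour and normal genotypes
independent given the data, P(same genotype) = Σ_g Pt(g)·Pn(g) and the
score is −10·log10 of that, capped at 255 (`score_cap`). This is the
standard likelihood-based construction for a tumour/normal genotype-change
score; the cap handles numerically-zero agreement probabilities.

**Filters.** All ten filters are evaluated on every record (no
short-circuit) so a verdict lists every reason for failure, making the
cascade order-independent and idempotent. Printed cutoffs: somatic score
20, QUAL 30, QD 1, homopolymer length 10, cluster size > 2, clipping rank
sum ±3, population allele frequency 1%, 150 internal cohort alleles.
Strand-bias (phred 60) and MQ0 (4 reads) cutoffs are conventional values
chosen once, since only the filter names are fixed; both are configurable
in `FilterThresholds`.

**Homopolymer rule.** The rule is disjunctive ("within ±5 bp around the
mutation or from the right of the mutation"), so both readings are
implemented as a union: a run of ≥ 10 identical bases either overlapping
the ±5 bp window around the variant or anchored immediately right of it.
The variant sits at the centre of an odd-length context sequence (±15 bp).

**Mutation clusters.** Clusters are maximal runs of a *single sample's*
variants with consecutive gaps ≤ 100 bp (configurable window; the cluster
size rule is fixed at > 2 but the window length was an open choice —
100 bp is conventional for clustered-artifact removal). Cross-sample
clustering is deliberately not used.

**Consequences.** Severity is a fixed ordering (transcript ablation >
splice acceptor/donor > stop gained > frameshift > stop lost > splice
region > initiator codon > damaging missense > in-frame indel > all
others); a variant is deleterious iff its top term is at or above the
in-frame indel tier.

**Clonality.** With purity p, local copy number CN and VAF v, the
expected copies per sequenced cell are D = p·CN + (1−p)·2; multiplicity is
m = round(v·D/p) clamped to [1, CN] and CCF = v·D/(p·m), clamped to
[0, 1.05]. The clamp absorbs binomial sampling noise above 1; the
round-and-clamp multiplicity is the minimal completion of a rule that is
otherwise unstated.

## Copy-number instability

Inputs are pre-segmented intervals (chrom, start, end, logR; 1-based
inclusive) plus per-SNP BAF tables restricted to blood-heterozygous
sites; interval intersection is done half-open internally.

**Classification.** Segments spanning a centromere are split at arm
boundaries first. A segment with BAF deviation < 0.05 is always `none`
(the false-positive correction — dosage evidence without allelic
imbalance is treated as artefact). Otherwise loss/gain requires
logR < −0.1 / > +0.1, large-scale means the segment covers strictly more
than one-third of its arm, focal strictly more than one-tenth;
|logR| ≤ 0.1 over more than one-third of an arm with BAF deviation ≥ 0.05
is copy-neutral LOH (the stated logR bound "between 0.1 and 0.1" is an
evident typo read as [−0.1, 0.1]).

**Purity.** Under single-copy loss the retained-allele fraction at a
blood-het SNP in the tumour/normal mixture is (1−p)/(2−p), so the mean
deviation from 0.5 is d = 0.5 − (1−p)/(2−p) and p = 4d/(1+2d). This
closed form (weighted by SNP count over qualifying loss segments with
≥ 10 SNPs, clamped to (0, 1]) substitutes for the cited external
purity-estimation package, which implements the same principle.

**PGA.** Percentage of loss/gain base pairs over the genome total, with
overlapping altered segments counted once. Copy-neutral LOH is excluded
by definition ("loss or gain base pairs"); an `include_cn_loh` option
exists for sensitivity analysis. PGA defaults to autosomes only (sex
chromosomes are dropped from the arm table); CNV-high/low is a strict
comparison of PGA against the cohort mean or a fixed threshold (the
published reference mean is 4.8%).

**Associations.** Arm-level events use two-sided Fisher tests with BH
adjustment; per-gene associations use the two-sided Wilcoxon rank-sum on
per-gene logR (length-weighted mean of overlapping segments — the
summarisation rule was open; length weighting is the natural choice),
exact for ≤ 25 samples, normal approximation beyond.

## Differential testing (shared engine)

All assays (expression, miRNA, methylation M-values, ChIP log-signal)
share one moderated two-group test: per-feature least-squares fit of
`value ~ grade (+ stratum)`, residual variances s² with d degrees of
freedom shrunk toward a prior, s̃² = (d₀·s₀² + d·s²)/(d₀ + d), moderated
t = β/(s̃·SE) on d₀ + d degrees of freedom. The prior (d₀, s₀²) is fit by
the method of moments on log s² (matching mean and variance of
log s² − ψ(d/2) + log(d/2) to the scaled-F model, with a Newton inversion
of the trigamma function); when the observed spread of log-variances does
not exceed the expected chi-square spread, d₀ = ∞ and the test uses the
pooled prior variance with normal tails. The implementation reproduces
the Bioconductor empirical-Bayes reference (t, p, d₀, s₀²) to ≲ 1e−4
relative on shared random data (cross-checked in the test suite via
Rscript).

Stratification by NF2 status is realised as an additive two-factor model
rather than separate per-stratum fits; this keeps one coefficient per
feature for the grade effect and is the default definition of the
signature (the union-vs-intersection question across strata is thereby
resolved by the additive model). Significance is BH-adjusted p < 0.05
throughout.

Batch adjustment is a per-feature location/scale transform (batch means
to the grand mean, batch SDs to the pooled SD). This is a simplified,
non-empirical-Bayes form of batch correction: with the few thousand
features used at desk scale the shrinkage across features that the full
model adds is not needed for calibration (verified by the
batch-plus-null simulation in the tests), and the synthetic generator
injects batch effects as exactly this kind of additive shift.

## Expression specifics

Quantile normalisation maps every sample onto the mean quantile vector
(ties receive the mean of their quantiles). The atypical signature is
all features at adjusted p < 0.05; PCA runs on the centred, unit-scaled
signature submatrix and grade separation is summarised by the silhouette
on the first two components. The grade classifier is a random forest on
the top 25 genes by adjusted p with 5,000 trees by default (the pipeline
uses 1,000 at desk scale), a fixed seed, and the out-of-bag error as its
internal accuracy estimate. Probe-level QC (zero-expressed proportion,
mean-intensity and RIN exclusions) is consumed as a precomputed
sample-inclusion decision in the sample sheet.

## miRNA networks

Counts (5p and 3p strands as distinct features, totals per library) are
normalised to log2(RPM + 1); the pseudocount of 1 anchors zero counts at
zero and is recorded here as a design choice. Regulatory edges require
target-prediction support in ≥ 3 of 6 databases (Miranda, miRBase,
MirTarget2, PicTar, TarBase, TargetScan — consumed as an evidence table;
database snapshots are inputs, not dependencies) *and* Spearman ρ < 0
with raw p < 0.05 over shared samples. Raw rather than adjusted p follows
the stated definition of "significant negative correlation"; an FDR
variant can be obtained by post-filtering the emitted edge list. The
negative-vs-positive target comparison counts significant correlations
per miRNA by sign and applies a paired one-sided Wilcoxon signed-rank
across miRNAs.

## Methylation

QC removes sites with missing values, SNP overlap, sex-chromosome
location, or detection-p > 0.05 in ≥ 50% of samples (counted under the
first failing rule). Differential sites are tested on M-values
(log2(β/(1−β)), β clipped to [0.01, 0.99]) because M-values stabilise
variance for the moderated test, while the effect-size gate stays on the
β scale: a call requires adjusted p < 0.05 **and** |Δ median β| > 0.1.
Testing on β directly is available by passing the β matrix to the shared
engine; the divergence (test scale vs effect scale) is deliberate and
documented here.

Consensus clustering draws 80% of samples without replacement per
iteration (1,000 iterations by default; the acceptance suite runs 200,
which the recovery checks show is already stable at desk scale), clusters
with average linkage on 1 − Pearson correlation, and defines
consensus[i,j] as co-cluster count over co-sampling count. Final labels
cluster the consensus matrix itself (average linkage on 1 − consensus).
Everything is driven by one seed.

The per-sample hypermethylation score is the fraction of QC-passing
sites with β exceeding the reference-group median by > 0.1; this is the
per-sample analogue of a group-level differential-site count, needed to
correlate hypermethylation with PGA per sample (both readings of the
quantity are effectively reported: the group-level count via
`diff_methylation`, the per-sample fraction via
`hypermeth_pga_correlation`).

Regulatory-domain enrichment re-implements the basal-plus-extension rule:
basal domain 5 kb upstream / 1 kb downstream of the TSS (strand-aware),
extended in each direction up to 1 Mb beyond the basal edge but never
into a neighbour's basal domain. A site hits a gene set iff it falls in
any member gene's domain; enrichment is the hypergeometric upper tail of
query hits against background hits, BH-adjusted across sets. Gene sets
are supplied as files (name + member genes + gene coordinates); no
external service or database content is bundled.

## ChIP and super-enhancers

Peaks (0-based half-open BED with reads-per-million signal and an input
control) are consumed from callers. Region signal is
max(0, ChIP − input). Peaks whose midpoint lies within ±2,000 bp of a TSS
are excluded entirely before stitching (the stricter of the two
historical behaviours; a flag can retain them), and remaining peaks merge
when gaps are ≤ 12,500 bp — stitching is idempotent by construction.

Super-enhancers are separated geometrically: regions sorted ascending by
signal, both rank and signal scaled to [0, 1], and the cutoff placed
where a line of slope 1 is tangent to the curve from below (the first
minimiser of scaled-signal − scaled-rank); regions with signal strictly
above the cutoff signal are super. A brute-force scan over all cutoff
candidates serves as the test oracle.

Differential binding reuses the shared moderated test on log2(signal+1)
per region — one differential engine across assays; a negative-binomial
count model is noted as future work. Nearest genes are assigned by TSS
distance to the region centre (the assignment rule was open).
Concordance requires region and nearest-gene adjusted p < 0.05 with
matching fold-change signs. Broad-mark (H3K27me3) analysis uses
fixed-width 10 kb bins and summarises the genome-wide direction as the
fraction of significant bins with positive fold change.

## TERT promoter screen

Offsets are signed base pairs from the TSS (negative = upstream). On the
minus strand upstream means larger coordinates, so position =
TSS − offset; the two printed hotspot pairs (−124 → chr5:1,295,228,
−146 → chr5:1,295,250) jointly force the TSS at chr5:1,295,104, which is
the packaged default. The recurrence report tabulates mutated/total by
recurrence status with percentages rounded half-up.

## Synthetic cohorts

The generator emulates the statistical structure of the real assays on a
reduced toy genome — 22 autosomes of 130 Mb with a 60 Mb p arm and 70 Mb
q arm — because the arm-fraction rules only need arm boundaries, not real
cytogenetics. Defaults (the study conditions): 20 atypical + 20 benign
samples, purity uniform on (0.5, 0.9), driver subgroups allocated
deterministically by largest remainder (atypical: 55% NF2, 20%
NF2/SMARCB1, 15% TRAF7/PI3K, 10% unknown; benign: 40% NF2 with the
remainder spread across TRAF7/PI3K, TRAF7/KLF4, Hedgehog, POLR2A and
unknown — NF2 loss dominant in atypical as in the disease), CNV-high
fractions 0.7 atypical / 0.2 benign, 14q-loss probabilities 0.6 / 0.1.
NF2-subgroup samples carry a chr22q loss; CNV-high samples add 1p, 10p,
10q and 6q losses (PGA ≈ 11.5–14% vs ≈ 0–2.4% for CNV-low, so the
cohort-mean status rule is recoverable).

Noise models: Gaussian on the log2 expression scale (SD 0.5) and on the
β scale (SD 0.05, clipped to [0, 1]); negative-binomial miRNA counts
(dispersion 20) around log-scale latents; log-normal ChIP signal noise.
Planted effects: 50 differential genes at |logFC| 2 (including EZH2 up),
a 28-member chr14q32 miRNA cluster at logFC −1 plus an extra −0.5 in
14q-lost samples, 13 up-regulated miRNAs, let-7c/d/e down with EZH2
anti-coupled to let-7c, 300 hypermethylated sites at Δβ 0.3 in the
CNV-high/NF2-SMARCB1 cluster (kept off chr1/14/22 so the masking
robustness check is meaningful) plus a 200-site block elevated in
proportion to PGA, five super-enhancer loci (three with a 4× atypical
multiplier whose nearest genes are planted up-regulated), and a +0.5 log2
global H3K27me3 shift in atypical samples. A batch effect is injected as
an additive +1 shift for the second batch, matching the simplified
correction downstream.

BAF simulation draws Binomial(depth, f)/depth at the admixture-weighted
allele fraction f = (p·b + (1−p))/(p·CN + 2(1−p)) with the imbalanced
allele chosen at random per SNP; SNP density is one per 250 kb at depth
500, giving ≈ 240–280 informative SNPs per whole-arm loss so purity
recovery is tight (±0.05).

What the generator does **not** emulate: read-level data, linkage
disequilibrium, probe chemistry (type I/II designs), realistic gene/CpG
coordinates, cell-type composition, and correlated noise across assays
beyond the planted couplings. Passing tests therefore demonstrate that
the algorithms recover planted structure under the stated noise models,
not that they would do so at real-data effect sizes and artefact rates.

## Problem sizes and numerical choices

Desk-scale defaults keep every test and the full pipeline comfortably
fast while preserving the statistical regime: 2,000 genes / 150 miRNAs /
2,000 CpGs / 60 enhancer loci / 300 broad bins; consensus clustering at
200 iterations in the acceptance checks (1,000 by default); the pipeline
random forest at 1,000 trees (5,000 at the function level). Calibration
and precision suites use 200 replicates.

Tie-breaks and degenerate inputs: quantile normalisation gives ties the
mean of their quantiles; the super-enhancer cutoff takes the first
minimiser on ties and calls nothing when all signals are equal;
zero-variance miRNAs are excluded from testing with a warning; samples
without qualifying loss segments fall back to a configured default
purity (0.7) in the pipeline; constant hypermethylation or PGA yields an
NA correlation with a warning; the CCF clamp is 1.05. All randomness in
the generator, consensus clustering and the random forest flows from
explicit seeds, and pipeline reruns with identical configs are
byte-identical (checksummed in the manifest).

## Known limitations

- The filter cascade consumes caller annotations; it cannot rescue
  variants a caller never emitted, and the strand-bias/MQ0 defaults are
  conventions rather than fitted values.
- The purity estimator assumes single-copy loss in the segments it uses;
  subclonal or multi-copy losses bias it downward.
- The additive stratified model estimates one shared grade effect across
  strata; strongly stratum-specific effects dilute.
- The negative-binomial option for ChIP differential counts is not
  implemented; the moderated test on log signal is used throughout.
- Cohort-scale published quantities (e.g. signature size 483, 67
  differential miRNAs, 19 concordant super-enhancers, relative risk 3.78)
  depend on the original per-sample data and are not reproduced at desk
  scale; the package reproduces the mechanics and the in-text worked
  examples (TERT coordinates and recurrence frequencies) exactly.
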