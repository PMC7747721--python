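# Methods

`ewaskit` implements the analysis chain of a two-cohort, case/control
EWAS on methylation arrays, followed by candidate-region genetics and
methylation-QTL modelling. This note records the models, the defaults
and the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Data model

Methylation is carried as beta values (methylated fraction, in [0, 1])
in probes × samples matrices. Probe annotation (chromosome, 1-based
coordinate, gene, gene feature, CpG-island relation, array membership)
follows the Illumina manifest convention; region spans are computed as
`max(pos) − min(pos)`, which reproduces printed spans such as 1546 bp
for a 4-CpG gene-body region and 211 bp for a 5-CpG promoter region.
Multi-gene annotations (";"-separated) are grouped by the first listed
gene. Genotypes are unphased biallelic minor-allele dosages (0/1/2,
−1 missing) read from and written to PLINK text PED/MAP.

## Probe filtering and harmonisation

A probe is removed if its detection P-value exceeds 0.01 (by default in
*any* sample; a sample-fraction rule is available since array pipelines
differ on this point), if its beadcount is below 3 in at least 5% of
samples, if it is flagged non-CpG / SNP-overlapping / cross-hybridising,
or if it maps to a sex chromosome. Removals are attributed to the first
triggering rule so the report's counts partition the input exactly.
Cross-array harmonisation intersects the two cohorts' probe sets (the
older array's probes are a subset of the newer array's).

**Batch screening.** The probe-centred matrix is decomposed by SVD; each
retained right-singular vector (one score per sample, default 5
components) is tested against each covariate — Kruskal–Wallis for
categorical (slide, cohort, group), Pearson correlation for numeric.
A batch effect is "significant" when any component associates with the
batch label at small p.

**Batch adjustment** is the parametric empirical-Bayes location/scale
model: each probe is standardised against a design holding batch
indicators plus protected biological covariates (group), per-batch means
and variances are shrunk toward pooled priors (normal prior on means,
inverse-gamma on variances, hyperparameters by method of moments,
posterior equations iterated to relative change < 1e-6), and the matrix
is reconstructed. The adjustment operates on logit-transformed betas
(clipped at 1e-6) and maps back through the logistic function, which
preserves the [0, 1] range without truncation. The implementation was
cross-checked against the reference R implementation (`sva::ComBat`) on
a shared fixture; agreement is < 0.01 on the logit scale, the residual
coming from the reference's looser EB convergence tolerance. Note what
the EB model does *not* promise: it removes the systematic batch shift,
but roughly half of the per-probe batch-mean *sampling noise* survives
shrinkage, so post-adjustment batch-mean gaps are small but not zero.

## Differential methylation

Per-CpG tests are two-sided Welch t-tests on the beta scale (effects are
reported and thresholded as beta differences; testing on the same scale
keeps the two criteria commensurable), pairwise-complete over missing
cells, with Benjamini–Hochberg q-values over all tested probes. Because
small cohorts rarely yield FDR-significant CpGs, DMP selection is the
joint rule: unadjusted p < 0.05 **and** |Δβ| ≥ 0.10. Both thresholds are
configurable.

**DMR grouping** ships in two modes because gene-level published tables
and the strict distance rule genuinely disagree in practice:

* `gene` (default): group selected DMPs by gene key; ≥ 2 members with a
  common delta sign form a region regardless of gaps. Mixed-sign gene
  groups are split into per-sign subgroups, each of which must reach the
  member minimum on its own — this preserves the consistent-direction
  requirement while matching gene-level counting. A consequence worth
  noting: a gene whose two selected CpGs disagree in sign yields no
  region in this implementation.
* `strict-distance`: within a gene (or a chromosome, for unannotated
  probes), chain CpGs whose adjacent gaps are < 1500 bp with consistent
  direction; maximal chains of ≥ 2 are regions. A property test checks
  this against a brute-force chain oracle.

Unannotated (intergenic) DMPs are always chained by distance with
synthetic `chrom:start` region keys. The index (tagging) CpG of a region
is the member with the smallest p, ties broken by larger |Δβ|, then
lower coordinate. Region coherence is summarised by the minimum pairwise
Pearson correlation across samples (flag threshold 0.85).

## Replication and the combined scan

DMPs replicate by probe-id intersection with sign agreement; DMRs by
region key plus direction. The combined-cohort region scan pools the
harmonised, batch-adjusted cohorts (cohort is a batch label upstream)
and re-tests every CpG of a target gene or interval against
direction-aware thresholds (default: Δβ ≤ −0.05 and p < 0.005 for a
hypomethylation scan — ">5% hypomethylation" is read as a beta-scale
case−control difference below −0.05).

## Genetics

Sample QC drops call rate < 95%; variant QC drops call rate < 98%,
MAF < 0.05, and Hardy–Weinberg exact p < 1e-5 — a p exactly at the
threshold is kept, since the criterion is *significant deviation*. HWE
is computed in controls only by default (configurable), the standard
choice since cases may carry true association signal. The HWE test is
the exact conditional test (probability of the heterozygote count given
allele counts, summed over outcomes no more likely than observed),
computed by the numerically stable recurrence; a seeded permutation
variant is provided. Allele association is the two-sided Fisher exact
test by hypergeometric enumeration; odds ratios are oriented as odds of
the minor allele in cases, with a 0.5 continuity correction only when a
cell is zero. A dominant "carrier" table (≥ 1 risk allele vs none) is
emitted alongside the allele table.

Two-locus LD is estimated from unphased genotypes by EM over the four
haplotype frequencies; only double heterozygotes are phase-ambiguous.
The EM is initialised from the composite-LD (Burrows) covariance — an
equilibrium start is a saddle point of the EM map whenever all ambiguity
sits in double heterozygotes — and the log-likelihood is asserted
non-decreasing. D′ confidence intervals come from the normalised
likelihood profile over a 101-point D′ grid with allele frequencies held
at their MLEs (5th/95th percentiles). Haplotype blocks use the
confidence-interval rules: a pair is strong LD if its CI is
[≥ 0.70, ≥ 0.98], strong recombination if the upper bound is < 0.90; a
block is a maximal span whose outermost pair is strong LD and ≥ 95% of
informative inner pairs are strong LD, chosen greedily longest-first
(bp length) without overlap. All four thresholds are configurable.

## mQTL models

Methylation-by-genotype comparisons are run both on the three genotype
classes and on the dominant carrier coding, with one-way ANOVA (plus a
Welch t-test in the two-class case). Classes with < 2 samples are
flagged rather than silently dropped. The joint model is a logistic
regression of case status on the SNP coding and the CpG beta
(statsmodels maximum-likelihood Newton fit; the CpG predictor is
z-scored by default for coefficient comparability). Non-convergence and
quasi-separation (any |coefficient| > 15) are flagged in the result,
never silently ignored. Complete-case analysis throughout.

## Synthetic data

The generator draws, for each probe, a baseline beta (uniform 0.10–0.90
for background probes; planted CpGs get baselines leaving room for their
effect), maps it to the logit scale, adds a group effect at planted DMR
CpGs, a per-slide batch offset and Gaussian noise, and maps back through
the logistic. Two calibrations matter:

* the planted logit offset is solved numerically (Gauss–Hermite
  quadrature + root finding) so the *expected beta-scale* case−control
  difference equals the requested Δ — the noise smooths the logistic, so
  a naive logit difference would understate the effect;
* the default noise (`noise_sd = 0.55`, ≈ 0.12 beta-scale SD at
  mid-range baselines) gives a Δ = 0.10 effect roughly 50–80% per-CpG
  power at 23 vs 16 samples — the regime where no CpG survives FDR
  control and the joint p/Δ rule is the operative selector. A
  consequence: an 0.08 effect cannot reach p < 0.005 at pooled desk
  scale under this default; the pooled-region tests therefore plant
  their region with `noise_sd = 0.20` (≈ 0.04 beta-scale SD), the
  tighter precision typical of a coherent promoter region.

Genotypes are drawn per group at declared MAFs under Hardy–Weinberg
equilibrium (a `violate_hwe` knob plants excess homozygosity for QC
tests). LD blocks copy a latent block haplotype with probability D′ (so
a target of 1.0 copies exactly); the focal SNP's frequency differs
between cases (0.40) and controls (0.13), sizing the carrier odds ratio
near 5. Risk-allele carriers are shifted by a configurable amount
(default −0.10) at a tagged CpG, creating the mQTL. Default cohort
sizes are 23/16 (discovery, 450K-subset probes) and 12/12 (validation,
full probe set).

What the generator does **not** emulate: bimodal genome-wide beta
distributions, probe-type (Infinium I/II) chemistry bias, cell-type
composition effects, correlated background probes, or idat-level
intensities. Passing tests therefore demonstrate the algorithms'
correctness and calibration under the stated noise model, not
performance on raw array data.

## Problem sizes and determinism

Monte-Carlo tests use fixed seed lists (50 seeds for the batch-screen
and end-to-end replication properties; 600-probe cohorts for the
end-to-end runs; 5000 probes for the null-calibration check). The
exact-test oracle checks run exhaustively over all genotype tables with
n ≤ 50 (Hardy–Weinberg) and all 2×2 tables with grand total ≤ 30 plus
2000 seeded random tables with margins up to 60 (Fisher), against
independent factorial / hypergeometric enumeration oracles. Every
generator is a pure function of (design, seed); pipeline outputs embed a
hash of the scientific configuration so identical configurations produce
byte-identical tables.

## Known limitations

* Covariate-adjusted (age/sex) differential methylation models are out
  of scope; the cohorts are assumed matched.
* The moderated-variance (empirical-Bayes) test variant is not the
  default; Welch is, because thresholds act on the beta scale.
* The D′ CI is a profile-likelihood approximation with allele
  frequencies fixed at their MLEs, as in the conventional block-calling
  software; it narrows too quickly for very rare haplotypes.
* Two-locus EM only; no multi-marker phasing.
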