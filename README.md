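# ewaskit

A toolkit for small-cohort, two-cohort case/control EWAS on Illumina
methylation arrays (450K/EPIC beta values), with candidate-region
genetics and methylation-QTL modelling. It was built around the analysis
pattern of a progressive multiple-sclerosis CD4⁺ T-cell methylation
study — two small cohorts on different array generations, harmonised,
screened for differentially methylated regions, replicated across
cohorts, and followed up with haplotype-block and mQTL analysis — but
every stage is a general, configurable operation.

Intended users: epigenomics analysts who start from beta-value matrices
(not idats) and need a tested, scriptable pipeline for the
underpowered-cohort regime where FDR control yields nothing and
selection must combine unadjusted significance with effect size.

## What it computes

For each CpG with case mean β̄₁ and control mean β̄₀:

* **Δβ = β̄₁ − β̄₀**, two-sided Welch t-test p, BH q-value;
* **DMP selection**: keep a CpG iff p < 0.05 **and** |Δβ| ≥ 0.10;
* **DMR grouping**: ≥ 2 selected CpGs on the same gene with a common
  direction (gene mode), or chained at < 1500 bp gaps (strict-distance
  mode);
* **replication**: probe- and region-level intersection across cohorts
  with sign consistency, plus a pooled-cohort per-region re-scan;
* **harmonisation**: probe filtering (detection P > 0.01, beadcount < 3
  in ≥ 5% of samples, flagged probes, XY), SVD batch screening, and
  parametric empirical-Bayes (ComBat-style) batch adjustment on the
  logit scale;
* **genetics**: PLINK PED/MAP I/O, call-rate/MAF/Hardy–Weinberg-exact
  variant QC, two-sided Fisher allele and carrier association with odds
  ratios, two-locus EM haplotype frequencies with D′/r² and
  likelihood-profile D′ CIs, and Gabriel-style confidence-interval
  haplotype blocks;
* **mQTL**: methylation-by-genotype ANOVA (genotype and carrier
  codings) and a joint logistic model of phenotype on SNP + CpG,
  flagging separation and non-convergence.

A synthetic-data module generates full study bundles (two cohorts,
manifests, sample sheets, genotypes with planted LD blocks and a planted
mQTL) as pure functions of a design and a seed, so the entire pipeline
is testable offline. See `docs/methods.md` for models, defaults and
numerical details.

## Worked example

The package ships the two published cohort tables as typed fixtures.
Grouping the 24 discovery-cohort CpGs and intersecting with the
validation cohort:

```python
from ewaskit import dmr, replication, tables

disc = dmr.call_dmrs(tables.discovery_dmr_cpgs(), mode="gene")
valid = dmr.call_dmrs(tables.validation_dmr_cpgs(), mode="gene")
print(f"discovery regions: {len(disc)}")
for d in sorted(disc, key=lambda d: -d.n_cpgs):
    print(f"  {d.region_key:8s} {d.direction:5s} {d.n_cpgs} CpGs "
          f"span {d.span_bp} bp  max|d|={d.max_abs_delta:.2f}  index={d.index_cpg}")
pairs = replication.intersect_dmrs(disc, valid)
print("replicated in both cohorts, same direction:",
      ", ".join(a.region_key for a, _ in pairs))
```

prints

```
discovery regions: 9
  MDGA1    hyper 4 CpGs span 1546 bp  max|d|=0.18  index=cg14926196
  HTR2A    hypo  3 CpGs span 143 bp  max|d|=0.16  index=cg23881368
  IGF2BP1  hypo  3 CpGs span 657 bp  max|d|=0.11  index=cg18128536
  SLC17A9  hyper 3 CpGs span 315 bp  max|d|=0.17  index=cg19142181
  ZNF714   hyper 2 CpGs span 57 bp  max|d|=0.20  index=cg09352518
  HDAC4    hypo  2 CpGs span 64 bp  max|d|=0.12  index=cg07673080
  CERK     hyper 2 CpGs span 87 bp  max|d|=0.20  index=cg16154810
  POU6F2   hypo  2 CpGs span 266 bp  max|d|=0.14  index=cg20302533
  PTPRN2   hyper 2 CpGs span 639929 bp  max|d|=0.11  index=cg23299919
replicated in both cohorts, same direction: HTR2A, HDAC4, SLC17A9
```

Nine discovery regions; the largest (MDGA1) has four gene-body CpGs in a
1546 bp window with up to 18% hypermethylation in cases; three regions
(HTR2A hypomethylated, HDAC4 hypomethylated, SLC17A9 hypermethylated)
replicate across cohorts with consistent direction. The promoter
(HTR2A) region in the validation cohort spans 5 CpGs within 211 bp.
Note PTPRN2: in gene mode the rule keeps same-sign gene groups
regardless of gaps, hence its wide span — strict-distance mode splits
it.

## Command line

```sh
ewaskit simulate --seed 1 --outdir sim          # synthetic study bundle
ewaskit harmonize sim/discovery --out disc.tsv  # probe filtering
ewaskit dmp sim/discovery --out dmps.tsv        # per-CpG stats + selection
ewaskit dmr dmps.tsv --out dmrs.tsv             # region grouping
ewaskit blocks sim/genotypes.ped sim/genotypes.map --region 13:47400677-47477087
ewaskit run-all --seed 1 --outdir run           # full pipeline
```

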