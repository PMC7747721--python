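"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a two-cohort methylation case/control study:

* beta values arise from a per-probe baseline on the logit scale plus a
  group effect at planted DMR CpGs, a per-slide batch offset and
  Gaussian logit-scale noise, mapped through the logistic function (so
  every value lands in (0, 1) without truncation);
* the planted group effect is calibrated numerically so the *expected*
  case-minus-control difference on the beta scale equals the requested
  delta despite the nonlinearity;
* genotypes are drawn per group at stated minor-allele frequencies
  under Hardy-Weinberg equilibrium, with block-wise LD built by copying
  a latent block haplotype, and an optional methylation shift applied to
  risk-allele carriers at a tagged CpG.

Defaults mirror a small progressive-MS CD4+ T-cell study design:
discovery cohort 23 cases / 16 controls on a 450K-subset array,
validation cohort 12 / 12 on the EPIC superset, planted effect sizes
|delta| 0.10-0.20, and noise giving roughly 50-80% per-CpG power at
delta = 0.10 in the discovery cohort.

All generators are pure functions of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ewaskit.data_io import GenotypeData, validate_beta

_AUTOSOMES = [str(c) for c in range(1, 23)]


@dataclass(frozen=True)
class PlantedDMR:
    gene: str
    chrom: str
    start_pos: int
    n_cpgs: int
    spacing_bp: int
    delta: float
    feature: str = "TSS1500"
    cgi_relation: str = "OpenSea"

    def __post_init__(self) -> None:
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs >= 1")
        if abs(self.delta) > 0.5:
            raise ValueError("|delta| <= 0.5")
        if self.spacing_bp < 2:
            raise ValueError("spacing_bp >= 2")

    @property
    def positions(self) -> list[int]:
        return [self.start_pos + k * self.spacing_bp for k in range(self.n_cpgs)]


@dataclass(frozen=True)
class CohortDesign:
    n_case: int = 23
    n_control: int = 16
    n_probes: int = 5000
    cohort: str = "discovery"
    planted_dmrs: tuple[PlantedDMR, ...] = ()
    n_batches: int = 2
    batch_shift: float = 0.0        # logit-scale slide offset (slide k: k * shift)
    noise_sd: float = 0.55          # logit-scale residual SD
    frac_epic_only: float = 0.2     # probes absent from the 450K subset
    seed: int = 0


@dataclass(frozen=True)
class LDBlock:
    n_snps: int
    d_prime: float = 1.0
    maf: float | None = None        # block latent-allele frequency; None -> drawn


@dataclass(frozen=True)
class MQTLDesign:
    snp_id: str = "rs_focal"
    risk_allele: str = "C"
    other_allele: str = "T"
    maf_case: float = 0.40
    maf_control: float = 0.13
    carrier_methylation_shift: float = -0.10
    tagged_cpg: str = ""
    chrom: str = "13"
    region_start: int = 47_400_677
    region_end: int = 47_477_087
    blocks: tuple[LDBlock, ...] = (LDBlock(4), LDBlock(5), LDBlock(4))
    focal_block: int = 1            # index of the block containing the focal SNP
    violate_hwe: float = 0.0        # excess-homozygosity mixing weight, for QC tests
    seed: int = 0

    def __post_init__(self) -> None:
        for maf in (self.maf_case, self.maf_control):
            if not 0 < maf < 0.5:
                raise ValueError("declared MAF must be in (0, 0.5)")
        if abs(self.carrier_methylation_shift) > 0.5:
            raise ValueError("|carrier_methylation_shift| <= 0.5")


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def generate_manifest(design: CohortDesign) -> pd.DataFrame:
    """Probe manifest with planted DMR CpGs at deterministic coordinates."""
    rng = np.random.default_rng(design.seed)
    taken: dict[tuple[str, int], str] = {}
    rows = []
    for dmr in design.planted_dmrs:
        for pos in dmr.positions:
            key = (dmr.chrom, pos)
            if key in taken:
                raise ValueError(
                    f"planted regions overlap at {dmr.chrom}:{pos} "
                    f"({taken[key]} vs {dmr.gene})"
                )
            pid = f"cgP{len(rows):06d}"
            taken[key] = dmr.gene
            rows.append(
                {
                    "probe_id": pid,
                    "chrom": dmr.chrom,
                    "pos": pos,
                    "gene": dmr.gene,
                    "feature": dmr.feature,
                    "cgi_relation": dmr.cgi_relation,
                    "planted": True,
                }
            )
    n_background = design.n_probes - len(rows)
    if n_background < 0:
        raise ValueError("n_probes smaller than the number of planted CpGs")
    chroms = rng.choice(_AUTOSOMES, size=n_background)
    positions = rng.integers(10_000, 200_000_000, size=n_background)
    has_gene = rng.random(n_background) < 0.5
    features = rng.choice(["TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR"],
                          size=n_background)
    cgis = rng.choice(["Island", "Shore", "Shelf", "OpenSea"], size=n_background)
    for i in range(n_background):
        rows.append(
            {
                "probe_id": f"cgB{i:06d}",
                "chrom": str(chroms[i]),
                "pos": int(positions[i]),
                "gene": f"GENE{i % max(1, n_background // 3)}" if has_gene[i] else "",
                "feature": features[i] if has_gene[i] else "intergenic",
                "cgi_relation": cgis[i],
                "planted": False,
            }
        )
    manifest = pd.DataFrame(rows).set_index("probe_id")
    on_450k = rng.random(len(manifest)) >= design.frac_epic_only
    manifest["on_450k"] = on_450k
    manifest["on_epic"] = True
    return manifest


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(31)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _smoothed_logistic(mu: float, sd: float) -> float:
    """E[logistic(mu + sd*Z)] by Gauss-Hermite quadrature."""
    return float(_GH_WEIGHTS @ (1.0 / (1.0 + np.exp(-(mu + sd * _GH_NODES)))))


def calibrated_delta_logit(baseline_beta: float, delta: float, noise_sd: float) -> float:
    """Logit-scale group offset whose expected beta-scale effect is ``delta``.

    Solves E[logistic(mu + d + eps)] - E[logistic(mu + eps)] = delta for d,
    eps ~ N(0, noise_sd); the smoothing of the logistic by the noise makes
    the naive logit-difference biased toward zero.
    """
    if delta == 0:
        return 0.0
    mu = float(np.log(baseline_beta / (1 - baseline_beta)))
    base = _smoothed_logistic(mu, noise_sd)
    target = base + delta
    if not 0.001 < target < 0.999:
        raise ValueError(f"delta {delta} infeasible at baseline {baseline_beta}")

    def f(d: float) -> float:
        return _smoothed_logistic(mu + d, noise_sd) - target

    return float(optimize.brentq(f, -15.0, 15.0, xtol=1e-10))


def generate_cohort(
    manifest: pd.DataFrame, design: CohortDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beta matrix and sample sheet for one cohort.

    Baselines are drawn per probe; planted CpGs get baselines that leave
    room for the planted effect. Samples are interleaved across slides
    so batch is not confounded with group.
    """
    missing = [
        pos
        for dmr in design.planted_dmrs
        for pos in dmr.positions
        if not ((manifest["chrom"] == dmr.chrom) & (manifest["pos"] == pos)).any()
    ]
    if missing:
        raise ValueError(f"manifest lacks planted CpG positions {missing[:3]}")

    rng = np.random.default_rng(design.seed + 1)
    n_probes = len(manifest)
    n = design.n_case + design.n_control

    sample_ids = [f"{design.cohort}_case_{i:02d}" for i in range(design.n_case)] + [
        f"{design.cohort}_ctrl_{i:02d}" for i in range(design.n_control)
    ]
    group = np.array(["case"] * design.n_case + ["control"] * design.n_control)
    # interleave slides so batch is never confounded with group; prefix the
    # cohort so slide labels stay unique after pooling cohorts
    batch = np.array(
        [f"{design.cohort}_slide{(i % design.n_batches) + 1}" for i in range(n)]
    )

    baseline = rng.uniform(0.10, 0.90, size=n_probes)
    delta_by_probe = np.zeros(n_probes)
    probe_pos = manifest["pos"].to_numpy()
    probe_chrom = manifest["chrom"].to_numpy()
    for dmr in design.planted_dmrs:
        for pos in dmr.positions:
            idx = np.flatnonzero((probe_chrom == dmr.chrom) & (probe_pos == pos))[0]
            lo, hi = (0.15, 0.75 - dmr.delta) if dmr.delta > 0 else (0.25 - dmr.delta, 0.85)
            baseline[idx] = rng.uniform(lo, hi)
            delta_by_probe[idx] = dmr.delta

    mu = np.log(baseline / (1 - baseline))
    delta_logit = np.zeros(n_probes)
    for idx in np.flatnonzero(delta_by_probe):
        delta_logit[idx] = calibrated_delta_logit(
            baseline[idx], delta_by_probe[idx], design.noise_sd
        )

    is_case = (group == "case").astype(float)
    slide_index = np.array([int(b.rsplit("slide", 1)[1]) - 1 for b in batch], dtype=float)
    logits = (
        mu[:, None]
        + delta_logit[:, None] * is_case[None, :]
        + design.batch_shift * slide_index[None, :]
        + rng.normal(0.0, design.noise_sd, size=(n_probes, n))
    )
    beta = pd.DataFrame(
        1.0 / (1.0 + np.exp(-logits)), index=manifest.index, columns=sample_ids
    )

    sheet = pd.DataFrame(
        {
            "group": group,
            "cohort": design.cohort,
            "batch": batch,
            "age": np.round(rng.normal(58.5, 9.0, size=n), 1),
            "sex": "F",
            "edss": np.where(group == "case", np.round(rng.normal(6.4, 1.2, n), 1), np.nan),
            "disease_duration": np.where(
                group == "case", np.round(rng.normal(25.0, 11.0, n), 1), np.nan
            ),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return validate_beta(beta), sheet


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _draw_genotypes(rng, freq: float, n: int, violate_hwe: float = 0.0) -> np.ndarray:
    """Minor-allele dosages under HWE, optionally mixed with pure homozygosity."""
    hap1 = rng.random(n) < freq
    hap2 = rng.random(n) < freq
    g = (hap1.astype(np.int8) + hap2.astype(np.int8))
    if violate_hwe > 0:
        # a fraction of samples drawn fully homozygous (excess F)
        forced = rng.random(n) < violate_hwe
        hom = (rng.random(n) < freq).astype(np.int8) * 2
        g = np.where(forced, hom, g)
    return g


def generate_genotypes(
    mqtl: MQTLDesign, sheet: pd.DataFrame, beta: pd.DataFrame
) -> tuple[GenotypeData, pd.DataFrame]:
    """SNP panel with block LD plus a genotype-coupled methylation shift.

    Returns the genotype data and a copy of ``beta`` where risk-allele
    carriers are shifted by ``carrier_methylation_shift`` at the tagged
    CpG. The focal SNP's allele frequency differs between cases and
    controls; every other SNP is frequency-matched across groups.
    """
    if mqtl.tagged_cpg and mqtl.tagged_cpg not in beta.index:
        raise ValueError(f"tagged CpG {mqtl.tagged_cpg!r} absent from beta matrix")
    rng = np.random.default_rng(mqtl.seed + 2)
    samples = list(sheet.index)
    n = len(samples)
    is_case = (sheet["group"] == "case").to_numpy()

    n_snps = sum(b.n_snps for b in mqtl.blocks)
    positions = np.sort(
        rng.choice(np.arange(mqtl.region_start, mqtl.region_end + 1), n_snps, replace=False)
    )

    geno = np.zeros((n, n_snps), dtype=np.int8)
    snp_rows = []
    focal_dosage = None
    j = 0
    allele_pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    for b_idx, block in enumerate(mqtl.blocks):
        if b_idx == mqtl.focal_block:
            # latent block haplotypes at per-group risk-allele frequency
            lat1 = np.where(is_case, rng.random(n) < mqtl.maf_case,
                            rng.random(n) < mqtl.maf_control)
            lat2 = np.where(is_case, rng.random(n) < mqtl.maf_case,
                            rng.random(n) < mqtl.maf_control)
        else:
            f = block.maf if block.maf is not None else rng.uniform(0.15, 0.45)
            lat1 = rng.random(n) < f
            lat2 = rng.random(n) < f
        f_indep = block.maf if block.maf is not None else 0.3
        for s in range(block.n_snps):
            focal = b_idx == mqtl.focal_block and s == block.n_snps // 2
            if block.d_prime >= 1.0 or focal:
                h1, h2 = lat1, lat2
            else:
                copy1 = rng.random(n) < block.d_prime
                copy2 = rng.random(n) < block.d_prime
                h1 = np.where(copy1, lat1, rng.random(n) < f_indep)
                h2 = np.where(copy2, lat2, rng.random(n) < f_indep)
            dosage = h1.astype(np.int8) + h2.astype(np.int8)
            if mqtl.violate_hwe > 0 and not focal:
                forced = rng.random(n) < mqtl.violate_hwe
                hom = (rng.random(n) < f_indep).astype(np.int8) * 2
                dosage = np.where(forced, hom, dosage).astype(np.int8)
            if focal:
                snp_id = mqtl.snp_id
                var_allele, ref_allele = mqtl.risk_allele, mqtl.other_allele
                focal_dosage = dosage
            else:
                snp_id = f"rs_b{b_idx}_{s}"
                var_allele, ref_allele = allele_pairs[j % len(allele_pairs)]
            # orient coding to the observed minor allele
            if dosage.sum() > n:  # variant allele is the major one here
                dosage = (2 - dosage).astype(np.int8)
                var_allele, ref_allele = ref_allele, var_allele
            geno[:, j] = dosage
            snp_rows.append(
                {
                    "snp_id": snp_id,
                    "chrom": mqtl.chrom,
                    "pos": int(positions[j]),
                    "allele1": var_allele,
                    "allele2": ref_allele,
                }
            )
            j += 1

    snps = pd.DataFrame(snp_rows).set_index("snp_id")
    pheno = pd.Series(np.where(is_case, "2", "1"), index=samples, name="phenotype")
    g = GenotypeData(sample_ids=samples, snps=snps, genotypes=geno, phenotypes=pheno)

    beta_out = beta.copy()
    if mqtl.tagged_cpg and focal_dosage is not None:
        carrier = focal_dosage >= 1
        shifted = beta_out.loc[mqtl.tagged_cpg].to_numpy() + np.where(
            carrier, mqtl.carrier_methylation_shift, 0.0
        )
        beta_out.loc[mqtl.tagged_cpg] = np.clip(shifted, 0.01, 0.99)
    return g, beta_out
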