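"""SNP QC, allele association, LD statistics and haplotype blocks.

Implements the classical single-marker toolbox used around a candidate
region:

* sample / variant QC on call rate, minor-allele frequency and the
  Hardy-Weinberg exact test (conditional test of heterozygote counts
  given allele counts, computed by the stable recurrence; a permutation
  variant is available behind a seed);
* two-sided Fisher exact allele-frequency tests by hypergeometric
  enumeration, with the odds ratio oriented as odds of the minor allele
  in cases and a 0.5 continuity correction only when a cell is zero;
* two-locus haplotype frequency estimation from unphased genotypes by
  EM (the double-heterozygote phase resolved iteratively to maximum
  likelihood), yielding D, D' and r^2, with a likelihood-profile
  confidence interval for D';
* haplotype-block detection with confidence-interval (Gabriel-style)
  rules: a pair is "strong LD" when the D' CI is [>= 0.70, >= 0.98] and
  "strong recombination" when the CI upper bound is < 0.90; a block is
  a maximal span whose outermost pair is strong LD and at least 95% of
  informative inner pairs are strong LD, taken greedily longest-first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ewaskit.data_io import MISSING, GenotypeData

GABRIEL_CI_LOW = 0.70
GABRIEL_CI_HIGH = 0.98
GABRIEL_RECOMB_HIGH = 0.90
GABRIEL_INFORMATIVE_FRAC = 0.95


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    P-value is the summed probability of all heterozygote counts no more
    likely than the observed one, conditional on the allele counts.
    Symmetric under swapping the two homozygote counts.
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    rare = 2 * min(n_aa_hom, n_bb_hom) + n_het  # copies of the rarer allele

    # probabilities over all het counts with the same parity as `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(len(hets))
    # start from the largest possible het count and recurse downward:
    # P(h-2)/P(h) = h*(h-1) / (4*(hom_r+1)*(hom_c+1))
    idx = len(hets) - 1
    probs[idx] = 1.0
    for i in range(idx, 0, -1):
        h = hets[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    probs /= probs.sum()

    obs = probs[np.searchsorted(hets, n_het)]
    p = probs[probs <= obs * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def hwe_permutation(
    n_aa_hom: int, n_het: int, n_bb_hom: int, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Permutation analogue: shuffle allele copies into pairs and compare.

    Extremeness is ordered by the exact conditional probability of the
    resulting heterozygote count, so the test targets the same
    alternative as :func:`hwe_exact`.
    """
    n = n_aa_hom + n_het + n_bb_hom
    rare = 2 * min(n_aa_hom, n_bb_hom) + n_het
    alleles = np.array([1] * rare + [0] * (2 * n - rare), dtype=np.int8)
    rng = np.random.default_rng(seed)

    def log_prob(h: int) -> float:
        # conditional probability up to a shared constant
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        from math import lgamma

        return (
            h * np.log(2.0)
            - lgamma(hom_r + 1)
            - lgamma(h + 1)
            - lgamma(hom_c + 1)
        )

    obs_lp = log_prob(n_het)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(alleles)
        h = int(np.sum(alleles[0::2] != alleles[1::2]))
        if log_prob(h) <= obs_lp + 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def snp_sample_qc(
    g: GenotypeData, sample_callrate_min: float = 0.95
) -> tuple[GenotypeData, pd.DataFrame]:
    """Drop samples whose genotype call rate falls below the threshold."""
    call_rate = (g.genotypes != MISSING).mean(axis=1)
    keep = call_rate >= sample_callrate_min
    if not keep.any():
        raise ValueError("sample QC removed every sample")
    report = pd.DataFrame(
        {"call_rate": call_rate, "kept": keep},
        index=pd.Index(g.sample_ids, name="sample_id"),
    )
    return g.subset_samples(keep), report


def snp_variant_qc(
    g: GenotypeData,
    sheet: pd.DataFrame | None = None,
    callrate_min: float = 0.98,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-5,
    hwe_in: str = "controls",
) -> tuple[GenotypeData, pd.DataFrame]:
    """Per-variant QC on call rate, MAF and Hardy-Weinberg deviation.

    A SNP is kept iff call rate >= ``callrate_min``, MAF >= ``maf_min``
    and HWE exact p >= ``hwe_p_min`` (a p exactly at the threshold is
    kept: "significant deviation" means strictly below). By default HWE
    is evaluated in controls only; pass ``hwe_in="all"`` to use every
    sample, or provide ``sheet`` with a ``group`` column to identify
    controls (falls back to PED phenotype "1" = control).
    """
    if hwe_in not in ("controls", "all"):
        raise ValueError("hwe_in must be 'controls' or 'all'")
    obs = g.genotypes != MISSING
    call_rate = obs.mean(axis=0)
    minor = np.where(obs, g.genotypes, 0).sum(axis=0)
    total = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, minor / total, 0.0)
    maf = np.minimum(maf, 1 - maf)

    if hwe_in == "controls":
        if sheet is not None:
            ctrl = sheet.loc[g.sample_ids, "group"].to_numpy() == "control"
        elif g.phenotypes is not None:
            ctrl = g.phenotypes.to_numpy() == "1"
        else:
            ctrl = np.ones(g.n_samples, dtype=bool)
    else:
        ctrl = np.ones(g.n_samples, dtype=bool)
    if not ctrl.any():
        ctrl = np.ones(g.n_samples, dtype=bool)

    hwe_p = np.ones(g.n_snps)
    sub = g.genotypes[ctrl]
    for j in range(g.n_snps):
        col = sub[:, j]
        col = col[col != MISSING]
        if len(col):
            hwe_p[j] = hwe_exact(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )

    fail_reasons = []
    for j in range(g.n_snps):
        reasons = []
        if call_rate[j] < callrate_min:
            reasons.append("call_rate")
        if maf[j] < maf_min:
            reasons.append("maf")
        if hwe_p[j] < hwe_p_min:
            reasons.append("hwe")
        fail_reasons.append(",".join(reasons))
    kept = np.array([r == "" for r in fail_reasons])
    report = pd.DataFrame(
        {
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "kept": kept,
            "fail_reasons": fail_reasons,
        },
        index=g.snps.index,
    )
    return g.subset_snps(np.flatnonzero(kept)), report


def extract_region(
    g: GenotypeData, chrom: str, start: int, end: int
) -> GenotypeData:
    """Inclusive-interval filter on SNP position."""
    mask = (
        (g.snps["chrom"].astype(str) == str(chrom))
        & (g.snps["pos"] >= start)
        & (g.snps["pos"] <= end)
    ).to_numpy()
    if not mask.any():
        raise ValueError(f"no SNPs in {chrom}:{start}-{end}")
    return g.subset_snps(np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Fisher allele association
# ---------------------------------------------------------------------------


def fisher_exact_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of every table (same margins) whose
    probability does not exceed the observed one.
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


@dataclass
class AlleleAssocResult:
    snp_id: str
    contingency: np.ndarray        # rows: case/control; cols: minor/major allele
    odds_ratio: float
    fisher_p: float
    carrier_contingency: np.ndarray  # rows: case/control; cols: carrier/non-carrier
    carrier_odds_ratio: float
    carrier_fisher_p: float


def _oriented_or(a: float, b: float, c: float, d: float) -> float:
    """(a*d)/(b*c) with a 0.5 continuity correction iff any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def allele_assoc(
    g: GenotypeData, sheet: pd.DataFrame, snp_id: str
) -> AlleleAssocResult:
    """Allele-count and carrier-count case/control association for one SNP."""
    dosage = g.column(snp_id)
    groups = sheet.loc[g.sample_ids, "group"].to_numpy()
    obs = dosage != MISSING
    for label in ("case", "control"):
        if not obs[groups == label].any():
            raise ValueError(f"SNP {snp_id!r} entirely missing in {label} group")

    case, ctrl = obs & (groups == "case"), obs & (groups == "control")
    a = int(dosage[case].sum())                  # minor alleles in cases
    b = int(2 * case.sum() - a)
    c = int(dosage[ctrl].sum())
    d = int(2 * ctrl.sum() - c)
    table = np.array([[a, b], [c, d]])

    carrier = dosage >= 1
    ca = int((carrier & case).sum())
    cb = int(case.sum() - ca)
    cc = int((carrier & ctrl).sum())
    cd = int(ctrl.sum() - cc)
    ctable = np.array([[ca, cb], [cc, cd]])

    return AlleleAssocResult(
        snp_id=snp_id,
        contingency=table,
        odds_ratio=_oriented_or(a, b, c, d),
        fisher_p=fisher_exact_two_sided(table),
        carrier_contingency=ctable,
        carrier_odds_ratio=_oriented_or(ca, cb, cc, cd),
        carrier_fisher_p=fisher_exact_two_sided(ctable),
    )


# ---------------------------------------------------------------------------
# two-locus LD
# ---------------------------------------------------------------------------

# haplotype order: AB, Ab, aB, ab (A/B = minor alleles)
_HAP_A = np.array([1, 1, 0, 0])
_HAP_B = np.array([1, 0, 1, 0])


def _genotype_class_probs(hap_freqs: np.ndarray) -> np.ndarray:
    """9-class (g1, g2) probabilities under random pairing of haplotypes."""
    probs = np.zeros((3, 3))
    for h1 in range(4):
        for h2 in range(4):
            g1 = _HAP_A[h1] + _HAP_A[h2]
            g2 = _HAP_B[h1] + _HAP_B[h2]
            probs[g1, g2] += hap_freqs[h1] * hap_freqs[h2]
    return probs


def _genotype_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ok = (x != MISSING) & (y != MISSING)
    table = np.zeros((3, 3), dtype=int)
    for g1, g2 in zip(x[ok], y[ok]):
        table[g1, g2] += 1
    return table


def _em_haplotypes(
    table: np.ndarray, tol: float = 1e-12, max_iter: int = 1000
) -> tuple[np.ndarray, list[float]]:
    """EM estimate of the four haplotype frequencies from a 3x3 genotype table."""
    n = table.sum()
    loglik_trace: list[float] = []
    # haplotype contributions known for all cells except the double het
    base_counts = np.zeros(4)
    for g1 in range(3):
        for g2 in range(3):
            c = table[g1, g2]
            if c == 0 or (g1 == 1 and g2 == 1):
                continue
            # unambiguous decomposition into two haplotypes
            h_a = [1] * g1 + [0] * (2 - g1)
            h_b = [1] * g2 + [0] * (2 - g2)
            for allele_a, allele_b in zip(h_a, h_b):
                idx = (1 - allele_a) * 2 + (1 - allele_b)
                base_counts[idx] += c
    n_dh = table[1, 1]
    # composite-LD start: a symmetric (equilibrium) start is a saddle point
    # of the EM map when all ambiguity sits in the double heterozygotes
    g1 = np.repeat(np.arange(3), 3).reshape(3, 3)
    g2 = g1.T
    n_tot = max(n, 1)
    p_a = float((table * g1).sum()) / (2 * n_tot)
    p_b = float((table * g2).sum()) / (2 * n_tot)
    cov = float((table * (g1 - 2 * p_a) * (g2 - 2 * p_b)).sum()) / n_tot / 2.0
    d0 = np.clip(cov, -0.24, 0.24)
    if abs(d0) < 1e-6:
        d0 = 1e-6
    freqs = np.clip(
        np.array(
            [
                p_a * p_b + d0,
                p_a * (1 - p_b) - d0,
                (1 - p_a) * p_b - d0,
                (1 - p_a) * (1 - p_b) + d0,
            ]
        ),
        1e-6,
        None,
    )
    freqs /= freqs.sum()
    for _ in range(max_iter):
        p_cis = freqs[0] * freqs[3]          # AB/ab
        p_trans = freqs[1] * freqs[2]        # Ab/aB
        w = p_cis / (p_cis + p_trans) if (p_cis + p_trans) > 0 else 0.5
        counts = base_counts.copy()
        counts[[0, 3]] += n_dh * w
        counts[[1, 2]] += n_dh * (1 - w)
        new = counts / (2 * n)
        probs = _genotype_class_probs(new)
        with np.errstate(divide="ignore"):
            ll = float(np.sum(table * np.where(table > 0, np.log(probs + 1e-300), 0.0)))
        if loglik_trace and ll + 1e-9 < loglik_trace[-1]:
            raise AssertionError("EM log-likelihood decreased")
        converged = bool(loglik_trace) and abs(ll - loglik_trace[-1]) < tol
        loglik_trace.append(ll)
        freqs = new
        if converged:
            break
    return freqs, loglik_trace


@dataclass
class LDResult:
    snp_a: str
    snp_b: str
    haplotype_freqs: np.ndarray    # AB, Ab, aB, ab
    d: float
    d_prime: float
    r_squared: float
    d_prime_ci: tuple[float, float]


def _d_stats(freqs: np.ndarray) -> tuple[float, float, float]:
    p_a, p_b = freqs[0] + freqs[1], freqs[0] + freqs[2]
    d = freqs[0] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / denom if denom > 0 else 0.0
    return d, min(1.0, d_prime), min(1.0, r2)


def _dprime_ci(table: np.ndarray, freqs: np.ndarray, grid: int = 101) -> tuple[float, float]:
    """Likelihood-profile CI for |D'| with allele frequencies held at the MLE."""
    p_a, p_b = freqs[0] + freqs[1], freqs[0] + freqs[2]
    d_mle = freqs[0] - p_a * p_b
    sign = 1.0 if d_mle >= 0 else -1.0
    if sign >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max <= 0:
        return 0.0, 0.0
    dps = np.linspace(0.0, 1.0, grid)
    logliks = np.empty(grid)
    for i, dp in enumerate(dps):
        d = sign * dp * d_max
        f = np.array(
            [
                p_a * p_b + d,
                p_a * (1 - p_b) - d,
                (1 - p_a) * p_b - d,
                (1 - p_a) * (1 - p_b) + d,
            ]
        )
        f = np.clip(f, 1e-12, 1.0)
        probs = _genotype_class_probs(f / f.sum())
        logliks[i] = np.sum(table * np.log(probs + 1e-300))
    lik = np.exp(logliks - logliks.max())
    lik /= lik.sum()
    cum = np.cumsum(lik)
    low = dps[int(np.searchsorted(cum, 0.05))]
    high = dps[int(np.searchsorted(cum, 0.95))]
    return float(low), float(min(1.0, high))


def ld_stats(g: GenotypeData, snp_a: str, snp_b: str) -> LDResult:
    """Pairwise LD from unphased genotypes via two-locus EM."""
    x, y = g.column(snp_a), g.column(snp_b)
    table = _genotype_table(x, y)
    for axis, name in ((1, snp_a), (0, snp_b)):
        marg = table.sum(axis=axis)
        copies = marg[1] + 2 * marg[2]
        if copies == 0 or copies == 2 * table.sum():
            raise ValueError(f"SNP {name!r} is monomorphic in the paired data")
    freqs, _ = _em_haplotypes(table)
    d, d_prime, r2 = _d_stats(freqs)
    ci = _dprime_ci(table, freqs)
    return LDResult(
        snp_a=snp_a,
        snp_b=snp_b,
        haplotype_freqs=freqs,
        d=d,
        d_prime=d_prime,
        r_squared=r2,
        d_prime_ci=ci,
    )


# ---------------------------------------------------------------------------
# haplotype blocks
# ---------------------------------------------------------------------------


@dataclass
class HaploBlock:
    snp_ids: list[str]
    start_pos: int
    end_pos: int

    @property
    def length_bp(self) -> int:
        return self.end_pos - self.start_pos


def gabriel_blocks(
    g: GenotypeData,
    region: tuple[str, int, int] | None = None,
    ci_low_min: float = GABRIEL_CI_LOW,
    ci_high_min: float = GABRIEL_CI_HIGH,
    recomb_high_max: float = GABRIEL_RECOMB_HIGH,
    informative_frac: float = GABRIEL_INFORMATIVE_FRAC,
) -> list[HaploBlock]:
    """Confidence-interval haplotype-block detection on a sorted SNP map."""
    if region is not None:
        g = extract_region(g, *region)
    if g.n_snps < 2:
        return []
    order = np.argsort(g.snps["pos"].to_numpy(), kind="stable")
    g = g.subset_snps(order)
    ids = list(g.snps.index)
    pos = g.snps["pos"].to_numpy()
    m = len(ids)

    strong = np.zeros((m, m), dtype=bool)
    informative = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                ld = ld_stats(g, ids[i], ids[j])
            except ValueError:
                continue
            low, high = ld.d_prime_ci
            if low >= ci_low_min and high >= ci_high_min:
                strong[i, j] = informative[i, j] = True
            elif high < recomb_high_max:
                informative[i, j] = True

    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if not strong[i, j]:
                continue
            inner = [(k, l) for k in range(i, j + 1) for l in range(k + 1, j + 1)]
            n_info = sum(informative[k, l] for k, l in inner)
            n_strong = sum(strong[k, l] for k, l in inner)
            if n_info and n_strong / n_info >= informative_frac:
                candidates.append((i, j))
    # greedy longest-first (bp length, then SNP count), non-overlapping
    candidates.sort(key=lambda ij: (pos[ij[1]] - pos[ij[0]], ij[1] - ij[0]), reverse=True)
    used = np.zeros(m, dtype=bool)
    blocks: list[HaploBlock] = []
    for i, j in candidates:
        if used[i : j + 1].any():
            continue
        used[i : j + 1] = True
        blocks.append(
            HaploBlock(snp_ids=ids[i : j + 1], start_pos=int(pos[i]), end_pos=int(pos[j]))
        )
    blocks.sort(key=lambda b: b.start_pos)
    return blocks
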