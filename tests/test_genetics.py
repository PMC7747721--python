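"""Genetics module tests.

The Hardy-Weinberg and Fisher tests are checked against independent
brute-force enumeration oracles built from first-principles counting
formulas (exact integer arithmetic), not against the implementations'
own recurrences.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ewaskit import genetics
from ewaskit.data_io import MISSING, GenotypeData

from conftest import make_sheet


def hwe_oracle(n_hom_rare: int, n_het: int, n_hom_common: int) -> float:
    """Exact HWE p by direct factorial counting.

    P(h | n, n_rare) proportional to the number of allele-to-genotype
    assignments: multinomial(n; hom_r, h, hom_c) * 2^h. All arithmetic
    in exact integers/rationals.
    """
    n = n_hom_rare + n_het + n_hom_common
    rare = 2 * min(n_hom_rare, n_hom_common) + n_het
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        if hom_c < 0:
            continue
        w = comb(n, h) * comb(n - h, hom_r) * 2**h
        weights[h] = w
    total = sum(weights.values())
    obs = weights[n_het]
    p = Fraction(sum(w for w in weights.values() if w <= obs), total)
    return float(p)


class TestHWEExact:
    def test_monomorphic_p_one(self):
        assert genetics.hwe_exact(5, 0, 0) == 1.0

    def test_small_table_enumeration(self):
        # (1,2,1): 4 copies of each allele, possible het counts {0,2,4}
        assert genetics.hwe_exact(1, 2, 1) == pytest.approx(hwe_oracle(1, 2, 1), abs=1e-12)

    def test_extreme_heterozygosity(self):
        assert genetics.hwe_exact(0, 100, 0) == pytest.approx(
            hwe_oracle(0, 100, 0), abs=1e-12
        )

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_matches_oracle_and_symmetry(self, a, h, b):
        if a + h + b == 0:
            return
        p = genetics.hwe_exact(a, h, b)
        assert p == pytest.approx(hwe_oracle(a, h, b), rel=1e-9)
        assert p == pytest.approx(genetics.hwe_exact(b, h, a), rel=1e-12)
        assert 0 < p <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            genetics.hwe_exact(-1, 2, 3)

    def test_permutation_variant_agrees(self):
        exact = genetics.hwe_exact(20, 10, 20)
        perm = genetics.hwe_permutation(20, 10, 20, n_perm=4000, seed=1)
        assert perm == pytest.approx(exact, abs=0.02)


def _geno(dosages: dict[str, list[int]], positions=None, chrom="13") -> GenotypeData:
    snp_ids = list(dosages)
    n = len(next(iter(dosages.values())))
    positions = positions or [1000 * (i + 1) for i in range(len(snp_ids))]
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "allele1": "A",
            "allele2": "G",
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    geno = np.column_stack([dosages[s] for s in snp_ids]).astype(np.int8)
    return GenotypeData(
        sample_ids=[f"s{i}" for i in range(n)], snps=snps, genotypes=geno
    )


class TestQC:
    def test_complete_data_no_sample_removals(self):
        g = _geno({"rs1": [0, 1, 2, 1], "rs2": [1, 1, 0, 2]})
        kept, report = genetics.snp_sample_qc(g)
        assert kept.n_samples == 4 and report["kept"].all()

    def test_low_callrate_sample_dropped(self):
        dosages = {f"rs{j}": [1] * 20 for j in range(50)}
        g = _geno(dosages)
        g.genotypes[0, :5] = MISSING  # sample 0 missing 10% of 50 SNPs
        kept, report = genetics.snp_sample_qc(g, sample_callrate_min=0.95)
        assert not report.loc["s0", "kept"]
        assert kept.n_samples == 19

    def test_zero_threshold_identity(self):
        g = _geno({"rs1": [0, MISSING, 2]})
        kept, _ = genetics.snp_sample_qc(g, sample_callrate_min=0.0)
        assert kept.n_samples == 3

    def test_monomorphic_fails_maf(self):
        g = _geno({"rs1": [0, 0, 0, 0]})
        _, report = genetics.snp_variant_qc(g, hwe_in="all")
        assert "maf" in report.loc["rs1", "fail_reasons"]

    def test_planted_failures_counted(self):
        rng = np.random.default_rng(0)
        dosages = {
            f"rs{j}": list(rng.binomial(2, 0.3, size=40).astype(int)) for j in range(96)
        }
        dosages["bad_cr"] = [MISSING] * 2 + [1] * 38          # call rate 0.95 < 0.98
        dosages["bad_maf"] = [0] * 39 + [1]                   # maf 0.0125 < 0.05
        dosages["bad_hwe1"] = [2] * 20 + [0] * 20             # no hets at 50% maf
        dosages["bad_hwe2"] = [2] * 15 + [0] * 25
        g = _geno(dosages, positions=list(range(1000, 1000 + 100)))
        kept, report = genetics.snp_variant_qc(g, hwe_in="all")
        assert not report.loc[["bad_cr", "bad_maf", "bad_hwe1", "bad_hwe2"], "kept"].any()
        assert kept.n_snps == 96

    def test_hwe_boundary_kept(self):
        # deviation is "significant" only strictly below the threshold:
        # a SNP whose HWE p equals hwe_p_min exactly is kept
        dosages = [0] * 5 + [1] * 10 + [2] * 10
        p = genetics.hwe_exact(5, 10, 10)
        g = _geno({"rs1": dosages})
        _, rep = genetics.snp_variant_qc(g, hwe_in="all", hwe_p_min=p, maf_min=0.0)
        assert "hwe" not in rep.loc["rs1", "fail_reasons"]


class TestExtractRegion:
    def test_inclusive_boundaries(self):
        g = _geno(
            {"rs1": [0, 1], "rs2": [1, 1], "rs3": [2, 1]},
            positions=[47_400_677, 47_450_000, 47_477_088],
        )
        sub = genetics.extract_region(g, "13", 47_400_677, 47_477_087)
        assert list(sub.snps.index) == ["rs1", "rs2"]

    def test_counting_within_window(self):
        rng = np.random.default_rng(3)
        pos = sorted(rng.choice(np.arange(47_390_000, 47_490_000), 60, replace=False))
        in_window = sum(47_400_677 <= p <= 47_477_087 for p in pos)
        dosages = {f"rs{j}": list(rng.binomial(2, 0.4, 10).astype(int)) for j in range(60)}
        g = _geno(dosages, positions=[int(p) for p in pos])
        sub = genetics.extract_region(g, "13", 47_400_677, 47_477_087)
        assert sub.n_snps == in_window

    def test_empty_window_rejected(self):
        g = _geno({"rs1": [0, 1]}, positions=[100])
        with pytest.raises(ValueError, match="no SNPs"):
            genetics.extract_region(g, "13", 10_000, 20_000)


class TestAlleleAssoc:
    def test_equal_frequencies_null(self):
        g = _geno({"rs1": [1, 1, 0, 2, 1, 1, 0, 2]})
        sheet = make_sheet(4, 4)
        sheet.index = g.sample_ids
        res = genetics.allele_assoc(g, sheet, "rs1")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_known_table_or_and_p(self):
        # alleles: cases 30 minor/14 major; controls 10 minor/16 major
        # OR = (30*16)/(14*10) = 480/140
        case_dosages = [2] * 8 + [1] * 14 + [0] * 0   # 22 cases: 30 minor alleles
        ctrl_dosages = [2] * 2 + [1] * 6 + [0] * 5    # 13 controls: 10 minor
        g = _geno({"rs1": case_dosages + ctrl_dosages})
        sheet = make_sheet(22, 13)
        sheet.index = g.sample_ids
        res = genetics.allele_assoc(g, sheet, "rs1")
        assert res.contingency.tolist() == [[30, 14], [10, 16]]
        assert res.odds_ratio == pytest.approx(480 / 140)
        assert res.fisher_p == pytest.approx(
            stats.fisher_exact([[30, 14], [10, 16]])[1], rel=1e-9
        )

    def test_zero_cell_continuity_correction(self):
        g = _geno({"rs1": [1, 1, 1, 0, 0, 0]})
        sheet = make_sheet(3, 3)
        sheet.index = g.sample_ids
        res = genetics.allele_assoc(g, sheet, "rs1")
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1

    def test_missing_in_group_rejected(self):
        g = _geno({"rs1": [MISSING, MISSING, 1, 0]})
        sheet = make_sheet(2, 2)
        sheet.index = g.sample_ids
        with pytest.raises(ValueError, match="entirely missing"):
            genetics.allele_assoc(g, sheet, "rs1")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    def test_fisher_matches_scipy_oracle(self, a, b, c, d):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        mine = genetics.fisher_exact_two_sided(np.array([[a, b], [c, d]]))
        ref = stats.fisher_exact([[a, b], [c, d]])[1]
        assert mine == pytest.approx(ref, rel=1e-7, abs=1e-12)


class TestLDStats:
    def test_snp_against_duplicate(self):
        col = [0, 1, 2, 1, 0, 2, 1, 1, 0, 2] * 5
        g = _geno({"rs1": col, "rs2": col})
        ld = genetics.ld_stats(g, "rs1", "rs2")
        assert ld.r_squared == pytest.approx(1.0, abs=1e-3)
        assert ld.d_prime == pytest.approx(1.0, abs=1e-3)

    def test_full_ld_haplotypes_recovered(self):
        rng = np.random.default_rng(8)
        hap1 = (rng.random(300) < 0.3).astype(int)
        hap2 = (rng.random(300) < 0.3).astype(int)
        dosage = hap1 + hap2
        g = _geno({"rs1": list(dosage), "rs2": list(dosage)})
        ld = genetics.ld_stats(g, "rs1", "rs2")
        assert ld.d_prime == pytest.approx(1.0, abs=1e-3)
        assert ld.haplotype_freqs[1] + ld.haplotype_freqs[2] < 1e-3

    def test_equilibrium_r2_near_zero(self):
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.binomial(2, 0.4, 500)
            b = rng.binomial(2, 0.3, 500)
            g = _geno({"rs1": list(a), "rs2": list(b)})
            r2s.append(genetics.ld_stats(g, "rs1", "rs2").r_squared)
        assert np.mean(r2s) < 0.01

    def test_monomorphic_rejected(self):
        g = _geno({"rs1": [0, 0, 0], "rs2": [0, 1, 2]})
        with pytest.raises(ValueError, match="monomorphic"):
            genetics.ld_stats(g, "rs1", "rs2")

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(9)
        lat1 = (rng.random(200) < 0.35).astype(int)
        lat2 = (rng.random(200) < 0.35).astype(int)
        noisy = lambda h: np.where(rng.random(200) < 0.9, h, (rng.random(200) < 0.35).astype(int))
        g = _geno(
            {
                "rs1": list((lat1 + lat2).astype(int)),
                "rs2": list((noisy(lat1) + noisy(lat2)).astype(int)),
            }
        )
        ld = genetics.ld_stats(g, "rs1", "rs2")
        low, high = ld.d_prime_ci
        assert low - 0.05 <= ld.d_prime <= high + 0.05


class TestGabrielBlocks:
    def _block_genotypes(self, rng, n, n_snps, maf=0.35):
        hap1 = (rng.random(n) < maf).astype(int)
        hap2 = (rng.random(n) < maf).astype(int)
        return {f"snp{k}": list(hap1 + hap2) for k in range(n_snps)}

    def test_perfect_ld_single_block(self):
        rng = np.random.default_rng(10)
        dosages = self._block_genotypes(rng, 200, 5)
        g = _geno(dosages)
        blocks = genetics.gabriel_blocks(g)
        assert len(blocks) == 1 and len(blocks[0].snp_ids) == 5

    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(11)
        n = 300
        b1 = self._block_genotypes(rng, n, 4, maf=0.35)
        b2 = self._block_genotypes(rng, n, 4, maf=0.4)
        dosages = {f"a{k}": v for k, v in zip(range(4), b1.values())}
        dosages.update({f"b{k}": v for k, v in zip(range(4), b2.values())})
        g = _geno(dosages, positions=[1000, 1200, 1400, 1600, 50_000, 50_200, 50_400, 50_600])
        blocks = genetics.gabriel_blocks(g)
        assert len(blocks) == 2
        assert [b.snp_ids for b in blocks] == [
            ["a0", "a1", "a2", "a3"], ["b0", "b1", "b2", "b3"],
        ]

    def test_single_snp_no_blocks(self):
        g = _geno({"rs1": [0, 1, 2, 1]})
        assert genetics.gabriel_blocks(g) == []

    def test_blocks_disjoint_and_ordered(self):
        rng = np.random.default_rng(12)
        n = 250
        dosages = {}
        positions = []
        for blk in range(3):
            part = self._block_genotypes(rng, n, 3, maf=0.3 + 0.05 * blk)
            for k, v in enumerate(part.values()):
                dosages[f"b{blk}s{k}"] = v
                positions.append(blk * 100_000 + k * 500 + 1000)
        g = _geno(dosages, positions=positions)
        blocks = genetics.gabriel_blocks(g)
        seen = []
        for b in blocks:
            assert not (set(b.snp_ids) & set(seen))
            seen += b.snp_ids
        starts = [b.start_pos for b in blocks]
        assert starts == sorted(starts)
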