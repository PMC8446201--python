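"""Genotype QC, association scan, FDR and inflation diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gesskit.gwas import (
    FarmcpuOptions,
    GenotypeMatrix,
    bh_fdr,
    farmcpu_scan,
    hwe_test,
    inflation_factor,
    qc_filter,
    qq_manhattan_data,
)


def make_genotypes(n, m, seed, maf=None):
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, m) if maf is None else np.full(m, maf)
    codes = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    snps = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": [str(1 + j // max(m // 3, 1)) for j in range(m)],
            "pos": [50_000 * (1 + j) for j in range(m)],
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeMatrix(
        codes=codes, snps=snps, samples=[str(i) for i in range(n)]
    )


class TestHwe:
    def test_exact_hardy_weinberg_proportions_give_p_one(self):
        assert hwe_test((25, 50, 25)) == pytest.approx(1.0)

    def test_matches_scalar_chi_square_oracle(self):
        n0, n1, n2 = 60, 20, 20
        n = 100
        p = (2 * n2 + n1) / (2 * n)
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        chi2 = (((np.array([n0, n1, n2]) - exp) ** 2) / exp).sum()
        assert hwe_test((n0, n1, n2)) == pytest.approx(
            stats.chi2.sf(chi2, 1), abs=1e-12
        )

    def test_exact_test_close_to_chi_square_at_large_counts(self):
        p_chi = hwe_test((400, 440, 160))
        p_ex = hwe_test((400, 440, 160), exact=True)
        assert p_ex == pytest.approx(p_chi, rel=0.5)

    def test_monomorphic_counts_are_null(self):
        assert hwe_test((100, 0, 0)) == 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_test((0, 0, 0))


class TestQcFilter:
    def test_planted_defects_are_exactly_removed(self):
        n, m = 400, 1000
        geno = make_genotypes(n, m, seed=1)
        codes = geno.codes.copy()
        rng = np.random.default_rng(2)
        bad = rng.choice(m, size=50, replace=False)
        bad_maf = bad[:15]
        bad_hwe = bad[15:30]
        bad_pos = bad[30:40]
        bad_conc = bad[40:]
        codes[:, bad_maf] = 0
        codes[0, bad_maf] = 1  # MAF 1/(2n) < 0.05
        codes[:, bad_hwe] = 1  # all heterozygous: extreme HWE violation
        snps = geno.snps.copy()
        snps.loc[bad_pos, "pos"] = np.nan
        conc = np.ones(m)
        conc[bad_conc] = 0.85
        geno2 = GenotypeMatrix(codes=codes, snps=snps, samples=geno.samples)
        kept, report = qc_filter(geno2, concordance=conc)
        assert report["n_kept"] == m - 50
        assert kept.n_snps == m - 50
        assert set(kept.snps["snp"]) == set(
            geno.snps["snp"].drop(index=bad)
        )

    def test_monomorphic_snp_removed(self):
        geno = make_genotypes(200, 10, seed=3)
        codes = geno.codes.copy()
        codes[:, 4] = 0
        kept, report = qc_filter(
            GenotypeMatrix(codes=codes, snps=geno.snps, samples=geno.samples)
        )
        assert "s4" not in set(kept.snps["snp"])

    def test_everything_removed_is_an_error(self):
        geno = make_genotypes(100, 5, seed=4)
        codes = np.zeros_like(geno.codes)
        with pytest.raises(ValueError, match="all SNPs removed"):
            qc_filter(
                GenotypeMatrix(codes=codes, snps=geno.snps, samples=geno.samples)
            )


class TestBhFdr:
    def test_worked_example_two_rejections(self):
        p = [0.0001, 0.004, 0.019, 0.095, 0.201, 0.278, 0.298, 0.344, 0.459, 0.9]
        flags, qvals, thr = bh_fdr(p, alpha=0.05)
        assert flags.sum() == 2
        assert thr == pytest.approx(0.004)
        # brute-force step-up enumeration
        ps = np.sort(p)
        m = len(p)
        k = max((i + 1 for i in range(m) if ps[i] <= (i + 1) * 0.05 / m), default=0)
        assert flags.sum() == k

    def test_all_ones_give_no_rejections(self):
        flags, _, thr = bh_fdr(np.ones(8))
        assert flags.sum() == 0 and np.isnan(thr)

    def test_boundary_all_at_alpha_over_m(self):
        m = 10
        flags, _, _ = bh_fdr(np.full(m, 0.05 / m), alpha=0.05)
        assert flags.all()

    def test_lowering_alpha_never_adds_rejections(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 200) ** 2
        prev = bh_fdr(p, alpha=0.10)[0]
        for alpha in (0.05, 0.01, 0.001):
            cur = bh_fdr(p, alpha=alpha)[0]
            assert not np.any(cur & ~prev)
            prev = cur

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([])


class TestInflationFactor:
    def test_all_half_is_exactly_one(self):
        assert inflation_factor(np.full(101, 0.5)) == pytest.approx(1.0)

    def test_uniform_null_near_one(self):
        p = np.random.default_rng(1).uniform(0, 1, 100_000)
        assert 0.98 < inflation_factor(p) < 1.02

    def test_halving_pvalues_inflates(self):
        p = np.random.default_rng(2).uniform(0.01, 1, 5000)
        assert inflation_factor(p / 2) > inflation_factor(p)


class TestScan:
    def test_single_marker_mode_matches_ols_oracle(self):
        import statsmodels.api as sm

        geno = make_genotypes(80, 12, seed=5)
        y = np.random.default_rng(6).standard_normal(80)
        res = farmcpu_scan(geno, y, options=FarmcpuOptions(max_qtn=0))
        X = geno.dosage()
        for j in range(12):
            fit = sm.OLS(y, sm.add_constant(X[:, j])).fit()
            assert res.table["p"].iloc[j] == pytest.approx(
                fit.pvalues[1], abs=1e-10
            )
            assert res.table["effect"].iloc[j] == pytest.approx(
                fit.params[1], abs=1e-10
            )

    def test_weighted_mode_matches_wls_oracle(self):
        import statsmodels.api as sm

        geno = make_genotypes(80, 6, seed=7)
        rng = np.random.default_rng(8)
        y = rng.standard_normal(80)
        w = rng.uniform(0.5, 2.0, 80)
        res = farmcpu_scan(geno, y, weights=w, options=FarmcpuOptions(max_qtn=0))
        X = geno.dosage()
        for j in range(6):
            fit = sm.WLS(y, sm.add_constant(X[:, j]), weights=w).fit()
            assert res.table["p"].iloc[j] == pytest.approx(
                fit.pvalues[1], abs=1e-10
            )

    def test_invariant_to_snp_column_order(self):
        geno = make_genotypes(100, 30, seed=9)
        y = np.random.default_rng(10).standard_normal(100)
        res1 = farmcpu_scan(geno, y)
        perm = np.random.default_rng(11).permutation(30)
        geno2 = geno.subset_snps(perm)
        res2 = farmcpu_scan(geno2, y)
        merged = res1.table.merge(res2.table, on="snp", suffixes=("_a", "_b"))
        assert np.allclose(merged["p_a"], merged["p_b"], atol=1e-10)

    def test_planted_qtl_is_top_hit(self):
        geno = make_genotypes(500, 100, seed=12)
        rng = np.random.default_rng(13)
        x = geno.codes[:, 42].astype(float)
        y = 0.8 * (x - x.mean()) + rng.standard_normal(500)
        res = farmcpu_scan(geno, y)
        assert res.table["p"].idxmin() == 42
        assert res.table["significant"].iloc[42]

    def test_constant_response_rejected(self):
        geno = make_genotypes(50, 5, seed=14)
        with pytest.raises(ValueError, match="constant"):
            farmcpu_scan(geno, np.ones(50))

    def test_too_few_animals_rejected(self):
        geno = make_genotypes(20, 5, seed=15)
        with pytest.raises(ValueError, match="at least 30"):
            farmcpu_scan(geno, np.random.default_rng(1).standard_normal(20))


class TestPlotData:
    def test_qq_identity_for_uniform_p(self):
        geno = make_genotypes(40, 50, seed=16)
        y = np.random.default_rng(17).standard_normal(40)
        res = farmcpu_scan(geno, y, options=FarmcpuOptions(max_qtn=0))
        qq, man = qq_manhattan_data(res)
        assert len(qq) == 50
        assert (np.diff(qq["expected"]) <= 0).all()
        # observed sorted descending too
        assert (np.diff(qq["observed"]) <= 1e-12).all()

    def test_manhattan_coordinates_monotone_within_chromosome(self):
        geno = make_genotypes(40, 60, seed=18)
        y = np.random.default_rng(19).standard_normal(40)
        res = farmcpu_scan(geno, y, options=FarmcpuOptions(max_qtn=0))
        _, man = qq_manhattan_data(res)
        for _, grp in man.groupby("chrom"):
            assert (np.diff(grp["cum_pos"]) > 0).all()

    def test_threshold_line_consistent_with_bh(self):
        geno = make_genotypes(200, 40, seed=20)
        rng = np.random.default_rng(21)
        x = geno.codes[:, 7].astype(float)
        y = 1.0 * (x - x.mean()) + rng.standard_normal(200)
        res = farmcpu_scan(geno, y, options=FarmcpuOptions(max_qtn=0))
        flags, _, thr = bh_fdr(res.table["p"].to_numpy(), alpha=0.05)
        assert res.fdr_threshold == pytest.approx(thr, nan_ok=True)
        assert np.array_equal(res.table["significant"], flags)
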