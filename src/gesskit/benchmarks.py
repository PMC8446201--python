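"""Self-calibration studies: the package checking itself under its own model.

Each function simulates data with the synthetic-herd generator under the
documented study conditions and measures how well an analysis stage
recovers the truth: REML parameter recovery at scale, GWAS null
calibration and QTL localization, and the planted-defect QC panel.  The
acceptance suite and the reproduction script both run these so the
reported numbers always come from a fresh computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gesskit.gwas import FarmcpuOptions, GenotypeMatrix, farmcpu_scan, qc_filter
from gesskit.reml import RemlOptions, TraitModelSpec, reml_estimate
from gesskit.simulate import SimConfig, simulate_herd

# Gestation-length simulation truth: the seven (co)variance components of
# the GL model (days^2); sire-dam genetic correlation 0.787
GL_TRUTH = np.array([3.9844, 3.1303, 3.9699, 1.16e-6, 0.5436, 3.2778, 27.1262])

GL_SPEC = TraitModelSpec(
    trait="GL",
    fixed_factors=["calf_sex", "parity_group", "calf_size_group"],
)


def gl_recovery_config(seed: int) -> SimConfig:
    """Scaled-down commercial-herd conditions for the GL recovery study.

    40,000 gestation-length records: 5,000 recorded cows with 8 parities
    each, serviced by a rolling AI-stud pool of 150 bulls (~267 records
    per bull) that also sires the cow generations, 8 herds x 8 years x 6
    months contemporary groups, two ancestor generations.
    """
    return SimConfig(
        n_founders=400,
        n_generations=2,
        cows_per_generation=[800, 5000],
        bulls_per_generation=60,
        n_service_sires=150,
        n_parities=8,
        n_herds=8,
        n_years=8,
        n_months=6,
        g0=np.array([[GL_TRUTH[0], GL_TRUTH[1]], [GL_TRUTH[1], GL_TRUTH[2]]]),
        pe_m_var=GL_TRUTH[3],
        pe_f_var=GL_TRUTH[4],
        hym_var=GL_TRUTH[5],
        resid_var=GL_TRUTH[6],
        n_snps=0,
        seed=seed,
    )


def gl_recovery_study(n_seeds: int = 10, seed0: int = 1) -> dict:
    """AI-REML recovery of all 7 GL components, one fit per seed.

    A seed passes when every estimate lies within 3 of its own reported
    (AI-matrix) standard errors of the simulation truth.
    """
    results = []
    for k in range(n_seeds):
        cfg = gl_recovery_config(seed0 + k)
        ped, _, records, _, _ = simulate_herd(cfg)
        vc = reml_estimate(records, GL_SPEC, ped, options=RemlOptions())
        ok = np.abs(vc.theta - GL_TRUTH) <= 3 * vc.se()
        results.append(
            {
                "seed": seed0 + k,
                "theta": vc.theta,
                "se": vc.se(),
                "converged": vc.converged,
                "passed": bool(ok.all()),
            }
        )
    return {
        "n_records": 40_000,
        "n_seeds": n_seeds,
        "n_passed": sum(r["passed"] for r in results),
        "results": results,
    }


def _synthetic_panel(n: int, m: int, seed: int, maf_low: float = 0.05):
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, 0.5, m)
    codes = rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    snps = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(m)],
            "chrom": [str(1 + j // 1000) for j in range(m)],
            "pos": [100_000 * (1 + j % 1000) for j in range(m)],
            "a1": "A",
            "a2": "B",
        }
    )
    geno = GenotypeMatrix(
        codes=codes, snps=snps, samples=[str(i) for i in range(n)]
    )
    return geno, rng


def gwas_null_calibration(n: int = 2000, m: int = 5000, seed: int = 7) -> dict:
    """Scan of a purely polygenic (no-QTL) response: lambda and type-I."""
    geno, rng = _synthetic_panel(n, m, seed)
    y = rng.standard_normal(n)
    res = farmcpu_scan(geno, y, options=FarmcpuOptions())
    p = res.table["p"].to_numpy()
    return {
        "n_animals": n,
        "n_snps": m,
        "lambda": float(res.lam),
        "type1_at_001": float(np.mean(p < 0.01)),
        "n_significant": int(res.table["significant"].sum()),
    }


def gwas_localization_study(
    n_seeds: int = 20,
    n: int = 2000,
    m: int = 5000,
    qtl_variance: float = 0.05,
    window_bp: int = 1_000_000,
    seed0: int = 100,
) -> dict:
    """Power study: one QTL explaining 5% of the response variance.

    Counts the seeds in which the minimum-p SNP lies within 1 Mb of the
    causal site.
    """
    hits = 0
    for k in range(n_seeds):
        geno, rng = _synthetic_panel(n, m, seed0 + k)
        causal = int(rng.integers(0, m))
        x = geno.codes[:, causal].astype(float)
        x = x - x.mean()
        beta = np.sqrt(qtl_variance / ((1 - qtl_variance) * max(np.var(x), 1e-12)))
        y = beta * x + rng.standard_normal(n)
        res = farmcpu_scan(geno, y, options=FarmcpuOptions())
        top = int(np.argmin(res.table["p"].to_numpy()))
        snps = geno.snps
        same_chr = snps["chrom"].iloc[top] == snps["chrom"].iloc[causal]
        dist = abs(int(snps["pos"].iloc[top]) - int(snps["pos"].iloc[causal]))
        hits += bool(same_chr and dist <= window_bp)
    return {"n_seeds": n_seeds, "n_localized": hits}


def planted_qc_panel(n: int = 400, m: int = 1000, n_bad: int = 50, seed: int = 2):
    """Panel with known QC violations; returns (report, expected survivors).

    Plants four kinds of defects in disjoint SNP sets: near-zero MAF,
    extreme Hardy-Weinberg departure, missing map position, and low
    imputation concordance.  Clean SNPs are drawn with population MAF
    >= 0.12 so that sampling noise cannot push them below the 0.05 filter
    (the planted defects must be the only violations).
    """
    geno, _ = _synthetic_panel(n, m, seed, maf_low=0.12)
    rng = np.random.default_rng(seed + 1)
    bad = rng.choice(m, size=n_bad, replace=False)
    quarters = np.array_split(bad, 4)
    codes = geno.codes.copy()
    codes[:, quarters[0]] = 0
    codes[0, quarters[0]] = 1  # MAF = 1/(2n)
    codes[:, quarters[1]] = 1  # all heterozygous
    snps = geno.snps.copy()
    snps.loc[quarters[2], "pos"] = np.nan
    concordance = np.ones(m)
    concordance[quarters[3]] = 0.85
    planted = GenotypeMatrix(codes=codes, snps=snps, samples=geno.samples)
    _, report = qc_filter(planted, concordance=concordance)
    return report, m - n_bad
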