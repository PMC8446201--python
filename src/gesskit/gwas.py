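"""Genotype QC, FarmCPU-style multi-locus GWAS, FDR and inflation diagnostics.

The association scan regresses de-regressed proofs (DRP) on SNP dosages in
an iterative two-step procedure: (i) a fixed-effect step testing every SNP
by weighted least squares with the current pseudo-QTNs as covariates (any
pseudo-QTN within an exclusion window of the tested SNP is dropped from its
covariate set), and (ii) a selection step that proposes pseudo-QTN sets
from p-value bins across a grid of bin sizes and set sizes and keeps the
set maximizing the likelihood of a random-effect model whose kinship is
built from the candidate QTNs.  Iteration stops when the pseudo-QTN set is
stable, when no SNP reaches the entry threshold, or at ``max_iterations``.
With ``max_qtn=0`` the scan reduces exactly to single-marker weighted
regression.

Multiple testing is controlled by Benjamini-Hochberg FDR at the genome-wise
5% level; the inflation factor lambda compares the median observed
association chi-square with its null median (0.4549).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeMatrix",
    "GwasResult",
    "FarmcpuOptions",
    "qc_filter",
    "hwe_test",
    "farmcpu_scan",
    "bh_fdr",
    "inflation_factor",
    "qq_manhattan_data",
]

MISSING = -1
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


@dataclass
class GenotypeMatrix:
    """Animals x SNPs additive minor-allele dosages with SNP metadata.

    ``codes`` is int8 with values {0, 1, 2} and -1 for missing; ``snps`` has
    columns ``snp``, ``chrom``, ``pos`` (bp, may be NaN for unplaced
    markers), ``a1``, ``a2``.  Chromosome labels are strings so autosomes
    and the X pseudo-autosomal label coexist.
    """

    codes: np.ndarray
    snps: pd.DataFrame
    samples: list

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.snps = self.snps.reset_index(drop=True)
        if self.codes.shape != (len(self.samples), len(self.snps)):
            raise ValueError("codes shape does not match samples x snps")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,missing}")
        if self.snps["snp"].duplicated().any():
            raise ValueError("duplicate SNP ids")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP, missing codes ignored."""
        x = np.ma.masked_equal(self.codes, MISSING)
        freq = x.mean(axis=0).filled(np.nan) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def genotype_counts(self) -> np.ndarray:
        """(m, 3) counts of codes 0/1/2 per SNP."""
        out = np.empty((self.n_snps, 3), dtype=np.int64)
        for g in (0, 1, 2):
            out[:, g] = (self.codes == g).sum(axis=0)
        return out

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            codes=self.codes[:, keep],
            snps=self.snps.loc[np.asarray(keep)].reset_index(drop=True)
            if np.asarray(keep).dtype == bool
            else self.snps.iloc[keep].reset_index(drop=True),
            samples=list(self.samples),
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            codes=self.codes[idx],
            snps=self.snps.copy(),
            samples=[self.samples[i] for i in idx],
        )

    def dosage(self, mean_impute: bool = True) -> np.ndarray:
        """Float dosage matrix; missing codes mean-imputed per SNP."""
        x = self.codes.astype(float)
        if mean_impute:
            miss = self.codes == MISSING
            if miss.any():
                x[miss] = np.nan
                col_means = np.nanmean(x, axis=0)
                col_means = np.where(np.isnan(col_means), 0.0, col_means)
                ind = np.where(miss)
                x[ind] = col_means[ind[1]]
        return x


def hwe_test(counts, exact: bool = False) -> float:
    """Hardy-Weinberg test p-value from genotype counts (n0, n1, n2).

    Default: 1-df chi-square of observed vs expected genotype counts under
    the allele frequencies.  ``exact=True`` uses the Wigginton-Cutler-Abecasis
    exact test (recommended for small counts).
    """
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("no genotypes")
    if exact:
        return _hwe_exact(n1, min(n0, n2), n)
    p = (2 * n2 + n1) / (2.0 * n)
    if p == 0.0 or p == 1.0:
        return 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(np.sum((np.array([n0, n1, n2]) - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_exact(n_het: int, n_rare_hom: int, n: int) -> float:
    """Exact HWE test (sum of probabilities <= observed heterozygote count)."""
    n_rare = n_het + 2 * n_rare_hom
    if n_rare == 0:
        return 1.0
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    # downward recursion from the mode
    het = mid
    while het >= 2:
        nxt = (
            probs[het]
            * het
            * (het - 1.0)
            / (4.0 * ((n_rare - het) / 2.0 + 1.0) * ((2 * n - n_rare - het) / 2.0 + 1.0))
        )
        probs[het - 2] = nxt
        het -= 2
    het = mid
    while het <= n_rare - 2:
        nxt = (
            probs[het]
            * 4.0
            * ((n_rare - het) / 2.0)
            * ((2 * n - n_rare - het) / 2.0)
            / ((het + 2.0) * (het + 1.0))
        )
        probs[het + 2] = nxt
        het += 2
    total = sum(probs.values())
    obs = probs[n_het]
    pval = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return float(min(1.0, pval))


def qc_filter(
    genotypes: GenotypeMatrix,
    concordance: np.ndarray | None = None,
    maf_min: float = 0.05,
    hwe_min_p: float = 1e-6,
    concordance_min: float = 0.90,
):
    """Remove SNPs failing the panel QC rules; returns (filtered, report).

    Rules (a SNP may fail several; the report counts each rule and the
    survivors): minor allele frequency < ``maf_min``; Hardy-Weinberg
    p-value < ``hwe_min_p``; unknown chromosome or position; imputation
    concordance <= ``concordance_min`` (when a concordance vector is given).
    """
    m = genotypes.n_snps
    maf = genotypes.maf()
    counts = genotypes.genotype_counts()
    hwe_p = np.array([hwe_test(counts[j]) for j in range(m)])
    chrom = genotypes.snps["chrom"]
    pos = genotypes.snps["pos"]
    no_place = (
        chrom.isna().to_numpy()
        | (chrom.astype(str).str.strip().isin(["", "0", "nan"])).to_numpy()
        | pos.isna().to_numpy()
    )
    fail_maf = ~(maf >= maf_min)
    fail_hwe = hwe_p < hwe_min_p
    fail_conc = np.zeros(m, dtype=bool)
    if concordance is not None:
        fail_conc = ~(np.asarray(concordance, dtype=float) > concordance_min)
    drop = fail_maf | fail_hwe | no_place | fail_conc
    report = {
        "n_input": int(m),
        "removed_maf": int(fail_maf.sum()),
        "removed_hwe": int(fail_hwe.sum()),
        "removed_unplaced": int(no_place.sum()),
        "removed_concordance": int(fail_conc.sum()),
        "removed_total": int(drop.sum()),
        "n_kept": int((~drop).sum()),
    }
    if report["n_kept"] == 0:
        raise ValueError("all SNPs removed by QC")
    return genotypes.subset_snps(~drop), report


@dataclass
class FarmcpuOptions:
    max_qtn: int = 10
    max_iterations: int = 10
    bin_sizes: tuple = (10_000, 100_000, 1_000_000)
    qtn_grid: tuple = ()  # default: (5, 10, ...) capped at max_qtn
    exclusion_window: int = 10_000_000
    p_threshold: float | None = None  # default 0.01 / n_snps
    alpha: float = 0.05
    use_weights: bool = True
    collinearity_r: float = 0.99


@dataclass
class GwasResult:
    """Scan output: per-SNP table plus scan-level diagnostics."""

    table: pd.DataFrame  # snp, chrom, pos, maf, effect, p, fdr_q, significant
    lam: float
    pseudo_qtns: list
    n_iterations: int
    fdr_threshold: float


def _wls_scan(y, X, Q, w):
    """Weighted least squares of y on each column of X given covariates Q.

    Returns (beta, p) arrays; SNPs with no residual variance get p = 1.
    """
    sw = np.sqrt(w)
    yw = y * sw
    Qw = Q * sw[:, None]
    Xw = X * sw[:, None]
    Qq, _ = np.linalg.qr(Qw)
    y_r = yw - Qq @ (Qq.T @ yw)
    X_r = Xw - Qq @ (Qq.T @ Xw)
    gg = np.einsum("ij,ij->j", X_r, X_r)
    gy = X_r.T @ y_r
    yy = float(y_r @ y_r)
    n, k = X.shape[0], Q.shape[1]
    df = n - k - 1
    if df <= 0:
        raise ValueError("not enough observations for the covariate set")
    ok = gg > 1e-10 * n
    beta = np.zeros(X.shape[1])
    pvals = np.ones(X.shape[1])
    beta[ok] = gy[ok] / gg[ok]
    rss = np.maximum(yy - beta[ok] * gy[ok], 0.0)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / np.sqrt(sigma2 / gg[ok])
    p_ok = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals[ok] = np.clip(p_ok, np.finfo(float).tiny, 1.0)
    return beta, pvals


def _ml_loglik_lowrank(y, M):
    """Max marginal ML of y = mu + u + e, var(u) = sigma2_g M M'/k (low rank).

    Profile likelihood over the variance ratio on a log grid; used only to
    rank candidate pseudo-QTN sets.
    """
    n = len(y)
    yc = y - y.mean()
    k = M.shape[1]
    Ms = (M - M.mean(axis=0)) / np.maximum(M.std(axis=0), 1e-9)
    U, d, _ = np.linalg.svd(Ms, full_matrices=False)
    xi = d**2 / k  # nonzero eigenvalues of the QTN kinship
    a = U.T @ yc
    rest = max(float(yc @ yc - a @ a), 0.0)
    best = -np.inf
    for delta in np.logspace(-4, 4, 41):
        denom = 1.0 + delta * xi
        quad = float(np.sum(a**2 / denom) + rest)
        sigma2 = quad / n
        ll = -0.5 * (
            n * np.log(2 * np.pi * sigma2) + float(np.sum(np.log(denom))) + n
        )
        best = max(best, ll)
    return best


def _select_qtns(snps, pvals, X, y, opt: FarmcpuOptions):
    """Pseudo-QTN selection across the (bin size, set size) grid."""
    chrom = snps["chrom"].astype(str).to_numpy()
    pos = snps["pos"].to_numpy(dtype=float)
    order = np.argsort(pvals, kind="stable")
    grid_counts = opt.qtn_grid or tuple(
        t for t in range(5, max(opt.max_qtn, 5) + 1, 5)
    )
    grid_counts = tuple(min(t, opt.max_qtn) for t in grid_counts) or (opt.max_qtn,)
    best_set: list = []
    best_ll = -np.inf
    for b in opt.bin_sizes:
        seen_bins = set()
        reps = []
        for j in order:
            key = (chrom[j], int(pos[j] // b))
            if key in seen_bins:
                continue
            seen_bins.add(key)
            reps.append(j)
            if len(reps) >= max(grid_counts):
                break
        for t in sorted(set(grid_counts)):
            cand = reps[:t]
            cand = _drop_collinear(X, cand, opt.collinearity_r)
            if not cand:
                continue
            ll = _ml_loglik_lowrank(y, X[:, cand])
            if ll > best_ll:
                best_ll = ll
                best_set = list(cand)
    return sorted(best_set)


def _drop_collinear(X, idx, r_max):
    kept: list = []
    for j in idx:
        xj = X[:, j]
        if xj.std() < 1e-9:
            continue
        redundant = False
        for i in kept:
            r = np.corrcoef(X[:, i], xj)[0, 1]
            if abs(r) > r_max:
                redundant = True
                break
        if redundant:
            warnings.warn(f"collinear pseudo-QTN at column {j} dropped")
            continue
        kept.append(j)
    return kept


def farmcpu_scan(
    genotypes: GenotypeMatrix,
    drp: np.ndarray,
    weights: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    options: FarmcpuOptions | None = None,
) -> GwasResult:
    """Iterative multi-locus scan of DRPs on SNP dosages.

    ``drp`` (and optional ``weights``) are aligned with ``genotypes.samples``;
    ``covariates`` is an optional n x c design (an intercept is always
    added).  Returns per-SNP effects (DRP units per minor allele), p-values,
    BH-FDR flags at ``options.alpha``, MAF, the inflation factor and the
    final pseudo-QTN list.
    """
    opt = options or FarmcpuOptions()
    y = np.asarray(drp, dtype=float)
    n, m = genotypes.n_samples, genotypes.n_snps
    if len(y) != n:
        raise ValueError("drp length does not match samples")
    if np.std(y) == 0:
        raise ValueError("constant DRP: nothing to regress")
    if n < 30:
        raise ValueError("need at least 30 animals with DRP and genotypes")
    w = np.ones(n) if (weights is None or not opt.use_weights) else np.asarray(
        weights, dtype=float
    )
    X = genotypes.dosage(mean_impute=True)
    base = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        base.append(cov)
    Q_base = np.column_stack(base) if len(base) > 1 else base[0][:, None]
    p_threshold = opt.p_threshold if opt.p_threshold is not None else 0.01 / m

    chrom = genotypes.snps["chrom"].astype(str).to_numpy()
    pos = genotypes.snps["pos"].to_numpy(dtype=float)

    def fixed_step(qtns: list):
        if not qtns:
            return _wls_scan(y, X, Q_base, w)
        # exclusion set per SNP: pseudo-QTNs within the window of that SNP
        near = np.zeros((len(qtns), m), dtype=bool)
        for qi, q in enumerate(qtns):
            near[qi] = (chrom == chrom[q]) & (
                np.abs(pos - pos[q]) <= opt.exclusion_window
            )
        # group SNPs by identical exclusion pattern and scan each group
        pattern_ids = np.zeros(m, dtype=np.int64)
        for qi in range(len(qtns)):
            pattern_ids |= near[qi].astype(np.int64) << qi
        beta = np.zeros(m)
        pvals = np.ones(m)
        for pat in np.unique(pattern_ids):
            cols = np.flatnonzero(pattern_ids == pat)
            keep = [q for qi, q in enumerate(qtns) if not (pat >> qi) & 1]
            Q = (
                np.column_stack([Q_base, X[:, keep]]) if keep else Q_base
            )
            b, pv = _wls_scan(y, X[:, cols], Q, w)
            beta[cols] = b
            pvals[cols] = pv
        return beta, pvals

    qtns: list = []
    n_iter = 0
    beta, pvals = fixed_step(qtns)
    for n_iter in range(1, opt.max_iterations + 1):
        if opt.max_qtn == 0:
            break
        if not qtns and float(pvals.min()) > p_threshold:
            break  # nothing reaches the entry threshold: single-marker scan
        new = _select_qtns(genotypes.snps, pvals, X, y, opt)
        if new == qtns:
            break
        qtns = new
        beta, pvals = fixed_step(qtns)

    flags, qvals, thr = bh_fdr(pvals, alpha=opt.alpha)
    lam = inflation_factor(pvals)
    table = pd.DataFrame(
        {
            "snp": genotypes.snps["snp"],
            "chrom": genotypes.snps["chrom"],
            "pos": genotypes.snps["pos"],
            "maf": genotypes.maf(),
            "effect": beta,
            "p": pvals,
            "fdr_q": qvals,
            "significant": flags,
        }
    )
    return GwasResult(
        table=table,
        lam=lam,
        pseudo_qtns=[genotypes.snps["snp"].iloc[j] for j in qtns],
        n_iterations=n_iter,
        fdr_threshold=thr,
    )


def bh_fdr(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up; returns (flags, q-values, threshold).

    The threshold is the largest p-value rejected (NaN when none is).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    flags, qvals, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    thr = float(p[flags].max()) if flags.any() else float("nan")
    return flags, qvals, thr


def inflation_factor(pvalues) -> float:
    """Genomic inflation lambda = median(chi2_1 quantiles of p) / 0.4549."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def qq_manhattan_data(result: GwasResult):
    """Plot-ready tables: (qq DataFrame, manhattan DataFrame).

    QQ: sorted expected vs observed -log10 p.  Manhattan: per-SNP cumulative
    genome coordinate (chromosomes laid end to end in sorted label order)
    plus the -log10 of the BH threshold.
    """
    p = result.table["p"].to_numpy()
    m = len(p)
    order = np.argsort(p)
    qq = pd.DataFrame(
        {
            "expected": -np.log10((np.arange(1, m + 1) - 0.5) / m),
            "observed": -np.log10(p[order]),
        }
    )
    tab = result.table.copy()

    def _chrom_key(c):
        s = str(c)
        return (0, int(s)) if s.isdigit() else (1, s)

    chroms = sorted(tab["chrom"].astype(str).unique(), key=_chrom_key)
    offset = 0.0
    cum = np.zeros(len(tab))
    for c in chroms:
        mask = (tab["chrom"].astype(str) == c).to_numpy()
        cpos = tab.loc[mask, "pos"].to_numpy(dtype=float)
        cum[mask] = cpos + offset
        offset += cpos.max() + 1.0
    man = pd.DataFrame(
        {
            "snp": tab["snp"],
            "chrom": tab["chrom"],
            "cum_pos": cum,
            "neglog10_p": -np.log10(tab["p"].to_numpy()),
        }
    )
    man.attrs["fdr_threshold_neglog10"] = (
        -np.log10(result.fdr_threshold) if np.isfinite(result.fdr_threshold) else np.nan
    )
    return qq, man
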