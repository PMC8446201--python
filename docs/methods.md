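# Methods

## The model

For one female reproductive trait measured on cows (conception rate CR,
56-day non-return rate NRR56, calving ease CE, stillbirth SB, gestation
length GL), the package fits

```
y = Xb + Z1 u_m + Z2 u_f + W1 pe_m + W2 pe_f + Zh hym + e
```

where `u_m` is the additive genetic effect of the **service sire** (GESS —
the bull whose semen produced the insemination, not the cow's own sire) and
`u_f` that of the **dam** (GED, the cow herself).  The two genetic effects
are correlated:

```
cov([u_m; u_f]) = G0 ⊗ A ,   G0 = [[σ²_m, σ_mf], [σ_mf, σ²_f]]
```

with `A` the pedigree numerator-relationship matrix (diagonal `1 + F`).
`pe_m`/`pe_f` are permanent-environment effects of bull and cow, `hym` the
herd–year–month contemporary group, `e ~ N(0, Iσ²_e)`.  Binary and ordinal
traits are analyzed on the observed 0/1 scale with this linear model; the
synthetic-data generator creates them by thresholding a latent Gaussian, so
estimated observed-scale components are smaller than the latent truth — only
the continuous trait (GL) is used for parameter-recovery claims.

Derived parameters (per genetic effect):

```
h²  = σ²_effect / D          re = (σ²_effect + σ²_pe,effect) / D
r   = σ_mf / sqrt(σ²_m σ²_f)
```

The phenotypic denominator `D` sums the six variances; by default the
`2σ_mf` term is **omitted** (`include_cov=False`).  Both conventions are
implemented; the omitted-covariance form is the one whose ratios are
internally consistent with the published component table this package's
worked examples use, and the flag makes the other convention one argument
away.  Standard errors of the ratios use the delta method with analytic
gradients on the AI sampling covariance; Wald tests compare estimates to
zero.

## AI-REML

The seven (co)variance parameters are estimated by average-information REML
on Henderson's mixed-model equations (MME):

* **Factorization.**  The dense fixed-effect block is absorbed via its
  Schur complement (dense intercept rows otherwise cause catastrophic
  fill-in); the sparse random block is factorized as `L D L'` by an
  in-house up-looking sparse LDL' kernel (numba).  A fill-reducing MMD
  ordering is computed once per data set and reused, so repeated numeric
  factorizations cost a fraction of a second even at ~18 000 unknowns.
  The in-house factorization is used because its `L` pattern is the exact
  elimination closure — a property the selected inversion below requires
  and which library LU factors do not guarantee (symmetric pruning drops
  fill positions whose values cancel exactly, which happens routinely with
  the rational entries of Henderson's A⁻¹).
* **Score.**  The REML gradient is computed exactly from the trace
  identities `dl/dθ = −½[tr(P V_θ) − y'P V_θ P y]`.  The data part comes
  from working variates on the current solution; the trace part needs
  entries of `C⁻¹` only on the sparsity pattern of `C`, which the Takahashi
  selected-inverse recursion delivers exactly from the LDL' factor (dense
  inverse on systems below ~2 000 unknowns).  The residual trace uses
  `tr(C⁻¹W'W) = σ²_e (dim − tr(C⁻¹ P_prior))`.
* **Curvature.**  The average-information matrix `AI = ½ F'PF` from the
  working variates; its inverse at convergence is the sampling covariance
  of the estimates.
* **Parameterization.**  Newton steps are taken on an unconstrained
  working scale — the Cholesky factor `(a, b, c)` of `G0` and the logs of
  the four plain variances — so positive-definiteness holds by
  construction and the `r = ±1` boundary is the smooth point `c = 0`.
  Steps are Levenberg-damped (damping ×10 on a rejected proposal, ÷5 on
  acceptance) with a per-parameter box trust region (≤ 2 nats for log
  variances), and a proposal is accepted only if the restricted
  log-likelihood does not decrease.
* **Convergence.**  Declared when the Newton decrement (expected loglik
  gain of the undamped step) falls below 1e-3, when parameters stop moving
  (relative change < 1e-6), or when an essentially undamped step gains
  < 1e-8 relative loglik (movement along a likelihood-flat ridge).
  Because the Cholesky scale has parameterization saddles on its
  boundaries, a converged point near a boundary is probed with small
  interior candidates and iteration resumes if any improves the
  likelihood (at most two restarts).  Typical fits converge in 6–12
  iterations.

Degenerate inputs: factor levels with no records are dropped with a
warning; a near-singular `G0` proposal is ridge-stabilized; variances are
floored at `1e-8 ×` the phenotypic variance; fits that exhaust the line
search report `converged=False` unless at least one Newton step succeeded.

## BLUP, reliability, deregression, EBV correlations

BLUP solutions come from one MME solve at converged components; animals
without records receive parent averages automatically through the A⁻¹
ties.  Reliability is `1 − PEV/((1+F)σ²_u)` with PEV read off the exact
inverse coefficient matrix by unit-vector solves (intended for desk-scale
animal sets such as the genotyped bulls).

De-regressed proofs follow the parent-average construction: with
`r²_PA = (r²_sire + r²_dam)/4` and own-information reliability
`r²* = (r² − r²_PA)/(1 − r²_PA)`,

```
DRP = PA + (EBV − PA)/r²*        w = (1−h²) / ((c + (1−r²)/r²) h²)
```

with `c` (default 0.5) the fraction of genetic variance not captured by
markers; `--simple` mode uses `DRP = EBV/r²`.  Animals with accuracy
`sqrt(r²) ≤ 0.10` are flagged out of downstream analyses.

Approximate genetic correlations between two EBV sets use Calo's method:
the raw EBV correlation scaled by
`sqrt(Σr²₁ · Σr²₂)/Σ sqrt(r²₁ r²₂)` (≥ 1 by Cauchy–Schwarz), clamped to
[−1, 1].  The SE is the reliability-weighted large-sample form
`(1−r²)/sqrt(n_eff − 2)` with `n_eff` the effective count implied by the
weights `sqrt(r²₁ r²₂)`; a nonparametric bootstrap SE is available as a
cross-check (the two agree to within roughly a factor of 1.5 on desk-scale
sets — the closed form is reported by default, and both can be requested).

## Multi-locus GWAS

Genotype QC removes SNPs with MAF < 0.05, Hardy–Weinberg p < 1e-6 (1-df
χ², exact-test option for small counts), unknown chromosome/position, or
imputation concordance ≤ 0.90, and reports counts per rule.

The association scan is an iterative two-step multi-locus procedure in the
FarmCPU family, re-implemented from its published description:

1. **Fixed-effect step** — every SNP is tested by (optionally
   DRP-weighted) least squares with the current pseudo-QTNs as covariates;
   pseudo-QTNs within a 10 Mb exclusion window of the tested SNP are
   dropped from its covariate set (SNPs are grouped by identical exclusion
   pattern, so the scan stays vectorized).  P-values are exact t-tests.
2. **Selection step** — candidate pseudo-QTN sets are the per-bin best
   SNPs across a grid of bin sizes {10 kb, 100 kb, 1 Mb} × set sizes
   {5, 10, …, max_qtn}; each candidate set is scored by the maximum
   likelihood of a random-effect model whose kinship is built from the
   candidate QTNs (low-rank, profile ML over the variance ratio on a log
   grid), and the best set is kept.  Nearly collinear QTNs (|r| > 0.99)
   are dropped with a warning.

Iteration stops when the pseudo-QTN set stabilizes, after 10 iterations,
or — crucially for calibration — immediately after the first pass if no
SNP reaches the entry threshold `0.01/m`: under the null the scan reduces
to single-marker regression and stays calibrated (λ ≈ 1, nominal type-I
error).  `max_qtn=0` forces plain single-marker (weighted) regression, the
verifiable baseline.  Missing genotypes are mean-imputed per SNP after QC;
X-pseudo-autosomal SNPs are treated as diploid autosomal.  Multiple
testing uses Benjamini–Hochberg FDR at the 5% genome-wise level
(statsmodels); the inflation factor is `median(χ²_obs)/0.4549`.

## Window annotation

Significant SNPs map to genes/QTL whose body `[start, end]` intersects
`[pos − w, pos + w]` with `w = 200 kb` by default and inclusive
boundaries; distance is gene-body distance (0 inside the feature) and the
side is reported relative to the SNP position.  BED input (0-based
half-open) is converted to the internal 1-based inclusive convention;
GFF3 is taken as is.  No live database queries: annotation comes from
local files.

## The synthetic-data generator

The generator emulates the statistical structure the model assumes, scaled
to desk size:

* a multi-generation pedigree whose later generations are sired from a
  rolling AI-stud pool of `n_service_sires` bulls drawn with Zipf-like
  usage weights — the same pool that later services the recorded cows.
  This mirrors commercial AI breeding and matters statistically: the
  sire-daughter ties are what separate the sire genetic variance from the
  sire permanent-environment variance;
* bivariate breeding values gene-dropped with founder covariance `G0` and
  Mendelian-sampling variance `(½ − (F_s + F_d)/4) G0` (reduced by
  parental inbreeding);
* repeated records per cow-parity with herd–year–month groups and
  configurable fixed-effect levels; insemination-success traits generate a
  run of services ending at the first conception, calving traits one
  record per parity; binary/ordinal phenotypes threshold the latent value
  (default cut points calibrated to incidences of 0.43 for CR, 5.21% for
  CE > 1, 6.67% for SB);
* biallelic SNPs dropped Mendelianly from founder allele frequencies, with
  optional major QTL added into the breeding values.

Services per bull are heavily right-skewed (Zipf exponent 1.1); with ten
bulls and ~4 900 services the empirical mean reproduces the ~489
services/bull figure of a large commercial population.  What the
generator does **not** emulate: semen-quality biology, estrus cycling,
seasonal effects, genotyping error, selection (matings are random given
the stud pool), or missing-data patterns of real herd software.  Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to violations
of them.

### Study conditions used by the self-calibration runs

* **GL recovery**: 5 000 recorded cows × 8 parities = 40 000 records,
  150-bull stud pool (~267 records/bull), 8 herds × 8 years × 6 months,
  two ancestor generations (~6 300 pedigree animals, MME dimension
  ~18 100).  Truth = the GL variance components above.  A seed passes when
  all seven estimates fall within 3 of their own reported SEs; 10 seeds
  are run and at least 9 must pass.  One fit takes ~20 s on one CPU.
* **GWAS null calibration**: 2 000 animals × 5 000 independent SNPs,
  polygenic-noise response; λ must lie in [0.9, 1.1] and the empirical
  type-I error at nominal 0.01 in [0.005, 0.02].
* **GWAS localization**: one planted QTL explaining 5% of the response
  variance; the top SNP must lie within 1 Mb of the causal site in at
  least 18 of 20 seeds.

## Known limitations

* Single-trait analyses only; no between-trait REML, no Gibbs sampling,
  no dominance/epistasis, no genomic relationship matrices.
* Threshold (probit) models are not implemented; binary/ordinal traits are
  analyzed on the observed scale by deliberate design.
* Reliability computation is exact but per-animal solve-based — suited to
  hundreds, not hundreds of thousands, of animals.
* The deregression reliability of the parent average uses the standard
  `(r²_s + r²_d)/4` approximation rather than the full two-equation
  system.
* On data sets whose REML optimum lies on the correlation boundary
  (|r| → 1, common at very small n), estimates converge to the boundary
  and reported SEs of the genetic parameters become large; this is a
  property of the likelihood, not of the optimizer.
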