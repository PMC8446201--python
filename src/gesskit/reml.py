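"""Correlated service-sire/dam linear mixed model and AI-REML.

Model, for one reproductive trait measured on the cow:

    y = X b + Z1 u_m + Z2 u_f + W1 pe_m + W2 pe_f + Zh hym + e

with u = [u_m; u_f] ~ N(0, G0 (x) A), where u_m is the additive genetic
effect of the service sire (GESS), u_f that of the dam (GED), G0 their 2x2
genetic (co)variance, A the pedigree numerator-relationship matrix; pe_m and
pe_f are i.i.d. permanent-environment effects of sire and cow, hym the
herd-year-month contemporary group, e ~ N(0, I sigma2_e).

The seven (co)variance parameters

    theta = (sigma2_m, sigma_mf, sigma2_f, sigma2_pe_m, sigma2_pe_f,
             sigma2_hym, sigma2_e)

are estimated by average-information REML on Henderson's mixed-model
equations (MME).  Each iteration factorizes the sparse MME coefficient
matrix once (the small dense fixed-effect block absorbed by its Schur
complement); the AI matrix comes from working-variate solves on that
factorization, and the score from the exact trace identities, with traces
evaluated through a dense inverse on small systems and by Takahashi
selected inversion of the sparse factor on large ones.  Newton steps are
taken on an unconstrained working scale (Cholesky factor of G0 plus log
variances, so positive-definiteness holds by construction), with Levenberg
damping and a per-parameter trust region; a proposal is accepted only if
the restricted likelihood does not decrease.  The inverse AI matrix at
convergence is the sampling covariance of the estimates.

Derived parameters follow the observed-scale ratios

    h2_m  = sigma2_m / D,      re_m = (sigma2_m + sigma2_pe_m) / D,
    h2_f  = sigma2_f / D,      re_f = (sigma2_f + sigma2_pe_f) / D,
    r     = sigma_mf / sqrt(sigma2_m sigma2_f),

where the phenotypic denominator D sums all variance components and,
optionally, twice the sire-dam covariance (``include_cov``).  The default
omits the covariance term.  Standard errors use the delta method on the
AI sampling covariance; Wald tests compare each estimate to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats

from gesskit._selinv import SparseLDL
from gesskit.pedigree import Pedigree, a_inverse, log_det_a

__all__ = [
    "TraitModelSpec",
    "VarianceComponents",
    "DerivedParameters",
    "RemlOptions",
    "MixedModelDesign",
    "build_mme",
    "reml_estimate",
    "heritability",
    "repeatability",
    "genetic_correlation",
    "delta_method_se",
    "wald_test",
    "derive_parameters",
]

PARAM_NAMES = (
    "sigma2_m",
    "sigma_mf",
    "sigma2_f",
    "sigma2_pe_m",
    "sigma2_pe_f",
    "sigma2_hym",
    "sigma2_e",
)


@dataclass
class TraitModelSpec:
    """Which columns feed the model for one trait.

    ``fixed_factors`` are categorical record columns (e.g. AI technician,
    parity, semen type and insemination number for insemination traits;
    calf sex, parity and calf-size group for calving traits).  Random terms
    can be switched off for degenerate/toy configurations; the genetic term
    indexes u_m by ``sire_column`` and u_f by ``cow_column``.
    """

    trait: str
    response: str = "phenotype"
    fixed_factors: list = field(default_factory=list)
    sire_column: str = "service_sire"
    cow_column: str = "cow"
    hym_column: str = "hym"
    include_genetic: bool = True
    include_pe_m: bool = True
    include_pe_f: bool = True
    include_hym: bool = True


@dataclass
class VarianceComponents:
    """Seven (co)variance parameters plus their sampling covariance."""

    sigma2_m: float
    sigma_mf: float
    sigma2_f: float
    sigma2_pe_m: float
    sigma2_pe_f: float
    sigma2_hym: float
    sigma2_e: float
    cov: np.ndarray = None  # 7x7 sampling covariance, PARAM_NAMES order
    loglik: float = np.nan
    converged: bool = True
    n_iter: int = 0

    @property
    def theta(self) -> np.ndarray:
        return np.array(
            [
                self.sigma2_m,
                self.sigma_mf,
                self.sigma2_f,
                self.sigma2_pe_m,
                self.sigma2_pe_f,
                self.sigma2_hym,
                self.sigma2_e,
            ]
        )

    @property
    def g0(self) -> np.ndarray:
        return np.array(
            [[self.sigma2_m, self.sigma_mf], [self.sigma_mf, self.sigma2_f]]
        )

    @classmethod
    def from_theta(cls, theta, cov=None, **kw) -> "VarianceComponents":
        return cls(*[float(t) for t in theta], cov=cov, **kw)

    def se(self) -> np.ndarray:
        if self.cov is None:
            return np.full(7, np.nan)
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def to_dict(self) -> dict:
        d = {k: float(v) for k, v in zip(PARAM_NAMES, self.theta)}
        d["loglik"] = float(self.loglik)
        d["converged"] = bool(self.converged)
        d["n_iter"] = int(self.n_iter)
        if self.cov is not None:
            d["cov"] = np.asarray(self.cov).tolist()
        return d


@dataclass
class DerivedParameters:
    """Heritabilities, repeatabilities and sire-dam genetic correlation."""

    h2_ss: float
    h2_d: float
    re_ss: float
    re_d: float
    r: float
    se_h2_ss: float = np.nan
    se_h2_d: float = np.nan
    se_re_ss: float = np.nan
    se_re_d: float = np.nan
    se_r: float = np.nan
    p_h2_ss: float = np.nan
    p_h2_d: float = np.nan
    p_re_ss: float = np.nan
    p_re_d: float = np.nan
    p_r: float = np.nan

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


@dataclass
class RemlOptions:
    max_iter: int = 200
    tol_param: float = 1e-6  # relative parameter change
    tol_decrement: float = 1e-3  # Newton decrement (expected loglik gain)
    max_halvings: int = 20
    verbose: bool = False


# ---------------------------------------------------------------------------
# design / MME assembly


class MixedModelDesign:
    """Cached design matrices and sufficient statistics for one trait/data.

    Holds W = [X | Z1 | Z2 | W1 | W2 | Zh], W'W, W'y, y'y and the sparse
    A-inverse so that the MME for any parameter value can be assembled
    cheaply.  Column blocks (slices) follow the stacking order fixed
    effects, u_m (pedigree order), u_f (pedigree order), pe_m, pe_f, hym.
    """

    def __init__(self, records: pd.DataFrame, spec: TraitModelSpec, ped: Pedigree):
        records = records.reset_index(drop=True)
        self.spec = spec
        self.ped = ped
        self.n = len(records)
        if self.n == 0:
            raise ValueError("no records")
        y = records[spec.response].to_numpy(dtype=float)
        self.y = y

        # fixed-effects design: intercept + treatment coding, observed levels
        X_cols = [np.ones(self.n)]
        self.fixed_labels = ["intercept"]
        for factor in spec.fixed_factors:
            cat = pd.Categorical(records[factor].astype(str))
            levels = list(cat.categories)
            counts = cat.value_counts()
            kept = [lv for lv in levels if counts[lv] > 0]
            for lv in levels:
                if counts[lv] == 0:
                    warnings.warn(f"factor {factor}: level {lv!r} has no records")
            for lv in kept[1:]:  # first observed level is the reference
                X_cols.append((cat == lv).astype(float))
                self.fixed_labels.append(f"{factor}={lv}")
        X = np.column_stack(X_cols)
        self.p = X.shape[1]

        q = len(ped)
        self.q = q
        rows = np.arange(self.n)
        blocks = [sp.csc_matrix(X)]
        sizes = [self.p]
        names = ["fixed"]

        if spec.include_genetic:
            sire_idx = np.array(
                [ped.index_of(a) for a in records[spec.sire_column]], dtype=np.int64
            )
            cow_idx = np.array(
                [ped.index_of(a) for a in records[spec.cow_column]], dtype=np.int64
            )
            Z1 = sp.coo_matrix(
                (np.ones(self.n), (rows, sire_idx)), shape=(self.n, q)
            ).tocsc()
            Z2 = sp.coo_matrix(
                (np.ones(self.n), (rows, cow_idx)), shape=(self.n, q)
            ).tocsc()
            blocks += [Z1, Z2]
            sizes += [q, q]
            names += ["u_m", "u_f"]
            self.sire_idx, self.cow_idx = sire_idx, cow_idx
        if spec.include_pe_m:
            pe_m_ids, pm = np.unique(records[spec.sire_column], return_inverse=True)
            self.pe_m_ids = list(pe_m_ids)
            blocks.append(
                sp.coo_matrix(
                    (np.ones(self.n), (rows, pm)), shape=(self.n, len(pe_m_ids))
                ).tocsc()
            )
            sizes.append(len(pe_m_ids))
            names.append("pe_m")
        if spec.include_pe_f:
            pe_f_ids, pf = np.unique(records[spec.cow_column], return_inverse=True)
            self.pe_f_ids = list(pe_f_ids)
            blocks.append(
                sp.coo_matrix(
                    (np.ones(self.n), (rows, pf)), shape=(self.n, len(pe_f_ids))
                ).tocsc()
            )
            sizes.append(len(pe_f_ids))
            names.append("pe_f")
        if spec.include_hym:
            hym_ids, hy = np.unique(records[spec.hym_column], return_inverse=True)
            self.hym_ids = list(hym_ids)
            blocks.append(
                sp.coo_matrix(
                    (np.ones(self.n), (rows, hy)), shape=(self.n, len(hym_ids))
                ).tocsc()
            )
            sizes.append(len(hym_ids))
            names.append("hym")

        self.block_names = names
        offs = np.concatenate([[0], np.cumsum(sizes)])
        self.slices = {
            nm: slice(int(offs[i]), int(offs[i + 1])) for i, nm in enumerate(names)
        }
        self.dim = int(offs[-1])
        self.W = sp.hstack(blocks, format="csr")
        self.WtW = (self.W.T @ self.W).tocsc()
        self.Wty = self.W.T @ y
        self.yty = float(y @ y)

        if spec.include_genetic:
            self.ainv = a_inverse(ped)
            self.log_det_a = log_det_a(ped)
        else:
            self.ainv = None
            self.log_det_a = 0.0

    # which of the seven parameters the trait model activates
    def active_mask(self) -> np.ndarray:
        m = np.zeros(7, dtype=bool)
        if self.spec.include_genetic:
            m[0:3] = True
        m[3] = self.spec.include_pe_m
        m[4] = self.spec.include_pe_f
        m[5] = self.spec.include_hym
        m[6] = True
        return m

    def precision(self, theta: np.ndarray) -> sp.csc_matrix:
        """Block-diagonal prior precision for the random effects."""
        diag = np.zeros(self.dim)
        parts = []
        if self.spec.include_genetic:
            g0 = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
            if np.linalg.det(g0) <= 1e-12 * max(g0[0, 0] * g0[1, 1], 1e-300):
                warnings.warn("near-singular G0; ridge-stabilized")
                g0 = g0 + 1e-8 * np.trace(g0) * np.eye(2)
            g0inv = np.linalg.inv(g0)
            # keep the full 2x2-block symbolic pattern even when the
            # covariance is exactly zero (selected inversion reads C^-1 on
            # the pattern of C, so the pattern must not collapse)
            g0inv = np.where(g0inv == 0.0, 1e-300, g0inv)
            gen = sp.kron(g0inv, self.ainv, format="coo")
            off = self.slices["u_m"].start
            parts.append(
                sp.coo_matrix(
                    (gen.data, (gen.row + off, gen.col + off)),
                    shape=(self.dim, self.dim),
                )
            )
        for nm, t in (("pe_m", theta[3]), ("pe_f", theta[4]), ("hym", theta[5])):
            if nm in self.slices:
                diag[self.slices[nm]] = 1.0 / t
        parts.append(sp.diags(diag))
        out = parts[0]
        for pmat in parts[1:]:
            out = out + pmat
        return out.tocsc()

    def assemble(self, theta: np.ndarray):
        """MME coefficient matrix and right-hand side at theta."""
        sige = theta[6]
        C = (self.WtW / sige + self.precision(theta)).tocsc()
        rhs = self.Wty / sige
        return C, rhs

    def log_det_g(self, theta: np.ndarray) -> float:
        out = 0.0
        if self.spec.include_genetic:
            g0 = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
            det = np.linalg.det(g0)
            if det <= 0:
                return np.nan  # outside the parameter space
            out += self.q * np.log(det) + 2.0 * self.log_det_a
        for nm, t in (("pe_m", theta[3]), ("pe_f", theta[4]), ("hym", theta[5])):
            if nm in self.slices:
                out += (self.slices[nm].stop - self.slices[nm].start) * np.log(t)
        return out

    def factorize(self, theta: np.ndarray):
        """Factorize the MME at theta.

        The small dense fixed-effect block is absorbed through its Schur
        complement so only the sparse random-effect block reaches the LU
        (dense intercept rows otherwise cause catastrophic fill-in).
        """
        C, rhs = self.assemble(theta)
        p = self.p
        fac = _Factor(self, np.asarray(theta, dtype=float))
        Cff = C[:p, :p].toarray()
        if self.dim > p:
            Cfr = C[:p, p:].tocsr()
            Crr = C[p:, p:].tocsc()
            # The random block is factorized as L D L' in a fill-reducing
            # ordering computed once per design (the pattern never changes
            # over iterations); the in-house factorization carries the
            # exact elimination-closure pattern that selected inversion
            # requires.
            order = getattr(self, "_fill_order", None)
            if order is None:
                lu = spla.splu(
                    Crr,
                    permc_spec="MMD_AT_PLUS_A",
                    diag_pivot_thresh=0.0,
                    options={"SymmetricMode": True},
                )
                order = np.empty(Crr.shape[0], dtype=np.int64)
                order[lu.perm_c] = np.arange(Crr.shape[0])
                self._fill_order = order
            fac.ldl = SparseLDL(Crr, order=order)
            Yf = fac.ldl.solve(Cfr.toarray().T)  # (dim-p) x p
            S = Cff - Cfr @ Yf
            S = (S + S.T) / 2
            sign, logdet_s = np.linalg.slogdet(S)
            if sign <= 0:
                raise RuntimeError("fixed-effect block is singular")
            fac.Cfr = Cfr
            fac.Yf = Yf
            fac.S = S
            fac.logdet_c = float(fac.ldl.log_det + logdet_s)
        else:
            sign, logdet_s = np.linalg.slogdet(Cff)
            if sign <= 0:
                raise RuntimeError("fixed-effect block is singular")
            fac.dense_ff = Cff
            fac.logdet_c = float(logdet_s)
        fac.sol = fac.solve(rhs)
        return fac


class _Factor:
    """One factorized MME: solutions, likelihood and P-operator products."""

    def __init__(self, design, theta):
        self.design = design
        self.theta = np.asarray(theta, dtype=float)
        self.ldl = None
        self.Cfr = None
        self.Yf = None
        self.S = None
        self.dense_ff = None
        self.sol = None
        self.logdet_c = np.nan
        self._selinv = None

    def solve(self, v: np.ndarray) -> np.ndarray:
        """C^-1 v through the Schur-absorbed factorization (v may be 2-D)."""
        d = self.design
        p = d.p
        if self.ldl is None:
            return np.linalg.solve(self.dense_ff, v)
        squeeze = v.ndim == 1
        V = v[:, None] if squeeze else v
        vf, vr = V[:p], V[p:]
        t = self.ldl.solve(vr)
        sf = np.linalg.solve(self.S, vf - self.Cfr @ t)
        sr = t - self.Yf @ sf
        out = np.vstack([sf, sr])
        return out[:, 0] if squeeze else out

    @property
    def loglik(self) -> float:
        """Restricted log-likelihood (with the -(n-p)/2 log 2pi constant)."""
        d = self.design
        sige = self.theta[6]
        ypy = (d.yty - self.sol @ d.Wty) / sige
        m2l = (
            self.logdet_c
            + d.log_det_g(self.theta)
            + d.n * np.log(sige)
            + ypy
            + (d.n - d.p) * np.log(2.0 * np.pi)
        )
        return -0.5 * m2l

    def residual(self) -> np.ndarray:
        return self.design.y - self.design.W @ self.sol

    def p_apply(self, f: np.ndarray) -> np.ndarray:
        """P f = R^-1 (f - W s_f) where C s_f = W'R^-1 f."""
        d = self.design
        sige = self.theta[6]
        s_f = self.solve((d.W.T @ f) / sige)
        return (f - d.W @ s_f) / sige

    def working_variates(self, mask: np.ndarray) -> np.ndarray:
        """Columns f_j = (dV/dtheta_j) P y for the active parameters."""
        d = self.design
        sige = self.theta[6]
        e = self.residual()
        py = e / sige
        cols = []
        if d.spec.include_genetic:
            g0 = np.array(
                [[self.theta[0], self.theta[1]], [self.theta[1], self.theta[2]]]
            )
            g0inv = np.linalg.inv(g0)
            U = np.vstack(
                [self.sol[d.slices["u_m"]], self.sol[d.slices["u_f"]]]
            )  # 2 x q
            basis = [
                np.array([[1.0, 0.0], [0.0, 0.0]]),
                np.array([[0.0, 1.0], [1.0, 0.0]]),
                np.array([[0.0, 0.0], [0.0, 1.0]]),
            ]
            for E in basis:
                T = E @ g0inv @ U  # 2 x q
                Z1 = d.W[:, d.slices["u_m"]]
                Z2 = d.W[:, d.slices["u_f"]]
                cols.append(Z1 @ T[0] + Z2 @ T[1])
        for nm, ti in (("pe_m", 3), ("pe_f", 4), ("hym", 5)):
            if nm in d.slices:
                cols.append(d.W[:, d.slices[nm]] @ self.sol[d.slices[nm]] / self.theta[ti])
        cols.append(py)
        F = np.column_stack(cols)
        return F

    def ai_matrix(self, mask: np.ndarray) -> np.ndarray:
        F = self.working_variates(mask)
        PF = self.p_apply(F)
        ai = 0.5 * (F.T @ PF)
        return (ai + ai.T) / 2

    def _trace_terms(self, method: str) -> dict:
        """Traces of C^-1 against the prior-precision blocks.

        Returns ``{"T": 2x2 genetic matrix, "pe_m": float, ...}`` where
        T[k, l] = tr(A^-1 C^-1[u_l, u_k]) and the scalars are diagonal
        sums of C^-1 on the pe/hym blocks.  ``method`` is ``"dense"``
        (explicit inverse via solves; small systems) or ``"selinv"``
        (Takahashi selected inversion of the sparse factor plus the
        low-rank Schur correction for the absorbed fixed block).
        """
        d = self.design
        out: dict = {}
        if method == "dense":
            Cinv = self.solve(np.eye(d.dim))
            if d.spec.include_genetic:
                sl_m, sl_f = d.slices["u_m"], d.slices["u_f"]
                T = np.empty((2, 2))
                for k, slk in ((0, sl_m), (1, sl_f)):
                    for l, sll in ((0, sl_m), (1, sl_f)):
                        T[k, l] = float(
                            np.sum(d.ainv.multiply(Cinv[sll, slk].T))
                        )
                out["T"] = T
            for nm in ("pe_m", "pe_f", "hym"):
                if nm in d.slices:
                    sl = d.slices[nm]
                    out[nm] = float(np.trace(Cinv[sl, sl]))
            return out

        p = d.p
        if self._selinv is None:
            self._selinv = self.ldl.selected_inverse()
        Sig = self._selinv  # Crr^-1 on the factor pattern
        Sinv = np.linalg.inv(self.S)
        Yf = self.Yf
        diag = Sig.diagonal()

        def rsl(name):
            sl = d.slices[name]
            return slice(sl.start - p, sl.stop - p)

        if d.spec.include_genetic:
            sm, sf = rsl("u_m"), rsl("u_f")
            AYf = {0: d.ainv @ Yf[sm], 1: d.ainv @ Yf[sf]}
            Yblk = {0: Yf[sm], 1: Yf[sf]}
            T = np.empty((2, 2))
            for k, slk in ((0, sm), (1, sf)):
                for l, sll in ((0, sm), (1, sf)):
                    sel = float(np.sum(d.ainv.multiply(Sig[sll, slk].T)))
                    low = float(np.sum((Yblk[k].T @ AYf[l]) * Sinv))
                    T[k, l] = sel + low
            out["T"] = T
        for nm in ("pe_m", "pe_f", "hym"):
            if nm in d.slices:
                sl = rsl(nm)
                Yb = Yf[sl]
                out[nm] = float(np.sum(diag[sl])) + float(
                    np.einsum("ip,pq,iq->", Yb, Sinv, Yb)
                )
        return out

    def score(self, mask: np.ndarray, method: str = "auto") -> np.ndarray:
        """Exact REML score (gradient of the restricted log-likelihood).

        dl/dtheta_j = -1/2 [ tr(P dV/dtheta_j) - y'P (dV/dtheta_j) P y ].
        The data part comes from the working variates; the trace part from
        tr(C^-1 dC/dtheta_j) + d log|G| evaluated exactly on the current
        factorization (dense inverse on small systems, selected inversion
        on large ones).  The residual trace uses the identity
        tr(C^-1 W'W) = sigma2_e (dim - tr(C^-1 P_prior)).
        """
        d = self.design
        th = self.theta
        sige = th[6]
        act = np.flatnonzero(mask)
        F = self.working_variates(mask)
        py = self.residual() / sige
        data_part = F.T @ py  # y'P V_j P y per active parameter
        if method == "auto":
            method = "dense" if d.dim <= 2000 else "selinv"
        traces = self._trace_terms(method)

        grad_m2l = {}
        tr_cp = 0.0  # tr(C^-1 P_prior)
        if d.spec.include_genetic:
            g0 = np.array([[th[0], th[1]], [th[1], th[2]]])
            g0inv = np.linalg.inv(g0)
            T = traces["T"]
            tr_cp += float(np.sum(g0inv * T))  # T is symmetric
            basis = {
                0: np.array([[1.0, 0.0], [0.0, 0.0]]),
                1: np.array([[0.0, 1.0], [1.0, 0.0]]),
                2: np.array([[0.0, 0.0], [0.0, 1.0]]),
            }
            for j, E in basis.items():
                S_ij = g0inv @ E @ g0inv
                grad_m2l[j] = d.q * float(np.sum(g0inv * E)) - float(
                    np.sum(S_ij * T)
                )
        for j, nm in ((3, "pe_m"), (4, "pe_f"), (5, "hym")):
            if nm in d.slices:
                sl = d.slices[nm]
                k = sl.stop - sl.start
                tr_blk = traces[nm]
                tr_cp += tr_blk / th[j]
                grad_m2l[j] = k / th[j] - tr_blk / th[j] ** 2
        # residual variance: tr(C^-1 W'W) via the prior-trace identity
        tr_ww = sige * (d.dim - tr_cp)
        grad_m2l[6] = d.n / sige - tr_ww / sige**2

        out = np.zeros(len(act))
        for k, j in enumerate(act):
            out[k] = -0.5 * (grad_m2l[j] - data_part[k])
        return out


def build_mme(
    records: pd.DataFrame,
    spec: TraitModelSpec,
    ped: Pedigree,
    components: VarianceComponents | np.ndarray,
):
    """Assemble Henderson's MME at the given variance components.

    Returns (C, rhs, design): the sparse coefficient matrix, the right-hand
    side and the cached :class:`MixedModelDesign` (which records the block
    layout: p fixed columns, 2q genetic, then pe/hym blocks).
    """
    theta = (
        components.theta
        if isinstance(components, VarianceComponents)
        else np.asarray(components, dtype=float)
    )
    design = MixedModelDesign(records, spec, ped)
    C, rhs = design.assemble(theta)
    return C, rhs, design


def restricted_loglik(design: MixedModelDesign, theta: np.ndarray) -> float:
    """Exact restricted log-likelihood at theta (sparse evaluation)."""
    return design.factorize(np.asarray(theta, dtype=float)).loglik


# ---------------------------------------------------------------------------
# AI-REML


def _default_init(design: MixedModelDesign) -> np.ndarray:
    vp = float(np.var(design.y))
    if vp <= 0:
        vp = 1.0
    return np.array([0.1 * vp, 0.0, 0.1 * vp, 0.05 * vp, 0.05 * vp, 0.1 * vp, 0.6 * vp])


def _project(theta: np.ndarray, floor: float) -> np.ndarray:
    """Clamp variances to the feasible region and G0 to the PSD cone."""
    t = theta.copy()
    for j in (0, 2, 3, 4, 5, 6):
        t[j] = max(t[j], floor)
    bound = 0.999 * np.sqrt(t[0] * t[2])
    if abs(t[1]) > bound:
        t[1] = np.sign(t[1]) * bound
    return t


def _theta_to_phi(theta: np.ndarray, floor: float) -> np.ndarray:
    """Unconstrained working parameters.

    The genetic block is parameterized by its Cholesky factor
    G0 = L L', L = [[a, 0], [b, c]] (PSD by construction; the r = +/-1
    boundary is the smooth point c = 0), the remaining variances by logs.
    """
    t = theta
    a = np.sqrt(max(t[0], floor))
    b = t[1] / a
    c = np.sqrt(max(t[2] - b * b, floor))
    return np.array(
        [a, b, c] + [np.log(max(t[j], floor)) for j in (3, 4, 5, 6)]
    )


def _phi_to_theta(phi: np.ndarray, floor: float) -> np.ndarray:
    a, b, c = abs(phi[0]), phi[1], abs(phi[2])
    a = max(a, np.sqrt(floor))
    c = max(c, np.sqrt(floor))
    return np.array(
        [
            a * a,
            a * b,
            b * b + c * c,
            np.exp(phi[3]),
            np.exp(phi[4]),
            np.exp(phi[5]),
            np.exp(phi[6]),
        ]
    )


def _phi_jacobian(phi: np.ndarray, floor: float) -> np.ndarray:
    """J[i, j] = d theta_i / d phi_j (7 x 7)."""
    a, b, c = max(abs(phi[0]), np.sqrt(floor)), phi[1], max(abs(phi[2]), np.sqrt(floor))
    J = np.zeros((7, 7))
    J[0, 0] = 2 * a
    J[1, 0] = b
    J[1, 1] = a
    J[2, 1] = 2 * b
    J[2, 2] = 2 * c
    for j in (3, 4, 5, 6):
        J[j, j] = np.exp(phi[j])
    return J


def reml_estimate(
    records: pd.DataFrame,
    spec: TraitModelSpec,
    ped: Pedigree,
    init: np.ndarray | None = None,
    options: RemlOptions | None = None,
) -> VarianceComponents:
    """AI-REML estimation of the seven (co)variance parameters.

    Newton-type iterations with the average-information matrix as
    curvature, run on an unconstrained working scale (Cholesky factor of
    the genetic block, log variances) so the PSD and positivity
    constraints hold by construction.  Steps are Levenberg-damped and
    line-searched so the restricted log-likelihood never decreases;
    convergence is declared when the Newton decrement (the expected
    loglik gain) falls below ``tol_decrement`` or the parameters stop
    moving.  The inverse AI matrix at the optimum is the sampling
    covariance of the estimates on the original (co)variance scale.
    """
    opt = options or RemlOptions()
    design = MixedModelDesign(records, spec, ped)
    mask = design.active_mask()
    if not design.spec.include_genetic:
        raise ValueError("REML fit requires the genetic term")
    for nm in ("pe_m", "pe_f", "hym"):
        if nm in design.slices:
            k = design.slices[nm].stop - design.slices[nm].start
            if k < 2:
                raise ValueError(f"random term {nm} has fewer than 2 levels")

    vp = float(np.var(design.y))
    floor = 1e-8 * max(vp, 1e-12)
    theta = _default_init(design) if init is None else np.asarray(init, dtype=float)
    theta = _project(theta, floor)
    theta[~mask] = 0.0
    scale = np.full(7, vp)

    act = np.flatnonzero(mask)
    phi = _theta_to_phi(theta, floor)
    fac = design.factorize(theta)
    ll = fac.loglik
    converged = False
    lm_damp = 0.01
    it = 0
    total_it = 0
    restarts = 0
    while True:
        theta, ll, fac, converged, it, lm_damp = _newton_iterations(
            design, mask, act, theta, phi, fac, ll, lm_damp,
            floor, scale, vp, opt, opt.max_iter - total_it,
        )
        total_it += it
        # The Cholesky/log working scale has parameterization saddles at
        # its boundaries (e.g. the gradient in the off-diagonal factor
        # vanishes as the correlation reaches +/-1), so a converged point
        # on a boundary is probed with small interior candidates; if any
        # improves the likelihood, iteration resumes from there.
        if restarts >= 2 or total_it >= opt.max_iter:
            break
        escaped = False
        for cand in _boundary_probes(theta, mask, vp, floor):
            try:
                cand_fac = design.factorize(cand)
            except (RuntimeError, ValueError):
                continue
            if cand_fac.loglik > ll + 1e-6 * max(1.0, abs(ll)):
                theta, ll, fac = cand, cand_fac.loglik, cand_fac
                escaped = True
                break
        if not escaped:
            break
        phi = _theta_to_phi(theta, floor)
        restarts += 1
    it = total_it

    # sampling covariance from the AI matrix at the final point
    ai = fac.ai_matrix(mask)
    try:
        cov_act = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        cov_act = np.linalg.pinv(ai)
    cov = np.zeros((7, 7))
    cov[np.ix_(act, act)] = cov_act
    if not converged:
        warnings.warn(f"AI-REML did not converge in {it} iterations")
    return VarianceComponents.from_theta(
        theta, cov=cov, loglik=float(ll), converged=converged, n_iter=it
    )


def _boundary_probes(theta, mask, vp, floor):
    """Interior candidates next to any parameter resting on a boundary."""
    out = []
    g11, g12, g22 = theta[0], theta[1], theta[2]
    if g11 > 0 and g22 > 0:
        r = g12 / np.sqrt(g11 * g22)
        if abs(r) > 0.95:  # near the correlation boundary
            for r_new in (0.9 * r, 0.6 * r):
                cand = theta.copy()
                cand[1] = r_new * np.sqrt(g11 * g22)
                out.append(cand)
    for j in (0, 2, 3, 4, 5):
        if mask[j] and theta[j] < 1e-4 * vp:
            for frac in (0.01, 0.05):
                cand = theta.copy()
                cand[j] = frac * vp
                out.append(cand)
    return out


def _newton_iterations(
    design, mask, act, theta, phi, fac, ll, lm_damp, floor, scale, vp, opt, max_iter
):
    converged = False
    it = 0
    for it in range(1, max(max_iter, 1) + 1):
        grad_t = fac.score(mask)
        ai_t = fac.ai_matrix(mask)
        J = _phi_jacobian(phi, floor)[np.ix_(act, act)]
        grad_p = J.T @ grad_t
        ai_p = J.T @ ai_t @ J

        ridge = 1e-10 * (np.trace(ai_p) / len(ai_p) + 1.0)
        try:
            decrement = 0.5 * float(
                grad_p @ np.linalg.solve(ai_p + ridge * np.eye(len(ai_p)), grad_p)
            )
        except np.linalg.LinAlgError:
            decrement = np.inf
        if 0 <= decrement < opt.tol_decrement:
            converged = True
            break

        # Levenberg-damped Newton step on the working scale; damping grows
        # on rejected proposals, shrinks after accepted ones
        new_theta = None
        new_ll = -np.inf
        diag_ai = np.abs(np.diag(ai_p)) + ridge
        for _ in range(opt.max_halvings):
            try:
                step = np.linalg.solve(ai_p + lm_damp * np.diag(diag_ai), grad_p)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(ai_p, grad_p, rcond=None)[0]
            # cap: log-variances move at most ~2 nats, Cholesky entries at
            # most their own magnitude (or a fraction of the trait scale)
            cap = np.empty(len(act))
            for k, j in enumerate(act):
                if j <= 2:
                    cap[k] = max(abs(phi[j]), 0.3 * np.sqrt(vp))
                else:
                    cap[k] = 2.0
            step = np.clip(step, -cap, cap)  # box trust region per parameter
            phi_cand = phi.copy()
            phi_cand[act] += step
            cand = _phi_to_theta(phi_cand, floor)
            cand[~mask] = 0.0
            try:
                cand_fac = design.factorize(cand)
                cand_ll = cand_fac.loglik
            except (RuntimeError, ValueError):
                cand_ll = -np.inf
            if np.isfinite(cand_ll) and cand_ll >= ll - 1e-9 * max(1.0, abs(ll)):
                new_theta, new_ll, fac = cand, cand_ll, cand_fac
                phi = _theta_to_phi(cand, floor)
                lm_damp = max(lm_damp / 5.0, 1e-4)
                break
            lm_damp = min(lm_damp * 10.0, 1e7)
        if new_theta is None:
            # no uphill step at any damping: stationary within the
            # line-search resolution (the raw decrement can stay large in
            # likelihood-flat directions where AI is near-singular)
            converged = it > 1
            break

        rel_change = np.max(
            np.abs(new_theta[act] - theta[act])
            / np.maximum(np.abs(theta[act]), scale[act] * 1e-3)
        )
        dll = new_ll - ll
        theta, ll = new_theta, new_ll
        if opt.verbose:
            print(
                f"iter {it}: loglik={ll:.6f} rel_change={rel_change:.2e} "
                f"dll={dll:.2e} decrement={decrement:.2e} damp={lm_damp:.1e}"
            )
        if rel_change < opt.tol_param:
            converged = True
            break
        # an essentially undamped Newton step that gains almost nothing:
        # remaining movement is along a likelihood-flat ridge
        if lm_damp <= 1e-3 and dll < 1e-8 * max(1.0, abs(ll)):
            converged = True
            break

    return theta, ll, fac, converged, it, lm_damp


# ---------------------------------------------------------------------------
# derived parameters


def _denominator(theta: np.ndarray, include_cov: bool) -> float:
    d = theta[0] + theta[2] + theta[3] + theta[4] + theta[5] + theta[6]
    if include_cov:
        d += 2.0 * theta[1]
    if d == 0:
        raise ZeroDivisionError("phenotypic variance is zero")
    return float(d)


def heritability(vc: VarianceComponents, include_cov: bool = False):
    """(h2_ss, h2_d): genetic variance of each effect over phenotypic.

    With ``include_cov=True`` the phenotypic denominator also carries twice
    the sire-dam genetic covariance.
    """
    t = vc.theta
    d = _denominator(t, include_cov)
    return float(t[0] / d), float(t[2] / d)


def repeatability(vc: VarianceComponents, include_cov: bool = False):
    """(re_ss, re_d): (genetic + permanent-environment) over phenotypic."""
    t = vc.theta
    d = _denominator(t, include_cov)
    return float((t[0] + t[3]) / d), float((t[2] + t[4]) / d)


def genetic_correlation(vc: VarianceComponents) -> float:
    """Sire-dam genetic correlation sigma_mf / sqrt(sigma2_m sigma2_f)."""
    t = vc.theta
    if t[0] <= 0 or t[2] <= 0:
        raise ValueError("genetic correlation undefined for zero variance")
    r = t[1] / np.sqrt(t[0] * t[2])
    return float(np.clip(r, -1.0, 1.0))


def _target_gradient(theta: np.ndarray, target: str, include_cov: bool) -> np.ndarray:
    """Analytic gradient of a derived parameter w.r.t. the 7 components."""
    t = np.asarray(theta, dtype=float)
    g = np.zeros(7)
    if target == "r":
        r = t[1] / np.sqrt(t[0] * t[2])
        g[0] = -0.5 * r / t[0]
        g[1] = 1.0 / np.sqrt(t[0] * t[2])
        g[2] = -0.5 * r / t[2]
        return g
    d = _denominator(t, include_cov)
    numerators = {
        "h2_ss": t[0],
        "h2_d": t[2],
        "re_ss": t[0] + t[3],
        "re_d": t[2] + t[4],
    }
    dnum = {
        "h2_ss": np.array([1, 0, 0, 0, 0, 0, 0], dtype=float),
        "h2_d": np.array([0, 0, 1, 0, 0, 0, 0], dtype=float),
        "re_ss": np.array([1, 0, 0, 1, 0, 0, 0], dtype=float),
        "re_d": np.array([0, 0, 1, 0, 1, 0, 0], dtype=float),
    }
    if target not in numerators:
        raise ValueError(f"unknown target {target!r}")
    num = numerators[target]
    dden = np.array([1, 2.0 if include_cov else 0.0, 1, 1, 1, 1, 1])
    return (dnum[target] * d - num * dden) / d**2


def delta_method_se(
    vc: VarianceComponents,
    target,
    include_cov: bool = False,
) -> float:
    """Delta-method standard error of a derived parameter.

    ``target`` is one of ``{"h2_ss", "h2_d", "re_ss", "re_d", "r"}`` or a
    callable f(theta) (gradient then by central finite differences).
    SE = sqrt(g' C g) with C the sampling covariance of the components.
    """
    if vc.cov is None:
        raise ValueError("variance components carry no sampling covariance")
    C = np.asarray(vc.cov, dtype=float)
    ev = np.linalg.eigvalsh((C + C.T) / 2)
    if ev[0] < -1e-8 * max(1.0, ev[-1]):
        raise ValueError("sampling covariance is not positive semi-definite")
    t = vc.theta
    if callable(target):
        g = np.zeros(7)
        for j in range(7):
            h = 1e-6 * max(abs(t[j]), 1e-8)
            tp, tm = t.copy(), t.copy()
            tp[j] += h
            tm[j] -= h
            g[j] = (target(tp) - target(tm)) / (2 * h)
    else:
        g = _target_gradient(t, target, include_cov)
    return float(np.sqrt(max(g @ C @ g, 0.0)))


def wald_test(estimate: float, se: float) -> float:
    """Two-sided Wald p-value: 2 (1 - Phi(|estimate| / SE))."""
    if se <= 0:
        raise ValueError("SE must be positive")
    z = abs(estimate) / se
    return float(2.0 * stats.norm.sf(z))


def derive_parameters(
    vc: VarianceComponents, include_cov: bool = False
) -> DerivedParameters:
    """All derived parameters with delta-method SEs and Wald p-values."""
    h2_ss, h2_d = heritability(vc, include_cov)
    re_ss, re_d = repeatability(vc, include_cov)
    r = genetic_correlation(vc)
    out = DerivedParameters(h2_ss=h2_ss, h2_d=h2_d, re_ss=re_ss, re_d=re_d, r=r)
    if vc.cov is not None:
        for name, est in (
            ("h2_ss", h2_ss),
            ("h2_d", h2_d),
            ("re_ss", re_ss),
            ("re_d", re_d),
            ("r", r),
        ):
            se = delta_method_se(vc, name, include_cov)
            setattr(out, f"se_{name}", se)
            if se > 0:
                setattr(out, f"p_{name}", wald_test(est, se))
    return out
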