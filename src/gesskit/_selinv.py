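"""Sparse LDL' factorization and selected inversion for SPD systems.

Two numba-compiled kernels back the REML engine:

* an up-looking sparse LDL' factorization (the classic compact algorithm:
  elimination-tree symbolic pass, then one sparse triangular solve per
  row).  Its L pattern is the exact elimination closure, which the
  selected inversion below requires;
* the Takahashi selected inverse: the entries of (L D L')^-1 on the
  pattern of L + L', computed exactly by the recursion

      Z_ij = - sum_{k > j, L_kj != 0} L_kj Z_ik        (i > j)
      Z_jj = 1/d_j - sum_{k > j, L_kj != 0} L_kj Z_kj

  processed column-by-column from last to first.  Every lookup Z_ik lies
  on the pattern by the clique (fill-path) property of the closed
  factorization, so the recursion is exact.  These entries are all the
  REML score needs: traces of C^-1 against matrices whose pattern is
  contained in the pattern of C.

A fill-reducing ordering must be applied by the caller (the matrix is
factorized as given); forward/backward substitution, log-determinant and
the selected inverse all operate on the same arrays.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba present in supported envs

    def njit(*a, **k):  # type: ignore[misc]
        if len(a) == 1 and callable(a[0]):
            return a[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _ldl_factor_kernel(n, Ap, Ai, Ax):  # pragma: no cover - jitted
    parent = np.full(n, -1, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    Lnz = np.zeros(n, dtype=np.int64)
    # symbolic pass: elimination tree and column counts
    for k in range(n):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i < k:
                while flag[i] != k:
                    if parent[i] == -1:
                        parent[i] = k
                    Lnz[i] += 1
                    flag[i] = k
                    i = parent[i]
    Lp = np.zeros(n + 1, dtype=np.int64)
    for k in range(n):
        Lp[k + 1] = Lp[k] + Lnz[k]
    Li = np.zeros(Lp[n], dtype=np.int64)
    Lx = np.zeros(Lp[n], dtype=np.float64)
    D = np.zeros(n)
    Y = np.zeros(n)
    pattern = np.empty(n, dtype=np.int64)
    lnz_cur = np.zeros(n, dtype=np.int64)
    flag[:] = -1
    ok = True
    for k in range(n):
        top = n
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            Y[i] += Ax[p]
            ln = 0
            while flag[i] != k:
                pattern[ln] = i
                ln += 1
                flag[i] = k
                i = parent[i]
            while ln > 0:
                ln -= 1
                top -= 1
                pattern[top] = pattern[ln]
        D[k] = Y[k]
        Y[k] = 0.0
        for s in range(top, n):
            i = pattern[s]
            yi = Y[i]
            Y[i] = 0.0
            p2 = Lp[i] + lnz_cur[i]
            for p in range(Lp[i], p2):
                Y[Li[p]] -= Lx[p] * yi
            lki = yi / D[i]
            D[k] -= lki * yi
            Li[p2] = k
            Lx[p2] = lki
            lnz_cur[i] += 1
        if D[k] <= 0.0:
            ok = False
            break
    return Lp, Li, Lx, D, ok


@njit(cache=True)
def _ldl_solve_kernel(Lp, Li, Lx, D, X):  # pragma: no cover - jitted
    n = D.size
    m = X.shape[1]
    for j in range(n):  # forward: L y = b
        for p in range(Lp[j], Lp[j + 1]):
            i = Li[p]
            lx = Lx[p]
            for c in range(m):
                X[i, c] -= lx * X[j, c]
    for j in range(n):
        for c in range(m):
            X[j, c] /= D[j]
    for j in range(n - 1, -1, -1):  # back: L' x = y
        for p in range(Lp[j], Lp[j + 1]):
            i = Li[p]
            lx = Lx[p]
            for c in range(m):
                X[j, c] -= lx * X[i, c]
    return X


@njit(cache=True)
def _takahashi_kernel(n, Lp, Li, Lx, dinv, mmax):  # pragma: no cover - jitted
    """Clique-gather Takahashi recursion on a closed strictly-lower pattern.

    Per column j the dense block M[a, b] = Z[rows_a, rows_b] over the
    column's rows is gathered by scanning the already-finished columns
    (all needed entries are on the pattern), then the column is updated
    with one mat-vec.
    """
    Zx = np.zeros(Lx.size)
    Zd = np.zeros(n)
    pos = np.full(n, -1, dtype=np.int64)
    M = np.zeros((mmax, mmax))
    for j in range(n - 1, -1, -1):
        start = Lp[j]
        end = Lp[j + 1]
        m = end - start
        if m == 0:
            Zd[j] = dinv[j]
            continue
        for a in range(m):
            pos[Li[start + a]] = a
        for a in range(m):
            for b in range(m):
                M[a, b] = 0.0
        for b in range(m):
            k = Li[start + b]
            M[b, b] = Zd[k]
            for idx in range(Lp[k], Lp[k + 1]):
                a = pos[Li[idx]]
                if a >= 0:
                    M[a, b] = Zx[idx]
                    M[b, a] = Zx[idx]
        s_d = 0.0
        for a in range(m):
            s = 0.0
            for b in range(m):
                s += M[a, b] * Lx[start + b]
            Zx[start + a] = -s
            s_d += Lx[start + a] * s
        Zd[j] = dinv[j] + s_d
        for a in range(m):
            pos[Li[start + a]] = -1
    return Zx, Zd


class SparseLDL:
    """LDL' factorization of an SPD sparse matrix in a given ordering.

    Parameters
    ----------
    C : sparse SPD matrix (any scipy format).
    order : optional fill-reducing permutation (C[order][:, order] is
        factorized); solves and the selected inverse are expressed in the
        original index space.
    """

    def __init__(self, C: sp.spmatrix, order: np.ndarray | None = None):
        C = sp.csc_matrix(C)
        n = C.shape[0]
        self.n = n
        self.order = None if order is None else np.asarray(order, dtype=np.int64)
        Cp = C if self.order is None else C[self.order][:, self.order]
        upper = sp.triu(Cp, format="csc")
        upper.sort_indices()
        Lp, Li, Lx, D, ok = _ldl_factor_kernel(
            n,
            upper.indptr.astype(np.int64),
            upper.indices.astype(np.int64),
            upper.data.astype(np.float64),
        )
        if not ok:
            raise RuntimeError("matrix is not positive definite")
        self.Lp, self.Li, self.Lx, self.D = Lp, Li, Lx, D

    @property
    def log_det(self) -> float:
        return float(np.sum(np.log(self.D)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        squeeze = b.ndim == 1
        B = b[:, None] if squeeze else b
        B = np.array(B, dtype=np.float64, order="C", copy=True)
        if self.order is not None:
            B = np.ascontiguousarray(B[self.order])
        X = _ldl_solve_kernel(self.Lp, self.Li, self.Lx, self.D, B)
        if self.order is not None:
            out = np.empty_like(X)
            out[self.order] = X
            X = out
        return X[:, 0] if squeeze else X

    def selected_inverse(self) -> sp.csc_matrix:
        """Entries of C^-1 on the pattern of L + L', exactly.

        Entries off that pattern are absent from the returned matrix (not
        zero in C^-1, simply not computed), so it must only be used
        against matrices whose pattern is contained in the pattern of C.
        """
        mmax = int(np.diff(self.Lp).max()) if self.n and self.Lp[-1] else 1
        Zx, Zd = _takahashi_kernel(
            self.n, self.Lp, self.Li, self.Lx, 1.0 / self.D, max(mmax, 1)
        )
        idx = (
            np.arange(self.n, dtype=np.int64)
            if self.order is None
            else self.order
        )
        col_of = np.repeat(np.arange(self.n), np.diff(self.Lp))
        rows = idx[self.Li]
        cols = idx[col_of]
        drows = idx[np.arange(self.n)]
        return sp.coo_matrix(
            (
                np.concatenate([Zx, Zx, Zd]),
                (
                    np.concatenate([rows, cols, drows]),
                    np.concatenate([cols, rows, drows]),
                ),
            ),
            shape=(self.n, self.n),
        ).tocsc()
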