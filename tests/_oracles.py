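"""Independent reference implementations used as test oracles.

Everything here is deliberately naive and dense: relationship matrices via
the gene-flow decomposition A = T D T', mixed-model solutions via explicit
generalized least squares on the full covariance V, and the restricted
log-likelihood evaluated directly from V.  None of it shares code with the
package's sparse implementations.
"""

from __future__ import annotations

import numpy as np


def relationship_via_gene_flow(sire, dam, f=None):
    """A = T D T' from the gene-flow (T) decomposition.

    ``sire``/``dam`` are arrays of parent row indices (-1 unknown) in
    topological order.  Mendelian-sampling variances d_i use the parents'
    inbreeding, obtained from the recursion itself (diag(A) = 1 + F).
    """
    n = len(sire)
    T = np.zeros((n, n))
    d = np.zeros(n)
    A = np.zeros((n, n))
    for i in range(n):
        T[i, i] = 1.0
        if sire[i] >= 0:
            T[i] += 0.5 * T[sire[i]]
        if dam[i] >= 0:
            T[i] += 0.5 * T[dam[i]]
        fs = A[sire[i], sire[i]] - 1.0 if sire[i] >= 0 else -1.0
        fd = A[dam[i], dam[i]] - 1.0 if dam[i] >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        # running A needed only for parent inbreeding on the diagonal
        A[: i + 1, : i + 1] = (T[: i + 1, : i + 1] * d[: i + 1]) @ T[
            : i + 1, : i + 1
        ].T
    return A


def dense_v_matrix(design, theta):
    """Explicit phenotypic covariance V for a fitted design at theta."""
    W = design.W.toarray()
    n = design.n
    V = theta[6] * np.eye(n)
    sl = design.slices
    if design.spec.include_genetic:
        A = design.ainv  # invert the sparse A^-1 exactly
        A = np.linalg.inv(A.toarray())
        g0 = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        Z = W[:, sl["u_m"].start : sl["u_f"].stop]
        G = np.kron(g0, A)
        V += Z @ G @ Z.T
    for nm, t in (("pe_m", theta[3]), ("pe_f", theta[4]), ("hym", theta[5])):
        if nm in sl:
            Zk = W[:, sl[nm]]
            V += t * (Zk @ Zk.T)
    return V


def gls_solutions(design, theta):
    """GLS fixed effects and BLUP random effects from dense V."""
    y = design.y
    p = design.p
    W = design.W.toarray()
    X = W[:, :p]
    V = dense_v_matrix(design, theta)
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    beta = np.linalg.solve(XtVi @ X, XtVi @ y)
    resid = y - X @ beta
    sol = [beta]
    sl = design.slices
    if design.spec.include_genetic:
        A = np.linalg.inv(design.ainv.toarray())
        g0 = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        Z = W[:, sl["u_m"].start : sl["u_f"].stop]
        G = np.kron(g0, A)
        sol.append(G @ Z.T @ Vi @ resid)
    for nm, t in (("pe_m", theta[3]), ("pe_f", theta[4]), ("hym", theta[5])):
        if nm in sl:
            Zk = W[:, sl[nm]]
            sol.append(t * (Zk.T @ Vi @ resid))
    return np.concatenate(sol)


def dense_restricted_loglik(design, theta):
    """REML log-likelihood evaluated directly from the dense V."""
    y = design.y
    p = design.p
    X = design.W.toarray()[:, :p]
    V = dense_v_matrix(design, theta)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    quad = float(r @ Vi @ r)
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    n = len(y)
    return -0.5 * (ld_v + ld_x + quad + (n - p) * np.log(2 * np.pi))


def prediction_error_variance(design, theta):
    """Dense inverse of the full MME coefficient matrix."""
    C, _ = design.assemble(theta)
    return np.linalg.inv(C.toarray())
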