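"""Pedigree ordering, inbreeding and numerator-relationship algebra.

The numerator relationship matrix A (diagonal 1 + F, F the inbreeding
coefficient) defines the covariance structure of the correlated service-sire
and dam genetic effects: cov([u_m; u_f]) = G0 (x) A.  The mixed-model
equations need the sparse inverse of A, obtained from Henderson's rules with
inbreeding; inbreeding coefficients come from the Meuwissen-Luo recursion.

Unknown parents are treated as unrelated non-inbred founders; external ids
are mapped to dense integer codes internally and preserved on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = -1

__all__ = [
    "Pedigree",
    "sort_pedigree",
    "inbreeding",
    "a_submatrix",
    "a_inverse",
    "read_pedigree_csv",
    "write_pedigree_csv",
]


@dataclass
class Pedigree:
    """Topologically ordered pedigree with integer-coded parents.

    Attributes
    ----------
    ids : list
        External animal identifiers, in topological order (parents before
        offspring).
    sire, dam : np.ndarray of int
        Row index of each animal's sire/dam, ``-1`` when unknown.
    sex : np.ndarray of str
        ``"M"`` or ``"F"`` (``"U"`` when unstated).
    f : np.ndarray of float
        Inbreeding coefficients, founders 0.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    f: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype=object)
        if self.f is None:
            self.f = inbreeding(self)
        self._index = {a: i for i, a in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id) -> int:
        try:
            return self._index[animal_id]
        except KeyError:
            raise KeyError(f"animal {animal_id!r} not in pedigree") from None

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.ids, dtype=object)

        def _parent(idx: np.ndarray) -> np.ndarray:
            out = np.full(len(self), "0", dtype=object)
            known = idx >= 0
            out[known] = ids[idx[known]]
            return out

        return pd.DataFrame(
            {
                "animal": ids,
                "sire": _parent(self.sire),
                "dam": _parent(self.dam),
                "sex": self.sex,
                "f": self.f,
            }
        )


class PedigreeCycleError(ValueError):
    """An animal is its own ancestor."""


def sort_pedigree(rows: pd.DataFrame) -> Pedigree:
    """Topologically sort raw pedigree rows into a :class:`Pedigree`.

    Parameters
    ----------
    rows : DataFrame
        Columns ``animal``, ``sire``, ``dam`` and optionally ``sex``.
        ``"0"``, ``0``, empty string or NaN mark unknown parents.  Parents
        that appear only as parents are added as founders.

    Raises
    ------
    PedigreeCycleError
        If the ancestry graph has a cycle; the message names one animal on it.
    ValueError
        If animal ids are duplicated.
    """
    rows = rows.copy()
    animals = list(rows["animal"])
    if len(set(animals)) != len(animals):
        dup = rows["animal"][rows["animal"].duplicated()].iloc[0]
        raise ValueError(f"duplicate animal id {dup!r}")

    def _clean(v):
        if pd.isna(v) or v == 0 or v == "0" or v == "":
            return None
        return v

    parent_of = {}
    sex_in = {}
    if "sex" in rows.columns:
        for a, s in zip(rows["animal"], rows["sex"]):
            if not pd.isna(s):
                sex_in[a] = s
    for a, s, d in zip(rows["animal"], rows["sire"], rows["dam"]):
        parent_of[a] = (_clean(s), _clean(d))

    # implicit founders: parents never listed as animals
    known = set(parent_of)
    extra = []
    for a, (s, d) in list(parent_of.items()):
        for p, psex in ((s, "M"), (d, "F")):
            if p is not None and p not in known:
                known.add(p)
                extra.append(p)
                parent_of[p] = (None, None)
                sex_in.setdefault(p, psex)
    # infer sex from parental role where unstated
    for a, (s, d) in parent_of.items():
        if s is not None:
            sex_in.setdefault(s, "M")
        if d is not None:
            sex_in.setdefault(d, "F")

    # Kahn-style topological order, deterministic (input order preserved)
    order: list = []
    state: dict = {}

    def _visit(a) -> None:
        stack = [(a, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 2
                order.append(node)
                continue
            st = state.get(node, 0)
            if st == 2:
                continue
            if st == 1:
                raise PedigreeCycleError(
                    f"ancestry cycle detected through animal {node!r}"
                )
            state[node] = 1
            stack.append((node, True))
            s, d = parent_of[node]
            for p in (d, s):
                if p is not None and state.get(p, 0) != 2:
                    if state.get(p, 0) == 1:
                        raise PedigreeCycleError(
                            f"ancestry cycle detected through animal {p!r}"
                        )
                    stack.append((p, False))

    for a in extra + animals:
        if state.get(a, 0) != 2:
            _visit(a)

    index = {a: i for i, a in enumerate(order)}
    n = len(order)
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    sex = np.array([sex_in.get(a, "U") for a in order], dtype=object)
    for a in order:
        s, d = parent_of[a]
        if s is not None:
            sire[index[a]] = index[s]
        if d is not None:
            dam[index[a]] = index[d]
    return Pedigree(ids=order, sire=sire, dam=dam, sex=sex)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo recursion.

    F_i = a(sire_i, dam_i)/2; founders have F = 0.  Runs in O(n * pedigree
    depth^2) using the L-vector decomposition A = L D L'.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    f = np.zeros(n)
    d = np.zeros(n)  # Mendelian-sampling variance coefficients
    for i in range(n):
        s, dm = sire[i], dam[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[dm] if dm >= 0 else -1.0
        d[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or dm < 0:
            f[i] = 0.0
            continue
        # accumulate L row for animal i over its ancestors
        L = {i: 1.0}
        fi = -1.0
        # process ancestors in decreasing index order
        stack = sorted(L)
        while stack:
            j = stack.pop()  # largest index
            lj = L.pop(j)
            fi += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p in L:
                        L[p] += 0.5 * lj
                    else:
                        L[p] = 0.5 * lj
                        stack.append(p)
            stack.sort()
        f[i] = fi
        d[i] = 0.5 - 0.25 * (fs + fd)
    return f


def a_submatrix(ped: Pedigree, ids=None) -> np.ndarray:
    """Dense numerator-relationship block for the given external ids.

    Uses the tabular recursion a_ij = (a_{i,s(j)} + a_{i,d(j)})/2,
    a_jj = 1 + F_j, over the full pedigree, then extracts the requested rows
    and columns.  Intended for desk-scale subsets (the full matrix for a few
    thousand animals at most).
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        ajj = 1.0
        if s >= 0 and d >= 0:
            ajj += 0.5 * A[s, d]
        A[j, j] = ajj
        # off-diagonals with all earlier animals
        if j > 0:
            row = np.zeros(j)
            if s >= 0:
                row += 0.5 * A[s, :j]
            if d >= 0:
                row += 0.5 * A[d, :j]
            A[j, :j] = row
            A[:j, j] = row
    if ids is None:
        return A
    idx = np.array([ped.index_of(a) for a in ids], dtype=np.int64)
    return A[np.ix_(idx, idx)]


def a_inverse(ped: Pedigree) -> sp.csc_matrix:
    """Sparse inverse of A via Henderson's rules with inbreeding.

    Each animal contributes at most 9 nonzeros through the triple
    (animal, sire, dam) weighted by the inverse Mendelian-sampling variance
    1/d_i with d_i = 0.5 - 0.25 (F_s + F_d) (terms for unknown parents drop
    out and d_i grows accordingly).
    """
    n = len(ped)
    sire, dam, f = ped.sire, ped.dam, ped.f
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = sire[i], dam[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[d] if d >= 0 else -1.0
        alpha = 1.0 / (0.5 - 0.25 * (fs + fd))
        entries = [(i, 1.0)]
        if s >= 0:
            entries.append((s, -0.5))
        if d >= 0:
            entries.append((d, -0.5))
        for a, wa in entries:
            for b, wb in entries:
                rows.append(a)
                cols.append(b)
                vals.append(alpha * wa * wb)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def mendelian_variance_coefficients(ped: Pedigree) -> np.ndarray:
    """d_i = var(Mendelian sampling)/sigma2_a per animal (founders d=1)."""
    fs = np.where(ped.sire >= 0, ped.f[np.maximum(ped.sire, 0)], -1.0)
    fd = np.where(ped.dam >= 0, ped.f[np.maximum(ped.dam, 0)], -1.0)
    return 0.5 - 0.25 * (fs + fd)


def log_det_a(ped: Pedigree) -> float:
    """log |A| = sum_i log d_i from the factorization A = T D T'."""
    return float(np.sum(np.log(mendelian_variance_coefficients(ped))))


def read_pedigree_csv(path) -> Pedigree:
    """Read ``animal,sire,dam[,sex,...]`` CSV ("0"/empty = unknown parent)."""
    df = pd.read_csv(path, dtype={"animal": str, "sire": str, "dam": str})
    return sort_pedigree(df)


def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)
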