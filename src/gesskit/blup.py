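"""BLUP solutions, reliabilities, de-regressed proofs, EBV correlations.

Breeding values for the two correlated genetic effects (service sire GESS,
dam GED) come from Henderson's mixed-model equations at converged variance
components.  Reliability is the squared accuracy 1 - PEV / ((1 + F) sigma2_u)
with the prediction-error variance read off the inverse MME coefficient
matrix (exact; intended for desk-scale systems).  De-regressed proofs (DRP)
follow the Garrick, Taylor & Fernando (2009) construction: the parent
average and the shrinkage of the own contribution are removed and each DRP
receives an information weight

    w_i = (1 - h2) / ((c + (1 - r2_i) / r2_i) h2)

with c the fraction of genetic variance not accounted for by markers.
Approximate genetic correlations between two EBV sets use Calo's method:
the raw EBV correlation scaled by sqrt(sum r2_1 sum r2_2) / sum sqrt(r2_1 r2_2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gesskit.pedigree import Pedigree
from gesskit.reml import MixedModelDesign, VarianceComponents

__all__ = [
    "BlupSolution",
    "solve_blup",
    "reliability",
    "deregress",
    "approx_genetic_correlation",
]


@dataclass
class BlupSolution:
    """All MME solutions plus the factorization for downstream PEV work."""

    design: MixedModelDesign
    components: VarianceComponents
    solutions: np.ndarray

    def effect(self, name: str) -> np.ndarray:
        return self.solutions[self.design.slices[name]]

    def ebv_table(self, effect: str = "u_m") -> pd.DataFrame:
        """Per-animal EBV table for one genetic effect (pedigree order)."""
        tag = "GESS" if effect == "u_m" else "GED"
        return pd.DataFrame(
            {
                "animal": self.design.ped.ids,
                "effect": tag,
                "ebv": self.effect(effect),
            }
        )


def solve_blup(
    records: pd.DataFrame,
    spec,
    ped: Pedigree,
    components: VarianceComponents,
) -> BlupSolution:
    """Solve the MME at converged components; returns all solutions.

    Animals without own records or descendants receive parent-average EBVs
    automatically through the A-inverse ties.  Redundant fixed-effect
    levels are absorbed by reference-level (treatment) coding at design
    construction.
    """
    design = MixedModelDesign(records, spec, ped)
    fac = design.factorize(components.theta)
    sol = fac.sol
    fac_cache = fac
    out = BlupSolution(design=design, components=components, solutions=sol)
    out._factor = fac_cache  # kept for reliability()
    return out


def reliability(
    blup: BlupSolution,
    effect: str = "u_m",
    animals=None,
) -> pd.DataFrame:
    """Reliability r2_i = 1 - PEV_i / ((1 + F_i) sigma2_u) per animal.

    PEV is the diagonal of the inverse MME coefficient matrix on the
    requested genetic block, obtained by unit-vector solves on the stored
    factorization (exact).  ``animals`` restricts to a subset of external
    ids (default: every pedigree animal).
    """
    design = blup.design
    ped = design.ped
    fac = blup._factor
    sl = design.slices[effect]
    sigma2_u = (
        blup.components.sigma2_m if effect == "u_m" else blup.components.sigma2_f
    )
    if animals is None:
        animals = list(ped.ids)
    idx = np.array([ped.index_of(a) for a in animals], dtype=np.int64)
    rel = np.zeros(len(idx))
    dim = design.dim
    for k, i in enumerate(idx):
        e = np.zeros(dim)
        e[sl.start + i] = 1.0
        pev = float(fac.solve(e)[sl.start + i])
        denom = (1.0 + ped.f[i]) * sigma2_u
        rel[k] = 1.0 - pev / denom if denom > 0 else 0.0
    rel = np.clip(rel, 0.0, 1.0 - 1e-12)
    return pd.DataFrame({"animal": animals, "reliability": rel})


def _parent_average(ped: Pedigree, ebv: np.ndarray):
    """PA_i and the PA reliability proxy (r2_s + r2_d)/4 need rel; here EBV only."""
    pa = np.zeros(len(ped))
    for i in range(len(ped)):
        s, d = ped.sire[i], ped.dam[i]
        tot = 0.0
        if s >= 0:
            tot += 0.5 * ebv[s]
        if d >= 0:
            tot += 0.5 * ebv[d]
        pa[i] = tot
    return pa


def deregress(
    ebv_table: pd.DataFrame,
    ped: Pedigree,
    h2: float,
    c: float = 0.5,
    min_accuracy: float = 0.10,
    simple: bool = False,
) -> pd.DataFrame:
    """Garrick-style de-regressed proofs with information weights.

    Parameters
    ----------
    ebv_table : DataFrame
        Columns ``animal``, ``ebv``, ``reliability``.
    h2 : float
        Heritability of the underlying evaluation (for the weights).
    c : float
        Fraction of genetic variance not accounted for by markers.
    min_accuracy : float
        Animals with accuracy sqrt(r2) at or below this are flagged
        ``included=False`` (and excluded downstream).
    simple : bool
        If True, DRP = EBV / r2 (no parent-average removal).

    Returns the table with ``drp``, ``weight``, ``included`` columns.
    DRP_i = PA_i + (EBV_i - PA_i) / r2*, with r2* the own-information
    reliability after removing the parent average,
    r2* = (r2_i - r2_PA) / (1 - r2_PA), r2_PA = (r2_s + r2_d)/4.
    """
    tab = ebv_table.reset_index(drop=True).copy()
    rel = tab["reliability"].to_numpy(dtype=float)
    ebv = tab["ebv"].to_numpy(dtype=float)
    if np.any(rel >= 1.0):
        raise ValueError("reliabilities must be < 1")

    rel_of = dict(zip(tab["animal"], rel))
    ebv_of = dict(zip(tab["animal"], ebv))
    n = len(tab)
    pa = np.zeros(n)
    rel_pa = np.zeros(n)
    for k, animal in enumerate(tab["animal"]):
        i = ped.index_of(animal)
        s, d = ped.sire[i], ped.dam[i]
        sid = ped.ids[s] if s >= 0 else None
        did = ped.ids[d] if d >= 0 else None
        es = ebv_of.get(sid, 0.0) if sid is not None else 0.0
        ed = ebv_of.get(did, 0.0) if did is not None else 0.0
        rs = rel_of.get(sid, 0.0) if sid is not None else 0.0
        rd = rel_of.get(did, 0.0) if did is not None else 0.0
        pa[k] = 0.5 * (es + ed)
        rel_pa[k] = 0.25 * (rs + rd)

    drp = np.full(n, np.nan)
    weight = np.full(n, np.nan)
    included = np.zeros(n, dtype=bool)
    acc = np.sqrt(np.clip(rel, 0.0, None))
    for k in range(n):
        if rel[k] <= 0:
            continue
        if simple:
            drp[k] = ebv[k] / rel[k]
            r2_star = rel[k]
        else:
            r2_star = (rel[k] - rel_pa[k]) / (1.0 - rel_pa[k])
            if r2_star <= 0:
                continue
            drp[k] = pa[k] + (ebv[k] - pa[k]) / r2_star
        weight[k] = (1.0 - h2) / ((c + (1.0 - rel[k]) / rel[k]) * h2)
        included[k] = acc[k] > min_accuracy
    tab["parent_average"] = pa
    tab["drp"] = drp
    tab["weight"] = weight
    tab["included"] = included
    return tab


def approx_genetic_correlation(
    ebv1: np.ndarray,
    rel1: np.ndarray,
    ebv2: np.ndarray,
    rel2: np.ndarray,
    se_method: str = "closed_form",
    n_bootstrap: int = 1000,
    seed: int = 0,
):
    """Calo-type approximate genetic correlation between two EBV sets.

    r_approx = cor(EBV1, EBV2) * sqrt(sum(r2_1) * sum(r2_2)) / sum(sqrt(r2_1 r2_2)),
    clamped to [-1, 1].  The reliability factor is >= 1 by Cauchy-Schwarz,
    so |r_approx| >= |raw Pearson|.

    SE by the reliability-weighted large-sample form
    (1 - r^2) / sqrt(n_eff - 2) with n_eff the effective number of animals
    implied by the weights sqrt(r2_1 r2_2), or by a nonparametric bootstrap
    (``se_method="bootstrap"``).

    Returns (r_approx, se).
    """
    ebv1 = np.asarray(ebv1, dtype=float)
    ebv2 = np.asarray(ebv2, dtype=float)
    rel1 = np.asarray(rel1, dtype=float)
    rel2 = np.asarray(rel2, dtype=float)
    n = len(ebv1)
    if not (len(ebv2) == len(rel1) == len(rel2) == n):
        raise ValueError("inputs must have equal length")
    if n < 3:
        raise ValueError("need at least 3 common animals")
    if np.any(rel1 <= 0) or np.any(rel2 <= 0) or np.any(rel1 > 1) or np.any(rel2 > 1):
        raise ValueError("reliabilities must lie in (0, 1]")

    def _calo(e1, e2, r1, r2):
        raw = np.corrcoef(e1, e2)[0, 1]
        factor = np.sqrt(np.sum(r1) * np.sum(r2)) / np.sum(np.sqrt(r1 * r2))
        return float(np.clip(raw * factor, -1.0, 1.0))

    r = _calo(ebv1, ebv2, rel1, rel2)
    if se_method == "closed_form":
        w = np.sqrt(rel1 * rel2)
        n_eff = float(np.sum(w)) ** 2 / float(np.sum(w**2))
        se = (1.0 - r**2) / np.sqrt(max(n_eff - 2.0, 1.0))
    elif se_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            if np.std(ebv1[idx]) == 0 or np.std(ebv2[idx]) == 0:
                reps[b] = np.nan
                continue
            reps[b] = _calo(ebv1[idx], ebv2[idx], rel1[idx], rel2[idx])
        se = float(np.nanstd(reps, ddof=1))
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return r, float(se)
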