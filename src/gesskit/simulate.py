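"""Synthetic herd generator for the correlated service-sire/dam model.

Emulates the data-generating process the analysis assumes: a multi-
generation pedigree, bivariate (service-sire, dam) breeding values gene-
dropped with covariance G0 (x) A, permanent-environment and herd-year-month
effects, repeated insemination/calving records per cow with skewed service
counts per bull, and SNP genotypes transmitted Mendelianly from founder
allele frequencies.

The defaults mirror a scaled-down commercial Holstein population: binary
conception outcomes with ~0.43 incidence, calving-ease scores >1 at ~5.2%,
stillbirth at ~6.7%, gestation length centred at 278.36 d, and a Zipf-like
service-sire usage giving a heavy-tailed services-per-bull distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from gesskit.pedigree import Pedigree, UNKNOWN

__all__ = [
    "SimConfig",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_records",
    "simulate_genotypes",
    "simulate_herd",
    "write_event_log",
]


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Parameters of one synthetic herd.

    The seven (co)variance parameters play the role of simulation truth for
    the analysis model y = Xb + Z1 u_m + Z2 u_f + W1 pe_m + W2 pe_f
    + Zh hym + e with cov([u_m; u_f]) = G0 (x) A.

    Attributes
    ----------
    g0 : 2x2 array
        Genetic covariance of the service-sire and dam effects,
        [[sigma2_m, sigma_mf], [sigma_mf, sigma2_f]]; must be symmetric PSD.
    trait_kind : {"binary", "ordinal3", "continuous"}
        Observed-scale coding: latent Gaussian thresholded at ``cut_points``
        for binary/ordinal traits, identity for continuous.
    services_per_cow_parity : dict
        Distribution spec for insemination counts within a cow-parity,
        e.g. ``{"kind": "geometric", "p": 0.5, "max": 6}`` (relevant for
        insemination-success traits; calving traits get one record/parity).
    sire_usage_zipf : float
        Exponent of the Zipf-like weights with which cows draw service
        sires; reproduces the heavy right tail of services per bull.
    qtl_spec : list of (snp_index, effect_m, effect_f)
        Optional major loci whose additive genotype contributions are added
        to the corresponding breeding values.
    """

    n_founders: int = 120
    n_generations: int = 2
    cows_per_generation: int = 300
    bulls_per_generation: int = 15
    n_service_sires: int = 20
    n_parities: int = 3
    sire_usage_zipf: float = 1.1
    services_per_cow_parity: dict = field(
        default_factory=lambda: {"kind": "geometric", "p": 0.45, "max": 8}
    )
    n_herds: int = 4
    n_years: int = 3
    n_months: int = 12
    g0: np.ndarray = field(
        default_factory=lambda: np.array([[3.9844, 3.1303], [3.1303, 3.9699]])
    )
    pe_m_var: float = 1.16e-6
    pe_f_var: float = 0.5436
    hym_var: float = 3.2778
    resid_var: float = 27.1262
    trait_kind: str = "continuous"
    mean: float = 278.36
    cut_points: tuple = ()
    fixed_effect_levels: dict = field(
        default_factory=lambda: {
            "calf_sex": {"M": 0.0, "F": -1.2},
            "parity_group": {"1": 0.0, "2": 0.6, "3+": 0.9},
            "calf_size_group": {"30-40": 0.0, "40-50": 0.8, "50-60": 1.6},
        }
    )
    n_snps: int = 500
    maf_dist: dict = field(
        default_factory=lambda: {"kind": "uniform", "low": 0.05, "high": 0.5}
    )
    qtl_spec: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.g0 = np.asarray(self.g0, dtype=float)
        if self.g0.shape != (2, 2) or abs(self.g0[0, 1] - self.g0[1, 0]) > 1e-12:
            raise ConfigurationError("g0 must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(self.g0)[0] < -1e-10 * max(1.0, self.g0.trace()):
            raise ConfigurationError("g0 must be positive semi-definite")
        for name in ("pe_m_var", "pe_f_var", "hym_var", "resid_var"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.trait_kind not in ("binary", "ordinal3", "continuous"):
            raise ConfigurationError(f"unknown trait_kind {self.trait_kind!r}")
        if self.trait_kind == "binary" and len(self.cut_points) != 1:
            raise ConfigurationError("binary traits need exactly 1 cut point")
        if self.trait_kind == "ordinal3" and len(self.cut_points) != 2:
            raise ConfigurationError("ordinal3 traits need exactly 2 cut points")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["g0"] = self.g0.tolist()
        return d


def _spawn(seed: int, stage: str) -> np.random.Generator:
    """Stage-scoped generator: one root seed, documented stream per stage."""
    return np.random.default_rng(np.random.SeedSequence((seed, _STAGES[stage])))


_STAGES = {"pedigree": 0, "bv": 1, "records": 2, "genotypes": 3}


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Generate a multi-generation pedigree with an AI-stud service pool.

    Founders are unrelated with unknown parents (roughly half male).  Each
    later generation is sired from a rolling stud pool of the most recent
    ``n_service_sires`` bulls, drawn with Zipf-like usage weights — the
    same pool that later services the record cows.  Dams come from the
    previous generation's females.  ``cows_per_generation`` may be a single
    count or a per-generation list (the last entry is the recorded cow
    generation).
    """
    if config.n_founders < 2:
        raise ConfigurationError("need at least 2 founders")
    if config.n_generations < 0:
        raise ConfigurationError("n_generations must be >= 0")
    rng = _spawn(config.seed, "pedigree")

    ids: list = []
    sire: list = []
    dam: list = []
    sex: list = []

    n_male_founders = max(1, config.n_founders // 2)
    for i in range(config.n_founders):
        ids.append(f"F{i:05d}")
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
        sex.append("M" if i < n_male_founders else "F")

    stud = [i for i, s in enumerate(sex) if s == "M"][-config.n_service_sires :]
    prev_females = [i for i, s in enumerate(sex) if s == "F"]
    if config.n_generations > 0 and (not stud or not prev_females):
        raise ConfigurationError("founder pool lacks one sex; cannot breed")

    cows_per_gen = config.cows_per_generation
    if np.isscalar(cows_per_gen):
        cows_per_gen = [int(cows_per_gen)] * config.n_generations

    for g in range(config.n_generations):
        new_males: list = []
        new_females: list = []
        n_off = cows_per_gen[g] + config.bulls_per_generation
        usage = _sire_usage_weights(len(stud), config.sire_usage_zipf, rng)
        sires_g = rng.choice(stud, size=n_off, p=usage)
        dams_g = rng.choice(prev_females, size=n_off)
        for j in range(n_off):
            idx = len(ids)
            is_bull = j < config.bulls_per_generation
            ids.append(f"G{g + 1}{'B' if is_bull else 'C'}{j:05d}")
            sire.append(int(sires_g[j]))
            dam.append(int(dams_g[j]))
            sex.append("M" if is_bull else "F")
            (new_males if is_bull else new_females).append(idx)
        stud = (stud + new_males)[-config.n_service_sires :]
        prev_females = new_females or prev_females

    return Pedigree(
        ids=ids,
        sire=np.array(sire, dtype=np.int64),
        dam=np.array(dam, dtype=np.int64),
        sex=np.array(sex, dtype=object),
    )


def simulate_breeding_values(
    ped: Pedigree, g0: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Gene-drop bivariate breeding values (u_m, u_f) down the pedigree.

    Founders are drawn from N(0, G0).  A descendant is the parent average
    plus a Mendelian-sampling deviation with covariance d_i * G0 where
    d_i = 1/2 - (F_s + F_d)/4 (standard gene dropping with inbreeding;
    terms for unknown parents drop out).  Over replicates the realized
    covariance of the stacked values converges to G0 (x) A.

    Returns an (n, 2) array ordered like the pedigree.
    """
    g0 = np.asarray(g0, dtype=float)
    ev = np.linalg.eigvalsh(g0)
    if ev[0] < -1e-10 * max(1.0, abs(ev).max()):
        raise ValueError("g0 must be positive semi-definite")
    # PSD square root (handles singular G0, e.g. the zero matrix)
    w, v = np.linalg.eigh(g0)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T

    rng = np.random.default_rng(np.random.SeedSequence((seed, _STAGES["bv"])))
    n = len(ped)
    z = rng.standard_normal((n, 2)) @ root.T  # N(0, G0) draws, scaled below
    u = np.zeros((n, 2))
    sire, dam, f = ped.sire, ped.dam, ped.f
    for i in range(n):
        s, d = sire[i], dam[i]
        pa = np.zeros(2)
        fs = f[s] if s >= 0 else -1.0
        fd = f[d] if d >= 0 else -1.0
        if s >= 0:
            pa += 0.5 * u[s]
        if d >= 0:
            pa += 0.5 * u[d]
        di = 0.5 - 0.25 * (fs + fd)
        u[i] = pa + np.sqrt(di) * z[i]
    return u


def _draw_services(rng: np.random.Generator, spec: dict, size: int) -> np.ndarray:
    kind = spec.get("kind", "geometric")
    if kind == "geometric":
        k = rng.geometric(spec.get("p", 0.45), size=size)
    elif kind == "poisson":
        k = 1 + rng.poisson(spec.get("mean", 1.0), size=size)
    elif kind == "fixed":
        k = np.full(size, int(spec.get("value", 1)))
    else:
        raise ConfigurationError(f"unknown services distribution {kind!r}")
    return np.clip(k, 1, int(spec.get("max", 10)))


def _sire_usage_weights(n: int, exponent: float, rng) -> np.ndarray:
    """Zipf-like usage weights, randomly assigned to sires."""
    ranks = rng.permutation(n) + 1
    w = ranks.astype(float) ** (-exponent)
    return w / w.sum()


def simulate_records(
    ped: Pedigree,
    bv: np.ndarray,
    config: SimConfig,
) -> pd.DataFrame:
    """Generate phenotype records under the full mixed model.

    Record cows are the females of the last generation (or founder females
    when ``n_generations == 0``); service sires are the stud bulls that
    sired that generation, drawn again with Zipf-like usage weights — the
    pedigree ties between record cows and their service sires are what
    identifies the genetic (vs permanent-environment) sire variance.  Each
    record carries its herd-year-month label and trait-appropriate
    fixed-effect levels, and

        phenotype = mean + sum(fixed) + u_m(sire) + u_f(cow)
                    + pe_m(sire) + pe_f(cow) + hym + e,

    thresholded at ``config.cut_points`` for binary/ordinal traits.

    For continuous/ordinal calving traits one record per cow-parity is
    produced; for binary insemination traits each cow-parity generates a
    run of services ending at the first conception.
    """
    rng = _spawn(config.seed, "records")
    sexes = np.asarray(ped.sex)
    males = np.flatnonzero(sexes == "M")
    females = np.flatnonzero(sexes == "F")
    if males.size == 0 or females.size == 0:
        raise ConfigurationError("pedigree lacks males or females")
    if config.n_generations > 0:
        cows_per_gen = config.cows_per_generation
        if np.isscalar(cows_per_gen):
            n_last = int(cows_per_gen)
        else:
            n_last = int(cows_per_gen[-1])
        last_gen = np.arange(len(ped) - n_last - config.bulls_per_generation, len(ped))
        cows = last_gen[np.asarray(ped.sex)[last_gen] == "F"]
        service_sires = np.unique(ped.sire[last_gen])
        service_sires = service_sires[service_sires >= 0]
    else:
        cows = females
        service_sires = males[-config.n_service_sires :]
    n_ss = len(service_sires)
    usage = _sire_usage_weights(n_ss, config.sire_usage_zipf, rng)

    pe_m = rng.normal(0.0, np.sqrt(config.pe_m_var), size=len(ped))
    pe_f = rng.normal(0.0, np.sqrt(config.pe_f_var), size=len(ped))
    hym_levels = [
        f"h{h}_y{y}_m{m}"
        for h in range(config.n_herds)
        for y in range(config.n_years)
        for m in range(config.n_months)
    ]
    hym_eff = dict(
        zip(hym_levels, rng.normal(0.0, np.sqrt(config.hym_var), len(hym_levels)))
    )
    herd_of_cow = rng.integers(0, config.n_herds, size=cows.size)

    success_trait = config.trait_kind == "binary" and len(config.cut_points) == 1

    rows = []
    for ci, cow in enumerate(cows):
        herd = herd_of_cow[ci]
        for parity in range(1, config.n_parities + 1):
            year = min(parity - 1, config.n_years - 1)
            if success_trait:
                n_srv = int(_draw_services(rng, config.services_per_cow_parity, 1)[0])
            else:
                n_srv = 1
            month = int(rng.integers(0, config.n_months))
            for srv in range(1, n_srv + 1):
                sire_i = int(rng.choice(service_sires, p=usage))
                month = (month + (0 if srv == 1 else int(rng.integers(1, 3)))) % config.n_months
                hym = f"h{herd}_y{year}_m{month}"
                fixed = 0.0
                levels = {}
                for factor, effects in config.fixed_effect_levels.items():
                    names = list(effects)
                    lv = names[int(rng.integers(0, len(names)))]
                    levels[factor] = lv
                    fixed += effects[lv]
                latent = (
                    config.mean
                    + fixed
                    + bv[sire_i, 0]
                    + bv[cow, 1]
                    + pe_m[sire_i]
                    + pe_f[cow]
                    + hym_eff[hym]
                    + rng.normal(0.0, np.sqrt(config.resid_var))
                )
                if config.trait_kind == "continuous":
                    y = latent
                elif config.trait_kind == "binary":
                    y = float(latent > config.cut_points[0])
                else:  # ordinal3
                    y = 1.0 + float(latent > config.cut_points[0]) + float(
                        latent > config.cut_points[1]
                    )
                row = {
                    "cow": ped.ids[cow],
                    "service_sire": ped.ids[sire_i],
                    "parity": parity,
                    "insemination_number": srv,
                    "hym": hym,
                    "phenotype": y,
                    "latent": latent,
                }
                row.update(levels)
                rows.append(row)
                if success_trait and y == 1.0:
                    break
    return pd.DataFrame(rows)


def simulate_genotypes(ped: Pedigree, config: SimConfig):
    """Gene-drop biallelic SNP genotypes down the pedigree.

    Founder alleles are drawn per SNP from ``maf_dist``; descendants receive
    one uniformly chosen allele from each parent's pair (a missing parent
    contributes a population allele).  Returns a
    :class:`gesskit.gwas.GenotypeMatrix` of additive codes (minor-allele
    dosage 0/1/2) with synthetic map positions, one chromosome per ~1000
    SNPs, ~100 kb spacing.
    """
    from gesskit.gwas import GenotypeMatrix

    if config.n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    spec = config.maf_dist
    rng = _spawn(config.seed, "genotypes")
    m = config.n_snps
    if spec.get("kind", "uniform") == "uniform":
        maf = rng.uniform(spec.get("low", 0.05), spec.get("high", 0.5), size=m)
    elif spec["kind"] == "fixed":
        maf = np.full(m, float(spec["value"]))
    else:
        raise ConfigurationError(f"unknown maf distribution {spec['kind']!r}")
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ConfigurationError("minor allele frequencies must lie in (0, 0.5]")

    n = len(ped)
    # allele pairs, int8: 1 = minor allele carried
    a1 = np.zeros((n, m), dtype=np.int8)
    a2 = np.zeros((n, m), dtype=np.int8)
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0:
            pick = rng.integers(0, 2, size=m, dtype=np.int8)
            a1[i] = np.where(pick == 0, a1[s], a2[s])
        else:
            a1[i] = rng.random(m) < maf
        if d >= 0:
            pick = rng.integers(0, 2, size=m, dtype=np.int8)
            a2[i] = np.where(pick == 0, a1[d], a2[d])
        else:
            a2[i] = rng.random(m) < maf
    codes = (a1 + a2).astype(np.int8)

    snps = pd.DataFrame(
        {
            "snp": [f"snp{j:06d}" for j in range(m)],
            "chrom": [str(1 + j // 1000) for j in range(m)],
            "pos": [100_000 * (1 + j % 1000) for j in range(m)],
            "a1": "A",
            "a2": "B",
        }
    )
    return GenotypeMatrix(
        codes=codes, snps=snps, samples=[str(x) for x in ped.ids]
    )


def apply_qtl_effects(bv: np.ndarray, genotypes, qtl_spec: list) -> np.ndarray:
    """Add additive QTL contributions to the breeding values.

    qtl_spec is a list of (snp_index, effect_m, effect_f); contribution is
    centred dosage times effect, added to u_m and/or u_f.
    """
    out = bv.copy()
    for snp_idx, eff_m, eff_f in qtl_spec:
        x = genotypes.codes[:, snp_idx].astype(float)
        x = x - x.mean()
        out[:, 0] += eff_m * x
        out[:, 1] += eff_f * x
    return out


def simulate_herd(config: SimConfig):
    """Full generator: pedigree, breeding values, records, genotypes, truth.

    Returns (pedigree, bv, records, genotypes, truth_dict).  ``truth``
    carries every simulated (co)variance component for recovery tests.
    """
    ped = simulate_pedigree(config)
    bv = simulate_breeding_values(ped, config.g0, seed=config.seed)
    genotypes = None
    if config.n_snps > 0:
        genotypes = simulate_genotypes(ped, config)
        if config.qtl_spec:
            bv = apply_qtl_effects(bv, genotypes, config.qtl_spec)
    records = simulate_records(ped, bv, config)
    truth = {
        "sigma2_m": float(config.g0[0, 0]),
        "sigma_mf": float(config.g0[0, 1]),
        "sigma2_f": float(config.g0[1, 1]),
        "sigma2_pe_m": config.pe_m_var,
        "sigma2_pe_f": config.pe_f_var,
        "sigma2_hym": config.hym_var,
        "sigma2_e": config.resid_var,
        "trait_kind": config.trait_kind,
        "mean": config.mean,
        "seed": config.seed,
    }
    return ped, bv, records, genotypes, truth


def write_event_log(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Expand analysis-ready service records into a raw insemination log.

    Synthesizes dates so that the editing layer can re-derive CR and NRR56:
    services within a cow-parity are spaced 21-45 days apart, the conceiving
    service (phenotype == 1) is followed by a calving ~278 days later and a
    positive pregnancy diagnosis ~40 days later.
    """
    rng = np.random.default_rng(seed)
    base = pd.Timestamp("2015-01-01")
    rows = []
    for (cow, parity), grp in records.groupby(["cow", "parity"], sort=False):
        t = base + pd.Timedelta(days=int(rng.integers(0, 3000)))
        grp = grp.sort_values("insemination_number")
        conceived = False
        for _, r in grp.iterrows():
            rows.append(
                {
                    "cow": cow,
                    "parity": parity,
                    "event": "insemination",
                    "date": t,
                    "service_sire": r["service_sire"],
                    "ai_technician": r.get("ai_technician", "t1"),
                    "semen_type": r.get("semen_type", "conventional"),
                }
            )
            if r["phenotype"] == 1.0:
                rows.append(
                    {"cow": cow, "parity": parity, "event": "diagnosis_positive",
                     "date": t + pd.Timedelta(days=40)}
                )
                rows.append(
                    {"cow": cow, "parity": parity, "event": "calving",
                     "date": t + pd.Timedelta(days=int(rng.normal(278, 5)))}
                )
                conceived = True
                break
            t = t + pd.Timedelta(days=int(rng.integers(21, 46)))
        del conceived
    return pd.DataFrame(rows)
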