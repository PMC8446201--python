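import numpy as np
import pandas as pd
import pytest

from gesskit.pedigree import Pedigree
from gesskit.reml import TraitModelSpec
from gesskit.simulate import SimConfig, simulate_herd


@pytest.fixture
def trio_pedigree():
    """Unrelated sire and dam plus one offspring."""
    return Pedigree(
        ids=["s", "d", "o"],
        sire=np.array([-1, -1, 0]),
        dam=np.array([-1, -1, 1]),
        sex=np.array(["M", "F", "F"], dtype=object),
    )


def random_pedigree(n, seed, n_founders=None):
    """Random mating pedigree with known sexes, topologically ordered."""
    rng = np.random.default_rng(seed)
    n_founders = n_founders or max(4, n // 10)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    sex = np.array(["M" if i % 2 == 0 else "F" for i in range(n)], dtype=object)
    for i in range(n_founders, n):
        males = [j for j in range(i) if sex[j] == "M"]
        females = [j for j in range(i) if sex[j] == "F"]
        sire[i] = int(rng.choice(males))
        dam[i] = int(rng.choice(females))
    return Pedigree(
        ids=[f"a{i}" for i in range(n)], sire=sire, dam=dam, sex=sex
    )


@pytest.fixture
def small_herd():
    """~1.2k gestation-length records on a 740-animal pedigree."""
    cfg = SimConfig(
        n_founders=100,
        n_generations=2,
        cows_per_generation=300,
        bulls_per_generation=20,
        n_service_sires=20,
        n_parities=4,
        n_herds=3,
        n_years=4,
        n_months=6,
        n_snps=0,
        seed=3,
    )
    ped, bv, records, _, truth = simulate_herd(cfg)
    return ped, records, truth


@pytest.fixture
def tiny_herd():
    """Desk-scale data (n <= 150 records) for dense-oracle comparisons."""
    cfg = SimConfig(
        n_founders=20,
        n_generations=1,
        cows_per_generation=15,
        bulls_per_generation=4,
        n_service_sires=6,
        n_parities=3,
        n_herds=2,
        n_years=2,
        n_months=2,
        n_snps=0,
        seed=11,
    )
    ped, bv, records, _, truth = simulate_herd(cfg)
    return ped, records


@pytest.fixture
def gl_spec():
    return TraitModelSpec(
        trait="GL",
        fixed_factors=["calf_sex", "parity_group", "calf_size_group"],
    )


@pytest.fixture
def toy_event_log():
    """Hand-written insemination/diagnosis/calving log for the edit rules."""
    d = pd.Timestamp
    rows = [
        # cow A parity 1: three services, diagnosis after the third
        ("A", 1, "insemination", d("2020-01-01")),
        ("A", 1, "insemination", d("2020-01-25")),
        ("A", 1, "insemination", d("2020-02-20")),
        ("A", 1, "diagnosis_positive", d("2020-03-30")),
        ("A", 1, "calving", d("2020-11-25")),
        # cow B parity 1: no diagnosis, calving present
        ("B", 1, "insemination", d("2020-02-01")),
        ("B", 1, "insemination", d("2020-03-01")),
        ("B", 1, "calving", d("2020-12-05")),
        # cow C parity 1: no diagnosis, no calving
        ("C", 1, "insemination", d("2020-04-01")),
        ("C", 1, "insemination", d("2020-05-01")),
        # cow D: early return (day 10) then a long gap, ends with calving
        ("D", 1, "insemination", d("2020-01-01")),
        ("D", 1, "insemination", d("2020-01-11")),
        ("D", 1, "calving", d("2020-10-20")),
    ]
    return pd.DataFrame(rows, columns=["cow", "parity", "event", "date"])
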