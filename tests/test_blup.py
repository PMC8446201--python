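"""BLUP solutions, reliabilities, deregression, Calo correlations."""

import numpy as np
import pandas as pd
import pytest

from gesskit.blup import (
    approx_genetic_correlation,
    deregress,
    reliability,
    solve_blup,
)
from gesskit.pedigree import Pedigree
from gesskit.reml import VarianceComponents

from ._oracles import gls_solutions, prediction_error_variance

THETA = np.array([3.0, 1.2, 3.5, 0.7, 0.9, 2.0, 25.0])
VC = VarianceComponents.from_theta(THETA)


class TestSolveBlup:
    def test_matches_dense_gls_oracle(self, tiny_herd, gl_spec):
        ped, records = tiny_herd
        blup = solve_blup(records, gl_spec, ped, VC)
        oracle = gls_solutions(blup.design, THETA)
        assert np.abs(blup.solutions - oracle).max() < 1e-6

    def test_zero_phenotypes_give_zero_ebvs(self, tiny_herd, gl_spec):
        ped, records = tiny_herd
        rec = records.copy()
        rec["phenotype"] = 0.0
        blup = solve_blup(rec, gl_spec, ped, VC)
        assert np.allclose(blup.effect("u_m"), 0.0)
        assert np.allclose(blup.effect("u_f"), 0.0)

    def test_progeny_without_records_gets_parent_average(
        self, tiny_herd, gl_spec
    ):
        ped, records = tiny_herd
        # append a brand-new offspring of two existing animals, no records
        new = Pedigree(
            ids=list(ped.ids) + ["orphan"],
            sire=np.append(ped.sire, ped.index_of(records["service_sire"].iloc[0])),
            dam=np.append(ped.dam, ped.index_of(records["cow"].iloc[0])),
            sex=np.append(ped.sex, "F"),
        )
        blup = solve_blup(records, gl_spec, new, VC)
        for eff in ("u_m", "u_f"):
            u = blup.effect(eff)
            i = new.index_of("orphan")
            pa = 0.5 * (u[new.sire[i]] + u[new.dam[i]])
            assert u[i] == pytest.approx(pa, abs=1e-8)

    def test_ebv_table_layout(self, tiny_herd, gl_spec):
        ped, records = tiny_herd
        blup = solve_blup(records, gl_spec, ped, VC)
        tab = blup.ebv_table("u_m")
        assert list(tab.columns) == ["animal", "effect", "ebv"]
        assert (tab["effect"] == "GESS").all()
        assert len(tab) == len(ped)


class TestReliability:
    def test_matches_dense_inverse_oracle(self, tiny_herd, gl_spec):
        ped, records = tiny_herd
        blup = solve_blup(records, gl_spec, ped, VC)
        Cinv = prediction_error_variance(blup.design, THETA)
        sl = blup.design.slices["u_m"]
        rel = reliability(blup, effect="u_m")
        for k, animal in enumerate(ped.ids):
            pev = Cinv[sl.start + k, sl.start + k]
            expected = 1.0 - pev / ((1.0 + ped.f[k]) * THETA[0])
            assert rel["reliability"].iloc[k] == pytest.approx(
                max(expected, 0.0), abs=1e-10
            )

    def test_bounded_in_unit_interval(self, tiny_herd, gl_spec):
        ped, records = tiny_herd
        blup = solve_blup(records, gl_spec, ped, VC)
        rel = reliability(blup, effect="u_f")["reliability"]
        assert ((rel >= 0) & (rel < 1)).all()

    def test_disconnected_animal_has_zero_reliability(self, tiny_herd, gl_spec):
        ped, records = tiny_herd
        new = Pedigree(
            ids=list(ped.ids) + ["loner"],
            sire=np.append(ped.sire, -1),
            dam=np.append(ped.dam, -1),
            sex=np.append(ped.sex, "M"),
        )
        blup = solve_blup(records, gl_spec, new, VC)
        rel = reliability(blup, effect="u_m", animals=["loner"])
        assert rel["reliability"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_more_records_never_reduce_reliability(self, tiny_herd, gl_spec):
        ped, records = tiny_herd
        sire = records["service_sire"].iloc[0]
        blup_all = solve_blup(records, gl_spec, ped, VC)
        fewer = records[records["service_sire"] != sire].iloc[:-20]
        blup_few = solve_blup(fewer, gl_spec, ped, VC)
        r_all = reliability(blup_all, "u_m", animals=[sire])["reliability"].iloc[0]
        r_few = reliability(blup_few, "u_m", animals=[sire])["reliability"].iloc[0]
        assert r_all >= r_few - 1e-10


class TestDeregression:
    @pytest.fixture
    def ebv_tab(self, trio_pedigree):
        return pd.DataFrame(
            {
                "animal": ["s", "d", "o"],
                "ebv": [2.0, 1.0, 2.4],
                "reliability": [0.81, 0.64, 0.49],
            }
        )

    def test_full_reliability_no_parents_recovers_ebv(self, trio_pedigree):
        tab = pd.DataFrame(
            {"animal": ["s"], "ebv": [3.0], "reliability": [1.0 - 1e-9]}
        )
        out = deregress(tab, trio_pedigree, h2=0.1)
        assert out["drp"].iloc[0] == pytest.approx(3.0, abs=1e-6)

    def test_reregression_round_trip(self, trio_pedigree, ebv_tab):
        out = deregress(ebv_tab, trio_pedigree, h2=0.1)
        o = out[out["animal"] == "o"].iloc[0]
        rel_pa = 0.25 * (0.81 + 0.64)
        r2_star = (0.49 - rel_pa) / (1.0 - rel_pa)
        rebuilt = o["parent_average"] + r2_star * (o["drp"] - o["parent_average"])
        assert rebuilt == pytest.approx(2.4, abs=1e-6)

    def test_weights_follow_reliability_formula(self, trio_pedigree, ebv_tab):
        c, h2 = 0.5, 0.1
        out = deregress(ebv_tab, trio_pedigree, h2=h2, c=c)
        for _, row in out.iterrows():
            r2 = row["reliability"]
            expected = (1 - h2) / ((c + (1 - r2) / r2) * h2)
            assert row["weight"] == pytest.approx(expected)

    def test_low_accuracy_animals_flagged_out(self, trio_pedigree):
        tab = pd.DataFrame(
            {
                "animal": ["s", "d"],
                "ebv": [1.0, 1.0],
                "reliability": [0.0081, 0.25],  # accuracies 0.09 and 0.5
            }
        )
        out = deregress(tab, trio_pedigree, h2=0.1, min_accuracy=0.10)
        assert not out[out["animal"] == "s"]["included"].iloc[0]
        assert out[out["animal"] == "d"]["included"].iloc[0]

    def test_simple_mode_divides_by_reliability(self, trio_pedigree, ebv_tab):
        out = deregress(ebv_tab, trio_pedigree, h2=0.1, simple=True)
        assert np.allclose(out["drp"], ebv_tab["ebv"] / ebv_tab["reliability"])

    def test_unit_reliability_rejected(self, trio_pedigree):
        tab = pd.DataFrame(
            {"animal": ["s"], "ebv": [1.0], "reliability": [1.0]}
        )
        with pytest.raises(ValueError):
            deregress(tab, trio_pedigree, h2=0.1)


class TestCaloCorrelation:
    def test_identical_fully_reliable_sets(self):
        e = np.array([1.0, 2.0, 3.0, 4.0])
        r, se = approx_genetic_correlation(e, np.ones(4), e, np.ones(4))
        assert r == 1.0

    def test_weighting_factor_at_least_raw_pearson(self):
        rng = np.random.default_rng(3)
        e1 = rng.standard_normal(50)
        e2 = 0.5 * e1 + rng.standard_normal(50)
        rel1 = rng.uniform(0.2, 0.9, 50)
        rel2 = rng.uniform(0.2, 0.9, 50)
        r, _ = approx_genetic_correlation(e1, rel1, e2, rel2)
        raw = np.corrcoef(e1, e2)[0, 1]
        assert abs(r) >= abs(raw) - 1e-12

    def test_matches_scalar_formula_oracle(self):
        e1 = np.array([0.5, -1.2, 0.3, 2.2, -0.7])
        e2 = np.array([0.1, -0.9, 0.6, 1.4, -1.0])
        r1 = np.array([0.9, 0.5, 0.7, 0.3, 0.6])
        r2 = np.array([0.8, 0.6, 0.4, 0.5, 0.9])
        r, _ = approx_genetic_correlation(e1, r1, e2, r2)
        # independent scalar evaluation
        raw = np.corrcoef(e1, e2)[0, 1]
        factor = np.sqrt(r1.sum() * r2.sum()) / np.sum(np.sqrt(r1 * r2))
        assert r == pytest.approx(min(1.0, raw * factor))

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(8)
        e1, e2 = rng.standard_normal((2, 30))
        r1, r2 = rng.uniform(0.3, 0.95, (2, 30))
        a, _ = approx_genetic_correlation(e1, r1, e2, r2)
        b, _ = approx_genetic_correlation(e2, r2, e1, r1)
        assert a == pytest.approx(b)

    def test_bootstrap_se_agrees_with_closed_form(self):
        rng = np.random.default_rng(5)
        n = 300
        g = rng.standard_normal(n)
        e1 = g + rng.standard_normal(n)
        e2 = g + rng.standard_normal(n)
        rel = np.full(n, 0.8)
        _, se_cf = approx_genetic_correlation(e1, rel, e2, rel)
        _, se_bs = approx_genetic_correlation(
            e1, rel, e2, rel, se_method="bootstrap", n_bootstrap=500, seed=2
        )
        assert se_bs == pytest.approx(se_cf, rel=0.5)

    def test_too_few_animals_rejected(self):
        with pytest.raises(ValueError):
            approx_genetic_correlation([1, 2], [0.5, 0.5], [1, 2], [0.5, 0.5])

    def test_bad_reliabilities_rejected(self):
        with pytest.raises(ValueError):
            approx_genetic_correlation(
                [1, 2, 3], [0.5, 0.0, 0.5], [1, 2, 3], [0.5, 0.5, 0.5]
            )
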