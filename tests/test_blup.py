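import numpy as np
import pandas as pd
import pytest

import milkflow_gs as m
from milkflow_gs.blup import MultiTraitBLUP


def single_trait_params(h2=0.4):
    return m.TraitParameters(trait_names=("y",), h2=[h2],
                             genetic_corr=np.eye(1), phenotypic_corr=np.eye(1))


def toy_problem(seed=0, n_founders=3, n_offspring=3):
    """Six-animal pedigree with records on the offspring."""
    rng = np.random.default_rng(seed)
    records = [(f"f{i}", "0", "0", "M" if i == 0 else "F", 0)
               for i in range(n_founders)]
    for k in range(n_offspring):
        records.append((f"o{k}", "f0", f"f{1 + k % (n_founders - 1)}", "F", 1))
    ped = m.Pedigree.from_records(records)
    phen = pd.DataFrame({
        "id": [f"o{k}" for k in range(n_offspring)],
        "cg": ["c1"] * n_offspring,
        "y": rng.normal(size=n_offspring),
    })
    return ped, phen


class TestSingleTraitOracle:
    def test_matches_dense_normal_equations(self):
        """MME solution equals an explicitly inverted dense system."""
        params = single_trait_params()
        ped, phen = toy_problem(1)
        res = m.fit_multitrait_blup(phen, ped, params)

        # oracle: dense MME assembled by hand
        n = len(ped)
        A = m.build_A(ped).values
        lam = params.sigma2_e[0] / params.sigma2_a[0]
        Z = np.zeros((3, n))
        for r, aid in enumerate(phen["id"]):
            Z[r, list(ped.ids).index(aid)] = 1.0
        X = np.ones((3, 1))
        top = np.hstack([X.T @ X, X.T @ Z])
        bot = np.hstack([Z.T @ X, Z.T @ Z + lam * np.linalg.inv(A)])
        C = np.vstack([top, bot]) / params.sigma2_e[0]
        rhs = np.concatenate([X.T @ phen["y"], Z.T @ phen["y"]])
        rhs = rhs / params.sigma2_e[0]
        sol = np.linalg.solve(C, rhs)
        np.testing.assert_allclose(res.ebv["y"].values, sol[1:], atol=1e-8)
        # SEP from the inverse coefficient matrix
        Cinv = np.linalg.inv(C)
        np.testing.assert_allclose(res.sep["y"].values ** 2,
                                   Cinv.diagonal()[1:], atol=1e-8)

    def test_record_equal_to_cg_mean_gives_zero_ebv(self):
        params = single_trait_params()
        ped, phen = toy_problem(2)
        phen = phen.iloc[:1].copy()
        res = m.fit_multitrait_blup(phen, ped, params)
        np.testing.assert_allclose(res.ebv["y"].values, 0.0, atol=1e-10)

    def test_unrelated_unrecorded_animal_zero(self):
        params = single_trait_params()
        ped, phen = toy_problem(3)
        res = m.fit_multitrait_blup(phen, ped, params)
        # founder f2 is dam of o1 only; check a fully unrelated founder
        ped2 = m.Pedigree.from_records(
            list(ped.to_frame().itertuples(index=False))
            + [("lone", "0", "0", "M", 0)])
        res2 = m.fit_multitrait_blup(phen, ped2, params)
        assert res2.ebv.loc["lone", "y"] == pytest.approx(0.0, abs=1e-10)
        assert res2.reliability.loc["lone", "y"] == pytest.approx(0.0, abs=1e-6)


class TestMultiTrait:
    def test_diagonal_covariances_equal_independent_fits(self):
        """With diagonal G0 and R0, the 3-trait fit equals three
        single-trait fits."""
        rng = np.random.default_rng(4)
        names = ("t1", "t2", "t3")
        params3 = m.TraitParameters(
            trait_names=names, h2=[0.2, 0.4, 0.6],
            genetic_corr=np.eye(3), phenotypic_corr=np.eye(3))
        ped, phen = toy_problem(5, n_founders=4, n_offspring=6)
        for t in names:
            phen[t] = rng.normal(size=len(phen))
        phen = phen.drop(columns="y")
        res3 = m.fit_multitrait_blup(phen, ped, params3)
        for j, t in enumerate(names):
            p1 = m.TraitParameters(trait_names=(t,), h2=[params3.h2[j]],
                                   genetic_corr=np.eye(1),
                                   phenotypic_corr=np.eye(1))
            r1 = m.fit_multitrait_blup(
                phen[["id", "cg", t]], ped, p1)
            np.testing.assert_allclose(res3.ebv[t].values, r1.ebv[t].values,
                                       atol=1e-8)
            np.testing.assert_allclose(res3.sep[t].values, r1.sep[t].values,
                                       atol=1e-8)

    def test_correlated_traits_borrow_information(self, params):
        """An unmeasured-trait-poor animal gains reliability from a
        correlated trait with records (multi-trait advantage)."""
        # use two traits with high genetic correlation from the defaults
        sub = m.TraitParameters(
            trait_names=("TMT", "AT"), h2=[0.42, 0.02],
            genetic_corr=np.array([[1.0, 0.82], [0.82, 1.0]]),
            phenotypic_corr=np.array([[1.0, 0.17], [0.17, 1.0]]))
        cfg = m.SimulationConfig(n_founder_sires=10, n_founder_dams=200,
                                 n_generations=2, n_sires_per_generation=10,
                                 n_snps=20, n_qtl=0)
        ped = m.simulate_pedigree(cfg, 6)
        gen = m.simulate_genotypes(ped, cfg, 6)
        tbv = m.simulate_true_breeding_values(ped, gen, sub, cfg, 6)
        phen = m.simulate_phenotypes(ped, tbv, sub, cfg, 6)
        res = m.fit_multitrait_blup(phen, ped, sub)
        single = m.TraitParameters(trait_names=("AT",), h2=[0.02],
                                   genetic_corr=np.eye(1),
                                   phenotypic_corr=np.eye(1))
        res1 = m.fit_multitrait_blup(phen[["id", "cg", "AT"]], ped, single)
        sires = m.sire_ids(ped)
        assert (res.reliability.loc[sires, "AT"].mean()
                > res1.reliability.loc[sires, "AT"].mean() + 0.05)

    def test_missing_pattern_equals_dropped_records(self):
        """NaN-ing one trait of some records equals removing those records
        for that trait in an uncorrelated two-trait model."""
        rng = np.random.default_rng(7)
        names = ("t1", "t2")
        p2 = m.TraitParameters(trait_names=names, h2=[0.3, 0.3],
                               genetic_corr=np.eye(2),
                               phenotypic_corr=np.eye(2))
        ped, phen = toy_problem(8, n_founders=4, n_offspring=8)
        phen = phen.drop(columns="y")
        for t in names:
            phen[t] = rng.normal(size=len(phen))
        phen.loc[phen.index[:3], "t2"] = np.nan
        res = m.fit_multitrait_blup(phen, ped, p2)
        p1 = m.TraitParameters(trait_names=("t2",), h2=[0.3],
                               genetic_corr=np.eye(1),
                               phenotypic_corr=np.eye(1))
        kept = phen.dropna(subset=["t2"])[["id", "cg", "t2"]]
        r1 = m.fit_multitrait_blup(kept, ped, p1)
        np.testing.assert_allclose(res.ebv["t2"].values, r1.ebv["t2"].values,
                                   atol=1e-8)

    def test_all_missing_trait_errors(self):
        p2 = m.TraitParameters(trait_names=("t1", "t2"), h2=[0.3, 0.3],
                               genetic_corr=np.eye(2),
                               phenotypic_corr=np.eye(2))
        ped, phen = toy_problem(9)
        phen = phen.rename(columns={"y": "t1"})
        phen["t2"] = np.nan
        with pytest.raises(ValueError, match="no records"):
            m.fit_multitrait_blup(phen, ped, p2)

    def test_reliability_in_unit_interval(self, small_blup):
        rel = small_blup.reliability.values
        assert np.nanmin(rel) >= 0 and np.nanmax(rel) <= 1


class TestAccuracyScaling:
    def test_more_daughters_higher_accuracy(self, params):
        """corr(EBV, TBV) across sires increases with daughter count."""
        accs = []
        for daughters in (5, 28, 100):
            cfg = m.SimulationConfig(
                n_founder_sires=40, n_founder_dams=40 * daughters,
                n_generations=1, n_sires_per_generation=2,
                daughters_per_sire_mean=daughters, daughters_per_sire_sd=1.0,
                n_snps=20, n_qtl=0)
            ped = m.simulate_pedigree(cfg, 10)
            gen = m.simulate_genotypes(ped, cfg, 10)
            tbv = m.simulate_true_breeding_values(ped, gen, params, cfg, 10)
            phen = m.simulate_phenotypes(ped, tbv, params, cfg, 10)
            res = m.fit_multitrait_blup(phen, ped, params,
                                        compute_reliability=False)
            sires = m.sire_ids(ped)
            idx = ped.index_of(sires)
            accs.append(np.corrcoef(res.ebv["TMT"].values[idx],
                                    tbv["TMT"].values[idx])[0, 1])
        assert accs[0] < accs[1] < accs[2]


class TestParentAverage:
    def test_unknown_parents_zero(self, small_blup):
        ped = small_blup.model.pedigree
        founders = ped.ids[ped.is_founder][:5]
        pa, r2 = small_blup.parent_average(founders)
        assert (pa.values == 0).all() and (r2.values == 0).all()

    def test_single_known_parent_formula(self):
        params = single_trait_params()
        ped, phen = toy_problem(11)
        res = m.fit_multitrait_blup(phen, ped, params)
        ped2 = m.Pedigree.from_records(
            list(ped.to_frame().itertuples(index=False))
            + [("half", "f0", "0", "F", 1)])
        res2 = m.fit_multitrait_blup(phen, ped2, params)
        pa, r2 = res2.parent_average(["half"])
        assert pa.loc["half", "y"] == pytest.approx(
            0.5 * res2.ebv.loc["f0", "y"])
        assert r2.loc["half", "y"] == pytest.approx(
            0.25 * res2.reliability.loc["f0", "y"])

    def test_linearity(self, small_blup):
        ped = small_blup.model.pedigree
        ids = [a for a in ped.ids[~ped.is_founder]][:10]
        pa, _ = small_blup.parent_average(ids)
        doubled = small_blup.ebv * 2.0
        import copy

        res2 = copy.copy(small_blup)
        res2.ebv = doubled
        pa2, _ = m.BLUPResults.parent_average(res2, ids)
        np.testing.assert_allclose(pa2.values, 2.0 * pa.values)


class TestSplit:
    def _results_with_reliability(self, rel_values):
        """Minimal results stub over real small_blup-like frames."""
        ids = np.array([f"s{i}" for i in range(len(rel_values))], dtype=object)
        traits = ["TP", "TMT"]
        rel = pd.DataFrame(
            {t: rel_values for t in traits}, index=ids)
        stub = m.BLUPResults.__new__(m.BLUPResults)
        stub.ebv = rel * 0.0
        stub.reliability = rel
        return stub, ids

    def test_threshold_boundaries_strict(self):
        stub, ids = self._results_with_reliability([0.55, 0.60, 0.65])
        split = stub.split_training_validation(ids)
        train_tp, valid_tp = split["TP"]
        # TP threshold 0.50: all three strictly above
        assert len(train_tp) == 3
        train_tmt, valid_tmt = split["TMT"]
        # TMT threshold 0.60: 0.60 exactly goes to validation
        assert list(train_tmt) == ["s2"]
        assert "s1" in list(valid_tmt)

    def test_empty_training_raises(self):
        stub, ids = self._results_with_reliability([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="empty training set"):
            stub.split_training_validation(ids)


def test_confounded_cg_raises():
    params = single_trait_params()
    ped, phen = toy_problem(12)
    phen.loc[phen.index[-1], "y"] = np.nan
    phen.loc[phen.index[-1], "cg"] = "lonely"
    with pytest.raises(ValueError, match="singular"):
        MultiTraitBLUP(phen, ped, params)
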