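"""Connectedness, factor tables, regression trees, CV and the linear screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hybridpeel as hp
from hybridpeel.factors import (
    build_individual_factors, build_variant_factors, connectedness,
    crossvalidate, fit_tree, linear_screen, predict_low_accuracy,
    relationship_matrix, sensitivity_specificity,
)

from oracles import tabular_relationship


class TestConnectedness:
    def test_unrelated_founder_pair(self):
        ped = hp.Pedigree(["A", "B"], np.array([-1, -1]), np.array([-1, -1]))
        np.testing.assert_allclose(connectedness(ped), [0.0, 0.0])

    def test_parent_offspring_duo(self):
        ped = hp.Pedigree(["P", "C"], np.array([-1, 0]), np.array([-1, -1]))
        np.testing.assert_allclose(connectedness(ped), [0.5, 0.5])

    def test_full_sib_family_by_hand(self):
        ped = hp.Pedigree(["S", "D", "c1", "c2"],
                          np.array([-1, -1, 0, 0]), np.array([-1, -1, 1, 1]))
        conn = connectedness(ped)
        np.testing.assert_allclose(conn[0], 1.0)  # sire: 0.5 + 0.5
        np.testing.assert_allclose(conn[2], 1.5)  # sib: 0.5 + 0.5 + 0.5

    def test_matches_tabular_oracle_on_random_pedigree(self):
        params = hp.SimParams(n_founders=8, n_generations=3, population_size=40)
        ped = hp.generate_pedigree(params, 17)
        A = relationship_matrix(ped)
        oracle = tabular_relationship(ped)
        np.testing.assert_allclose(A, oracle, atol=1e-6)
        np.testing.assert_allclose(connectedness(ped),
                                   oracle.sum(1) - np.diag(oracle), atol=1e-5)

    def test_single_id_lookup(self):
        ped = hp.Pedigree(["P", "C"], np.array([-1, 0]), np.array([-1, -1]))
        assert connectedness(ped, "P") == pytest.approx(0.5)
        with pytest.raises(KeyError):
            connectedness(ped, "missing")


class TestIndividualFactors:
    @pytest.fixture(scope="class")
    def family_table(self):
        # gp pair -> P; P x Q -> C with one sequenced progeny
        ped = hp.Pedigree(["g1", "g2", "Q", "P", "C", "K"],
                          np.array([-1, -1, -1, 0, 3, 4]),
                          np.array([-1, -1, -1, 1, 2, 2]))
        statuses = np.array(["HD", "HD", "none", "HD", "LD", "none"])
        plan = {"K": 2.0}
        return ped, build_individual_factors(ped, statuses, plan)

    def test_schema_has_23_factor_columns(self, family_table):
        _, tab = family_table
        assert len([c for c in tab.columns if c != "id"]) == 23

    def test_founder_has_no_genotyped_ancestors(self, family_table):
        _, tab = family_table
        row = tab.set_index("id").loc["g1"]
        assert row.n_par_HD == 0 and row.n_gpar_HD == 0

    def test_direct_counts(self, family_table):
        _, tab = family_table
        row = tab.set_index("id").loc["C"]
        assert row.n_par_HD == 1 and row.n_par_none == 1
        assert row.n_gpar_HD == 2
        assert row.n_prog_seq == 1 and row.cov_prog_seq == 2.0


class TestVariantFactors:
    def test_panel_distance_and_read_counts(self, small_dataset):
        ds = small_dataset
        freqs = ds.truth.allele_freqs()
        tab = build_variant_factors(ds.gmap, ds.panels, ds.reads, freqs)
        on_panel = ds.panels.hd_mask
        assert (tab.loc[on_panel, "panel_dist"] == 0).all()
        assert (tab.loc[~on_panel, "panel_dist"] > 0).all()
        j = int(np.flatnonzero(ds.reads.total.sum(0) > 0)[0])
        row = tab.iloc[j]
        assert row.n_ind_seq == (ds.reads.total[:, j] > 0).sum()
        assert row.cum_coverage == ds.reads.total[:, j].sum()

    def test_maf_is_folded(self, small_dataset):
        ds = small_dataset
        freqs = np.full(ds.gmap.n_variants, 0.9)
        tab = build_variant_factors(ds.gmap, ds.panels, ds.reads, freqs)
        np.testing.assert_allclose(tab["maf"], 0.1)


class TestFitTree:
    def test_single_split_on_binary_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 500)
        tab = pd.DataFrame({"x": x, "noise": rng.random(500)})
        tree = fit_tree(tab, x.astype(float), min_leaf=20)
        assert tree.first_split_variable == "x"
        assert tree.nodes["r2_gain"].max() == pytest.approx(1.0)
        assert tree.estimator.tree_.node_count == 3

    def test_pure_noise_gives_root_only(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame(rng.random((10000, 3)), columns=list("abc"))
        tree = fit_tree(tab, rng.random(10000))
        assert tree.first_split_variable is None

    def test_stronger_factor_splits_first(self):
        rng = np.random.default_rng(2)
        f1 = rng.integers(0, 2, 2000).astype(float)
        f2 = rng.integers(0, 2, 2000).astype(float)
        y = np.sqrt(0.5) * f1 + np.sqrt(0.1) * f2 + rng.normal(0, np.sqrt(0.4), 2000)
        tree = fit_tree(pd.DataFrame({"f1": f1, "f2": f2}), y)
        assert tree.first_split_variable == "f1"

    def test_constant_response_root_only(self):
        tab = pd.DataFrame({"x": np.arange(50, dtype=float)})
        tree = fit_tree(tab, np.ones(50))
        assert tree.first_split_variable is None

    def test_merged_multiway_partitions(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 3, 3000)
        y = np.floor(x)  # three-level step of one variable -> two splits merged
        tree = fit_tree(pd.DataFrame({"x": x}), y)
        for path in tree.merged_splits():
            assert path == ["x"] or path == []


class TestPrediction:
    def test_flags_partition_rows(self, small_run):
        ds, _, _, report = small_run
        tab = build_individual_factors(ds.pedigree, ds.genotypes.status, ds.plan)
        acc = report.individuals["corrected"].to_numpy()
        ok = ~np.isnan(acc)
        tree = fit_tree(tab[ok], acc[ok])
        flags = predict_low_accuracy(tree, tab[ok])
        assert flags.shape == (ok.sum(),)
        assert flags.dtype == bool

    def test_leaf_threshold_rule(self):
        tab = pd.DataFrame({"x": np.r_[np.zeros(50), np.ones(50)]})
        y = np.r_[np.full(50, 0.80), np.full(50, 0.99)]
        tree = fit_tree(tab, y)
        flags = predict_low_accuracy(tree, tab, threshold=0.95)
        assert flags[:50].all() and not flags[50:].any()


class TestCrossvalidate:
    def test_confusion_arithmetic_is_exact(self):
        assert sensitivity_specificity(33, 17, 190, 10) == (0.66, 0.95)

    def test_perfect_predictor(self):
        rng = np.random.default_rng(5)
        y = np.where(rng.random(400) < 0.3, 0.7, 0.99)
        tab = pd.DataFrame({"x": (y < 0.95).astype(float),
                            "noise": rng.random(400)})
        cv = crossvalidate(tab, y, seed=1)
        assert cv.sensitivity == pytest.approx(1.0)
        assert cv.specificity == pytest.approx(1.0)

    def test_constant_predictor_flags_nobody(self):
        rng = np.random.default_rng(6)
        y = np.where(rng.random(400) < 0.1, 0.9, 0.99)  # mean well above 0.95
        tab = pd.DataFrame({"x": np.ones(400)})
        cv = crossvalidate(tab, y, seed=1)
        assert cv.sensitivity == 0.0 and cv.specificity == 1.0

    def test_band_breakdown_schema(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(0.3, 1.0, 500)
        tab = pd.DataFrame({"x": y + rng.normal(0, 0.05, 500)})
        cv = crossvalidate(tab, y, seed=0)
        assert cv.by_band["band"].tolist() == ["0.0-0.5", "0.5-0.75", "0.75-0.85",
                                               "0.85-0.9", "0.9-0.95"]

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="k"):
            crossvalidate(pd.DataFrame({"x": np.arange(30.0)}), np.ones(30), k=1)


class TestLinearScreen:
    def test_planted_factor_detected(self):
        rng = np.random.default_rng(8)
        x = rng.random(500)
        z = rng.random(500)
        y = 0.5 * x + rng.normal(0, 0.01, 500)
        out = linear_screen(pd.DataFrame({"x": x, "z": z}), y)
        assert out.set_index("factor").loc["x", "p_value"] < 1e-6

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(200):
            x = rng.random(1000)
            y = rng.random(1000)
            out = linear_screen(pd.DataFrame({"x": x}), y)
            pvals.append(out["p_value"].iloc[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_factor_table_rejected(self):
        with pytest.raises(ValueError, match="factor"):
            linear_screen(pd.DataFrame({"id": ["a", "b", "c"]}), np.ones(3))

    def test_aliased_column_dropped_with_warning(self):
        rng = np.random.default_rng(10)
        x = rng.random(200)
        tab = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.warns(UserWarning, match="aliased"):
            out = linear_screen(tab, x + rng.normal(0, 0.1, 200))
        assert out["factor"].tolist() == ["x"]
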