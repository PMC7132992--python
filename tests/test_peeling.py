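"""Peeling engine: penetrance, oracle equivalence, segregation, hybrid runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hybridpeel as hp
from hybridpeel.core import GenotypeMatrix, ReadCounts
from hybridpeel.peeling import (
    PeelSettings, dosages_from_probabilities, estimate_alt_freqs, hw_prior,
    interpolate_segregation, multi_locus_peel, peel_genotypes, penetrance,
    single_locus_peel,
)
from hybridpeel.synthetic_data import (
    SimParams, drop_genotypes, observe_arrays, uniform_map,
)

from oracles import enumerate_posteriors

TIGHT = PeelSettings(max_iter=100, tol=1e-12)
UNIFORM_SEG = lambda n: np.full((n, 4), 0.25)


def _pedigree(sire, dam):
    n = len(sire)
    return hp.Pedigree([f"i{k}" for k in range(n)], np.array(sire), np.array(dam))


class TestPenetrance:
    def test_two_ref_reads(self):
        rc = ReadCounts(np.array([[2]]), np.array([[0]]), np.ones(1))
        pen = penetrance(None, rc, PeelSettings(seq_error=0.01))[0, 0]
        np.testing.assert_allclose(pen, [0.9801, 0.25, 0.25, 0.0001])

    def test_no_data_all_ones(self):
        gm = GenotypeMatrix(np.array([[-1]], dtype=np.int8), np.array(["none"]))
        rc = ReadCounts(np.zeros((1, 1), int), np.zeros((1, 1), int), np.zeros(1))
        np.testing.assert_array_equal(penetrance(gm, rc, PeelSettings())[0, 0],
                                      np.ones(4))

    def test_balanced_reads_favor_heterozygotes(self):
        rc = ReadCounts(np.array([[5]]), np.array([[5]]), np.ones(1))
        pen = penetrance(None, rc, PeelSettings(seq_error=0.01))[0, 0]
        pen = pen / pen.sum()
        assert pen[1] + pen[2] > 0.99

    def test_array_genotype_weights(self):
        gm = GenotypeMatrix(np.array([[1]], dtype=np.int8), np.array(["HD"]))
        pen = penetrance(gm, None, PeelSettings(geno_error=1e-4))[0, 0]
        np.testing.assert_allclose(pen, [5e-5, 0.9999, 0.9999, 5e-5])


class TestSingleLocusOracle:
    """Posteriors must match exhaustive enumeration on loop-free pedigrees."""

    LOOP_FREE = [
        # trio
        ([-1, -1, 0], [-1, -1, 1]),
        # two full sibs and a half sib through a second (founder) dam
        ([-1, -1, -1, 0, 0, 0], [-1, -1, -1, 1, 1, 2]),
        # three generations, 6 members
        ([-1, -1, 0, -1, 2, 2], [-1, -1, 1, -1, 3, 3]),
        # 8 members: two founder couples, their children mated, grandchild
        ([-1, -1, -1, -1, 0, 2, 4, 4], [-1, -1, -1, -1, 1, 3, 5, 5]),
    ]

    @pytest.mark.parametrize("sire,dam", LOOP_FREE)
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_enumeration(self, sire, dam, seed):
        rng = np.random.default_rng(seed)
        ped = _pedigree(sire, dam)
        pen = rng.random((ped.n, 4)) + 0.02
        seg = rng.dirichlet(np.ones(4), size=ped.n)
        p = rng.uniform(0.1, 0.9)
        exact = enumerate_posteriors(ped, pen, seg, p)
        mine = single_locus_peel(ped, pen, seg, p, TIGHT)
        np.testing.assert_allclose(mine, exact, atol=1e-6)

    def test_looped_pedigree_with_partial_data(self):
        # full-sib mating (inbreeding loop): founders genotyped, sibs with
        # low-coverage reads, the inbred child unobserved
        ped = _pedigree([-1, -1, 0, 0, 2, -1], [-1, -1, 1, 1, 3, -1])
        gvals = np.array([[1], [0], [-1], [-1], [-1], [1]], dtype=np.int8)
        gm = GenotypeMatrix(gvals, np.array(["HD", "HD", "none", "none", "none", "HD"]))
        rc = ReadCounts(np.array([[0], [0], [1], [2], [0], [0]]),
                        np.array([[0], [0], [1], [0], [0], [0]]),
                        np.array([0, 0, 1.0, 1.0, 0, 0]))
        pen = penetrance(gm, rc, TIGHT)[:, 0, :]
        seg = UNIFORM_SEG(6)
        exact = enumerate_posteriors(ped, pen, seg, 0.4)
        mine = single_locus_peel(ped, pen, seg, 0.4, TIGHT)
        np.testing.assert_allclose(mine, exact, atol=1e-3)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.02, 1.0), min_size=24, max_size=24))
    def test_property_normalized_and_exact_on_tree(self, flat):
        ped = _pedigree([-1, -1, 0, -1, 2, 2], [-1, -1, 1, -1, 3, 3])
        pen = np.array(flat).reshape(6, 4)
        seg = UNIFORM_SEG(6)
        post = single_locus_peel(ped, pen, seg, 0.3, TIGHT)
        assert np.all(post >= 0)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-8)
        exact = enumerate_posteriors(ped, pen, seg, 0.3)
        np.testing.assert_allclose(post, exact, atol=1e-6)


class TestTransmission:
    def test_obligate_heterozygote(self, trio_pedigree):
        pen = np.ones((3, 4))
        pen[0] = [1, 1e-12, 1e-12, 1e-12]  # sire aa
        pen[1] = [1e-12, 1e-12, 1e-12, 1]  # dam AA
        post = single_locus_peel(trio_pedigree, pen, UNIFORM_SEG(3), 0.5, TIGHT)
        # paternal a, maternal A: ordered state aA with probability 1
        np.testing.assert_allclose(post[2], [0, 1, 0, 0], atol=1e-6)

    def test_seg_pp_copies_sires_paternal_allele(self, trio_pedigree):
        pen = np.ones((3, 4))
        pen[0] = [1e-12, 1e-12, 1, 1e-12]  # sire phased Aa (paternal A)
        seg = UNIFORM_SEG(3)
        seg[2] = [1, 0, 0, 0]  # pp fixed
        post = single_locus_peel(trio_pedigree, pen, seg, 0.5, TIGHT)
        p_paternal_A = post[2, 2] + post[2, 3]
        assert p_paternal_A >= 1 - 1e-6

    def test_monotone_in_consistent_reads(self, trio_pedigree):
        # child truly heterozygous; balanced reads must not lower P(het)
        gm = GenotypeMatrix(np.array([[1], [1], [-1]], dtype=np.int8),
                            np.array(["HD", "HD", "none"]))
        prev = 0.0
        for k in (0, 1, 2, 4, 8):
            rc = ReadCounts(np.array([[0], [0], [k]]), np.array([[0], [0], [k]]),
                            np.array([0, 0, 1.0]))
            pen = penetrance(gm, rc, TIGHT)[:, 0, :]
            post = single_locus_peel(trio_pedigree, pen, UNIFORM_SEG(3), 0.5, TIGHT)
            p_het = post[2, 1] + post[2, 2]
            assert p_het >= prev - 1e-12
            prev = p_het


class TestMultiLocus:
    @pytest.fixture(scope="class")
    def family(self):
        rng = np.random.default_rng(7)
        ids = ["gs1", "gd1", "gs2", "gd2", "sire", "dam"] + [f"c{i}" for i in range(8)]
        sire = np.array([-1, -1, -1, -1, 0, 2] + [4] * 8)
        dam = np.array([-1, -1, -1, -1, 1, 3] + [5] * 8)
        ped = hp.Pedigree(ids, sire, dam)
        gmap = uniform_map(1, 100.0, 200)
        params = SimParams(n_founders=4, founder_beta=(2, 2))
        truth = drop_genotypes(ped, gmap, params, rng)
        panels = hp.PanelSet(np.ones(200, bool), np.zeros(200, bool))
        gm = observe_arrays(truth, panels, np.array(["HD"] * ped.n))
        pen = penetrance(gm, None, PeelSettings())
        seg = multi_locus_peel(ped, pen, gmap, np.arange(200), PeelSettings())
        return ped, gmap, truth, seg

    def test_founders_stay_uniform(self, family):
        ped, _, _, seg = family
        np.testing.assert_array_equal(seg[ped.founders], 0.25)

    def test_recovery_of_true_states_third_generation(self, family):
        ped, _, truth, seg = family
        kids = np.arange(6, ped.n)  # parents are both non-founders
        post = np.take_along_axis(seg[kids], truth.seg[kids][..., None], 2)[..., 0]
        assert (post >= 0.95).mean() >= 0.95

    def test_zero_distance_limit_constant_segregation(self):
        rng = np.random.default_rng(3)
        ids = ["gs", "gd", "s", "d0", "c"]
        ped = hp.Pedigree(ids, np.array([-1, -1, 0, -1, 2]),
                          np.array([-1, -1, 1, -1, 3]))
        pos = np.cumsum(np.full(20, 1e-9))
        gmap = hp.GeneticMap(np.array(["1"] * 20), pos, [f"v{k}" for k in range(20)])
        pen = rng.random((5, 20, 4)) + 0.05
        seg = multi_locus_peel(ped, pen, gmap, np.arange(20), PeelSettings())
        assert np.abs(np.diff(seg[4], axis=0)).max() < 1e-3

    def test_unordered_loci_rejected(self):
        ped = _pedigree([-1, -1, 0], [-1, -1, 1])
        gmap = uniform_map(1, 10.0, 10)
        pen = np.ones((3, 3, 4))
        with pytest.raises(ValueError, match="ordered"):
            multi_locus_peel(ped, pen, gmap, np.array([5, 2, 8]), PeelSettings())


class TestInterpolation:
    def test_identity_at_panel_locus(self):
        gmap = uniform_map(1, 50.0, 100)
        rng = np.random.default_rng(0)
        seg_panel = rng.dirichlet(np.ones(4), size=(3, 2))
        panel_idx = np.array([10, 80])
        out = interpolate_segregation(seg_panel, gmap, panel_idx, np.array([10, 80]))
        np.testing.assert_allclose(out, seg_panel)

    def test_agreeing_certain_flanks_at_tiny_distance(self):
        pos = np.array([0.0, 1e-6, 2e-6])
        gmap = hp.GeneticMap(np.array(["1"] * 3), pos, ["a", "b", "c"])
        seg_panel = np.zeros((1, 2, 4))
        seg_panel[:, :, 0] = 1.0  # both flanks certain pp
        out = interpolate_segregation(seg_panel, gmap, np.array([0, 2]), np.array([1]))
        assert out[0, 0, 0] > 1 - 1e-5

    def test_disagreeing_flanks_bridge_monotonically(self):
        gmap = uniform_map(1, 100.0, 101)
        seg_panel = np.zeros((1, 2, 4))
        seg_panel[0, 0] = [1, 0, 0, 0]  # pp at left flank
        seg_panel[0, 1] = [0, 0, 1, 0]  # mp at right flank
        targets = np.arange(1, 100)
        out = interpolate_segregation(seg_panel, gmap, np.array([0, 100]), targets)
        sig_p = out[0, :, 0] + out[0, :, 1]  # P(paternal gamete = p)
        assert np.all(np.diff(sig_p) < 0)
        assert sig_p[0] > 0.9 and sig_p[-1] < 0.1

    def test_empty_panel_on_chromosome_rejected(self):
        gmap = uniform_map(2, 10.0, 10)
        seg_panel = np.full((1, 1, 4), 0.25)
        with pytest.raises(ValueError, match="no panel"):
            interpolate_segregation(seg_panel, gmap, np.array([2]), np.array([15]))


class TestHybridPeel:
    def test_fully_observed_hd_matches_truth_at_panel(self):
        params = SimParams(n_founders=20, n_generations=2, population_size=60)
        ped = hp.generate_pedigree(params, 5)
        gmap = uniform_map(1, 50.0, 100)
        truth = drop_genotypes(ped, gmap, params, 5)
        panels = hp.make_panels(gmap, 25, 5, maf=truth.allele_freqs())
        gm = observe_arrays(truth, panels, np.array(["HD"] * ped.n))
        panel_idx = np.flatnonzero(panels.hd_mask)
        # arrays are simulated noise-free, so score them with a matching
        # (tiny) observation error; otherwise rare-genotype founders get
        # pulled toward the Hardy-Weinberg prior by ~2e-3
        st = PeelSettings(max_iter=50, tol=1e-8, geno_error=1e-6)
        dos, _ = hp.hybrid_peel(ped, gm, None, gmap, panels, variants=panel_idx,
                                settings=st)
        np.testing.assert_allclose(dos.values, truth.genotypes()[:, panel_idx],
                                   atol=1e-3)

    def test_unobserved_child_gets_midparent_dosage(self):
        ped = _pedigree([-1, -1, 0], [-1, -1, 1])
        gmap = uniform_map(1, 10.0, 20)
        panels = hp.PanelSet(np.ones(20, bool), np.zeros(20, bool))
        rng = np.random.default_rng(8)
        gvals = np.vstack([rng.integers(0, 3, 20), rng.integers(0, 3, 20),
                           np.full(20, -1)]).astype(np.int8)
        gm = GenotypeMatrix(gvals, np.array(["HD", "HD", "none"]))
        dos, _ = hp.hybrid_peel(ped, gm, None, gmap, panels)
        mid = (gvals[0] + gvals[1]) / 2.0
        np.testing.assert_allclose(dos.values[2], mid, atol=1e-3)

    def test_allele_relabel_symmetry(self, small_dataset):
        ds = small_dataset
        sub = np.arange(0, ds.gmap.n_variants, 10)
        dos, _ = hp.hybrid_peel(ds.pedigree, ds.genotypes, ds.reads, ds.gmap,
                                ds.panels, variants=sub)
        flipped_g = ds.genotypes.values.copy()
        obs = flipped_g >= 0
        flipped_g[obs] = 2 - flipped_g[obs]
        gm2 = GenotypeMatrix(flipped_g, ds.genotypes.status.copy())
        rc2 = ReadCounts(ds.reads.alt.copy(), ds.reads.ref.copy(),
                         ds.reads.coverage.copy())
        dos2, _ = hp.hybrid_peel(ds.pedigree, gm2, rc2, ds.gmap, ds.panels,
                                 variants=sub)
        # symmetry holds to the engine's convergence tolerance
        np.testing.assert_allclose(dos2.values, 2.0 - dos.values, atol=1e-4)
        truth = ds.truth.genotypes()[:, sub].astype(float)
        freqs = dos.values.mean(axis=0) / 2.0
        for i in (0, ds.pedigree.n - 1):
            c1 = hp.maf_corrected_correlation(truth[i], dos.values[i], freqs)
            c2 = hp.maf_corrected_correlation(2 - truth[i], dos2.values[i], 1 - freqs)
            assert abs(c1 - c2) < 1e-6

    def test_probabilities_normalized(self, small_dataset):
        ds = small_dataset
        sub = np.arange(0, 40)
        _, probs = hp.hybrid_peel(ds.pedigree, ds.genotypes, ds.reads, ds.gmap,
                                  ds.panels, variants=sub,
                                  return_probabilities=True)
        np.testing.assert_allclose(probs.sum(axis=2), 1.0, atol=1e-5)
        assert np.all(probs >= 0)


class TestPriors:
    def test_hw_prior_shape(self):
        prior = hw_prior(np.array([0.2]))
        np.testing.assert_allclose(prior[0], [0.64, 0.16, 0.16, 0.04])

    def test_estimated_freqs_blend_arrays_and_reads(self):
        gm = GenotypeMatrix(np.array([[2], [-1]], dtype=np.int8),
                            np.array(["HD", "none"]))
        rc = ReadCounts(np.array([[0], [1]]), np.array([[0], [1]]),
                        np.array([0, 1.0]))
        p = estimate_alt_freqs(gm, rc, 2)
        np.testing.assert_allclose(p, [(1.0 + 0.5) / 2])

    def test_no_evidence_falls_back_to_half(self):
        gm = GenotypeMatrix(np.array([[-1]], dtype=np.int8), np.array(["none"]))
        assert estimate_alt_freqs(gm, None, 1)[0] == 0.5

    def test_dosage_from_probabilities(self):
        probs = np.array([[0.1, 0.2, 0.3, 0.4]])
        np.testing.assert_allclose(dosages_from_probabilities(probs), [1.3])
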