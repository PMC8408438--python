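"""Somatotopy statistics: Dice/MDR, suppression index, coverage, bootstrap."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import somatoprf as sp
from somatoprf.prf_model import DOG
from somatoprf.stats import DiceMatrix


def make_fit(voxel_id=0, free_energy=0.0, participant=None, roi=None, **params):
    return sp.VoxelFitResult(voxel_id, sp.PRFParameters(**params), free_energy,
                             1.0, 1.0, True, roi=roi, participant=participant)


class TestDice:
    def test_matches_exhaustive_set_oracle(self):
        """Dice equals 2|AnB|/(|A|+|B|) for every subset pair of a 6-voxel universe."""
        universe = range(6)
        subsets = list(itertools.chain.from_iterable(
            itertools.combinations(universe, k) for k in range(7)))
        for a in subsets:
            for b in subsets:
                sa, sb = set(a), set(b)
                if not sa and not sb:
                    continue
                oracle = 2 * len(sa & sb) / (len(sa) + len(sb))
                mask_a = np.isin(np.arange(6), list(sa))
                mask_b = np.isin(np.arange(6), list(sb))
                assert sp.dice(mask_a, mask_b) == pytest.approx(oracle)

    def test_reference_values(self):
        assert sp.dice({1, 2, 3}, {2, 3, 4}) == pytest.approx(2 / 3)
        assert sp.dice({1, 2}, {1, 2}) == 1.0
        assert sp.dice({1}, {2}) == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            sp.dice(np.zeros(4, dtype=bool), np.zeros(4, dtype=bool))


class TestDiceMatrix:
    def test_nine_by_six_shape_and_symmetry(self):
        maps = sp.simulate_participant_ensemble(9, 2.0, seed=0)
        dm = sp.build_dice_matrix(maps)
        assert dm.matrix.shape == (54, 54)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 1.0)
        assert dm.matrix.min() >= 0 and dm.matrix.max() <= 1

    def test_identical_maps_give_all_ones(self):
        m = np.array([True, True, False])
        maps = {(p, d): m for p in range(2) for d in ("D1", "D2")}
        dm = sp.build_dice_matrix(maps)
        assert np.allclose(dm.matrix, 1.0)

    def test_jitter_zero_is_block_diagonal(self):
        maps = sp.simulate_participant_ensemble(4, 0.0, seed=1)
        dm = sp.build_dice_matrix(maps)
        for a in range(6):
            assert np.allclose(dm.block(a, a), 1.0)
            for b in range(6):
                if a != b:
                    assert np.allclose(dm.block(a, b), 0.0)

    def test_empty_map_rejected_with_location(self):
        maps = {(0, "D1"): np.array([True]), (0, "D2"): np.array([False]),
                (1, "D1"): np.array([True]), (1, "D2"): np.array([True])}
        with pytest.raises(ValueError, match="D2"):
            sp.build_dice_matrix(maps)


def block_matrix(intra, inter, n_digits=3, n_participants=4):
    P, D = n_participants, n_digits
    m = np.full((D * P, D * P), inter)
    for a in range(D):
        m[a * P:(a + 1) * P, a * P:(a + 1) * P] = intra
    np.fill_diagonal(m, 1.0)
    labels = [(p, f"D{a + 1}") for a in range(D) for p in range(P)]
    return DiceMatrix(m, labels, P, D)


class TestMDR:
    def test_block_matrix_value(self):
        assert sp.mdr(block_matrix(0.8, 0.2)) == pytest.approx(4.0)

    def test_constant_matrix_is_one(self):
        assert sp.mdr(block_matrix(0.5, 0.5)) == pytest.approx(1.0)

    def test_disjoint_interdigit_gives_infinity(self):
        assert np.isinf(sp.mdr(block_matrix(0.8, 0.0)))

    def test_invariant_to_participant_relabeling(self):
        maps = sp.simulate_participant_ensemble(5, 2.0, seed=3)
        dm = sp.build_dice_matrix(maps)
        relabeled = {(4 - p, d): m for (p, d), m in maps.items()}
        dm2 = sp.build_dice_matrix(relabeled)
        assert sp.mdr(dm) == pytest.approx(sp.mdr(dm2))

    def test_invariant_to_consistent_digit_relabeling(self):
        maps = sp.simulate_participant_ensemble(5, 2.0, seed=3)
        order = ["Palm", "D3", "D1", "D5", "D2", "D4"]
        relabeled = {(p, f"L{order.index(d)}"): m for (p, d), m in maps.items()}
        dm = sp.build_dice_matrix(maps)
        dm2 = sp.build_dice_matrix(relabeled)
        assert sp.mdr(dm) == pytest.approx(sp.mdr(dm2))


class TestMDRPermutation:
    def test_structured_ensemble_minimal_p(self):
        maps = sp.simulate_participant_ensemble(6, 0.0, seed=2)
        dm = sp.build_dice_matrix(maps)
        res = sp.mdr_permutation_test(dm, n_permutations=999, seed=5)
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_moderate_jitter_significant(self):
        maps = sp.simulate_participant_ensemble(9, 2.0, seed=4)
        dm = sp.build_dice_matrix(maps)
        res = sp.mdr_permutation_test(dm, n_permutations=5000, seed=6)
        assert res.mdr > 1.0
        assert res.p_value < 0.05

    def test_same_seed_same_p(self):
        maps = sp.simulate_participant_ensemble(5, 2.0, seed=7)
        dm = sp.build_dice_matrix(maps)
        a = sp.mdr_permutation_test(dm, n_permutations=500, seed=8)
        b = sp.mdr_permutation_test(dm, n_permutations=500, seed=8)
        assert a.p_value == b.p_value
        assert np.array_equal(a.permuted_mdrs, b.permuted_mdrs)

    def test_too_few_permutations_rejected(self):
        dm = block_matrix(0.8, 0.2)
        with pytest.raises(ValueError):
            sp.mdr_permutation_test(dm, n_permutations=50)


class TestSuppressionIndex:
    def test_reference_values(self):
        assert sp.suppression_index(sp.PRFParameters(
            model=DOG, sigma_x=2, sigma_y=2, sigma_d=1, beta_e=1, beta_i=0)) == 0.0
        assert sp.suppression_index(sp.PRFParameters(
            model=DOG, sigma_x=2, sigma_y=3, sigma_d=0, beta_e=1, beta_i=1)) == 1.0
        assert sp.suppression_index(sp.PRFParameters(
            model=DOG, sigma_x=1, sigma_y=1, sigma_d=1, beta_e=1, beta_i=0.25)
            ) == pytest.approx(1.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_to_common_amplitude_rescaling(self, scale):
        p1 = sp.PRFParameters(model=DOG, sigma_x=2, sigma_y=3, sigma_d=1.5,
                              beta_e=1.0, beta_i=0.4)
        p2 = sp.PRFParameters(model=DOG, sigma_x=2, sigma_y=3, sigma_d=1.5,
                              beta_e=scale, beta_i=0.4 * scale)
        assert sp.suppression_index(p1) == pytest.approx(sp.suppression_index(p2))

    def test_gaussian_model_rejected(self):
        with pytest.raises(ValueError):
            sp.suppression_index(sp.PRFParameters(beta_e=1.0))

    def test_zero_excitation_rejected(self):
        with pytest.raises(ValueError):
            sp.suppression_index(sp.PRFParameters(model=DOG, beta_e=0.0))


class TestRelativeVolume:
    def test_counts_to_fractions(self):
        labels = ["D1"] * 10 + ["D2"] * 10 + ["D3"] * 10 + ["D4"] * 10 \
            + ["D5"] * 5 + ["Palm"] * 5
        rv = sp.relative_volume(labels)
        assert rv == {"D1": 0.2, "D2": 0.2, "D3": 0.2, "D4": 0.2,
                      "D5": 0.1, "Palm": 0.1}
        assert sum(rv.values()) == pytest.approx(1.0)

    def test_single_digit(self):
        rv = sp.relative_volume(["D1", "D1"])
        assert rv["D1"] == 1.0 and sum(rv.values()) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sp.relative_volume([])


class TestPeakDistances:
    def test_collinear_peaks(self):
        fits, anat, labels = [], [], []
        for i, lab in enumerate(sp.DIGIT_LABELS):
            fits.append(make_fit(voxel_id=i, free_energy=10.0))
            anat.append([2.0 * i, 0.0, 0.0])
            labels.append(lab)
        d = sp.peak_distances(fits, anat, labels)
        assert d == pytest.approx({"D2": 0.2, "D3": 0.4, "D4": 0.6,
                                   "D5": 0.8, "Palm": 1.0})

    def test_peak_is_argmax_free_energy(self):
        fits = [make_fit(0, free_energy=1.0), make_fit(1, free_energy=9.0),
                make_fit(2, free_energy=5.0), make_fit(3, free_energy=2.0)]
        anat = [[0, 0, 0], [1, 0, 0], [5, 0, 0], [9, 0, 0]]
        labels = ["D1", "D1", "D2", "D2"]
        d = sp.peak_distances(fits, anat, labels, label_order=("D1", "D2"))
        # D1 peak at x=1 (F=9), D2 peak at x=5 (F=5); normalization to 1
        assert d["D2"] == 1.0

    def test_missing_digit_rejected(self):
        fits = [make_fit(0)]
        with pytest.raises(ValueError, match="D2"):
            sp.peak_distances(fits, [[0, 0, 0]], ["D1"], label_order=("D1", "D2"))

    def test_monotone_along_synthetic_strip(self, noiseless_dataset):
        ds = noiseless_dataset
        fits = [make_fit(t.voxel_id, free_energy=-float(i % 3))
                for i, t in enumerate(ds.truth)]
        anat = [t.anat_xyz for t in ds.truth]
        labels = [ds.space.segment_of(t.true_params.x0) for t in ds.truth]
        d = sp.peak_distances(fits, anat, labels)
        vals = [d[lab] for lab in ("D2", "D3", "D4", "D5", "Palm")]
        assert np.all(np.diff(vals) > 0)


class TestCoverageMap:
    def test_single_voxel_peaks_at_center(self, space):
        f = make_fit(x0=4.0, y0=-4.0, sigma_x=2.0, sigma_y=2.0)
        cm = sp.coverage_map([f], space)
        assert cm.grid.max() == pytest.approx(1.0)
        iy, ix = np.unravel_index(np.argmax(cm.grid), cm.grid.shape)
        assert space.xs[ix] == pytest.approx(4.0, abs=space.xs[1] - space.xs[0])
        assert space.ys[iy] == pytest.approx(-4.0, abs=space.xs[1] - space.xs[0])

    def test_duplicate_voxels_do_not_change_map(self, space):
        f = make_fit(x0=0.0, y0=0.0, sigma_x=3.0, sigma_y=3.0)
        one = sp.coverage_map([f], space)
        two = sp.coverage_map([f, f], space)
        assert np.allclose(one.grid, two.grid)

    def test_bounds_and_roi_filter(self, space):
        fits = [make_fit(i, roi="BA3b", x0=float(x), sigma_x=1.5, sigma_y=2.0)
                for i, x in enumerate((-10, -6, -2))]
        fits += [make_fit(9, roi="BA2", x0=8.0, sigma_x=6.0, sigma_y=8.0)]
        cm = sp.coverage_map(fits, space, roi="BA3b")
        assert cm.n_voxels == 3
        assert cm.grid.min() >= 0.0 and cm.grid.max() == pytest.approx(1.0)

    def test_wider_prfs_cover_more_space(self, space):
        """An ROI drawn with wide pRFs has a larger high-coverage area than a
        narrow-pRF ROI (the BA2-vs-BA3b contrast the coverage map shows)."""
        narrow = [make_fit(i, x0=float(x), sigma_x=1.0, sigma_y=1.5)
                  for i, x in enumerate((-8, 0, 8))]
        wide = [make_fit(i, x0=float(x), sigma_x=5.0, sigma_y=7.0)
                for i, x in enumerate((-8, 0, 8))]
        area_narrow = (sp.coverage_map(narrow, space).grid > 0.5).sum()
        area_wide = (sp.coverage_map(wide, space).grid > 0.5).sum()
        assert area_wide > area_narrow

    def test_empty_roi_rejected(self, space):
        with pytest.raises(ValueError):
            sp.coverage_map([make_fit(roi="BA1")], space, roi="BA2")


class TestWidthVolumeCorrelation:
    def test_perfect_anticorrelation(self):
        w = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = sp.width_volume_correlation(w, -w, n_boot=200, seed=0)
        assert res["r"] == pytest.approx(-1.0)

    def test_constructed_negative_relation_significant(self):
        # widths inversely proportional to volume, n = 9 participants x 6 digits
        rng = np.random.default_rng(1)
        vol = np.tile(np.array([0.25, 0.22, 0.2, 0.18, 0.1, 0.05]), 9)
        w = 1.0 / vol + rng.normal(0, 1.0, vol.size)
        res = sp.width_volume_correlation(w, vol, n_boot=2000, seed=2)
        assert res["r"] < 0
        assert res["p"] < 0.05
        assert res["ci_high"] < 0

    def test_same_seed_same_ci(self):
        w = [1.0, 3.0, 2.0, 5.0, 4.0]
        v = [0.2, 0.1, 0.3, 0.15, 0.25]
        a = sp.width_volume_correlation(w, v, n_boot=500, seed=3)
        b = sp.width_volume_correlation(w, v, n_boot=500, seed=3)
        assert a == b

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sp.width_volume_correlation([1, 1, 1], [0.1, 0.2, 0.3], n_boot=10)


class TestPairedBootstrap:
    def test_no_effect_gives_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert sp.paired_bootstrap_test(a, a, n_boot=100, seed=0)["p"] == 1.0

    def test_large_effect_tiny_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, 9)
        b = a + 5.0 + rng.normal(0, 0.1, 9)
        res = sp.paired_bootstrap_test(a, b, n_boot=5000, seed=2)
        assert res["p"] <= 0.001

    def test_identical_nonzero_differences_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            sp.paired_bootstrap_test(a + 2.0, a, n_boot=100)

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 9), rng.normal(0, 1, 9)
        r1 = sp.paired_bootstrap_test(a, b, n_boot=500, seed=4)
        r2 = sp.paired_bootstrap_test(a, b, n_boot=500, seed=4)
        assert r1 == r2
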