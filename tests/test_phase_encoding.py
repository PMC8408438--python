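"""Phase-encoding analysis: references, winner-take-all lags, combination."""

import numpy as np
import pytest

import somatoprf as sp
from somatoprf.phase_encoding import _circular_mean_lag


class TestLaggedReferences:
    def test_between_digit_gives_24_references(self, between_fwd):
        refs = sp.build_lagged_references(between_fwd)
        assert refs.shape == (24, 192)

    def test_within_digit_gives_12_references(self, within_fwd):
        refs = sp.build_lagged_references(within_fwd)
        assert refs.shape == (12, 96)

    def test_references_are_circular_shifts(self, between_fwd):
        refs = sp.build_lagged_references(between_fwd)
        cycle = refs[:, :24]
        for k in range(24):
            assert np.allclose(cycle[k], np.roll(cycle[0], k))
        # shifting by a whole cycle is the identity
        assert np.allclose(np.roll(cycle[5], 24), cycle[5])


class TestAssignLags:
    def test_noiseless_voxel_lag_in_generating_window(self, space, between_fwd, hrf):
        refs = sp.build_lagged_references(between_fwd)
        for k in range(6):
            p = sp.PRFParameters(x0=space.segment_center(k), y0=0.0,
                                 sigma_x=1.5, sigma_y=3.0)
            y = sp.simulate_voxel(p, between_fwd, space, hrf)
            (a,) = sp.assign_lags(y, refs, tr=2.0)
            assert a.included
            digit = sp.lag_to_digit(a, between_fwd, space)
            assert digit == space.digit_labels[k]

    def test_constant_series_excluded(self, between_fwd):
        refs = sp.build_lagged_references(between_fwd)
        (a,) = sp.assign_lags(np.ones(192), refs)
        assert not a.included and a.max_r == 0.0

    def test_inclusion_flag_matches_threshold(self, between_fwd):
        refs = sp.build_lagged_references(between_fwd)
        rng = np.random.default_rng(0)
        noise = rng.standard_normal((50, 192))
        for a in sp.assign_lags(noise, refs, threshold=0.25):
            assert a.included == (a.max_r > 0.25)

    def test_null_inclusion_fraction_is_small(self, between_fwd):
        refs = sp.build_lagged_references(between_fwd)
        frac = sp.null_inclusion_fraction(refs, n_voxels=500, seed=1)
        assert frac < 0.30  # r > 0.25 at 192 bins admits few pure-noise voxels

    def test_time_length_mismatch_rejected(self, between_fwd):
        refs = sp.build_lagged_references(between_fwd)
        with pytest.raises(ValueError):
            sp.assign_lags(np.zeros(100), refs)


class TestCombineDirections:
    def make(self, vid, lag, direction, r=0.9, included=True):
        return sp.LagAssignment(vid, lag, r, included, direction)

    def test_exact_reversal_cancels(self, between_fwd):
        out = sp.combine_directions([self.make(0, 10.0, "forward")],
                                    [self.make(0, 38.0, "backward")], between_fwd)
        assert out[0].best_lag == pytest.approx(10.0)

    def test_circular_mean_of_discrepant_lags(self, between_fwd):
        # backward 34 s maps to 14 s; circular mean of 10 and 14 is 12
        out = sp.combine_directions([self.make(0, 10.0, "forward")],
                                    [self.make(0, 34.0, "backward")], between_fwd)
        assert out[0].best_lag == pytest.approx(12.0)

    def test_wraparound_mean(self):
        # 2 s and 46 s on a 48 s cycle average to 0, not 24
        assert _circular_mean_lag(2.0, 46.0, 48.0) == pytest.approx(0.0, abs=1e-9)

    def test_included_requires_both_directions(self, between_fwd):
        out = sp.combine_directions(
            [self.make(0, 10.0, "forward", included=False)],
            [self.make(0, 38.0, "backward")], between_fwd)
        assert not out[0].included

    def test_voxel_missing_in_one_direction_dropped(self, between_fwd):
        out = sp.combine_directions([self.make(0, 10.0, "forward")],
                                    [self.make(1, 38.0, "backward")], between_fwd)
        assert out == []


class TestLagToDigit:
    def test_window_edges(self, space, between_fwd):
        a0 = sp.LagAssignment(0, 0.0, 0.9, True, "forward")
        assert sp.lag_to_digit(a0, between_fwd, space) == "D1"
        a_end = sp.LagAssignment(0, 47.9, 0.9, True, "forward")
        assert sp.lag_to_digit(a_end, between_fwd, space) == "Palm"

    def test_backward_direction_is_mapped(self, space, between_fwd):
        # backward lag 46 s maps to forward phase 2 s -> D1
        a = sp.LagAssignment(0, 46.0, 0.9, True, "backward")
        assert sp.lag_to_digit(a, between_fwd, space) == "D1"

    def test_not_included_rejected(self, space, between_fwd):
        a = sp.LagAssignment(0, 0.0, 0.1, False, "forward")
        with pytest.raises(ValueError):
            sp.lag_to_digit(a, between_fwd, space)

    def test_full_cycle_shift_is_identity(self, space, between_fwd):
        a = sp.LagAssignment(0, 10.0, 0.9, True, "forward")
        b = sp.LagAssignment(0, 10.0 + 48.0 - 48.0, 0.9, True, "forward")
        assert sp.lag_to_digit(a, between_fwd, space) == sp.lag_to_digit(b, between_fwd, space)


class TestNoiselessRecovery:
    def test_digit_recovery_and_monotone_lags(self, noiseless_dataset):
        """Winner-take-all on noiseless data recovers every generating digit,
        and combined forward/backward lags increase with digit index."""
        ds = noiseless_dataset
        space = ds.space
        fwd, bwd = ds.designs[0], ds.designs[1]
        n = fwd.n_timebins
        refs_f = sp.build_lagged_references(fwd)
        refs_b = sp.build_lagged_references(bwd)
        la_f = sp.assign_lags(ds.bold[:, :n], refs_f, tr=2.0, direction="forward")
        la_b = sp.assign_lags(ds.bold[:, n:2 * n], refs_b, tr=2.0, direction="backward")
        combined = sp.combine_directions(la_f, la_b, fwd)
        true_digits = [space.segment_of(t.true_params.x0) for t in ds.truth]
        recovered = [sp.lag_to_digit(a, fwd, space) for a in combined]
        assert recovered == true_digits
        # per-digit mean combined lag strictly increases along the hand
        lags = np.array([a.best_lag for a in combined])
        idx = np.array([space.segment_index_of(t.true_params.x0) for t in ds.truth])
        means = [lags[idx == k].mean() for k in range(6)]
        assert np.all(np.diff(means) > 0)

    def test_combined_lags_near_forward_lags(self, noiseless_dataset):
        # the reversal mapping cancels the hemodynamic delay up to the
        # half-block asymmetry of onset-locked references: within one TR
        ds = noiseless_dataset
        fwd, bwd = ds.designs[0], ds.designs[1]
        n = fwd.n_timebins
        la_f = sp.assign_lags(ds.bold[:, :n], sp.build_lagged_references(fwd),
                              tr=2.0, direction="forward")
        la_b = sp.assign_lags(ds.bold[:, n:2 * n], sp.build_lagged_references(bwd),
                              tr=2.0, direction="backward")
        combined = sp.combine_directions(la_f, la_b, fwd)
        cycle = fwd.cycle_seconds
        for f, c in zip(la_f, combined):
            delta = abs(c.best_lag - f.best_lag)
            assert min(delta, cycle - delta) <= 2.0
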