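"""Ratemap machinery: averaging, spike emulation, binning and smoothing."""

import numpy as np
import pytest

from slowplace.motion import Trajectory
from slowplace.ratemaps import (
    RateMap,
    SpikeRecord,
    average_map,
    bin_and_smooth,
    emulate_spikes,
    occupancy_limited_map,
    trajectory_ratemaps,
)


def make_map(values, valid=None, res=1.0, cell=0, direction="N"):
    values = np.asarray(values, dtype=float)
    valid = np.ones_like(values, bool) if valid is None else valid
    return RateMap(values.copy(), valid.copy(), res, (0.0, 0.0), cell, direction)


def uniform_traj(n=10000, seed=0, extent=30.0, dt=0.05):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-extent, extent, size=(n, 2))
    return Trajectory(pos, np.zeros(n), dt, 20.0)


class TestAverageMap:
    def test_mean_of_identical_maps_is_identity(self):
        maps = [make_map([[1.0, 2.0], [3.0, 4.0]], direction=d)
                for d in "ABCDEFGH"]
        avg = average_map(maps)
        assert np.allclose(avg.values, maps[0].values)

    def test_opposite_patterns_cancel(self):
        v = np.array([[1.0, -2.0], [0.5, 3.0]])
        maps = [make_map(v), make_map(-v)]
        assert np.allclose(average_map(maps).values, 0.0)

    def test_hand_computed_three_by_three(self):
        a = make_map([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        b = make_map([[9, 8, 7], [6, 5, 4], [3, 2, 1]])
        c = make_map([[0, 0, 0], [3, 3, 3], [6, 6, 6]])
        avg = average_map([a, b, c])
        expected = np.array([[10, 10, 10], [13, 13, 13], [16, 16, 16]]) / 3.0
        assert np.allclose(avg.values, expected)

    def test_inconsistent_masks_rejected(self):
        a = make_map(np.ones((2, 2)))
        b = make_map(np.ones((2, 2)), valid=np.array([[True, False]] * 2))
        with pytest.raises(ValueError):
            average_map([a, b])


class TestEmulateSpikes:
    def test_zero_activity_yields_no_spikes(self):
        traj = uniform_traj(500)
        recs = emulate_spikes(np.zeros((500, 2)), traj)
        assert all(len(r.spike_positions) == 0 for r in recs)

    def test_peak_activity_fires_every_step(self):
        traj = uniform_traj(500)
        recs = emulate_spikes(np.ones((500, 1)), traj)
        assert len(recs[0].spike_positions) == 500

    def test_half_probability_binomial(self):
        n = 10000
        traj = uniform_traj(n)
        acts = np.full((n, 1), 0.5)
        acts[0, 0] = 1.0  # sets the peak so p = 0.5 elsewhere
        rec = emulate_spikes(acts, traj, np.random.default_rng(0))[0]
        count = len(rec.spike_positions)
        sd = np.sqrt(n * 0.5 * 0.5)
        assert abs(count - n / 2) < 3 * sd

    def test_scale_invariance_of_distribution(self):
        n = 2000
        traj = uniform_traj(n)
        rng = np.random.default_rng(1)
        acts = np.abs(rng.normal(size=(n, 1)))
        r1 = emulate_spikes(acts, traj, np.random.default_rng(42))[0]
        r2 = emulate_spikes(7.3 * acts, traj, np.random.default_rng(42))[0]
        assert np.array_equal(r1.spike_positions, r2.spike_positions)

    def test_spikes_lie_on_trajectory(self):
        traj = uniform_traj(300)
        rng = np.random.default_rng(2)
        acts = np.abs(rng.normal(size=(300, 1)))
        rec = emulate_spikes(acts, traj, rng)[0]
        pos_set = {tuple(p) for p in traj.positions}
        assert all(tuple(p) in pos_set for p in rec.spike_positions)


class TestBinAndSmooth:
    def test_uniform_occupancy_uniform_spiking_is_flat(self):
        traj = uniform_traj(60000)
        rec = emulate_spikes(np.full((60000, 1), 1.0), traj)[0]
        m = bin_and_smooth(rec, traj, bin_size=5.0, kernel_width=5.0)
        vals = m.values[m.valid]
        assert vals.std() / vals.mean() < 0.05

    def test_four_bin_arithmetic_oracle(self):
        # 2x2 grid of 10-cm bins; occupancy and spikes placed by hand
        pos = np.array([[-5.0, -5.0]] * 4 + [[5.0, -5.0]] * 2
                       + [[-5.0, 5.0]] * 2 + [[5.0, 5.0]] * 2)
        traj = Trajectory(pos, np.zeros(len(pos)), dt=1.0, speed=20.0)
        spikes = SpikeRecord(np.array([[-5.0, -5.0]] * 2 + [[5.0, 5.0]]), 0, len(pos))
        m = bin_and_smooth(spikes, traj, bin_size=10.0, kernel_width=1e-9,
                           bounds=(-10, -10, 10, 10))
        # rate = count / occupancy-time: 2/4, 0/2, 0/2, 1/2
        assert m.values[0, 0] == pytest.approx(0.5)
        assert m.values[0, 1] == pytest.approx(0.0)
        assert m.values[1, 0] == pytest.approx(0.0)
        assert m.values[1, 1] == pytest.approx(0.5)

    def test_unvisited_bins_invalid_not_zero(self):
        pos = np.full((10, 2), 1.0)
        traj = Trajectory(pos, np.zeros(10), dt=0.05, speed=20.0)
        rec = SpikeRecord(pos[:3].copy(), 0, 10)
        m = bin_and_smooth(rec, traj, bin_size=3.0, bounds=(-10, -10, 10, 10))
        assert m.valid.sum() == 1
        assert np.isnan(m.values[~m.valid]).all()

    def test_smoothing_conserves_rate_mass(self):
        traj = uniform_traj(20000, seed=3)
        rng = np.random.default_rng(3)
        acts = np.abs(rng.normal(size=(20000, 1)))
        rec = emulate_spikes(acts, traj, rng)[0]
        rough = bin_and_smooth(rec, traj, bin_size=3.0, kernel_width=1e-9)
        smooth = bin_and_smooth(rec, traj, bin_size=3.0, kernel_width=3.0)
        a = np.nansum(rough.values[rough.valid])
        b = np.nansum(smooth.values[smooth.valid])
        assert abs(a - b) / a < 0.01

    def test_empty_trajectory_rejected(self):
        traj = Trajectory(np.empty((0, 2)), np.empty(0), 0.05, 20.0)
        rec = SpikeRecord(np.empty((0, 2)), 0, 0)
        with pytest.raises(ValueError):
            bin_and_smooth(rec, traj)


class TestOccupancyLimited:
    def test_full_cutoff_equals_untruncated(self):
        traj = uniform_traj(2000)
        rng = np.random.default_rng(5)
        acts = np.abs(rng.normal(size=(2000, 3)))
        a = occupancy_limited_map(acts, traj, traj.duration,
                                  np.random.default_rng(9))
        b = trajectory_ratemaps(acts, traj, np.random.default_rng(9))
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.valid, mb.valid)
            assert np.allclose(ma.values[ma.valid], mb.values[mb.valid])

    def test_mask_monotone_in_cutoff(self):
        rng = np.random.default_rng(6)
        pos = np.cumsum(rng.normal(scale=2.0, size=(4000, 2)), axis=0)
        traj = Trajectory(pos, np.zeros(4000), 0.05, 20.0)
        acts = np.abs(rng.normal(size=(4000, 1)))
        bounds = (pos[:, 0].min() - 3, pos[:, 1].min() - 3,
                  pos[:, 0].max() + 3, pos[:, 1].max() + 3)
        m2 = occupancy_limited_map(acts, traj, 120.0, np.random.default_rng(0),
                                   bounds=bounds)[0]
        m4 = occupancy_limited_map(acts, traj, 190.0, np.random.default_rng(0),
                                   bounds=bounds)[0]
        assert np.all(m4.valid[m2.valid])

    def test_cutoff_beyond_duration_rejected(self):
        traj = uniform_traj(100)
        with pytest.raises(ValueError):
            occupancy_limited_map(np.ones((100, 1)), traj, 100.0)
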