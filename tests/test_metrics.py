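"""Directional/spatial consistency, field segmentation, cell matching."""

import numpy as np
import pytest

from slowplace.metrics import (
    ConsistencyReport,
    classify_track_cell,
    classify_track_population,
    directional_consistency,
    field_rotation_deg,
    match_cells,
    segment_fields,
)
from slowplace.ratemaps import RateMap


def make_map(values, valid=None, res=1.0, cell=0, direction="N"):
    values = np.asarray(values, dtype=float)
    valid = np.ones_like(values, bool) if valid is None else np.asarray(valid, bool)
    return RateMap(values.copy(), valid.copy(), res, (0.0, 0.0), cell, direction)


def pearson_oracle(a, b):
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    return float(np.corrcoef(a, b)[0, 1])


class TestDirectionalConsistency:
    def test_identical_maps_give_one(self):
        rng = np.random.default_rng(0)
        v = rng.random((6, 6))
        maps = [make_map(v) for _ in range(8)]
        avg = make_map(v)
        assert directional_consistency(maps, avg) == pytest.approx(1.0)

    def test_independent_noise_maps_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(20):
            maps = [make_map(rng.random((60, 60))) for _ in range(8)]
            avg_v = np.mean([m.values for m in maps], axis=0)
            vals.append(directional_consistency(maps, make_map(avg_v)))
        # each map correlates with the average only through its own 1/8 share
        assert abs(np.mean(vals) - np.sqrt(1 / 8)) < 0.1

    def test_hand_computed_two_direction_example(self):
        a = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], float)
        b = np.array([[2, 2, 2], [5, 6, 4], [9, 7, 8]], float)
        avg = (a + b) / 2
        expected = (pearson_oracle(a, avg) + pearson_oracle(b, avg)) / 2
        got = directional_consistency([make_map(a), make_map(b)], make_map(avg))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_map_contributes_zero(self):
        flat = make_map(np.ones((4, 4)))
        varying = make_map(np.arange(16.0).reshape(4, 4))
        avg = make_map((flat.values + varying.values) / 2)
        got = directional_consistency([flat, varying], avg)
        assert got == pytest.approx(0.5 * pearson_oracle(varying.values, avg.values))

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        maps = [make_map(rng.random((8, 8))) for _ in range(8)]
        avg = make_map(np.mean([m.values for m in maps], axis=0))
        base = directional_consistency(maps, avg)
        scaled = directional_consistency(
            [make_map(5.0 * m.values) for m in maps], make_map(5.0 * avg.values)
        )
        assert scaled == pytest.approx(base)

    def test_empty_mask_rejected(self):
        m = make_map(np.ones((3, 3)), valid=np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            directional_consistency([m], m)


class TestSegmentFields:
    def test_all_zero_map_has_no_fields(self):
        assert segment_fields(make_map(np.zeros((30, 30)))) == []

    def test_two_disjoint_blocks(self):
        v = np.zeros((60, 60))
        v[5:15, 5:15] = 1.0
        v[40:50, 40:50] = 1.0
        fields = segment_fields(make_map(v))
        assert len(fields) == 2
        assert all(f.area_pixels == 100 for f in fields)

    def test_25_pixel_field_discarded(self):
        v = np.zeros((60, 60))
        v[10:15, 10:15] = 1.0  # exactly 25 pixels
        assert segment_fields(make_map(v)) == []
        v[10:15, 15] = 1.0  # 30 pixels
        assert len(segment_fields(make_map(v))) == 1

    def test_threshold_is_half_of_peak(self):
        v = np.zeros((40, 40))
        v[5:15, 5:15] = 1.0
        v[25:35, 25:35] = 0.45  # below half the peak
        assert len(segment_fields(make_map(v))) == 1

    def test_rescaling_preserves_count(self):
        rng = np.random.default_rng(3)
        v = np.clip(rng.normal(size=(50, 50)), 0, None)
        v[10:25, 10:25] += 3.0
        m1, m2 = make_map(v), make_map(0.01 * v)
        assert len(segment_fields(m1)) == len(segment_fields(m2))

    def test_min_area_scales_with_resolution(self):
        # 3-cm pixels: a 2x2-pixel block is 36 cm^2 > 25 cm^2, kept
        v = np.zeros((10, 10))
        v[4:6, 4:6] = 1.0
        assert len(segment_fields(make_map(v, res=3.0))) == 1
        # at 1 cm/pixel the same block is 4 cm^2, discarded
        assert segment_fields(make_map(v, res=1.0)) == []

    def test_centroid_position(self):
        v = np.zeros((20, 20))
        v[8:14, 2:8] = 1.0
        (f,) = segment_fields(make_map(v))
        assert f.centroid == pytest.approx((5.0, 11.0))

    def test_negative_activity_clipped(self):
        v = np.full((30, 30), -5.0)
        v[5:15, 5:15] = 1.0
        fields = segment_fields(make_map(v))
        assert len(fields) == 1 and fields[0].area_pixels == 100


class TestClassifyTrackCell:
    def field_map(self, where=None):
        v = np.zeros((10, 30))
        if where:
            y, x = where
            v[y:y + 4, x:x + 8] = 1.0
        return make_map(v, res=3.0)

    def test_both_zero_is_silent(self):
        assert classify_track_cell(self.field_map(), self.field_map(), 1.0) == "silent"

    def test_one_field_is_unidirectional(self):
        got = classify_track_cell(self.field_map((3, 5)), self.field_map(), 1.0)
        assert got == "unidirectional"

    def test_fields_both_ways_is_bidirectional(self):
        got = classify_track_cell(self.field_map((3, 5)), self.field_map((3, 20)), 1.0)
        assert got == "bidirectional"

    def test_below_floor_counts_as_silent(self):
        weak_a = self.field_map((3, 5))
        weak_a.values *= 0.01
        weak_b = self.field_map((3, 20))
        weak_b.values *= 0.01
        got = classify_track_cell(weak_a, weak_b, population_median_peak=10.0)
        assert got == "silent"

    def test_population_classification(self):
        maps_a = [self.field_map((3, 5)), self.field_map(), self.field_map((3, 1))]
        maps_b = [self.field_map((3, 20)), self.field_map(), self.field_map()]
        labels = classify_track_population(maps_a, maps_b)
        assert labels == ["bidirectional", "silent", "unidirectional"]


class TestMatchCells:
    def _random_maps(self, rng, n=8, shape=(20, 20)):
        return [make_map(rng.random(shape), cell=i) for i in range(n)]

    def test_shuffled_copy_recovered_exactly(self):
        rng = np.random.default_rng(4)
        maps_a = self._random_maps(rng)
        shuffle = rng.permutation(8)
        maps_b = [maps_a[j] for j in shuffle]
        perm, scores = match_cells(maps_a, maps_b)
        recovered = np.empty(8, int)
        recovered[shuffle] = np.arange(8)
        assert np.array_equal(perm, np.argsort(np.argsort(shuffle)) if False else
                              np.array([list(shuffle).index(i) for i in range(8)]))
        assert np.allclose(scores, 1.0)

    def test_noisy_shuffle_recovered(self):
        rng = np.random.default_rng(5)
        maps_a = self._random_maps(rng)
        shuffle = rng.permutation(8)
        maps_b = []
        for j in shuffle:
            noisy = maps_a[j].values + 0.1 * rng.random((20, 20))
            maps_b.append(make_map(noisy))
        perm, _ = match_cells(maps_a, maps_b)
        expected = np.array([list(shuffle).index(i) for i in range(8)])
        assert np.array_equal(perm, expected)

    def test_assignment_beats_random_permutations(self):
        rng = np.random.default_rng(6)
        maps_a = self._random_maps(rng, n=6)
        maps_b = self._random_maps(rng, n=6)
        perm, scores = match_cells(maps_a, maps_b)
        corr = np.zeros((6, 6))
        for i, ma in enumerate(maps_a):
            for j, mb in enumerate(maps_b):
                corr[i, j] = abs(np.corrcoef(ma.values.ravel(),
                                             mb.values.ravel())[0, 1])
        best = scores.sum()
        for _ in range(1000):
            p = rng.permutation(6)
            assert corr[np.arange(6), p].sum() <= best + 1e-12

    def test_size_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            match_cells(self._random_maps(rng, 3), self._random_maps(rng, 4))


class TestFieldRotation:
    @pytest.mark.parametrize("deg", [90.0, -90.0, 45.0])
    def test_pure_rotation_recovered(self, deg):
        th = np.radians(deg)
        before = (20.0, 5.0)
        after = (before[0] * np.cos(th) - before[1] * np.sin(th),
                 before[0] * np.sin(th) + before[1] * np.cos(th))
        assert field_rotation_deg(before, after) == pytest.approx(deg)


class TestConsistencyReport:
    def test_histograms_and_csv(self, tmp_path):
        rep = ConsistencyReport(
            per_cell_directional=np.array([0.9, 0.1, -0.2]),
            per_cell_field_count=np.array([1, 0, 2]),
            per_cell_peak=np.array([3.0, 0.5, 1.0]),
        )
        counts, _ = rep.field_count_histogram()
        assert counts.sum() == 3
        p = tmp_path / "rep.csv"
        rep.to_csv(p)
        assert p.read_text().count("\n") == 4

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            ConsistencyReport(np.array([1.5]), np.array([0]), np.array([0.0]))
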