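import numpy as np
import pytest

from mirsa.io import ConsistencyError, PixelMask
from mirsa.moran import (
    HH,
    ISOLATED,
    LL,
    DegenerateInputError,
    HotspotMap,
    build_weights,
    iou,
    local_moran,
    overlay_maps,
    threshold_coldspots,
    threshold_hotspots,
)

from _oracles import naive_local_moran


class TestWeights:
    def test_interior_pixel_has_eight_neighbors_weight_one_eighth(self):
        w = build_weights(PixelMask(np.ones((5, 5), bool)))
        center = 12  # raster rank of (2, 2)
        assert w.counts[center] == 8
        assert w.weight(center) == pytest.approx(1 / 8)

    def test_corner_pixel_has_three_neighbors(self):
        w = build_weights(PixelMask(np.ones((5, 5), bool)))
        assert w.counts[0] == 3
        assert w.weight(0) == pytest.approx(1 / 3)

    def test_fully_surrounded_off_mask_pixel_is_isolated(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        m[0, :] = True
        w = build_weights(PixelMask(m))
        iso_rank = int(np.nonzero(w.flat_index == 2 * 5 + 2)[0][0])
        assert w.counts[iso_rank] == 0
        assert w.isolated[iso_rank]

    def test_row_standardization_sums_to_one(self, rng):
        m = rng.random((8, 8)) > 0.3
        m[0, 0] = True
        w = build_weights(PixelMask(m))
        for i in range(w.n):
            k = int(w.counts[i])
            if k:
                assert k * w.weight(i) == pytest.approx(1.0)


class TestObservedI:
    @pytest.mark.parametrize("shape,hole", [((7, 9), False), ((12, 12), True),
                                            ((20, 20), True)])
    def test_matches_double_loop_oracle(self, rng, shape, hole):
        values = rng.normal(size=shape)
        mask = np.ones(shape, bool)
        if hole:
            mask[rng.random(shape) < 0.2] = False
            mask[0, 0] = True
        res = local_moran(values, build_weights(PixelMask(mask)), n_perm=99, seed=0)
        expect = naive_local_moran(values, mask)
        both = ~np.isnan(expect)
        np.testing.assert_allclose(res.observed_I[both], expect[both], atol=1e-12)
        assert np.isnan(res.observed_I[~both]).all()

    def test_alternating_stripes_have_negative_interior_autocorrelation(self):
        # rows of +1/-1: 6 of 8 queen neighbors carry the opposite sign,
        # so every interior lag is -z_i/2 and I_i < 0
        yy, _ = np.mgrid[:10, :10]
        values = np.where(yy % 2 == 0, 1.0, -1.0)
        res = local_moran(values, build_weights(PixelMask(np.ones((10, 10), bool))),
                          n_perm=99, seed=0)
        assert (res.observed_I[1:-1, 1:-1] < 0).all()

    def test_checkerboard_interior_lag_cancels_exactly(self):
        # under queen contiguity a +/-1 checkerboard's four same-color
        # diagonal neighbors cancel the four opposite edge neighbors
        yy, xx = np.mgrid[:10, :10]
        values = np.where((yy + xx) % 2 == 0, 1.0, -1.0)
        res = local_moran(values, build_weights(PixelMask(np.ones((10, 10), bool))),
                          n_perm=99, seed=0)
        np.testing.assert_allclose(res.observed_I[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            local_moran(np.full((5, 5), 3.0),
                        build_weights(PixelMask(np.ones((5, 5), bool))),
                        n_perm=99, seed=0)


class TestPermutationInference:
    def test_deterministic_given_seed(self, rng):
        values = rng.normal(size=(9, 9))
        w = build_weights(PixelMask(np.ones((9, 9), bool)))
        a = local_moran(values, w, n_perm=199, seed=42)
        b = local_moran(values, w, n_perm=199, seed=42)
        np.testing.assert_array_equal(a.pseudo_p, b.pseudo_p)
        c = local_moran(values, w, n_perm=199, seed=43)
        assert not np.array_equal(a.pseudo_p, c.pseudo_p)

    def test_pseudo_p_lower_bound(self, rng):
        values = rng.normal(size=(10, 10))
        res = local_moran(values, build_weights(PixelMask(np.ones((10, 10), bool))),
                          n_perm=99, seed=0)
        on = ~np.isnan(res.pseudo_p)
        assert (res.pseudo_p[on] >= 1 / 100).all()
        assert (res.pseudo_p[on] <= 1.0).all()

    def test_translation_invariance(self, rng):
        base = rng.normal(size=(8, 8))
        base[2:5, 2:5] += 3.0
        m = np.zeros((8, 8), bool)
        m[1:7, 1:7] = True
        big_v = np.zeros((12, 12))
        big_m = np.zeros((12, 12), bool)
        res0 = local_moran(base, build_weights(PixelMask(m)), 199, seed=5)
        hot0 = threshold_hotspots(res0, 0.05)
        # shifting image and mask together shifts the hotspot map identically
        big_v[3:11, 2:10] = base
        big_m[3:11, 2:10] = m
        res1 = local_moran(big_v, build_weights(PixelMask(big_m)), 199, seed=5)
        hot1 = threshold_hotspots(res1, 0.05)
        np.testing.assert_array_equal(hot1.values[3:11, 2:10], hot0.values)
        assert hot1.values.sum() == hot0.values.sum()


class TestHotspots:
    def _result(self, rng):
        values = rng.normal(size=(12, 12))
        values[3:7, 3:7] += 4.0
        w = build_weights(PixelMask(np.ones((12, 12), bool)))
        return local_moran(values, w, n_perm=199, seed=7)

    def test_alpha_below_resolution_gives_empty_map(self, rng):
        res = self._result(rng)
        assert threshold_hotspots(res, 1 / 1000).n_hotspot == 0

    def test_alpha_near_one_selects_all_hh_pixels(self, rng):
        res = self._result(rng)
        hot = threshold_hotspots(res, 0.999999)
        np.testing.assert_array_equal(hot.values, res.quadrant == HH)

    def test_hotspot_sets_monotone_in_alpha(self, rng):
        res = self._result(rng)
        prev = None
        for alpha in [0.005, 0.01, 0.05, 0.1, 0.5]:
            cur = threshold_hotspots(res, alpha).values
            if prev is not None:
                assert (prev <= cur).all()
            prev = cur

    def test_hotspots_are_significant_hh_pixels_only(self, rng):
        res = self._result(rng)
        hot = threshold_hotspots(res, 0.01)
        assert (res.quadrant[hot.values] == HH).all()
        assert (res.pseudo_p[hot.values] <= 0.01).all()
        assert not hot.values[~res.mask].any()

    def test_coldspots_are_significant_ll_pixels(self, rng):
        values = rng.normal(size=(12, 12))
        values[3:7, 3:7] -= 4.0
        res = local_moran(values, build_weights(PixelMask(np.ones((12, 12), bool))),
                          199, seed=3)
        cold = threshold_coldspots(res, 0.01)
        assert cold.n_hotspot > 0
        assert (res.quadrant[cold.values] == LL).all()

    def test_isolated_pixels_never_hotspots(self):
        m = np.zeros((6, 6), bool)
        m[0, :] = True
        m[4, 4] = True  # isolated
        values = np.zeros((6, 6))
        values[0, :] = [1, 5, 2, 8, 1, 3]
        values[4, 4] = 100.0
        res = local_moran(values, build_weights(PixelMask(m)), 99, seed=0)
        assert res.quadrant[4, 4] == ISOLATED
        assert not threshold_hotspots(res, 0.5).values[4, 4]


class TestOverlay:
    def _map(self, arr, tissue):
        return HotspotMap(arr, 0.01, "s", tissue)

    def test_disjoint_maps_give_single_assignments(self):
        a = np.zeros((4, 4), bool); a[0, 0] = True
        b = np.zeros((4, 4), bool); b[3, 3] = True
        ov = overlay_maps([self._map(a, "tumor"), self._map(b, "stroma")])
        assert ov.counts.max() == 1
        assert not ov.multiple.any()
        assert ov.tissues_at(0, 0) == {"tumor"}
        assert ov.tissues_at(3, 3) == {"stroma"}

    def test_identical_maps_flag_all_hotspots_multiple(self):
        a = np.zeros((4, 4), bool); a[1:3, 1:3] = True
        ov = overlay_maps([self._map(a, "tumor"), self._map(a.copy(), "stroma")])
        np.testing.assert_array_equal(ov.multiple, a)

    def test_pairwise_overlaps_match_enumeration_oracle(self, rng):
        maps = {t: rng.random((5, 5)) < 0.4 for t in ("tumor", "stroma", "necrosis")}
        ov = overlay_maps([self._map(v, k) for k, v in maps.items()])
        for r in range(5):
            for c in range(5):
                expect = {t for t, v in maps.items() if v[r, c]}
                assert ov.tissues_at(r, c) == expect
                assert ov.multiple[r, c] == (len(expect) > 1)
        mask = np.ones((5, 5), bool)
        ov2 = overlay_maps([self._map(v, k) for k, v in maps.items()], mask=mask)
        np.testing.assert_array_equal(
            ov2.unassigned, ~np.any(np.stack(list(maps.values())), axis=0)
        )

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ConsistencyError):
            overlay_maps([self._map(np.zeros((4, 4), bool), "a"),
                          self._map(np.zeros((5, 5), bool), "b")])


def test_iou_definition():
    a = np.zeros(10, bool); a[:4] = True
    b = np.zeros(10, bool); b[1:6] = True
    assert iou(a, b) == pytest.approx(3 / 6)
    assert iou(a, a) == 1.0
    assert iou(np.zeros(3, bool), np.zeros(3, bool)) == 1.0
    assert iou(a, ~a) == 0.0
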