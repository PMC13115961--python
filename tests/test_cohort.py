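import copy

import numpy as np
import pytest

import mirsa as M
from mirsa.cohort import (
    CalibrationDegenerateError,
    HotspotDatabase,
    build_database,
    cohort_sa,
    pick_references,
    reference_sa,
    stitch,
)
from mirsa.io import ConsistencyError, PixelMask
from mirsa.moran import _draw_wor, _pixel_rng
from mirsa.projection import ProjectionImage


def _proj(values, mask=None, sid="s", tissue="tumor"):
    values = np.asarray(values, float)
    if mask is None:
        mask = values != 0
    return ProjectionImage(values, PixelMask(mask), tissue, 10.0, sid)


class TestStitch:
    def test_pixel_conservation_and_gutter(self, rng):
        a = _proj(rng.normal(10, 1, (5, 5)), np.ones((5, 5), bool), "a")
        b = _proj(rng.normal(10, 1, (5, 5)), rng.random((5, 5)) > 0.3, "b")
        sup = stitch([a, b])
        assert sup.mask.n_on == a.mask.n_on + b.mask.n_on
        # one-pixel zero gutter between tiles: queen contiguity cannot
        # cross sample boundaries
        assert sup.values.shape == (5, 11)
        assert not sup.mask.values[:, 5].any()
        assert (sup.values[:, 5] == 0).all()

    def test_disassembly_recovers_original_grids(self, rng):
        projs = [
            _proj(rng.normal(10, 1, (4, 6)), np.ones((4, 6), bool), "a"),
            _proj(rng.normal(10, 1, (5, 5)), np.ones((5, 5), bool), "b"),
            _proj(rng.normal(10, 1, (3, 4)), np.ones((3, 4), bool), "c"),
        ]
        back = stitch(projs).disassemble()
        for orig, rec in zip(projs, back):
            assert rec.sample_id == orig.sample_id
            np.testing.assert_array_equal(rec.values[: orig.shape[0], : orig.shape[1]],
                                          orig.values)
            assert not rec.mask.values[orig.shape[0]:, :].any()
            assert not rec.mask.values[:, orig.shape[1]:].any()

    def test_unequal_tiles_zero_padded(self, rng):
        a = _proj(rng.normal(10, 1, (4, 6)), np.ones((4, 6), bool), "a")
        b = _proj(rng.normal(10, 1, (5, 5)), np.ones((5, 5), bool), "b")
        sup = stitch([a, b])
        ta, tb = sup.tiles
        assert (ta.height, ta.width) == (4, 6)
        assert (tb.height, tb.width) == (5, 5)
        # padding outside each sample's extent carries value 0, off-mask
        assert (sup.values[4, :6] == 0).all()
        assert not sup.mask.values[4, :6].any()

    def test_requires_two_samples_same_tissue(self, rng):
        a = _proj(rng.normal(10, 1, (4, 4)), np.ones((4, 4), bool), "a")
        with pytest.raises(ValueError):
            stitch([a])
        b = _proj(rng.normal(10, 1, (4, 4)), np.ones((4, 4), bool), "b", "stroma")
        with pytest.raises(ConsistencyError):
            stitch([a, b])


class TestCohortSA:
    def test_permutation_pool_spans_all_samples(self, rng):
        """Conditional draws in the stitched run come from the union of
        both samples' on-mask values (checked against the shared draw
        stream and by the drawn values' distribution)."""
        a = _proj(np.full((4, 4), 100.0) + rng.normal(0, 1, (4, 4)),
                  np.ones((4, 4), bool), "a")
        b = _proj(rng.normal(0, 1, (4, 4)), np.ones((4, 4), bool), "b")
        sup = stitch([a, b])
        n = sup.mask.n_on
        assert n == 32
        x = sup.values[sup.mask.values]
        # reconstruct the draws of the first on-mask pixel of tile b
        w = M.build_weights(sup.mask)
        tile_b = sup.tiles[1]
        flat = tile_b.row0 * sup.values.shape[1] + tile_b.col0
        i = int(np.nonzero(w.flat_index == flat)[0][0])
        rng_i = _pixel_rng(7, flat)
        draws = _draw_wor(rng_i, n - 1, 999, int(w.counts[i]))
        idx = draws + (draws >= i)
        drawn = x[idx].ravel()
        # half the pool sits near 100, half near 0; both must be drawn
        frac_high = (drawn > 50).mean()
        assert 0.4 < frac_high < 0.6
        assert set(np.unique(idx)) <= set(range(n))
        assert len(np.unique(idx)) > n // 2

    def test_identical_copies_share_deterministic_results(self, rng):
        vals = rng.normal(10, 1, (8, 8))
        vals[2:6, 2:6] += 4.0
        copies = [_proj(vals.copy(), np.ones((8, 8), bool), f"c{i}")
                  for i in range(3)]
        sa = cohort_sa(copies, alpha=0.01, n_perm=499, seed=3)
        # observed statistics and quadrants are exactly symmetric
        for r in sa.results[1:]:
            np.testing.assert_allclose(
                r.observed_I[:8, :8], sa.results[0].observed_I[:8, :8],
                atol=1e-12,
            )
            np.testing.assert_array_equal(
                r.quadrant[:8, :8], sa.results[0].quadrant[:8, :8]
            )
        # pseudo-p carries independent permutation noise per tile; the
        # resulting maps may disagree only near the significance edge
        maps = [h.values[:8, :8] for h in sa.hotspots]
        for m in maps[1:]:
            assert (m != maps[0]).mean() <= 0.05

    def test_disassembled_maps_partition_super_map(self, cohort_projections):
        _, projs = cohort_projections
        sa = cohort_sa(projs[:3], alpha=0.05, n_perm=199, seed=1)
        sup_hot = (sa.super_result.quadrant == M.moran.HH) & \
            (sa.super_result.pseudo_p <= 0.05)
        total = 0
        for tile, hot in zip(sa.super_image.tiles, sa.hotspots):
            rs, cs = sa.super_image.tile_slices(tile)
            np.testing.assert_array_equal(hot.values, sup_hot[rs, cs])
            total += hot.values.sum()
        assert total == sup_hot.sum()


class TestDatabase:
    def test_ratio_definition(self, rng):
        vals = rng.normal(10, 1, (10, 10))
        vals[:4, :4] += 5.0
        projs = [_proj(vals.copy(), np.ones((10, 10), bool), f"s{i}")
                 for i in range(2)]
        db = build_database(projs, alpha=0.05, n_perm=199, seed=2)
        for e in db.entries.values():
            assert e.tissue_area == 100
            assert e.ratio == pytest.approx(e.hotspots.n_hotspot / 100)
            assert 0.0 <= e.ratio <= 1.0

    def test_save_load_round_trip(self, tmp_path, cohort_projections):
        _, projs = cohort_projections
        db = build_database(projs[:3], alpha=0.05, n_perm=199, seed=4)
        db.save(tmp_path / "db")
        back = HotspotDatabase.load(tmp_path / "db")
        assert back.tissue_type == db.tissue_type
        assert back.alpha_db == db.alpha_db
        assert set(back.entries) == set(db.entries)
        for sid, e in db.entries.items():
            b = back.entries[sid]
            np.testing.assert_array_equal(b.hotspots.values, e.hotspots.values)
            np.testing.assert_allclose(b.moran.pseudo_p, e.moran.pseudo_p)
            np.testing.assert_allclose(b.projection.values, e.projection.values)
            assert b.ratio == e.ratio

    def test_pick_references_low_high(self):
        db = HotspotDatabase("tumor", 0.01, 999, 0)
        for sid, ratio in [("a", 0.30), ("b", 0.05), ("c", 0.62)]:
            db.entries[sid] = _entry(sid, ratio)
        assert pick_references(db, 2) == ["b", "c"]
        assert pick_references(db, 1) == ["b"]
        assert pick_references(db, 3) == ["b", "c", "a"]

    def test_pick_references_tie_broken_by_sample_id(self):
        db = HotspotDatabase("tumor", 0.01, 999, 0)
        for sid in ["s3", "s1", "s2"]:
            db.entries[sid] = _entry(sid, 0.5)
        assert pick_references(db, 2) == ["s1", "s3"]

    def test_pick_references_bounds(self):
        db = HotspotDatabase("tumor", 0.01, 999, 0)
        db.entries["a"] = _entry("a", 0.1)
        with pytest.raises(ValueError):
            pick_references(db, 2)
        with pytest.raises(ValueError):
            pick_references(db, 0)


def _entry(sid, ratio):
    from mirsa.cohort import DatabaseEntry
    from mirsa.moran import HotspotMap, MoranResult

    z = np.zeros((2, 2))
    proj = ProjectionImage(z, PixelMask(np.ones((2, 2), bool)), "tumor", 10.0, sid)
    res = MoranResult(z, z, z.astype(np.int8), np.ones((2, 2), bool),
                      0.0, 1.0, 4, 999, 0, sid)
    hot = HotspotMap(np.zeros((2, 2), bool), 0.01, sid, "tumor")
    return DatabaseEntry(sid, proj, res, hot, 4, ratio)


class TestReferenceSA:
    def test_self_consistency_with_database_sample(self, cohort_projections):
        _, projs = cohort_projections
        db = build_database(projs[:6], alpha=0.01, n_perm=1999, seed=5)
        sid = sorted(db.entries)[2]
        new = copy.deepcopy(db.entries[sid].projection)
        new.sample_id = "NEW"
        cal = reference_sa(new, db, seed=6)
        assert M.iou(cal.new_sample_hotspots.values,
                     db.entries[sid].hotspots.values) >= 0.9
        assert abs(cal.alpha_star - db.alpha_db) <= 0.005

    def test_alpha_grid_and_curve_well_defined(self, cohort_projections):
        _, projs = cohort_projections
        db = build_database(projs[:3], alpha=0.05, n_perm=199, seed=7)
        cal = reference_sa(projs[3], db, alpha_min=0.01, alpha_max=0.2,
                           alpha_step=0.01, n_perm=199, seed=8)
        alphas = [a for a, _ in cal.iou_curve]
        assert len(alphas) == 20
        assert alphas[0] == pytest.approx(0.01)
        assert alphas[-1] == pytest.approx(0.2)
        ious = np.array([v for _, v in cal.iou_curve])
        assert np.isfinite(ious).all()
        # argmax ties resolve to the smallest alpha
        best = ious.max()
        first = int(np.argmax(ious == best))
        assert cal.alpha_star == pytest.approx(alphas[first])
        assert cal.new_sample_hotspots.alpha == cal.alpha_star

    def test_default_grid_has_1000_levels(self):
        from mirsa.cohort import (
            DEFAULT_ALPHA_MAX,
            DEFAULT_ALPHA_MIN,
            DEFAULT_ALPHA_STEP,
        )

        n = int(round((DEFAULT_ALPHA_MAX - DEFAULT_ALPHA_MIN)
                      / DEFAULT_ALPHA_STEP)) + 1
        assert (DEFAULT_ALPHA_MIN, DEFAULT_ALPHA_MAX, DEFAULT_ALPHA_STEP, n) == \
            (0.0005, 0.5, 0.0005, 1000)

    def test_empty_reference_hotspots_degenerate(self, rng):
        db = HotspotDatabase("tumor", 0.01, 999, 0)
        flat = rng.normal(10, 1, (6, 6))
        for sid in ["a", "b"]:
            e = _entry(sid, 0.0)
            e.projection = _proj(flat.copy(), np.ones((6, 6), bool), sid)
            db.entries[sid] = e
        new = _proj(rng.normal(10, 1, (6, 6)), np.ones((6, 6), bool), "n")
        with pytest.raises(CalibrationDegenerateError):
            reference_sa(new, db, n_perm=199)
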