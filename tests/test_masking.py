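"""MIP, candidate thresholds, blob statistics, mask refinement, tracing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ccrit as cc
from oracles import (convex_pixel_area, random_connected_blob,
                     weighted_solidity as oracle_weighted_solidity)


class TestMIP:
    def test_constant_slices_give_max_slice(self):
        stack = cc.ImageStack(np.stack([np.full((6, 6), k) for k in [1, 2, 5, 3]]))
        np.testing.assert_array_equal(cc.max_intensity_projection(stack),
                                      np.full((6, 6), 5.0))

    def test_matches_per_pixel_loop_oracle(self, rng):
        data = rng.uniform(0, 100, (5, 12, 12))
        stack = cc.ImageStack(data)
        mip = cc.max_intensity_projection(stack)
        for r in range(12):
            for c in range(12):
                assert mip[r, c] == max(data[z, r, c] for z in range(5))

    def test_mip_dominates_every_slice(self, rng):
        stack = cc.ImageStack(rng.uniform(0, 10, (4, 9, 9)))
        mip = cc.max_intensity_projection(stack)
        assert all((mip >= s).all() for s in stack)

    def test_single_slice_stack_is_identity(self, rng):
        data = rng.uniform(0, 1, (1, 7, 7))
        np.testing.assert_array_equal(
            cc.max_intensity_projection(cc.ImageStack(data)), data[0])


class TestCandidateThresholds:
    def test_unit_bins_over_0_100(self):
        img = np.array([[0.0, 100.0]])
        np.testing.assert_allclose(cc.candidate_thresholds(img, 100),
                                   np.arange(1.0, 101.0))

    def test_central_threshold_is_range_midpoint(self):
        img = np.array([[10.0, 20.0]])
        t = cc.candidate_thresholds(img, 100)
        assert t[49] == pytest.approx(15.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(0.1, 200), st.integers(2, 150))
    def test_strictly_increasing_last_equals_max(self, lo, span, n_bins):
        img = np.array([[lo, lo + span]])
        t = cc.candidate_thresholds(img, n_bins)
        assert len(t) == n_bins
        assert np.all(np.diff(t) > 0)
        assert t[-1] == pytest.approx(lo + span)

    def test_constant_image_is_degenerate(self):
        with pytest.raises(cc.DegenerateInputError):
            cc.candidate_thresholds(np.full((4, 4), 3.0), 100)


class TestNucleusMask:
    def test_bright_squares_on_dark_field(self):
        mip = np.zeros((40, 40))
        mip[5:12, 5:12] = 200.0
        mip[25:30, 20:28] = 200.0
        mask = cc.nucleus_mask(mip, 100)   # central threshold = 100
        expected = mip > 100.0
        np.testing.assert_array_equal(mask, expected)

    def test_linear_ramp_selects_upper_half_strictly(self):
        mip = np.tile(np.arange(100.0), (4, 1))
        mask = cc.nucleus_mask(mip, 100)
        # range [0, 99], midpoint 49.5: columns 50.. are above
        np.testing.assert_array_equal(mask, mip > 49.5)

    def test_mask_shrinks_as_threshold_index_grows(self, rng):
        mip = rng.uniform(0, 1, (30, 30))
        prev = None
        for t in cc.candidate_thresholds(mip, 20):
            mask = mip > t
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask


class TestBlobs:
    def test_filled_square_is_solid_with_central_centroid(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        (blob,) = cc.label_blobs(mask)
        assert blob.area == 25
        assert blob.solidity == pytest.approx(1.0)
        assert blob.centroid == pytest.approx((4.0, 4.0))

    def test_single_pixel_and_line_are_solid(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        (blob,) = cc.label_blobs(mask)
        assert blob.solidity == 1.0
        line = np.zeros((8, 8), dtype=bool)
        line[3, 1:7] = True
        (blob,) = cc.label_blobs(line)
        assert blob.solidity == pytest.approx(1.0)

    def test_l_shape_matches_rasterized_hull_oracle(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1:11, 1:4] = True     # vertical arm
        mask[8:11, 1:11] = True    # horizontal arm
        (blob,) = cc.label_blobs(mask)
        assert blob.convex_area == convex_pixel_area(blob.pixels)
        assert blob.solidity == pytest.approx(blob.area / blob.convex_area)
        assert blob.solidity < 1.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_random_blob_solidity_matches_hull_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = random_connected_blob(rng)
        mask = np.zeros((25, 25), dtype=bool)
        mask[coords[:, 0], coords[:, 1]] = True
        (blob,) = cc.label_blobs(mask, connectivity=8)
        assert 0 < blob.solidity <= 1.0
        assert blob.convex_area == pytest.approx(convex_pixel_area(coords), abs=1e-9)

    def test_connectivity_splits_diagonal_blobs(self):
        mask = np.eye(4, dtype=bool)
        assert len(cc.label_blobs(mask, connectivity=8)) == 1
        assert len(cc.label_blobs(mask, connectivity=4)) == 4


class TestBackgroundSelection:
    def test_weighted_solidity_matches_loop_oracle(self, rng):
        mip = rng.uniform(0, 255, (48, 48))
        for cand in cc.background_candidates(mip, n_bins=20):
            areas = [b.area for b in cand.blobs]
            sols = [b.solidity for b in cand.blobs]
            assert cand.weighted_solidity == pytest.approx(
                oracle_weighted_solidity(areas, sols), abs=1e-9)

    def test_single_blob_candidate_weighting_identity(self):
        mip = np.full((10, 10), 100.0)
        mip[4:7, 4:7] = 0.0
        cands = cc.background_candidates(mip, n_bins=4)
        first = cands[0]               # only the dark square is below t_1
        assert len(first.blobs) == 1
        assert first.weighted_solidity == pytest.approx(first.blobs[0].solidity)

    def test_candidates_below_min_are_excluded(self, rng):
        mip = rng.uniform(10, 20, (16, 16))
        cands = cc.background_candidates(mip, n_bins=10)
        assert all(c.mask.any() for c in cands)
        assert all(len(c.blobs) > 0 for c in cands)

    def test_selection_is_exhaustive_argmin(self, rng):
        mip = rng.uniform(0, 255, (40, 40))
        cands = cc.background_candidates(mip, n_bins=30)
        best = cc.select_background_mask(cands)
        assert best.weighted_solidity == min(c.weighted_solidity for c in cands)
        # ties (if any) break toward the lowest threshold
        for c in cands:
            if c.weighted_solidity == best.weighted_solidity:
                assert best.threshold <= c.threshold


class TestRefinement:
    def test_small_blobs_removed_large_retained(self):
        mask = np.zeros((120, 220), dtype=bool)
        mask[10:18, 10:15] = True              # area 40 < 50: must vanish
        mask[40:80, 40:80] = True              # area 1600: survives, shrunk
        out = cc.refine_background_mask(mask, cc.RunConfig(erosion_radius=3))
        assert not out[:30, :30].any()
        assert out[55:65, 55:65].all()

    def test_interior_hole_filled(self):
        mask = np.zeros((140, 140), dtype=bool)
        rr, ccol = np.meshgrid(np.arange(140), np.arange(140), indexing="ij")
        disc = (rr - 70) ** 2 + (ccol - 70) ** 2 <= 55**2
        hole = (rr - 70) ** 2 + (ccol - 70) ** 2 <= 5**2    # ~80 px hole
        mask = disc & ~hole
        out = cc.refine_background_mask(mask, cc.RunConfig(erosion_radius=10))
        assert out[70, 70]                     # hole (<= 1500 px) filled

    def test_oversized_hole_left_open(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[5:195, 5:195] = True
        mask[50:150, 50:150] = False           # 10000 px >> 1500
        out = cc.refine_background_mask(mask, cc.RunConfig(erosion_radius=5))
        assert not out[100, 100]

    def test_empty_mask_passes_through(self):
        out = cc.refine_background_mask(np.zeros((30, 30), dtype=bool))
        assert not out.any()

    def test_output_subset_of_opened_except_holes(self, rng):
        from skimage import morphology
        cfg = cc.RunConfig(erosion_radius=2, open_disk_radius=2, open_min_area=9)
        mask = rng.uniform(size=(80, 80)) < 0.6
        out = cc.refine_background_mask(mask, cfg)
        opened = morphology.opening(mask, morphology.disk(2))
        filled = cc.masking.fill_holes(opened, cfg.infill_max_hole)
        assert not (out & ~filled).any()


class TestTraceBoundary:
    @staticmethod
    def _blob(mask):
        (blob,) = cc.label_blobs(np.asarray(mask, dtype=bool))
        return blob

    def test_three_by_three_square_boundary(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:4, 1:4] = True
        path = cc.trace_boundary(self._blob(mask))
        assert len(path) == 8
        assert path[0] == (1, 1)
        assert (2, 2) not in path              # interior pixel excluded
        # clockwise: from the top-left corner the walk moves east first
        assert path[1] == (1, 2)

    def test_single_pixel_blob(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        assert cc.trace_boundary(self._blob(mask)) == [(1, 1)]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_boundary_covers_exterior_adjacent_pixels(self, seed):
        rng = np.random.default_rng(seed)
        coords = random_connected_blob(rng, n_steps=60)
        mask = np.zeros((25, 25), dtype=bool)
        mask[coords[:, 0], coords[:, 1]] = True
        blob = self._blob(mask)
        path = set(cc.trace_boundary(blob))
        pixels = {tuple(p) for p in blob.pixels}
        assert path <= pixels
        # every pixel sharing an edge with the unbounded exterior is on the
        # trace; the dual of an 8-connected foreground is a 4-connected
        # background (diagonal pockets are holes), and pixels that touch the
        # exterior only at a corner are legitimately cut by the walk
        from scipy import ndimage
        padded = np.pad(mask, 1)             # border guaranteed background
        ext = ndimage.label(~padded)[0]      # 4-connected background
        ext_id = ext[0, 0]
        for r, c in pixels:
            for q in ((r, c + 1), (r + 2, c + 1), (r + 1, c), (r + 1, c + 2)):
                if ext[q] == ext_id:
                    assert (r, c) in path
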