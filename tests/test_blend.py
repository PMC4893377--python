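"""Distance-transform feathering weights and mosaic composition."""

import numpy as np
import pytest

from slitmosaic.blend import (
    compare_compositors,
    composite,
    distance_weights,
    seam_gradient_metric,
)


def _brute_force_distance(mask):
    """Nearest-background search by exhaustive enumeration."""
    h, w = mask.shape
    bg = [(r, c) for r in range(h) for c in range(w) if not mask[r, c]]
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                out[r, c] = min(np.hypot(r - br, c - bc) for br, bc in bg)
    return out


class TestDistanceWeights:
    def test_all_background_is_all_zero(self):
        assert not distance_weights(np.zeros((5, 5), bool)).any()

    def test_1d_row_profile(self):
        mask = np.array([[0, 1, 1, 1, 0]], bool)
        np.testing.assert_array_equal(distance_weights(mask)[0], [0, 1, 2, 1, 0])

    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        w = distance_weights(mask)
        assert w[2, 2] == 1.0 and w.sum() == 1.0

    def test_matches_brute_force(self, rng):
        mask = rng.random((7, 9)) > 0.4
        np.testing.assert_allclose(distance_weights(mask), _brute_force_distance(mask))

    def test_zero_outside_positive_inside(self, short_loop):
        m = short_loop.true_masks[0]
        w = distance_weights(m)
        assert not w[~m].any()
        assert (w[m] > 0).all()

    def test_monotone_influence_under_mask_shrink(self, short_loop):
        """Shrinking a frame's mask never increases its weight anywhere."""
        from scipy.ndimage import binary_erosion

        m = short_loop.true_masks[0]
        w_full = distance_weights(m)
        w_small = distance_weights(binary_erosion(m, iterations=2))
        assert (w_small <= w_full + 1e-12).all()

    def test_border_pixels_weigh_less_than_interior(self, short_loop):
        from scipy.ndimage import binary_erosion

        m = short_loop.true_masks[0]
        w = distance_weights(m)
        # border of the mask itself; pixels on the image edge (where the
        # slit runs out of the frame) are not content borders
        border = m & ~binary_erosion(m, border_value=1)
        interior = binary_erosion(m, iterations=3, border_value=1)
        assert w[border].max() < w[interior].min()


class TestComposite:
    def test_single_frame_restricted_to_mask(self, short_loop):
        frame = short_loop.frames[0]
        mask = short_loop.true_masks[0]
        canvas = composite([frame], [mask], [(0.0, 0.0)])
        cov = canvas.coverage[: mask.shape[0], : mask.shape[1]]
        np.testing.assert_array_equal(cov, mask)
        np.testing.assert_allclose(
            canvas.mosaic[: mask.shape[0], : mask.shape[1]][mask],
            frame.image[mask],
        )

    def test_two_pixel_worked_example(self):
        """Weights 1 and 3 with intensities 10/255 and 50/255 blend to the
        weighted mean 40/255."""
        img_a = np.full((1, 2, 3), 10 / 255)
        img_b = np.full((1, 2, 3), 50 / 255)
        # 1x2 masks: distance weights 1 each; scale frame b by stacking it
        # three times at the same position to realize weight 3
        canvas = composite(
            [img_a, img_b, img_b, img_b],
            [np.ones((1, 2), bool)] * 4,
            [(0, 0)] * 4,
        )
        np.testing.assert_allclose(canvas.mosaic[0, 0], 40 / 255, atol=1e-12)

    def test_identical_values_blend_to_same_value(self, rng):
        img = np.full((6, 6, 3), 0.37)
        m1 = rng.random((6, 6)) > 0.3
        m2 = rng.random((6, 6)) > 0.3
        canvas = composite([img, img], [m1, m2], [(0, 0), (0, 0)])
        assert np.allclose(canvas.mosaic[canvas.coverage], 0.37)

    def test_normalized_weights_sum_to_one(self, short_loop):
        """After division by the weight plane, effective per-frame weights
        sum to exactly 1 at every covered pixel."""
        n = 4
        pos = short_loop.trajectory.positions[:n]
        canvas = composite(short_loop.frames[:n], short_loop.true_masks[:n], pos)
        total = np.zeros_like(canvas.weight)
        for k in range(n):
            from slitmosaic.blend import distance_weights as dw

            w = dw(short_loop.true_masks[k])
            x = int(pos[k, 0] - canvas.origin[0])
            y = int(pos[k, 1] - canvas.origin[1])
            h, wd = w.shape
            total[y : y + h, x : x + wd] += w
        norm = total[canvas.coverage] / canvas.weight[canvas.coverage]
        np.testing.assert_allclose(norm, 1.0, atol=1e-9)

    def test_unplaced_frame_skipped_with_warning(self, short_loop):
        with pytest.warns(UserWarning, match="no solved position"):
            canvas = composite(
                short_loop.frames[:2],
                short_loop.true_masks[:2],
                [(0.0, 0.0), (np.nan, np.nan)],
            )
        assert canvas.coverage.sum() == short_loop.true_masks[0].sum()

    def test_subpixel_placement_spreads_mass(self):
        img = np.ones((2, 2, 3))
        mask = np.ones((2, 2), bool)
        canvas = composite([img], [mask], [(0.5, 0.0)])
        # half-pixel shift in x: weight is split between two columns
        assert canvas.coverage.sum() > mask.sum()
        assert np.allclose(canvas.mosaic[canvas.coverage], 1.0)


class TestCompositorComparison:
    def test_identical_frames_agree(self, short_loop):
        frame = short_loop.frames[0]
        mask = short_loop.true_masks[0]
        canvases = {
            name: composite([frame, frame], [mask, mask], [(0, 0), (0, 0)],
                            compositor=name)
            for name in ("feather", "mean", "median", "overwrite")
        }
        ref = canvases["feather"].mosaic
        for name, cv in canvases.items():
            np.testing.assert_allclose(cv.mosaic, ref, atol=1e-9, err_msg=name)

    def test_feathering_beats_overwrite_on_sweep(self, short_sweep):
        """With border illumination falloff, feathering hides the seams
        that hard overwriting leaves at slit borders."""
        pos = short_sweep.trajectory.positions
        metrics = compare_compositors(short_sweep.images, short_sweep.true_masks, pos)
        assert metrics["feather"] < metrics["overwrite"]

    def test_planted_glare_outlier_suppressed(self, clean_spec):
        """A bright spot wrongly kept in one frame's mask is outvoted: the
        feathered value stays closer to the other frames' consensus than
        overwrite compositing."""
        from slitmosaic import simulate

        traj = simulate.Trajectory(np.array([[100, 100]] * 3))
        seq = simulate.render_sequence(clean_spec, traj)
        images = [f.image.copy() for f in seq.frames]
        masks = [m.copy() for m in seq.true_masks]
        # plant a small saturated patch near the slit border of frame 2,
        # where its feather weight is small
        m = masks[2]
        cols = np.flatnonzero(m.any(axis=0))
        r, c = 64, cols[1]
        images[2][r : r + 2, c : c + 2] = 1.0
        truth = seq.frames[0].image[r, c]

        feather = composite(images, masks, traj.positions).mosaic
        over = composite(images, masks, traj.positions, compositor="overwrite").mosaic
        y0 = int(100 - 100)  # positions equal, origin at (100, 100)
        err_feather = np.abs(feather[r, c] - truth).mean()
        err_over = np.abs(over[r, c] - truth).mean()
        assert err_feather < err_over

    def test_seam_metric_zero_without_boundaries(self):
        img = np.full((4, 4, 3), 0.5)
        canvas = composite([img], [np.zeros((4, 4), bool)], [(0, 0)])
        assert seam_gradient_metric(canvas, [np.zeros((4, 4), bool)], [(0, 0)]) == 0.0
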