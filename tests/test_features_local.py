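import numpy as np
import pytest
from scipy.spatial.distance import pdist

from elytra_id import features_local as fl
from elytra_id.features_global import to_gray


class TestDetectCorners:
    def test_constant_image_has_no_corners(self):
        assert fl.detect_corners(np.full((64, 64), 99.0)).shape == (0, 2)

    def test_square_yields_its_four_vertices(self):
        img = np.zeros((400, 400))
        img[100:300, 100:300] = 255.0
        pts = fl.detect_corners(img)
        assert pts.shape == (4, 2)
        corners = np.array([[100, 100], [100, 299], [299, 100], [299, 299]])
        for c in corners:
            assert np.min(np.abs(pts - c).sum(axis=1)) <= 3

    def test_textured_fragment_yields_many_points(self, enhanced_fragment):
        gray = to_gray(enhanced_fragment.pixels)
        assert len(fl.detect_corners(gray)) > 100


class TestRefinePoints:
    def test_close_pair_merges_to_midpoint(self):
        out = fl.refine_points(np.array([[50, 50], [50, 60]]), (200, 200))
        assert out.shape == (1, 2)
        assert np.abs(out[0] - [50, 55]).max() <= 1

    def test_distant_pair_retained(self):
        pts = np.array([[50, 50], [50, 90]])
        out = fl.refine_points(pts, (200, 200))
        assert sorted(map(tuple, out)) == sorted(map(tuple, pts))

    def test_dense_tile_rejected_by_trimmed_mean_cap(self, rng):
        # 500 points packed into the first 101x101 tile, 10 spread elsewhere
        packed = np.column_stack([rng.integers(0, 101, 500),
                                  rng.integers(0, 101, 500)])
        spread_rows = np.arange(10) * 90 + 150
        spread = np.column_stack([spread_rows, np.full(10, 400)])
        pts = np.vstack([packed, spread])
        out = fl.refine_points(pts, (1100, 600))
        # trimmed mean of occupied-tile counts [500, 1 x 10] is 1 -> cap 2:
        # every packed point is dropped, the 10 spread points survive
        assert len(out) == 10
        assert (out[:, 0] >= 150).all()

    def test_output_pairwise_separation(self, rng):
        pts = np.column_stack([rng.integers(0, 300, 200),
                               rng.integers(0, 300, 200)])
        out = fl.refine_points(pts, (300, 300))
        if len(out) > 1:
            assert pdist(out).min() >= 15.0

    def test_empty_input(self):
        assert fl.refine_points(np.empty((0, 2)), (100, 100)).shape == (0, 2)


class TestColorGradientEdges:
    def test_constant_image_zero_edges(self):
        img = np.full((50, 50, 3), 120, dtype=np.uint8)
        assert np.allclose(fl.color_gradient_edges(img), 0.0)

    def test_single_channel_step_makes_vertical_ridge(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        img[:, 20:, 0] = 200
        edges = fl.color_gradient_edges(img)
        col_energy = edges.sum(axis=0)
        assert col_energy.argmax() in (19, 20)
        assert np.allclose(edges[:, :15], 0.0)
        assert np.allclose(edges[:, 25:], 0.0)

    def test_gray_replicated_rgb_is_sqrt3_of_single_channel(self, rng):
        gray = rng.uniform(0, 255, (40, 40))
        rgb = np.repeat(gray[..., None], 3, axis=2)
        mag_rgb = fl.color_gradient_edges(rgb, rescale=False)
        from skimage import filters
        mag_1 = np.sqrt(filters.sobel_h(gray) ** 2 + filters.sobel_v(gray) ** 2)
        assert np.allclose(mag_rgb, np.sqrt(3.0) * mag_1, atol=1e-9)


class TestWindowDescriptor:
    def test_length_and_constant_window(self):
        edges = np.full((200, 200), 10.0)
        rgb = np.full((200, 200, 3), 100, dtype=np.uint8)
        d = fl.window_descriptor(edges, rgb, (100, 100))
        assert d.shape == (415,)
        cells = d[:400].reshape(25, 16)
        assert np.allclose(cells[:, 1], 0.0)            # variances
        assert np.allclose(cells[:, 2:9], cells[:, 2:3])  # flat projections

    def test_single_row_line_projections_match_hand_interpolation(self):
        edges = np.zeros((200, 200))
        w = 3.0
        edges[107, :] = w  # one horizontal line; in cell row 0 at offset 7
        rgb = np.zeros((200, 200, 3), dtype=np.uint8)
        d = fl.window_descriptor(edges, rgb, (150, 150))
        cells = d[:400].reshape(5, 5, 16)
        cell = cells[0, 0]
        # row-sum profile: 20*w at row 7, zero elsewhere; nodes at 19/6 * i
        profile = np.zeros(20)
        profile[7] = 20.0 * w
        expected_vp = np.interp(np.linspace(0, 19, 7), np.arange(20), profile)
        assert np.allclose(cell[2:9], expected_vp)
        # column-sum profile is flat at w
        assert np.allclose(cell[9:16], w)
        assert cell[0] == pytest.approx(w / 20.0)

    def test_translation_covariance_in_interior(self, rng):
        base = rng.uniform(0, 255, (260, 260))
        rgb = np.repeat(base[..., None], 3, axis=2).astype(np.uint8)
        # unrescaled magnitudes: the [0, 255] rescale is a global operation
        # and is only shift-invariant when the image content is unchanged
        edges = fl.color_gradient_edges(rgb, rescale=False)
        d1 = fl.window_descriptor(edges, rgb, (120, 120))
        shifted_rgb = np.roll(rgb, (10, 10), axis=(0, 1))
        shifted_edges = fl.color_gradient_edges(shifted_rgb, rescale=False)
        d2 = fl.window_descriptor(shifted_edges, shifted_rgb, (130, 130))
        assert np.allclose(d1, d2, atol=1e-6)


class TestLocalVector:
    def test_zero_points_warns_and_zeroes(self):
        img = np.full((200, 200, 3), 128, dtype=np.uint8)
        with pytest.warns(UserWarning, match="no refined feature points"):
            vec = fl.local_features(img)
        assert len(vec) == 416  # 415 + n_points
        assert vec["n_points"] == 0.0
        assert np.allclose(vec.drop("n_points").values, 0.0)

    def test_mean_of_single_point_equals_window_descriptor(self, enhanced_fragment):
        vec, pts = fl.local_features(enhanced_fragment, return_points=True)
        assert vec["n_points"] == len(pts)
        edges = fl.color_gradient_edges(enhanced_fragment.pixels)
        descs = np.stack([
            fl.window_descriptor(edges, enhanced_fragment.pixels, p) for p in pts])
        assert np.allclose(vec.drop("n_points").values, descs.mean(axis=0))
        # averaging preserves per-channel colour-bin normalization
        color = vec[[f"loc_col_R{b}" for b in range(1, 6)]].values
        assert color.sum() == pytest.approx(1.0, abs=1e-9)

    def test_periodic_pattern_has_low_interpoint_dispersion(self):
        # tiled dark squares on a light field: every window sees the same motif
        img = np.full((400, 400, 3), 200, dtype=np.uint8)
        # one motif per 101-px refinement tile keeps per-tile counts equal
        for r in range(90, 300, 101):
            for c in range(90, 300, 101):
                img[r:r + 12, c:c + 12] = 60
        vec, pts = fl.local_features(img, return_points=True)
        # every refined point sits in the pad-free interior by construction
        assert ((pts >= 51) & (pts < 349)).all()
        edges = fl.color_gradient_edges(img)
        descs = np.stack([fl.window_descriptor(edges, img, p) for p in pts])
        mean = descs.mean(axis=0)
        sd = descs.std(axis=0)
        keep = mean > 1e-6
        cv = (sd[keep] / mean[keep]).mean()
        assert cv < 0.5
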