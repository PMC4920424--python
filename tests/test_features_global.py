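import numpy as np
import pytest
from skimage import draw

from elytra_id import features_global as fg


class TestStatisticalFeatures:
    def test_constant_image_degenerate_histogram(self):
        v = fg.statistical_features(np.full((50, 50), 77.0))
        names = dict(zip(fg.STATISTICAL_NAMES, v))
        assert names["stat_mean"] == pytest.approx(77.0)
        assert names["stat_std"] == 0.0
        assert names["stat_uniformity"] == 1.0
        assert names["stat_entropy"] == 0.0
        assert names["stat_smoothness"] == 0.0
        assert names["stat_third_moment"] == 0.0

    def test_two_level_histogram(self):
        img = np.zeros((10, 10))
        img[:5] = 255.0
        v = dict(zip(fg.STATISTICAL_NAMES, fg.statistical_features(img)))
        assert v["stat_entropy"] == pytest.approx(1.0)  # p = (1/2, 1/2)
        assert v["stat_uniformity"] == pytest.approx(0.5)

    @pytest.mark.parametrize("transform", [
        np.rot90,
        lambda img: np.pad(img, ((7, 0), (0, 11))),       # translation
        lambda img: np.kron(img, np.ones((2, 2))),        # 2x scale
    ])
    def test_hu_invariance(self, transform):
        glyph = np.zeros((128, 128))
        glyph[30:80, 40:70] = 200.0
        glyph[40:60, 60:90] = 120.0
        hu_ref = fg.statistical_features(glyph)[6:]
        hu_t = fg.statistical_features(transform(glyph))[6:]
        assert np.max(np.abs(hu_t - hu_ref) / np.abs(hu_ref)) <= 1e-3


class TestSpectraFeatures:
    def test_constant_image_all_zero(self):
        assert np.allclose(
            fg.spectra_features(np.full((64, 64), 128.0), resample=(64, 64)), 0.0)

    def test_matches_brute_force_radial_grouping(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        spec = fg.spectra_features(img, resample=(64, 64))
        mag = np.abs(np.fft.fftshift(np.fft.fft2(img)))
        oracle = np.zeros(81)
        for i in range(64):
            for j in range(64):
                r = int(round(np.hypot(i - 32, j - 32)))
                if 1 <= r <= 80:
                    oracle[r] += mag[i, j]
        nz = oracle[1:] > 0
        rel = np.abs(spec[nz] - oracle[1:][nz]) / oracle[1:][nz]
        assert rel.max() <= 1e-6
        assert np.allclose(spec[~nz], 0.0)

    def test_pure_cosine_peaks_at_its_frequency(self):
        x = np.arange(256)
        img = np.tile(128 + 100 * np.cos(2 * np.pi * 7 * x / 256), (256, 1))
        spec = fg.spectra_features(img)
        assert int(np.argmax(spec)) + 1 == 7


class TestColorFeatures:
    def test_pure_red_lands_in_extreme_bins(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        img[..., 0] = 255
        v = dict(zip(fg.COLOR_NAMES, fg.color_features(img)))
        assert v["col_R10"] == 1.0
        assert v["col_G01"] == 1.0
        assert v["col_B01"] == 1.0
        assert sum(fg.color_features(img)) == pytest.approx(3.0)

    def test_channels_normalized_and_permutation_invariant(self, rng):
        img = rng.integers(0, 256, (30, 30, 3)).astype(np.uint8)
        v = fg.color_features(img)
        assert v[:10].sum() == pytest.approx(1.0, abs=1e-9)
        assert v[10:20].sum() == pytest.approx(1.0, abs=1e-9)
        assert v[20:].sum() == pytest.approx(1.0, abs=1e-9)
        flat = img.reshape(-1, 3)
        shuffled = flat[rng.permutation(len(flat))].reshape(img.shape)
        assert np.allclose(fg.color_features(shuffled), v)


class TestGaborFeatures:
    def test_vertical_stripes_respond_at_zero_degrees(self):
        x = np.arange(128)
        img = np.tile(128 + 100 * np.sin(2 * np.pi * x / 8.0), (128, 1))
        v = fg.gabor_features(img)
        sums = {th: v[3 * i] for i, th in enumerate((0, 30, 60, 90, 120, 150))}
        assert v[-1] == 0.0
        assert sums[0] == max(sums.values())

    def test_horizontal_stripes_respond_at_ninety_degrees(self):
        y = np.arange(128)
        img = np.tile((128 + 100 * np.sin(2 * np.pi * y / 8.0))[:, None], (1, 128))
        v = fg.gabor_features(img)
        assert v[-1] == 90.0

    def test_constant_image_zero_std(self):
        v = fg.gabor_features(np.full((64, 64), 128.0))
        stds = v[2:18:3]
        assert stds.max() <= 1e-6

    def test_descriptor_length_and_kernel_validation(self):
        assert fg.gabor_features(np.zeros((64, 64))).shape == (19,)
        with pytest.raises(ValueError, match="kernel"):
            fg.gabor_features(np.zeros((16, 16)))


class TestKeyObjectFeatures:
    def test_constant_image_all_zero(self):
        img = np.full((100, 100, 3), 128, dtype=np.uint8)
        v = fg.key_object_features(img)
        assert v.shape == (68,)
        assert np.allclose(v, 0.0)

    def test_counts_twelve_dark_disks(self):
        img = np.full((300, 400, 3), 200, dtype=np.uint8)
        for i in range(12):
            rr, cc = draw.disk((50 + 60 * (i // 4), 60 + 90 * (i % 4)), 6,
                               shape=(300, 400))
            img[rr, cc] = 60
        v = dict(zip(fg.KEY_OBJECT_NAMES, fg.key_object_features(img)))
        # dark blobs appear in the large-minus-small polarity
        assert v["dog_ls_number_density"] * 300 * 400 == pytest.approx(12.0)
        assert v["dog_ls_mean_size"] > 0
        assert 0.0 < v["dog_ls_area_density"] < 1.0


class TestGlobalVector:
    def test_length_block_structure_and_determinism(self, enhanced_fragment):
        v1 = fg.global_features(enhanced_fragment)
        v2 = fg.global_features(enhanced_fragment)
        assert len(v1) == 210
        assert list(v1.index) == fg.GLOBAL_NAMES
        assert np.allclose(v1.values, v2.values)

    def test_pixel_shuffle_keeps_color_changes_spectra(self, rng):
        img = rng.integers(0, 256, (120, 140, 3)).astype(np.uint8)
        flat = img.reshape(-1, 3)
        shuffled = flat[rng.permutation(len(flat))].reshape(img.shape)
        a = fg.global_features(img)
        b = fg.global_features(shuffled)
        assert np.allclose(a[fg.COLOR_NAMES].values, b[fg.COLOR_NAMES].values)
        assert not np.allclose(a[fg.SPECTRA_NAMES].values, b[fg.SPECTRA_NAMES].values)
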