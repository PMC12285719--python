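"""HSL conversion, background masking, summaries, and hyperspectral sampling."""

import numpy as np
import pytest

from plumelayers.imaging import (
    HSLPixels,
    HyperspectralCube,
    hsl_threshold_mask,
    hsl_to_rgb,
    polygon_mask,
    read_cube,
    rgb_to_hsl,
    sample_roi_median,
    summarize_hsl,
    write_cube,
)


def one_pixel(r, g, b):
    return np.array([[[r, g, b]]], dtype=float)


class TestRgbToHsl:
    @pytest.mark.parametrize(
        "rgb,h,s,l",
        [
            ((1, 1, 1), 0, 0, 100),
            ((0, 0, 0), 0, 0, 0),
            ((1, 0, 0), 0, 100, 50),
            ((0, 1, 0), 120, 100, 50),
            ((0, 0, 1), 240, 100, 50),
            ((0.5, 0.5, 0.5), 0, 0, 50),
        ],
    )
    def test_primary_colors(self, rgb, h, s, l):
        px = rgb_to_hsl(one_pixel(*rgb))
        assert px.H[0, 0] == pytest.approx(h, abs=1e-9)
        assert px.S[0, 0] == pytest.approx(s, abs=1e-9)
        assert px.L[0, 0] == pytest.approx(l, abs=1e-9)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (32, 32, 3))
        px = rgb_to_hsl(img)
        back = rgb_to_hsl(hsl_to_rgb(px))
        chromatic = px.S > 1e-9
        assert np.allclose(px.H[chromatic], back.H[chromatic], atol=1e-9)
        assert np.allclose(px.S, back.S, atol=1e-9)
        assert np.allclose(px.L, back.L, atol=1e-9)


class TestThresholdMask:
    def test_half_masked(self):
        L = np.concatenate([np.full(50, 80.0), np.full(50, 40.0)]).reshape(10, 10)
        px = HSLPixels(np.zeros((10, 10)), np.zeros((10, 10)), L)
        mask = hsl_threshold_mask(px, [{"l_min": 60.0}])
        assert mask.sum() == 50
        assert np.all(mask.reshape(-1)[:50])

    def test_rule_matching_nothing(self):
        px = HSLPixels(np.zeros((4, 4)), np.zeros((4, 4)), np.full((4, 4), 50.0))
        assert not hsl_threshold_mask(px, [{"l_min": 99.0}]).any()

    def test_union_of_rules(self):
        L = np.repeat([5.0, 50.0, 80.0], 10).reshape(3, 10)
        px = HSLPixels(np.zeros_like(L), np.zeros_like(L), L)
        mask = hsl_threshold_mask(px, [{"l_min": 60.0}, {"l_max": 10.0}])
        assert mask.sum() == 20
        assert not mask[1].any()


class TestSummarize:
    def test_uniform_pixels(self):
        px = HSLPixels(
            np.full((5, 5), 120.0), np.full((5, 5), 30.0), np.full((5, 5), 45.0)
        )
        s = summarize_hsl(px)
        assert s.mean_l == 45.0
        assert s.mean_s == 30.0
        assert s.mean_hue_circular == pytest.approx(120.0, abs=1e-9)
        assert s.mean_hue_arithmetic == pytest.approx(120.0)

    def test_two_group_mean(self):
        L = np.repeat([40.0, 80.0], 8).reshape(4, 4)
        px = HSLPixels(np.zeros_like(L), np.zeros_like(L), L)
        assert summarize_hsl(px).mean_l == pytest.approx(60.0)

    def test_circular_mean_straddles_zero(self):
        H = np.array([[350.0, 10.0]])
        px = HSLPixels(H, np.full_like(H, 50.0), np.full_like(H, 50.0))
        s = summarize_hsl(px)
        angular_dev = min(s.mean_hue_circular, 360.0 - s.mean_hue_circular)
        assert angular_dev == pytest.approx(0.0, abs=1e-9)
        assert s.mean_hue_arithmetic == pytest.approx(180.0)

    def test_all_masked_error(self):
        px = HSLPixels(np.zeros((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="empty"):
            summarize_hsl(px, np.zeros((2, 2), dtype=bool))


class TestPolygonMask:
    def test_integer_rectangle_half_open(self):
        poly = np.array([[2.0, 3.0], [2.0, 7.0], [6.0, 7.0], [6.0, 3.0]])
        mask = polygon_mask(poly, (10, 10))
        rows, cols = np.nonzero(mask)
        assert rows.min() == 2 and rows.max() == 5
        assert cols.min() == 3 and cols.max() == 6
        assert mask.sum() == 16

    def test_triangle_area(self):
        poly = np.array([[0.0, 0.0], [0.0, 20.0], [20.0, 0.0]])
        mask = polygon_mask(poly, (25, 25))
        assert abs(mask.sum() - 200) < 15  # ~half the 20x20 square


class TestRoiSampling:
    def make_cube(self, value=0.3, shape=(20, 20), bands=5):
        centers = np.linspace(400, 700, bands)
        return HyperspectralCube(np.full((*shape, bands), value), centers)

    def test_constant_cube_exact(self):
        cube = self.make_cube(0.3)
        poly = np.array([[2.0, 2.0], [2.0, 18.0], [18.0, 18.0], [18.0, 2.0]])
        out = sample_roi_median(cube, poly, n=100, seed=1)
        assert np.all(out.samples == 0.3)
        assert np.allclose(out.mean_spectrum, 0.3, atol=1e-12)

    def test_median_robust_to_single_outlier(self):
        cube = self.make_cube(0.3)
        cube.pixels[10, 10, :] = 0.95
        poly = np.array([[9.0, 9.0], [9.0, 13.0], [13.0, 13.0], [13.0, 9.0]])
        out = sample_roi_median(cube, poly, n=50, seed=2)
        assert np.all(out.samples == 0.3)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        cube = self.make_cube()
        cube.pixels += rng.uniform(0, 0.1, cube.pixels.shape)
        cube.pixels = np.clip(cube.pixels, 0, 1)
        poly = np.array([[2.0, 2.0], [2.0, 18.0], [18.0, 18.0], [18.0, 2.0]])
        a = sample_roi_median(cube, poly, n=64, seed=7)
        b = sample_roi_median(cube, poly, n=64, seed=7)
        assert np.array_equal(a.locations, b.locations)
        assert np.array_equal(a.samples, b.samples)

    def test_locations_have_complete_neighborhoods(self):
        cube = self.make_cube(shape=(6, 6))
        poly = np.array([[0.0, 0.0], [0.0, 6.0], [6.0, 6.0], [6.0, 0.0]])
        out = sample_roi_median(cube, poly, n=50, seed=4)
        assert out.locations[:, 0].min() >= 1
        assert out.locations[:, 0].max() <= 4

    def test_empty_roi_error(self):
        cube = self.make_cube(shape=(6, 6))
        poly = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="3x3"):
            sample_roi_median(cube, poly, n=10, seed=5)

    def test_standard_error_scaling(self):
        # sample-mean spread shrinks roughly as 1/sqrt(n) on a noisy cube
        rng = np.random.default_rng(6)
        pixels = np.clip(0.5 + rng.normal(0, 0.05, (40, 40, 4)), 0, 1)
        cube = HyperspectralCube(pixels, np.linspace(400, 700, 4))
        poly = np.array([[2.0, 2.0], [2.0, 38.0], [38.0, 38.0], [38.0, 2.0]])
        errs = {}
        for n in (50, 500, 5000):
            devs = [
                np.abs(sample_roi_median(cube, poly, n=n, seed=s).mean_spectrum - 0.5).mean()
                for s in range(8)
            ]
            errs[n] = np.mean(devs)
        assert errs[5000] < errs[50]


class TestCubeIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        cube = HyperspectralCube(rng.uniform(0, 1, (8, 9, 6)), np.linspace(400, 700, 6))
        path = tmp_path / "cube.tiff"
        write_cube(path, cube)
        back = read_cube(path)
        assert np.allclose(back.pixels, cube.pixels, atol=1e-6)
        assert np.allclose(back.band_centers, cube.band_centers)
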