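"""Layer optics construction, three-path stack reflectance, and D recovery."""

import numpy as np
import pytest

from plumelayers.layers import (
    ACHROMATIC_PRESETS,
    AchromaticLayerParams,
    CarotenoidLayerParams,
    FeatherStack,
    LayerOptics,
    StructuralLayerParams,
    build_stack,
    carotenoid_absorbance,
    fit_optical_density,
    make_achromatic_layer,
    make_carotenoid_layer,
    make_downy_layer,
    make_structural_layer,
    stack_reflectance,
)
from plumelayers.spectra import (
    DEFAULT_GRID,
    Spectrum,
    brightness_B2,
    hue_H1,
    saturation_S8,
)


def flat_layer(R, T, grid=DEFAULT_GRID):
    mk = lambda v: Spectrum(grid, np.full(grid.n, float(v)))
    return LayerOptics(mk(R), mk(T), mk(1 - R - T))


class TestCarotenoidLayer:
    def test_no_pigment_limit(self):
        layer = make_carotenoid_layer(CarotenoidLayerParams(D=0.0, s_c=0.2))
        assert np.allclose(layer.R.values, 0.2)
        assert np.allclose(layer.T.values, 0.8)
        assert np.allclose(layer.A.values, 0.0, atol=1e-15)

    def test_beer_lambert_at_peak(self):
        # at the absorbance peak g=1, so D=1 transmits 10^-1 with no backscatter
        layer = make_carotenoid_layer(CarotenoidLayerParams(D=1.0, s_c=0.0))
        g = carotenoid_absorbance(DEFAULT_GRID)
        peak = int(np.argmax(g))
        assert g[peak] == 1.0
        assert layer.T.values[peak] == pytest.approx(0.1, abs=1e-12)
        assert layer.A.values[peak] == pytest.approx(0.9, abs=1e-12)

    def test_template_is_long_pass(self):
        g = carotenoid_absorbance(DEFAULT_GRID)
        wl = DEFAULT_GRID.wavelengths
        assert np.all(g[wl > 550] == 0)
        assert g.max() == 1.0


class TestStructuralLayer:
    def test_peak_value_exact(self):
        p = StructuralLayerParams(lambda0=500, Hpk=0.4, w=80, s_b=0.1, a_s=0.2)
        layer = make_structural_layer(p)
        at0 = np.flatnonzero(DEFAULT_GRID.wavelengths == 500)[0]
        assert layer.R.values[at0] == pytest.approx(0.5, abs=1e-12)

    def test_fwhm_parameterization(self):
        p = StructuralLayerParams(lambda0=500, Hpk=0.4, w=80, s_b=0.0, a_s=0.0)
        layer = make_structural_layer(p)
        wl = DEFAULT_GRID.wavelengths
        half = layer.R.values[wl == 540][0]
        assert half == pytest.approx(0.2, abs=1e-12)

    def test_no_absorption_limit(self):
        layer = make_structural_layer(StructuralLayerParams(a_s=0.0))
        assert np.allclose(layer.T.values, 1 - layer.R.values, atol=1e-15)

    def test_perfect_absorber(self):
        layer = make_structural_layer(StructuralLayerParams(Hpk=0.0, s_b=0.0, a_s=1.0))
        assert np.allclose(layer.T.values, 0.0, atol=1e-15)
        assert np.allclose(layer.A.values, 1.0, atol=1e-15)

    def test_overfull_peak_rejected(self):
        with pytest.raises(ValueError):
            StructuralLayerParams(Hpk=0.7, s_b=0.4)


class TestAchromaticLayer:
    @pytest.mark.parametrize("preset,R", [("white", 0.55), ("black", 0.05), ("gray", 0.30)])
    def test_presets(self, preset, R):
        layer = make_achromatic_layer(preset)
        assert np.allclose(layer.R.values, R)

    def test_opaque_when_tau_zero(self):
        layer = make_achromatic_layer(AchromaticLayerParams(R_level=0.3, tau=0.0))
        assert np.all(layer.T.values == 0)

    def test_downy_terminal(self):
        layer = make_downy_layer()
        assert np.all(layer.T.values == 0)
        assert np.allclose(layer.R.values, 0.30)


class TestStackReflectance:
    def test_transparent_colorful_passes_achromatic(self):
        stack = FeatherStack(flat_layer(0.0, 1.0), flat_layer(0.55, 0.0), make_downy_layer())
        assert np.allclose(stack_reflectance(stack).values, 0.55)

    def test_two_path_arithmetic(self):
        stack = FeatherStack(flat_layer(0.2, 0.5), flat_layer(0.55, 0.0), make_downy_layer())
        assert np.allclose(stack_reflectance(stack).values, 0.2 + 0.25 * 0.55)

    def test_three_path_arithmetic(self):
        stack = FeatherStack(flat_layer(0.2, 0.5), flat_layer(0.05, 0.2), make_downy_layer(0.3))
        expected = 0.2 + 0.25 * 0.05 + 0.25 * 0.04 * 0.3
        assert np.allclose(stack_reflectance(stack).values, expected)

    def test_grid_mismatch_rejected(self):
        from plumelayers.spectra import WavelengthGrid

        g2 = WavelengthGrid(300, 700, 2)
        with pytest.raises(ValueError, match="grid"):
            FeatherStack(
                flat_layer(0.2, 0.5), flat_layer(0.5, 0.0, grid=g2), make_downy_layer()
            )

    def test_matches_scalar_brute_force(self):
        # oracle: per-wavelength scalar evaluation of the three-path formula
        rng = np.random.default_rng(11)
        for _ in range(20):
            rc = rng.uniform(0, 0.5, 401)
            tc = rng.uniform(0, 1, 401) * (1 - rc)
            ra = rng.uniform(0, 0.6)
            ta = rng.uniform(0, 1) * (1 - ra)
            rd = rng.uniform(0, 0.5)
            stack = FeatherStack(
                LayerOptics(
                    Spectrum(DEFAULT_GRID, rc),
                    Spectrum(DEFAULT_GRID, tc),
                    Spectrum(DEFAULT_GRID, 1 - rc - tc),
                ),
                flat_layer(ra, ta),
                make_downy_layer(rd),
            )
            got = stack_reflectance(stack).values
            for k in range(0, 401, 37):
                expect = rc[k] + tc[k] * tc[k] * ra + tc[k] * tc[k] * ta * ta * rd
                assert abs(got[k] - min(expect, 1.0)) < 1e-14


class TestQualitativePatterns:
    def test_brightness_increases_with_achromatic_reflectance(self):
        # the central mechanism: a brighter hidden layer brightens the patch
        p = CarotenoidLayerParams()
        b = {
            bg: brightness_B2(stack_reflectance(build_stack(p, bg)))
            for bg in ("white", "gray", "black")
        }
        assert b["white"] > b["gray"] > b["black"]

    def test_carotenoid_hue_invariant_across_backgrounds(self):
        p = CarotenoidLayerParams()
        hues = {
            bg: hue_H1(stack_reflectance(build_stack(p, bg)))
            for bg in ACHROMATIC_PRESETS
        }
        assert len(set(hues.values())) == 1

    def test_structural_more_saturated_on_black(self):
        for hpk in (0.1, 0.35, 0.7):
            p = StructuralLayerParams(Hpk=hpk)
            s_black = saturation_S8(stack_reflectance(build_stack(p, "black")))
            s_white = saturation_S8(stack_reflectance(build_stack(p, "white")))
            assert s_black > s_white


class TestEnergyConservation:
    def test_randomized_layers_conserve_energy(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            c = make_carotenoid_layer(
                CarotenoidLayerParams(D=rng.uniform(0, 4), s_c=rng.uniform(0, 1))
            )
            hpk = rng.uniform(0, 0.9)
            s = make_structural_layer(
                StructuralLayerParams(
                    lambda0=rng.uniform(300, 700),
                    Hpk=hpk,
                    w=rng.uniform(10, 300),
                    s_b=rng.uniform(0, 1 - hpk),
                    a_s=rng.uniform(0, 1),
                )
            )
            a = make_achromatic_layer(
                AchromaticLayerParams(R_level=rng.uniform(0, 1), tau=rng.uniform(0, 1))
            )
            for layer in (c, s, a):
                total = layer.R.values + layer.T.values + layer.A.values
                assert np.max(np.abs(total - 1)) < 1e-12


class TestOpticalDensityFit:
    def test_noiseless_recovery(self):
        obs = stack_reflectance(build_stack(CarotenoidLayerParams(D=1.5), "gray"))
        D = fit_optical_density(obs, CarotenoidLayerParams(), "gray")
        assert abs(D - 1.5) / 1.5 < 0.01

    def test_zero_density_boundary(self):
        obs = stack_reflectance(build_stack(CarotenoidLayerParams(D=0.0), "gray"))
        assert fit_optical_density(obs, CarotenoidLayerParams(), "gray") <= 0.01

    def test_noisy_recovery(self):
        obs = stack_reflectance(build_stack(CarotenoidLayerParams(D=1.5), "gray"))
        rng = np.random.default_rng(9)
        noisy = Spectrum(
            DEFAULT_GRID, np.clip(obs.values * (1 + rng.normal(0, 0.01, 401)), 0, 1)
        )
        D = fit_optical_density(noisy, CarotenoidLayerParams(), "gray")
        assert abs(D - 1.5) / 1.5 < 0.05
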