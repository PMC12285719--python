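"""Multilayer optical model of a feather patch.

A plumage patch is modeled as a stack of three layers: an outer *colorful*
layer (carotenoid-pigmented barbs or structurally colored barb nanostructures),
a hidden *achromatic* layer (the white/gray/black feather regions that overlap
beneath the colorful tips), and a terminal gray *downy* layer.  Each layer is
summarized by per-wavelength reflectance R, transmittance T, and absorptance A
with R + T + A = 1.

Total patch reflectance is the sum of three light paths:

  (i)   light reflected directly from the colorful layer,
  (ii)  light transmitted through the colorful layer, reflected by the
        achromatic layer, and transmitted back out, and
  (iii) light transmitted through both colorful and achromatic layers,
        reflected by the downy layer, and transmitted back out,

i.e. ``R_tot = R_c + T_c^2 R_a + T_c^2 T_a^2 R_d`` (no higher-order
interreflection terms), clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid

__all__ = [
    "LayerOptics",
    "CarotenoidLayerParams",
    "StructuralLayerParams",
    "AchromaticLayerParams",
    "FeatherStack",
    "ACHROMATIC_PRESETS",
    "carotenoid_absorbance",
    "make_carotenoid_layer",
    "make_structural_layer",
    "make_achromatic_layer",
    "make_downy_layer",
    "build_stack",
    "stack_reflectance",
    "fit_optical_density",
]

_RTA_TOL = 1e-12


@dataclass
class LayerOptics:
    """Reflectance / transmittance / absorptance triple for one layer."""

    R: Spectrum
    T: Spectrum
    A: Spectrum

    def __post_init__(self) -> None:
        if not (self.R.grid == self.T.grid == self.A.grid):
            raise ValueError("R, T, A must share one wavelength grid")
        total = self.R.values + self.T.values + self.A.values
        if np.max(np.abs(total - 1.0)) > 1e-9:
            raise ValueError("energy not conserved: R + T + A != 1")
        for s, label in ((self.R, "R"), (self.T, "T"), (self.A, "A")):
            if np.any(s.values < -_RTA_TOL) or np.any(s.values > 1 + _RTA_TOL):
                raise ValueError(f"{label} outside [0, 1]")

    @property
    def grid(self) -> WavelengthGrid:
        return self.R.grid


@dataclass(frozen=True)
class CarotenoidLayerParams:
    """Carotenoid-pigmented barb layer.

    D is the pigment optical density (decadic, at the absorbance peak); s_c is
    the wavelength-flat fraction of light backscattered by the keratin matrix
    surrounding the pigment.  Backscattered light traverses the full pigment
    density once (down plus up through half depth each).
    """

    D: float = 1.0
    template: str = "lutein-like"
    s_c: float = 0.2

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("optical density D must be >= 0")
        if not 0 <= self.s_c <= 1:
            raise ValueError("backscatter fraction s_c must be in [0, 1]")


@dataclass(frozen=True)
class StructuralLayerParams:
    """Structurally colored barb layer: a Gaussian reflectance peak (FWHM
    parameterization) over an incoherent baseline, with flat internal
    absorptance a_s applied to the non-reflected light."""

    lambda0: float = 460.0
    Hpk: float = 0.35
    w: float = 100.0
    s_b: float = 0.05
    a_s: float = 0.1

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("FWHM w must be > 0")
        if self.Hpk + self.s_b > 1:
            raise ValueError("peak height + baseline exceeds 1")
        if not 0 <= self.a_s <= 1:
            raise ValueError("absorptance a_s must be in [0, 1]")


@dataclass(frozen=True)
class AchromaticLayerParams:
    """Achromatic (white/gray/black) layer: flat reflectance ``R_level`` and
    internal transmittance factor ``tau`` so that T = tau * (1 - R)."""

    R_level: float = 0.30
    tau: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.R_level <= 1:
            raise ValueError("R_level must be in [0, 1]")
        if not 0 <= self.tau <= 1:
            raise ValueError("tau must be in [0, 1]")


# White/black reflectances anchor to measured achromatic feather layers
# (~0.55 white, 0.05 black); gray is a documented midpoint convention.
ACHROMATIC_PRESETS: dict[str, AchromaticLayerParams] = {
    "white": AchromaticLayerParams(R_level=0.55, tau=0.4),
    "gray": AchromaticLayerParams(R_level=0.30, tau=0.1),
    "black": AchromaticLayerParams(R_level=0.05, tau=0.05),
}


@dataclass
class FeatherStack:
    """Ordered colorful + achromatic + downy layers on one grid; the downy
    layer is terminal (T identically 0)."""

    colorful: LayerOptics
    achromatic: LayerOptics
    downy: LayerOptics

    def __post_init__(self) -> None:
        if not (self.colorful.grid == self.achromatic.grid == self.downy.grid):
            raise ValueError("stack layers must share one wavelength grid")
        if np.any(self.downy.T.values != 0):
            raise ValueError("downy layer must be terminal (T identically 0)")

    @property
    def grid(self) -> WavelengthGrid:
        return self.colorful.grid


def carotenoid_absorbance(
    grid: WavelengthGrid = DEFAULT_GRID, template: str = "lutein-like"
) -> np.ndarray:
    """Unit-peak carotenoid absorbance shape g(lambda).

    The default is a generic lutein-like long-pass absorber: the sum of two
    Gaussians centered at 430 and 460 nm (sigma 30 nm), zero above 550 nm,
    normalized to unit peak.  A measured template can be substituted by
    registering it here.
    """
    if template != "lutein-like":
        raise ValueError(f"unknown carotenoid template {template!r}")
    wl = grid.wavelengths
    g = np.exp(-((wl - 430.0) ** 2) / (2 * 30.0**2)) + np.exp(
        -((wl - 460.0) ** 2) / (2 * 30.0**2)
    )
    g[wl > 550.0] = 0.0
    return g / g.max()


def _flat(grid: WavelengthGrid, value: float, name: str = "") -> Spectrum:
    return Spectrum(grid, np.full(grid.n, float(value)), name)


def make_carotenoid_layer(
    p: CarotenoidLayerParams, grid: WavelengthGrid = DEFAULT_GRID
) -> LayerOptics:
    """Carotenoid layer optics from Beer-Lambert attenuation.

    Internal transmittance t = 10^(-D * g); the backscattered fraction s_c and
    the forward fraction (1 - s_c) both traverse the pigment once:
    R = s_c * t, T = (1 - s_c) * t, A = 1 - R - T.
    """
    g = carotenoid_absorbance(grid, p.template)
    t = 10.0 ** (-p.D * g)
    R = p.s_c * t
    T = (1.0 - p.s_c) * t
    A = 1.0 - R - T
    return LayerOptics(Spectrum(grid, R, "R"), Spectrum(grid, T, "T"), Spectrum(grid, A, "A"))


def make_structural_layer(
    p: StructuralLayerParams, grid: WavelengthGrid = DEFAULT_GRID
) -> LayerOptics:
    """Structural layer: Gaussian reflectance peak (FWHM w) plus baseline s_b;
    absorptance a_s of the non-reflected light; T is the remainder."""
    wl = grid.wavelengths
    R = p.s_b + p.Hpk * np.exp(-4.0 * np.log(2.0) * (wl - p.lambda0) ** 2 / p.w**2)
    A = p.a_s * (1.0 - R)
    T = 1.0 - R - A
    return LayerOptics(Spectrum(grid, R, "R"), Spectrum(grid, T, "T"), Spectrum(grid, A, "A"))


def make_achromatic_layer(
    p: AchromaticLayerParams | str, grid: WavelengthGrid = DEFAULT_GRID
) -> LayerOptics:
    """Flat achromatic layer; ``p`` may be a preset name (white/gray/black)."""
    if isinstance(p, str):
        try:
            p = ACHROMATIC_PRESETS[p]
        except KeyError:
            raise ValueError(f"unknown achromatic preset {p!r}") from None
    R = float(p.R_level)
    T = p.tau * (1.0 - R)
    A = 1.0 - R - T
    return LayerOptics(_flat(grid, R, "R"), _flat(grid, T, "T"), _flat(grid, A, "A"))


def make_downy_layer(R_level: float = 0.30, grid: WavelengthGrid = DEFAULT_GRID) -> LayerOptics:
    """Terminal gray downy layer: flat reflector with no transmission."""
    return LayerOptics(
        _flat(grid, R_level, "R"), _flat(grid, 0.0, "T"), _flat(grid, 1.0 - R_level, "A")
    )


def build_stack(
    colorful_params: CarotenoidLayerParams | StructuralLayerParams,
    background: AchromaticLayerParams | str = "gray",
    downy_R: float = 0.30,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> FeatherStack:
    """Assemble a full stack from parameter objects (convenience)."""
    if isinstance(colorful_params, CarotenoidLayerParams):
        colorful = make_carotenoid_layer(colorful_params, grid)
    elif isinstance(colorful_params, StructuralLayerParams):
        colorful = make_structural_layer(colorful_params, grid)
    else:
        raise TypeError(f"unsupported colorful layer params: {type(colorful_params)}")
    return FeatherStack(colorful, make_achromatic_layer(background, grid), make_downy_layer(downy_R, grid))


def stack_reflectance(stack: FeatherStack) -> Spectrum:
    """Total patch reflectance by three-path summation, clamped to [0, 1]."""
    Rc, Tc = stack.colorful.R.values, stack.colorful.T.values
    Ra, Ta = stack.achromatic.R.values, stack.achromatic.T.values
    Rd = stack.downy.R.values
    Rtot = Rc + Tc**2 * Ra + Tc**2 * Ta**2 * Rd
    return Spectrum(stack.grid, np.clip(Rtot, 0.0, 1.0), "R_tot")


def fit_optical_density(
    observed: Spectrum,
    fixed: CarotenoidLayerParams,
    background: AchromaticLayerParams | str = "gray",
    downy_R: float = 0.30,
    bounds: tuple[float, float] = (0.0, 10.0),
) -> float:
    """Recover the pigment optical density D by bounded least squares.

    All stack parameters except D are held at ``fixed``; the residual is the
    sum of squared differences between the model patch reflectance and
    ``observed`` on its grid.
    """
    grid = observed.grid

    def sse(D: float) -> float:
        p = CarotenoidLayerParams(D=D, template=fixed.template, s_c=fixed.s_c)
        model = stack_reflectance(build_stack(p, background, downy_R, grid))
        r = model.values - observed.values
        val = float(r @ r)
        if not np.isfinite(val):
            raise ValueError("non-finite residual during optical-density fit")
        return val

    res = minimize_scalar(sse, bounds=bounds, method="bounded", options={"xatol": 1e-8})
    return float(res.x)
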