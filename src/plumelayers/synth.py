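"""Seeded synthetic-data generators.

These generators stand in for museum-specimen measurements: they produce
reflectance spectra of layered feather stacks on white/black/gray achromatic
backgrounds, stylized feather-on-background RGB images with an exact truth
mask, hyperspectral cubes with known region spectra, and paired
"female/male" dichromatism datasets in which the two groups share an
identical colorful layer and differ only in the hidden achromatic layer.

Every generator is a pure function of its arguments and seed.  Measurement
noise is multiplicative (spectrophotometer-like), iid Gaussian per
wavelength/pixel, with outputs clamped to [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imaging import HSLPixels, HyperspectralCube, hsl_to_rgb, polygon_mask
from .layers import (
    CarotenoidLayerParams,
    StructuralLayerParams,
    build_stack,
    stack_reflectance,
)
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid

__all__ = [
    "default_colorful_params",
    "gen_feather_spectrum",
    "gen_feather_image",
    "gen_hyperspectral_cube",
    "gen_dichromatism_dataset",
    "HI_GRID",
]

# Hyperspectral cubes use a coarser visible-range grid than point spectra,
# mirroring imager band spacing.
HI_GRID = WavelengthGrid(400.0, 700.0, 10.0)

# Default measurement noise: 2% multiplicative, typical of reflectance
# spectrophotometry repeatability.
DEFAULT_NOISE_SD = 0.02


def default_colorful_params(mechanism: str):
    """Default colorful-layer parameters per mechanism."""
    if mechanism == "carotenoid":
        return CarotenoidLayerParams()
    if mechanism == "structural":
        return StructuralLayerParams()
    raise ValueError(f"unknown mechanism {mechanism!r}")


def _apply_noise(values: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return values.copy()
    noisy = values * (1.0 + rng.normal(0.0, noise_sd, size=values.shape))
    return np.clip(noisy, 0.0, 1.0)


def gen_feather_spectrum(
    mechanism: str = "carotenoid",
    background: str = "gray",
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    params=None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> tuple[Spectrum, Spectrum]:
    """Simulated patch reflectance: returns (noisy, clean ground truth).

    The clean spectrum is the deterministic three-path stack output; noise is
    multiplicative Gaussian per wavelength.
    """
    if params is None:
        params = default_colorful_params(mechanism)
    clean = stack_reflectance(build_stack(params, background, grid=grid))
    rng = np.random.default_rng(seed)
    noisy = Spectrum(grid, _apply_noise(clean.values, noise_sd, rng), f"{mechanism}_{background}")
    return noisy, clean


def gen_feather_image(
    background: str = "white",
    feather_hsl: tuple[float, float, float] = (30.0, 70.0, 40.0),
    feather_fraction: float = 0.3,
    size: tuple[int, int] = (96, 96),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stylized feather-on-background RGB image plus exact truth mask.

    Feather pixels are rasterized as random thick barb-like strokes of the
    target HSL color (small seeded lightness jitter); the background is
    achromatic with per-pixel lightness jitter (white ~80-95%, black ~2-8%).
    The truth-mask pixel count matches ``feather_fraction`` exactly (to the
    nearest pixel).
    """
    if not 0 < feather_fraction < 1:
        raise ValueError("feather_fraction must be in (0, 1)")
    if background not in ("white", "black"):
        raise ValueError(f"background must be 'white' or 'black', got {background!r}")
    h, w = size
    rng = np.random.default_rng(seed)
    target = int(round(feather_fraction * h * w))
    target = max(1, target)
    mask = np.zeros((h, w), dtype=bool)
    # stamp random thick strokes until enough pixels accumulate
    while mask.sum() < target:
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.3, 0.9) * min(h, w)
        half_t = rng.integers(1, 3)
        tvals = np.linspace(-length / 2, length / 2, int(length * 2))
        rr = np.clip((r0 + tvals * np.sin(ang)).round().astype(int), 0, h - 1)
        cc = np.clip((c0 + tvals * np.cos(ang)).round().astype(int), 0, w - 1)
        before = mask.copy()
        for dr in range(-half_t, half_t + 1):
            for dc in range(-half_t, half_t + 1):
                mask[np.clip(rr + dr, 0, h - 1), np.clip(cc + dc, 0, w - 1)] = True
        excess = int(mask.sum()) - target
        if excess > 0:
            added = np.argwhere(mask & ~before)
            drop = added[rng.permutation(added.shape[0])[:excess]]
            mask[drop[:, 0], drop[:, 1]] = False
    # background lightness jitter keeps white above 60% and black below 10%
    if background == "white":
        bg_l = rng.uniform(80.0, 95.0, size=(h, w))
    else:
        bg_l = rng.uniform(2.0, 8.0, size=(h, w))
    fh, fs, fl = feather_hsl
    if not 10.0 < fl < 60.0:
        raise ValueError("feather lightness must lie strictly between the 10%/60% rules")
    jitter = rng.uniform(-2.0, 2.0, size=(h, w))
    feather_l = np.clip(fl + jitter, 11.0, 59.0)
    H = np.where(mask, fh, 0.0)
    S = np.where(mask, fs, 0.0)
    L = np.where(mask, feather_l, bg_l)
    img = hsl_to_rgb(HSLPixels(H, S, L))
    return img, mask


def gen_hyperspectral_cube(
    regions: list[tuple[np.ndarray, Spectrum]],
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    shape: tuple[int, int] = (80, 80),
    background_level: float = 0.5,
) -> tuple[HyperspectralCube, list[np.ndarray]]:
    """Hyperspectral cube with known region spectra; returns (cube, truth masks).

    Each region is a (polygon, Spectrum) pair; region pixels get the region
    spectrum under multiplicative noise, the rest a flat background.
    Overlapping polygons are rejected.
    """
    if not regions:
        raise ValueError("need at least one region")
    grid = regions[0][1].grid
    for _, spec in regions:
        if spec.grid != grid:
            raise ValueError("all region spectra must share one grid")
    h, w = shape
    bands = grid.n
    rng = np.random.default_rng(seed)
    pixels = np.full((h, w, bands), float(background_level))
    claimed = np.zeros((h, w), dtype=bool)
    masks = []
    for poly, spec in regions:
        m = polygon_mask(np.asarray(poly, dtype=float), shape)
        if (m & claimed).any():
            raise ValueError("overlapping region polygons")
        claimed |= m
        idx = np.argwhere(m)
        vals = np.tile(spec.values, (idx.shape[0], 1))
        pixels[idx[:, 0], idx[:, 1], :] = _apply_noise(vals, noise_sd, rng)
        masks.append(m)
    return HyperspectralCube(pixels, grid.wavelengths), masks


def gen_dichromatism_dataset(
    shared_colorful_params=None,
    sexA_background: str = "white",
    sexB_background: str = "black",
    n: int = 3,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> pd.DataFrame:
    """Replicate spectra for two sexes sharing one colorful layer but differing
    in achromatic background (the plumage-dichromatism design).

    Returns a tidy long table with columns sex, replicate, background, wl,
    reflectance; the seed is recorded in ``DataFrame.attrs``.
    """
    if n < 1:
        raise ValueError("need n >= 1 replicates")
    if shared_colorful_params is None:
        shared_colorful_params = CarotenoidLayerParams()
    rows = []
    for sex_idx, (sex, bg) in enumerate((("A", sexA_background), ("B", sexB_background))):
        for rep in range(n):
            rep_seed = (seed * 1_000_003 + sex_idx * 10_007 + rep) % (2**31)
            noisy, _ = gen_feather_spectrum(
                background=bg, noise_sd=noise_sd, seed=rep_seed,
                params=shared_colorful_params, grid=grid,
            )
            rows.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "replicate": rep,
                        "background": bg,
                        "wl": grid.wavelengths,
                        "reflectance": noisy.values,
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["seed"] = seed
    return out
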