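"""Image-side color extraction.

Covers the photographic half of the pipeline: cylindrical HSL conversion of
calibrated RGB images, threshold masking of white/black photographic
backgrounds (background rules such as "lightness above 60%" / "below 10%"),
summary statistics of the retained feather pixels, and seeded random sampling
of hyperspectral regions of interest with 3x3 median filtering.

Pixel coordinates are 0-based, row-major ``(row, col)``; ROI polygons are
half-open on the right/bottom edge (a pixel belongs to the ROI iff its center
``(row + 0.5, col + 0.5)`` lies inside the polygon).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "HSLPixels",
    "HSLSummary",
    "HyperspectralCube",
    "ROISampleSet",
    "rgb_to_hsl",
    "hsl_to_rgb",
    "hsl_threshold_mask",
    "BACKGROUND_RULES",
    "summarize_hsl",
    "polygon_mask",
    "sample_roi_median",
    "read_cube",
    "write_cube",
]


@dataclass
class HSLPixels:
    """Per-pixel cylindrical HSL: hue in degrees [0, 360), saturation and
    lightness in percent [0, 100].  Hue is 0 wherever saturation is 0."""

    H: np.ndarray
    S: np.ndarray
    L: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.H.shape


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return np.clip(img, 0.0, 1.0)


def rgb_to_hsl(img: np.ndarray) -> HSLPixels:
    """Standard cylindrical HSL conversion of an (H, W, 3) image in [0, 1]."""
    img = _check_rgb(img)
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    cmax = img.max(axis=2)
    cmin = img.min(axis=2)
    delta = cmax - cmin
    L = (cmax + cmin) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(delta == 0, 0.0, delta / (1.0 - np.abs(2.0 * L - 1.0)))
        hr = np.where(delta == 0, 0.0, ((g - b) / delta) % 6.0)
        hg = np.where(delta == 0, 0.0, (b - r) / delta + 2.0)
        hb = np.where(delta == 0, 0.0, (r - g) / delta + 4.0)
    H = np.where(cmax == r, hr, np.where(cmax == g, hg, hb)) * 60.0
    H = np.where(delta == 0, 0.0, H % 360.0)
    return HSLPixels(H, np.clip(S, 0, 1) * 100.0, L * 100.0)


def hsl_to_rgb(px: HSLPixels) -> np.ndarray:
    """Inverse cylindrical HSL conversion (exact round trip where S > 0)."""
    H = np.asarray(px.H, dtype=float) % 360.0
    S = np.asarray(px.S, dtype=float) / 100.0
    L = np.asarray(px.L, dtype=float) / 100.0
    c = (1.0 - np.abs(2.0 * L - 1.0)) * S
    hp = H / 60.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    zeros = np.zeros_like(c)
    conds = [hp < 1, hp < 2, hp < 3, hp < 4, hp < 5, hp >= 5]
    r1 = np.select(conds, [c, x, zeros, zeros, x, c])
    g1 = np.select(conds, [x, c, c, x, zeros, zeros])
    b1 = np.select(conds, [zeros, zeros, x, c, c, x])
    m = L - c / 2.0
    return np.clip(np.stack([r1 + m, g1 + m, b1 + m], axis=-1), 0.0, 1.0)


# Background lightness rules for the two photographic standards: white squares
# read above 60% lightness, black squares below 10%.
BACKGROUND_RULES = {
    "white": [{"l_min": 60.0}],
    "black": [{"l_max": 10.0}],
}


def hsl_threshold_mask(px: HSLPixels, rules: list[dict]) -> np.ndarray:
    """Boolean mask, True where a pixel matches ANY background rule.

    Each rule is a dict with optional keys ``h_min/h_max``, ``s_min/s_max``,
    ``l_min/l_max``; bounds are strict (``l_min=60`` means L > 60).  The
    retained (feather) pixels are the complement of the returned mask.
    """
    mask = np.zeros(px.shape, dtype=bool)
    channels = {"h": px.H, "s": px.S, "l": px.L}
    for rule in rules:
        hit = np.ones(px.shape, dtype=bool)
        for key, bound in rule.items():
            ch, kind = key.rsplit("_", 1)
            if ch not in channels or kind not in ("min", "max"):
                raise ValueError(f"malformed rule key {key!r}")
            hit &= channels[ch] > bound if kind == "min" else channels[ch] < bound
        mask |= hit
    return mask


@dataclass(frozen=True)
class HSLSummary:
    """Summary of retained pixels: mean lightness and saturation, hue as both
    a circular mean and a plain arithmetic mean, and a lightness density
    histogram (counts normalized to unit area)."""

    mean_l: float
    mean_s: float
    mean_hue_circular: float
    mean_hue_arithmetic: float
    n_pixels: int
    l_hist_density: np.ndarray
    l_hist_edges: np.ndarray


def summarize_hsl(px: HSLPixels, retained: np.ndarray | None = None, bins: int = 50) -> HSLSummary:
    """Summarize HSL values over retained (non-background) pixels."""
    if retained is None:
        retained = np.ones(px.shape, dtype=bool)
    if not retained.any():
        raise ValueError("all pixels masked: empty summary")
    H, S, L = px.H[retained], px.S[retained], px.L[retained]
    rad = np.deg2rad(H)
    circ = np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0
    dens, edges = np.histogram(L, bins=bins, range=(0.0, 100.0), density=True)
    return HSLSummary(
        mean_l=float(L.mean()),
        mean_s=float(S.mean()),
        mean_hue_circular=float(circ),
        mean_hue_arithmetic=float(H.mean()),
        n_pixels=int(retained.sum()),
        l_hist_density=dens,
        l_hist_edges=edges,
    )


@dataclass
class HyperspectralCube:
    """Pixel reflectances (H, W, bands) with ascending band-center wavelengths."""

    pixels: np.ndarray
    band_centers: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("cube must be (H, W, bands)")
        if self.band_centers.size != self.pixels.shape[2]:
            raise ValueError("band_centers length must match band count")
        if self.band_centers.size < 2 or np.any(np.diff(self.band_centers) <= 0):
            raise ValueError("need >= 2 strictly ascending band centers")


@dataclass
class ROISampleSet:
    """Seeded ROI samples: n pixel locations (row, col) and the per-band 3x3
    median spectrum at each, plus their mean."""

    polygon: np.ndarray
    n: int
    seed: int
    locations: np.ndarray  # (n, 2) int
    samples: np.ndarray  # (n, bands)
    mean_spectrum: np.ndarray  # (bands,)


def polygon_mask(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon given as (row, col) vertices into a boolean mask.

    Even-odd rule on pixel centers (row + 0.5, col + 0.5), so integer-vertex
    rectangles are half-open on the right/bottom edge.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must be (k >= 3, 2) vertices")
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    py, px_ = rows + 0.5, cols + 0.5
    inside = np.zeros(shape, dtype=bool)
    k = poly.shape[0]
    for i in range(k):
        r1, c1 = poly[i]
        r2, c2 = poly[(i + 1) % k]
        crosses = (r1 <= py) != (r2 <= py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = c1 + (py - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (px_ < x_int)
    return inside


def sample_roi_median(
    cube: HyperspectralCube,
    roi: np.ndarray,
    n: int = 500,
    seed: int = 0,
) -> ROISampleSet:
    """Draw n seeded sample locations uniformly with replacement from the ROI
    and extract the per-band median of each 3x3 pixel neighborhood.

    Pixels whose 3x3 window leaves the image are ineligible.
    """
    h, w, _ = cube.pixels.shape
    mask = polygon_mask(roi, (h, w))
    interior = np.zeros_like(mask)
    interior[1 : h - 1, 1 : w - 1] = mask[1 : h - 1, 1 : w - 1]
    eligible = np.argwhere(interior)
    if eligible.shape[0] == 0:
        raise ValueError("ROI contains no pixel with a complete 3x3 neighborhood")
    rng = np.random.default_rng(seed)
    locs = eligible[rng.integers(0, eligible.shape[0], size=n)]
    blocks = np.stack(
        [cube.pixels[locs[:, 0] + dr, locs[:, 1] + dc, :] for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
    )  # (9, n, bands)
    samples = np.median(blocks, axis=0)
    return ROISampleSet(
        polygon=np.asarray(roi, dtype=float),
        n=n,
        seed=seed,
        locations=locs,
        samples=samples,
        mean_spectrum=samples.mean(axis=0),
    )


def write_cube(path: str | Path, cube: HyperspectralCube) -> None:
    """Write a cube as a multi-band TIFF (bands-first pages) plus a JSON
    sidecar ``<path>.json`` with {"band_centers_nm": [...]}."""
    path = Path(path)
    tifffile.imwrite(path, np.moveaxis(cube.pixels, 2, 0).astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"band_centers_nm": cube.band_centers.tolist()}))


def read_cube(path: str | Path) -> HyperspectralCube:
    path = Path(path)
    pixels = np.moveaxis(tifffile.imread(path).astype(float), 0, 2)
    sidecar = path.with_suffix(path.suffix + ".json")
    centers = json.loads(sidecar.read_text())["band_centers_nm"]
    return HyperspectralCube(pixels, np.asarray(centers, dtype=float))
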