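"""Reflectance spectra: representation, I/O, smoothing, and colorimetric summaries.

A :class:`Spectrum` is reflectance (or transmittance/absorptance) as a function
of wavelength on a uniform nanometre grid, the common currency of the whole
pipeline.  Internally all values are fractions (0-1); spectra CSV files on disk
use the field's percent convention (0-100) unless stated otherwise.

The three colorimetric summaries are the classic segment statistics used for
bird plumage: brightness B2 (mean reflectance), saturation S8
((max - min)/mean), and hue H1 (wavelength of peak reflectance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "ColorMetrics",
    "DEFAULT_GRID",
    "read_spectra",
    "write_spectra",
    "resample",
    "smooth",
    "brightness_B2",
    "saturation_S8",
    "hue_H1",
    "color_metrics",
]


class SpectraFormatError(ValueError):
    """Raised for malformed spectra files or incompatible grids."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres, endpoints inclusive."""

    start: float = 300.0
    stop: float = 700.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be > 0, got {self.step}")
        if self.stop <= self.start:
            raise ValueError(f"stop must exceed start ({self.start}..{self.stop})")
        n_span = (self.stop - self.start) / self.step
        if abs(n_span - round(n_span)) > 1e-9:
            raise ValueError(
                f"(stop - start) = {self.stop - self.start} not divisible by step {self.step}"
            )

    @property
    def n(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n)


DEFAULT_GRID = WavelengthGrid(300.0, 700.0, 1.0)


@dataclass
class Spectrum:
    """Per-wavelength values on a :class:`WavelengthGrid`.

    Values are unitless fractions.  Raw measured reflectances may exceed 1
    (e.g. glossy standards); they are accepted here and only clamped where a
    physical layer model requires it.
    """

    grid: WavelengthGrid
    values: np.ndarray
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n,):
            raise ValueError(
                f"values length {self.values.shape} does not match grid size {self.grid.n}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("spectrum contains negative values")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def with_values(self, values: np.ndarray, name: str | None = None) -> "Spectrum":
        return Spectrum(self.grid, values, self.name if name is None else name)


@dataclass(frozen=True)
class ColorMetrics:
    """Brightness (B2, mean reflectance), saturation (S8, (max-min)/mean),
    hue (H1, wavelength of peak reflectance, nm)."""

    brightness: float
    saturation: float
    hue: float


def _infer_grid(wl: np.ndarray) -> WavelengthGrid:
    if wl.size < 2:
        raise SpectraFormatError("need at least two wavelength rows")
    steps = np.diff(wl)
    if np.any(steps <= 0):
        raise SpectraFormatError("wavelengths must be strictly ascending")
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise SpectraFormatError(f"non-uniform wavelength grid (steps {sorted(set(steps))})")
    return WavelengthGrid(float(wl[0]), float(wl[-1]), float(steps[0]))


def read_spectra(path: str | Path, unit: str = "percent") -> list[Spectrum]:
    """Read a spectra CSV (first column ``wl`` in nm, one column per sample).

    ``unit='percent'`` divides values by 100 on read (the on-disk dialect);
    ``unit='fraction'`` takes values as-is.
    """
    if unit not in ("percent", "fraction"):
        raise ValueError(f"unit must be 'percent' or 'fraction', got {unit!r}")
    df = pd.read_csv(path)
    if df.columns[0] != "wl":
        raise SpectraFormatError(f"first column must be 'wl', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise SpectraFormatError("no sample columns")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SpectraFormatError(f"non-numeric cell at row {row + 2}, column {col!r}")
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna().to_numpy())[0])
            raise SpectraFormatError(f"missing cell at row {row + 2}, column {col!r}")
    grid = _infer_grid(df["wl"].to_numpy(dtype=float))
    scale = 0.01 if unit == "percent" else 1.0
    return [
        Spectrum(grid, df[col].to_numpy(dtype=float) * scale, name=str(col))
        for col in df.columns[1:]
    ]


def write_spectra(path: str | Path, spectra: list[Spectrum], unit: str = "percent") -> None:
    """Write spectra sharing a grid to CSV in the dialect ``read_spectra`` reads."""
    if not spectra:
        raise ValueError("nothing to write")
    grid = spectra[0].grid
    for s in spectra:
        if s.grid != grid:
            raise SpectraFormatError("all spectra must share one grid")
    scale = 100.0 if unit == "percent" else 1.0
    data = {"wl": grid.wavelengths}
    for i, s in enumerate(spectra):
        data[s.name or f"spec{i + 1}"] = s.values * scale
    pd.DataFrame(data).to_csv(path, index=False)


def resample(spec: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linear interpolation onto ``target``; no extrapolation allowed."""
    src = spec.grid
    if target.start < src.start - 1e-9 or target.stop > src.stop + 1e-9:
        raise ValueError(
            f"target grid {target.start}-{target.stop} outside source {src.start}-{src.stop}"
        )
    if target == src:
        return Spectrum(target, spec.values.copy(), spec.name)
    vals = np.interp(target.wavelengths, src.wavelengths, spec.values)
    return Spectrum(target, vals, spec.name)


def smooth(spec: Spectrum, span: float = 0.3) -> Spectrum:
    """LOESS smoothing: local quadratic fits with tricube weights.

    ``span`` is the fraction of grid nodes in each local window (default 0.3,
    the convention for plumage spectra).  Constants and straight lines are
    reproduced; high-frequency measurement noise is attenuated.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = spec.grid.n
    if n < 10:
        raise ValueError("grid too small to smooth (need >= 10 nodes)")
    k = max(5, int(round(span * n)))
    k = min(k, n)
    x = spec.wavelengths
    y = spec.values
    out = np.empty(n)
    half = k // 2
    for i in range(n):
        lo = max(0, min(i - half, n - k))
        idx = slice(lo, lo + k)
        xi = x[idx] - x[i]
        d = np.abs(xi)
        dmax = d.max()
        w = (1 - (d / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d)
        # weighted quadratic fit evaluated at the centre (xi = 0)
        X = np.column_stack([np.ones_like(xi), xi, xi**2])
        Xw = X * w[:, None]
        beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y[idx], rcond=None)
        out[i] = beta[0]
    return spec.with_values(np.clip(out, 0.0, None))


def brightness_B2(spec: Spectrum) -> float:
    """Mean reflectance over the measured range (B2)."""
    return float(np.mean(spec.values))


def saturation_S8(spec: Spectrum) -> float:
    """(max - min) / mean reflectance (S8)."""
    b = brightness_B2(spec)
    if b <= 0:
        raise ValueError("saturation undefined for zero-brightness spectrum")
    return float((spec.values.max() - spec.values.min()) / b)


def hue_H1(spec: Spectrum) -> float:
    """Wavelength of maximum reflectance (H1); ties break to the shortest wavelength."""
    return float(spec.wavelengths[int(np.argmax(spec.values))])


def color_metrics(spec: Spectrum) -> ColorMetrics:
    return ColorMetrics(brightness_B2(spec), saturation_S8(spec), hue_H1(spec))
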