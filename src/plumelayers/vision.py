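"""Tetrachromat avian visual modeling.

Builds a violet-sensitive passerine-style visual system (four single cones
plus a double cone) from A1 visual-pigment templates, computes quantum
catches, maps relative catches into the avian tetrahedral color space
(achromatic center at the origin, vertices at circumradius 0.75), and
evaluates receptor-noise-limited chromatic (dS) and luminance (dL) distances
in just-noticeable-difference units.

Conventions: the illuminant is ideal (constant 1) so quantum catches are in
reflectance units; dS/dL use *raw* catches with natural-log contrasts, while
the tetrahedral mapping uses *relative* catches — mirroring how plumage
dichromatism is normally scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid

__all__ = [
    "VisualSystem",
    "QuantumCatches",
    "TetraPoint",
    "ContrastResult",
    "pigment_template_a1",
    "ocular_media_transmission",
    "build_visual_system",
    "quantum_catch",
    "tetra_point",
    "delta_S",
    "delta_L",
    "noise_weighted_distance",
]

CHANNELS = ("u", "s", "m", "l")

# Blue-tit-style violet/UV-sensitive defaults: lambda-max per single cone,
# cone abundance ratios, Weber fraction on the most abundant cone.
DEFAULT_LAMBDA_MAX = (371.0, 448.0, 503.0, 563.0)
DEFAULT_ABUNDANCES = (1.0, 2.0, 2.0, 4.0)
DEFAULT_WEBER = 0.1
DEFAULT_E_DOUBLE = 0.1


def pigment_template_a1(lambda_max: float, grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """Govardovskii A1 visual-pigment absorbance template (alpha + beta bands),
    normalized to unit peak on the grid."""
    wl = grid.wavelengths
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lm_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lm_beta) / b_beta) ** 2))
    s = alpha + beta
    return s / s.max()


def ocular_media_transmission(grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """Long-pass transmission of the avian ocular media (cornea, lens, humors):
    logistic with 50% transmission at 325 nm, scale 12 nm."""
    return 1.0 / (1.0 + np.exp(-(grid.wavelengths - 325.0) / 12.0))


@dataclass
class VisualSystem:
    """Four single-cone sensitivities (unit integral each), a double-cone
    sensitivity, per-channel Weber-derived noise values, and an illuminant."""

    S: np.ndarray  # (4, n) single-cone sensitivities
    S_D: np.ndarray  # (n,) double-cone sensitivity
    abundances: np.ndarray
    e: np.ndarray  # (4,) per-channel noise
    e_D: float
    illuminant: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        dl = self.grid.step
        integrals = self.S.sum(axis=1) * dl
        if np.max(np.abs(integrals - 1.0)) > 1e-9:
            raise ValueError("cone sensitivities must integrate to 1")
        if np.any(self.e <= 0) or self.e_D <= 0:
            raise ValueError("noise values must be positive")


@dataclass(frozen=True)
class QuantumCatches:
    """Raw catches Q per single cone, raw double-cone catch Q_D, and (when
    requested) relative catches u summing to 1."""

    Q: np.ndarray
    Q_D: float
    u: np.ndarray | None = None


@dataclass(frozen=True)
class TetraPoint:
    """A stimulus in tetrahedral color space: coordinates, chroma (distance
    from the achromatic origin, max 0.75) and double-cone luminance."""

    x: float
    y: float
    z: float
    chroma: float
    luminance: float


@dataclass(frozen=True)
class ContrastResult:
    """Receptor-noise-limited contrast between two stimuli (JND units)."""

    delta_f: np.ndarray
    dS: float
    dL: float


def build_visual_system(
    lambda_max: tuple[float, float, float, float] = DEFAULT_LAMBDA_MAX,
    abundances: tuple[float, ...] = DEFAULT_ABUNDANCES,
    weber_ref: float = DEFAULT_WEBER,
    e_D: float = DEFAULT_E_DOUBLE,
    grid: WavelengthGrid = DEFAULT_GRID,
    ocular_media: bool = True,
    double_cone_lambda_max: float | None = None,
    illuminant: Spectrum | None = None,
) -> VisualSystem:
    """Assemble a :class:`VisualSystem` from pigment peak wavelengths.

    Noise per channel follows the standard abundance scaling
    ``e_i = weber_ref * sqrt(n_ref / n_i)`` with ``n_ref`` the largest cone
    abundance.  The double cone uses the long-wavelength pigment (plus ocular
    media) unless a peak is given explicitly.
    """
    lm = np.asarray(lambda_max, dtype=float)
    if lm.shape != (4,) or np.any(np.diff(lm) <= 0):
        raise ValueError("lambda_max must be four strictly increasing wavelengths")
    wl = grid.wavelengths
    if np.any(lm < wl[0]) or np.any(lm > wl[-1]):
        raise ValueError("lambda_max outside wavelength grid")
    om = ocular_media_transmission(grid) if ocular_media else np.ones(grid.n)
    dl = grid.step

    def sensitivity(peak: float) -> np.ndarray:
        s = pigment_template_a1(peak, grid) * om
        return s / (s.sum() * dl)

    S = np.stack([sensitivity(p) for p in lm])
    S_D = sensitivity(double_cone_lambda_max if double_cone_lambda_max is not None else lm[3])
    n = np.asarray(abundances, dtype=float)
    if n.shape != (4,) or np.any(n <= 0):
        raise ValueError("need four positive cone abundances")
    e = weber_ref * np.sqrt(n.max() / n)
    illum = illuminant.values if illuminant is not None else np.ones(grid.n)
    return VisualSystem(S, S_D, n, e, float(e_D), illum, grid)


def quantum_catch(spec: Spectrum, vs: VisualSystem, mode: str = "raw") -> QuantumCatches:
    """Quantum catches Q_i = sum_lambda R * I * S_i * dlambda (plus double cone).

    ``mode='relative'`` additionally returns u_i = Q_i / sum(Q)."""
    if spec.grid != vs.grid:
        raise ValueError("spectrum and visual system must share one grid")
    if mode not in ("raw", "relative"):
        raise ValueError(f"mode must be 'raw' or 'relative', got {mode!r}")
    dl = vs.grid.step
    weighted = spec.values * vs.illuminant
    Q = vs.S @ weighted * dl
    Q_D = float(vs.S_D @ weighted * dl)
    if mode == "relative":
        total = Q.sum()
        if total <= 0:
            raise ValueError("degenerate stimulus: zero total quantum catch")
        return QuantumCatches(Q, Q_D, Q / total)
    return QuantumCatches(Q, Q_D)


# Regular tetrahedron, circumradius 0.75, centroid at the origin.  The u
# vertex points up the z axis; s, m, l sit on the circle z = -0.25 at
# 90, 210, 330 degrees (fixed orientation).
def _tetra_vertices() -> np.ndarray:
    r = 0.75
    z_low = -r / 3.0
    rho = r * np.sqrt(8.0) / 3.0
    ang = np.deg2rad([90.0, 210.0, 330.0])
    verts = [(0.0, 0.0, r)] + [(rho * np.cos(a), rho * np.sin(a), z_low) for a in ang]
    return np.array(verts)


TETRA_VERTICES = _tetra_vertices()


def tetra_point(qc: QuantumCatches) -> TetraPoint:
    """Map relative catches to the tetrahedral color space; chroma is the
    Euclidean distance from the achromatic origin."""
    if qc.u is None:
        total = qc.Q.sum()
        if total <= 0:
            raise ValueError("degenerate stimulus: zero total quantum catch")
        u = qc.Q / total
    else:
        u = qc.u
    p = u @ TETRA_VERTICES
    return TetraPoint(float(p[0]), float(p[1]), float(p[2]), float(np.linalg.norm(p)), qc.Q_D)


def noise_weighted_distance(delta_f: np.ndarray, e: np.ndarray) -> float:
    """General n-channel receptor-noise-limited distance.

    dS^2 = [sum over channel pairs (i<j) of (prod of e_k^2 for k not in
    {i,j}) * (df_i - df_j)^2] / [sum over (n-1)-channel subsets of the
    product of their e^2].  For n=2 this is |df1 - df2| / sqrt(e1^2 + e2^2);
    for n=4 it is the standard tetrachromat form.
    """
    delta_f = np.asarray(delta_f, dtype=float)
    e2 = np.asarray(e, dtype=float) ** 2
    n = delta_f.size
    if e2.size != n:
        raise ValueError("delta_f and e must have equal length")
    num = 0.0
    for i, j in combinations(range(n), 2):
        others = [k for k in range(n) if k not in (i, j)]
        num += np.prod(e2[others]) * (delta_f[i] - delta_f[j]) ** 2
    den = 0.0
    for subset in combinations(range(n), n - 1):
        den += np.prod(e2[list(subset)])
    return float(np.sqrt(num / den))


def _log_contrasts(specA: Spectrum, specB: Spectrum, vs: VisualSystem) -> np.ndarray:
    qa = quantum_catch(specA, vs, "raw").Q
    qb = quantum_catch(specB, vs, "raw").Q
    for name, q in zip(CHANNELS, np.minimum(qa, qb)):
        if q <= 0:
            raise ValueError(f"non-positive quantum catch in channel {name!r}")
    return np.log(qa / qb)


def delta_S(specA: Spectrum, specB: Spectrum, vs: VisualSystem) -> ContrastResult:
    """Chromatic receptor-noise-limited distance dS (JND)."""
    df = _log_contrasts(specA, specB, vs)
    return ContrastResult(df, noise_weighted_distance(df, vs.e), 0.0)


def delta_L(specA: Spectrum, specB: Spectrum, vs: VisualSystem) -> ContrastResult:
    """Luminance (double cone) receptor-noise-limited distance dL (JND)."""
    qa = quantum_catch(specA, vs, "raw").Q_D
    qb = quantum_catch(specB, vs, "raw").Q_D
    if qa <= 0 or qb <= 0:
        raise ValueError("non-positive double-cone quantum catch")
    dL = abs(np.log(qa / qb)) / vs.e_D
    return ContrastResult(np.zeros(4), 0.0, float(dL))
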