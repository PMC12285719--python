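# Methods

## The model

Body (contour) feathers overlap on a bird so that only the colorful tip of
each feather is exposed; the white or black *achromatic region* of the
feathers beneath forms a hidden, continuous layer behind every colorful
patch, with the gray downy feather bases behind that. `plumelayers` models a
plumage patch as this three-layer stack and asks how the hidden achromatic
layer changes the color an observer (avian or human) sees.

Each layer is summarized per wavelength (300–700 nm, 1 nm grid) by a
reflectance/transmittance/absorptance triple with `R + T + A = 1`. Total
patch reflectance is the sum of three single-bounce light paths —

```
R_tot(λ) = R_c + T_c² · R_a + T_c² · T_a² · R_d
```

direct reflection from the colorful layer (`c`), reflection from the
achromatic layer (`a`) seen through the colorful layer, and reflection from
the terminal downy layer (`d`) seen through both. Higher-order
interreflections are deliberately omitted: the three-path sum captures the
mechanism of interest (the hidden layer acting as a back-reflector) and
keeps every term physically interpretable. `R_tot` is clamped to [0, 1] as a
guard against pathological parameter sets; with the defaults the clamp is
never active.

### Colorful layers

**Carotenoid-pigmented barbs.** Diet-derived carotenoids color feathers by
selective absorption; the color only becomes visible through light scattered
back by the surrounding keratin. The layer is parameterized by a decadic
pigment optical density `D` and a wavelength-flat keratin backscatter
fraction `s_c`. With `ĝ(λ)` the unit-peak pigment absorbance shape, internal
transmittance is Beer–Lambert, `t(λ) = 10^(−D·ĝ(λ))`, and

```
R = s_c · t,   T = (1 − s_c) · t,   A = 1 − R − T.
```

Backscattered light is modeled as traversing one full optical density (half
the depth down, half back up), the simplest convention that keeps `D`
interpretable as the density a transmission measurement would report. The
default absorbance template is a generic lutein-like long-pass absorber: the
sum of two Gaussians at 430 and 460 nm (σ = 30 nm), set to zero above
550 nm and normalized to unit peak. Because the template vanishes at long
wavelengths, the modeled spectrum has a flat plateau above 550 nm whose
height — not position — responds to the background; hue (H1, with ties
broken to the shortest wavelength) is therefore background-invariant by
construction, matching the known behavior of carotenoid colors. A measured
absorbance template can replace the default without touching any other code.
Defaults: `D = 1.0`, `s_c = 0.2` (a visibly pigmented but translucent barb
layer; single-feather transmission in this regime is a few tens of percent).

**Structurally colored barbs.** Noniridescent structural color from spongy
keratin nanostructure is modeled phenomenologically as a Gaussian
reflectance peak over an incoherent baseline:

```
R(λ) = s_b + Hpk · exp(−4 ln2 (λ − λ0)² / w²),
A = a_s · (1 − R),   T = 1 − R − A.
```

`λ0` is the peak (hue) wavelength, `Hpk` the coherent peak height, `w` the
FWHM (narrow peak = saturated color), `s_b` incoherent baseline scatter, and
`a_s` a flat internal absorptance applied to non-reflected light. Defaults:
`λ0 = 460 nm`, `Hpk = 0.35`, `w = 100 nm`, `s_b = 0.05`, `a_s = 0.1` — a
typical blue barb with modest internal losses. No physical optics
(Fourier/FDTD) and no angular dependence are attempted; the sweep analyses
only rely on the peak-plus-baseline shape.

**Achromatic and downy layers.** Flat reflectors with `T = τ(1 − R)`.
Presets anchor to measured feather layers: white `R = 0.55`, black
`R = 0.05`; gray `R = 0.30` is a midpoint convention. Transmittance factors
`τ` = 0.4 (white), 0.1 (gray), 0.05 (black) encode that white feather
regions pass much more light than black ones; the literature reports the
ordering but not values, so these are documented package defaults. The downy
layer is a terminal opaque gray reflector (`R = 0.30`, `T ≡ 0`); the skin
and body behind it are not modeled.

## Colorimetry

Spectral summaries are the classic plumage segment statistics: brightness
B2 = mean reflectance over the grid (plain node mean; the grid is uniform so
this differs from trapezoid integration only at the endpoints), saturation
S8 = (max − min)/mean, hue H1 = wavelength of maximum reflectance with ties
to the shortest wavelength. Smoothing is LOESS — tricube weights, local
quadratic, window = span × node count with span 0.3 by default — which
reproduces constants and straight lines exactly (to numerical precision) and
attenuates measurement noise.

### Enhancement magnitude in sweeps

Sweep tables report both the absolute metric difference against the black
preset (`delta_*_vs_black`) and the proportional difference
(`rel_delta_*_vs_black`, relative to the black-preset value). For the
structural mechanism the *proportional* saturation enhancement,
`(S8_black − S8_white)/S8_black`, is the package's measure of how strongly
the dark backing drives saturation: it is the fraction of the
black-background saturation that the layer cannot sustain on white. The
absolute difference is not a useful effect-size measure across peak heights
because both backgrounds converge to the same (unsaturated) spectrum as
`Hpk → 0`, forcing the absolute delta through zero regardless of how
completely the backing controls the color there; the proportional measure
instead approaches 1 in that limit — the backing accounts for essentially
all of the saturation — and declines as the nanostructure's own reflectance
takes over, which is the behavior the sweep analyses assert.

## Avian visual model

Four single cones (u, s, m, l) built from the Govardovskii A1 visual-pigment
nomogram (α and β bands) at λmax = 371, 448, 503, 563 nm — a violet-type
passerine tuning — multiplied by a logistic long-pass ocular-media
transmission (50 % at 325 nm, scale 12 nm) and normalized to unit integral.
The double cone uses the l-cone pigment. Cone abundances 1:2:2:4 give
channel noise `e_i = w·√(n_l/n_i)` with Weber fraction `w = 0.1` on the most
abundant cone; double-cone noise `e_D = 0.1`. All of these are
literature-convention defaults and are overridable in
`build_visual_system` / YAML config. The illuminant is ideal (constant 1);
no photon-flux conversion is applied.

Quantum catches are `Q_i = Σ R(λ)·I(λ)·S_i(λ)·Δλ`. The tetrahedral color
space takes *relative* catches `u_i = Q_i/ΣQ` to the point `Σ u_i·V_i` of a
regular tetrahedron with centroid at the origin and circumradius 0.75 (u
vertex on +z; s, m, l on the z = −0.25 circle at 90°, 210°, 330° — a fixed,
documented orientation); chroma is the distance from the achromatic origin,
luminance is the raw double-cone catch. Discriminability uses *raw* catches:
contrasts `Δf_i = ln(Q_i^A/Q_i^B)` enter the receptor-noise-limited distance

```
ΔS² = Σ_{i<j} (Π_{k∉{i,j}} e_k²) (Δf_i − Δf_j)²  /  Σ_{|s|=n−1} Π_{k∈s} e_k²
```

implemented for any channel count n (for n = 2 it reduces to
|Δf₁ − Δf₂|/√(e₁²+e₂²); for n = 4 to the standard tetrachromat form), and
`ΔL = |Δf_D|/e_D`. Distances above 1 JND are flagged "theoretical", above 2
"reliable" (strict inequalities). Tests verify the implementation against an
independently hand-written scalar expansion of the tetrachromat formula.

## Image pipelines

RGB images are taken as reflectance-calibrated linear values in [0, 1].
Conversion to cylindrical HSL (hue in degrees, saturation/lightness in
percent) is the standard hextant construction, with hue defined as 0 where
saturation is 0. Background masking is rule-based: each rule gives optional
strict min/max bounds per channel and marks *background*; the retained
feather pixels are the complement. The default rules encode the measured
photographic standards — white backgrounds have lightness above 60 %, black
below 10 %. Hue is summarized by a circular mean (the arithmetic mean is
also reported for comparability) because red hues straddle 0°/360°.

Hyperspectral cubes are (rows × cols × bands) reflectance arrays with
ascending band centers (synthetic cubes use 400–700 nm at 10 nm). ROI
sampling draws n = 500 locations uniformly *with replacement* (seeded) from
the polygon's pixels — half-open polygon semantics on pixel centers,
0-based (row, col) — excluding pixels whose 3×3 window leaves the image, and
extracts the per-band median of each 3×3 neighborhood plus the mean spectrum
across samples.

## Synthetic data: what it emulates, and what it does not

The generators stand in for the study's measurements, with exact ground
truth: (i) patch spectra = deterministic stack output × multiplicative
Gaussian measurement noise (default sd 2 %, typical spectrophotometer
repeatability), clamped to [0, 1]; (ii) feather-on-background images =
random thick barb-like strokes of a target HSL color (lightness jittered
±2 %, kept strictly inside the 10–60 % band) over an achromatic background
jittered within 80–95 % (white) or 2–8 % (black) lightness, with the truth
mask trimmed to the requested feather fraction to the nearest pixel; (iii)
hyperspectral cubes = polygonal regions of known spectra under multiplicative
noise on a flat background; (iv) dichromatism datasets = replicate spectra
(default 3 per sex, matching typical per-patch feather sampling) sharing one
colorful layer and differing only in achromatic preset.

These synthetic data are *structurally* faithful but idealized: real feather
images have gradients, specularities, translucent barb edges and chromatic
backgrounds; real spectra have wavelength-correlated noise and calibration
drift; real hidden layers are not spectrally flat. Passing tests therefore
demonstrate that the extraction and modeling machinery is correct and
self-consistent, not that the model fits any particular specimen.

## Numerical choices and degenerate inputs

- Layer constructors guarantee `R + T + A = 1` to 1e-12 by constructing A as
  the remainder; the `LayerOptics` validator enforces it.
- `fit_optical_density` is bounded scalar least squares
  (`scipy.optimize.minimize_scalar`, bounds [0, 10], xatol 1e-8); with the
  long-pass template the SSE is unimodal in `D`.
- Saturation is undefined (error) for all-zero spectra; relative quantum
  catches error on zero total catch; ΔS errors name the offending channel on
  non-positive catches.
- Resampling is linear interpolation with extrapolation forbidden; values at
  coincident nodes are preserved exactly.
- H1 and hue-angle ties and orientations are fixed by documented
  conventions so results are bit-reproducible across platforms; all
  stochastic code takes an explicit integer seed through
  `numpy.random.default_rng`.

## Problem sizes

Default analyses use 20-point sweep grids over `D ∈ [0.1, 3]` and
`Hpk ∈ [0.05, 0.8]`; randomized validation uses 1000 fuzzed layers, 100
random stacks, 1000 random contrast pairs, 50 synthetic images (64×64), and
80×80×31 hyperspectral cubes with 500 ROI samples — sizes chosen so the full
suite and the acceptance script each run in seconds on one core while
keeping the statistical checks well-powered.

## Known limitations

- No interreflection series, BRDF/angular effects, or iridescent (barbule)
  structural color.
- The carotenoid template, achromatic transmittances, and visual-system
  data are documented defaults, not fitted to any specimen.
- The image generator produces stylized strokes, not realistic barb
  geometry; masking results on real photographs will depend on interactive
  threshold choices that the rule-based masker only approximates.
- Hue statistics for multimodal hue distributions are summarized by a single
  circular mean, which can be unrepresentative for strongly bimodal ROIs.
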