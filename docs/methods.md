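# Methods

This note records the models, conventions and numerical choices behind
`icealgae`, in the order the pipeline applies them.

## Forward model of the synthetic scenes

Every scene is generated from a single-path Beer–Lambert model,

    L_t(λ) = L_LED(λ) · T_ice(λ) · exp(−a*(λ) · B) · ε,

where `L_LED` is the lamp radiance (mW m⁻² sr⁻¹ nm⁻¹), `T_ice` a
smooth algae-free transmittance baseline, `a*` the chlorophyll-a
specific absorption (m² mg⁻¹), `B` the per-pixel areal Chl a
(mg m⁻²) and `ε` the sensor noise. Scattering is not modelled
explicitly; it is folded into `T_ice`, which the package stipulates as
a gently red-tilted curve at a configurable level (default 0.3). The
analysis only needs spectra with a controllable chlorophyll signal on a
realistic baseline, not physical ice optics, and no optical constants
exist for the reference ice anyway. Consequences: the synthetic
transmittances carry none of the scattering-induced spectral shape
changes, path-length amplification or sub-pixel mixing of real sea
ice, so passing tests certify the *analysis chain*, not radiative
transfer realism.

**Illumination.** Two lamp archetypes: `white` (blue pump at ~452 nm
plus a broad phosphor hump) and `solar` (flat-ish across PAR). A
seeded smooth ripple (2%) individualises lamps. Spectra are scaled to
an integrated PAR photon flux of 20 µmol photons m⁻² s⁻¹ by default
(Lambertian conversion E = πL, Planck photon energy), below the
30 µmol ceiling used in practice to avoid photo-damaging low-light-
adapted communities.

**Absorption.** Two Gaussian lobes, 440 nm (σ = 30 nm) and 670 nm
(σ = 15 nm), amplitudes 0.032 and 0.020 m² mg⁻¹ (blue:red 1.6:1) —
order-of-magnitude in-vivo values; all configurable. At these values
`exp(−a*(670)·B)` reaches 1/e at B = 50 mg m⁻².

**Biomass fields.** Kernel-smoothed seeded white noise (periodic
boundaries), empirically standardised, then exponentiated with
log-normal parameters matching the requested marginal mean/sd. The
default marginal (18.74 ± 18.04 mg m⁻², strongly right-skewed) is the
across-section distribution observed for bottom (0–3 cm) sections in
the reference field data; interior sections (3–9 cm) default to
0.62 ± 0.45 mg m⁻². In the pipeline each simulated section draws its
*own* mean from that across-section log-normal and varies internally
with a configurable within-section CV (default 0.5) — the across- and
within-section decomposition matters because the calibration's dynamic
range lives between sections.

`correlation_length` (default 12 cm) is defined operationally as the
practical range an exponential-model variogram fit recovers from the
delivered field. The internal kernel sigma is `range / 4.8` sigmas, an
empirically calibrated constant: a Gaussian kernel decorrelates (95%)
at 3.46 σ, but the conventional exponential fit reads the practical
range of such Gaussian-correlated, log-transformed fields ~40% longer.

**Cavities.** With `cavity_fraction > 0`, smoothed-noise blobs are
thresholded into a cavity mask; cavity pixels get near-unity
transmittance (default 0.95) and biomass pulled to 2% of the scene
mean, reproducing the bright algae-poor features used for in situ
normalisation.

**Noise.** Multiplicative Gaussian noise parameterised by SNR plus
additive read noise, clipped at zero. Poisson shot noise is omitted:
at the radiance level the multiplicative term already captures
signal-proportional variance. All draws flow from one explicit seed
per scene; no global random state is used or mutated.

## Preprocessing conventions

- Pipeline order (convert → mask → PAR subset → normalise → smooth) is
  enforced through the cube's units tag; operations reject cubes in the
  wrong stage.
- PAR is `[400, 700]` nm inclusive on both ends.
- Savitzky–Golay smoothing: window 9 bands, polynomial order exposed
  per scan type (1–3 in practice), mirror padding at the spectral
  edges.
- Spatial binning averages valid members of factor×factor blocks; a
  block is valid iff ≥ 50% (configurable) of a full block's members
  are valid. Pixel pitch is reported unrounded (0.624 mm × 4 = 2.496
  mm, conventionally quoted as "2.4 mm").
- Transmittance is never clipped above 1 — pseudo-transmittance
  legitimately exceeds 1 for pixels brighter than the cavity mean.
  Negative radiances clip to 0 at radiometric conversion, before any
  division.
- Wavelength lookup is nearest-band everywhere, rejecting requests
  farther than one sampling interval from every band.

## Spectral indices

Continuum removal uses the straight chord between the bands nearest
650 and 700 nm — the convention for fixed-window band-depth indices —
with an upper-convex-hull mode available for comparison. The AUC-family
indices integrate **band depth** (1 − continuum-removed transmittance)
by default, so all of them grow with absorption and calibrate with
positive slopes; the literal area under the continuum-removed
transmittance is available via `auc_mode="literal"`. Negative depths
(noise pushing the spectrum above its chord) clip to 0 before
integration by default; an un-clipped mode exists because field
practice varies.

LAUC uses the natural logarithm (base configurable). A numeric floor
of 10⁻⁶ guards every division and logarithm; values at or below it
propagate as NaN markers rather than exceptions, keeping per-pixel maps
total.

NDI pair optimisation computes, for every ordered band pair, the
Pearson correlation between section-level NDI (per-pixel mean, method
2) and log Chl a. Pair selection requires |r| ≥ 0.7, separation
> 12 nm (avoiding autocorrelated neighbours) and at least one band in
a chlorophyll absorption region (430–460 or 650–700 nm); ranking is by
|r|, ties by larger separation then lower λ₁. Unordered pairs are
reported once, oriented so r is positive.

Section-level index values default to method 2 (mean of per-pixel
indices) rather than method 1 (index of the mean spectrum): per-pixel
computation is more representative of noisy in situ acquisition, and
the two converge as within-section heterogeneity vanishes.

## Calibration

Ordinary least squares of `ln(Chl a)` on the index (statsmodels
backend). Metric conventions, stated because several variants exist:

- `R²_adj = 1 − (1 − R²)(n − 1)/(n − 2)`;
- `RMSE = √(RSS/n)` (the √(RSS/(n−2)) variant is also reported);
- `AIC = n·ln(RSS/n) + 2k`, k = 2. Absolute AIC values are
  convention-dependent; only within-run comparisons are meaningful.

Tenfold CV partitions rows by a seeded random permutation into
near-equal unstratified folds and pools all held-out squared errors
(identical to the mean of fold MSEs at equal fold sizes, and
deterministic when they are not). Back-transformation `exp(α + β·x)`
applies no smearing correction by default, matching how such maps are
produced in practice; Duan's factor can be passed explicitly.

The leaderboard ranks by adjusted R², ties by lower AIC then lower
CV-RMSE.

## Mapping and spatial statistics

Maps stay in linear mg m⁻²; undefined pixels are NaN in memory and an
explicit no-data sentinel in exported rasters. The defined-pixel set is
exactly the cube's valid mask intersected with index definedness.

The empirical variogram draws up to 10,000 defined pixels uniformly
without replacement (seeded; all pixels if fewer, making the estimate
deterministic) and bins all within-sample pairs isotropically at
5-pixel lag widths up to half the image diagonal,
`γ(h) = Σ(z_i − z_j)² / 2N(h)`. Pair accumulation is chunked so memory
stays bounded at the default sample size. Model fits (exponential or
spherical) use bounded least squares with nugget ≥ 0; the exponential
model's reported range is its practical range (3× the scale
parameter). Non-convergence is reported as a diagnostic, never an
exception.

Prewitt gradients are normalised by 6 (kernel sum per axis) and by the
pixel pitch so a ramp of 1 mg m⁻² per pixel reports its true physical
slope in mg m⁻² mm⁻¹ — the reported units force the pitch division.
Reflect padding at borders; any pixel whose 3×3 neighbourhood touches
an undefined pixel is undefined.

## Problem sizes

The default pipeline configuration mirrors the reference study's
scale: 42 bottom + 12 interior sections (48×48-pixel discs) and an
0.85 × 0.70 m under-ice block — 354×292 binned pixels from a
1416×1168 native scene. A full run takes about a minute on one CPU at
~2.6 GB peak memory. `PipelineConfig.demo()` (12 sections, 64×64
block) runs in a few seconds and is what the test suite uses;
statistical tests choose field sizes (up to 512²) where their
Monte-Carlo tolerances are meaningful.

## Known limitations

- No radiative transfer: scattering, anisotropic path lengths and the
  vertical distribution of absorbers within the ice are all collapsed
  into `T_ice(λ)` and the cosine vignetting profile of vertical scans.
- Calibration transfer between normalisation schemes (transmittance vs
  pseudo-transmittance) is exact in the simulator only because cavity
  spectra are spectrally flat scalings of the lamp; in real scenes the
  cavity baseline has its own spectral shape, and narrow-band NDI
  models transfer less robustly than the area-based indices.
- The variogram is isotropic; directional structure (current-aligned
  algal strands) is not resolved.
- Absolute semivariances of field variograms depend on units and
  normalisation; only shape and range are meaningful for comparison.
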