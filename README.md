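# icealgae

Quantitative mapping of sea-ice algal biomass from hyperspectral
transmittance imagery.

Ice algae concentrate in the porous skeletal layer at the bottom of sea
ice, with biomass varying by orders of magnitude over centimetres.
Point extractions (melted core sections measured fluorometrically)
cannot resolve this microspatial structure; pushbroom hyperspectral
scanning of ice cores in transmitted light can, once the spectra are
calibrated against extracted chlorophyll a. This package implements
that analysis end to end for researchers working with transmittance
cubes of ice-core sections and under-ice scenes:

- **Preprocessing** — DN-to-radiance conversion, core masking,
  restriction to PAR (400–700 nm), 4×4 spatial binning,
  Savitzky–Golay spectral smoothing, and normalisation to transmittance
  `T(λ) = L_t(λ) / L_LED(λ)` (ex situ) or pseudo-transmittance
  `T_d(λ) = L_d,t(λ) / L_d,cavity(λ)` (in situ, normalised by
  algae-poor cavity regions of the same scene).
- **Unsupervised exploration** — mean-centred PCA on pooled pixel
  spectra; PC1 loadings carry the lamp spectrum (transmitted-intensity
  proxy), PC2 loadings the chlorophyll-a absorption signature, so PC2
  score maps are a normalisation-free biomass proxy.
- **Spectral indices** — the two-band normalised difference index
  `NDI(λ₁, λ₂) = (T(λ₁) − T(λ₂)) / (T(λ₁) + T(λ₂))` with exhaustive
  wavelength-pair optimisation over a Pearson correlation surface, and
  the continuum-removal family over the 650–700 nm absorption feature:
  band-depth area `AUC₆₅₀₋₇₀₀`, its normalisations by constant band
  depth at 677 nm (`ANCB`) and per-spectrum maximal band depth
  (`ANMB`), and `LAUC = log(AUC₆₅₀₋₇₀₀)`, which linearises the
  exponential attenuation of light through an absorbing medium.
- **Calibration** — log-linear models `log(Chl a) = α + β·INDEX`
  fitted per index against extracted Chl a (mg m⁻²), scored by R²,
  adjusted R², RMSE, AIC and seeded tenfold cross-validation, with a
  ranked model leaderboard.
- **Mapping and spatial statistics** — per-pixel application of the
  best model to produce Chl a rasters, empirical variograms (default:
  10,000 random pixels, 5-pixel lags) with exponential/spherical model
  fits (nugget, sill, range), and Prewitt gradient-magnitude maps in
  mg m⁻² mm⁻¹.
- **Synthetic scenes** — a first-class simulator with known per-pixel
  truth: LED illumination spectra (white and solar variants, dimmed
  below 30 µmol photons m⁻² s⁻¹), two-Gaussian chlorophyll-a specific
  absorption peaking at 440/670 nm, log-normal spatially correlated
  biomass fields (default marginal 18.74 ± 18.04 mg m⁻²), bright
  algae-poor cavities, Beer–Lambert forward model
  `L_t = L_LED · T_ice · exp(−a*·B)`, and SNR-parameterised sensor
  noise. Every generator is seeded and bit-reproducible.

Cubes are exchanged as ENVI header + binary pairs (BIL/BSQ/BIP);
tabular artifacts as CSV, summaries as JSON, configuration as YAML.

## Worked example

Run the small demo configuration (12 simulated core sections, a
64×64-pixel under-ice block) end to end:

```python
import yaml
from icealgae.config import PipelineConfig

cfg = PipelineConfig.demo(seed=7)
open("demo.yaml", "w").write(yaml.safe_dump(cfg.model_dump()))
```

```sh
$ icealgae all --config demo.yaml --out demo_run
best model: LAUC  alpha=1.004 beta=1.130  R2_adj=0.972
artifacts in demo_run

$ icealgae spatial --config demo.yaml --out demo_run
variogram range 11.9 cm; gradient mean 1.00 mg m-2 mm-1
```

Reading the output: of the six candidate indices (two optimised NDIs,
AUC, ANCB, ANMB, LAUC), the log-area index LAUC wins the leaderboard —
its calibration `log(Chl a) = 1.004 + 1.130·LAUC` explains 97% of the
between-section variance on this draw, because the log of the
absorption-feature area is nearly linear in log biomass under
Beer–Lambert attenuation. The fitted model, applied per pixel to the
pseudo-transmittance block, yields a Chl a map whose empirical
variogram recovers the 12 cm correlation length the scene generator
injected, and whose Prewitt gradient magnitude summarises the mm-scale
patchiness. `demo_run/` holds the calibration table, leaderboard, PCA
loadings, variogram and JSON summaries, each stamped with the
configuration hash.

The same stages are available as library functions
(`icealgae.pipeline.run_pipeline`, or the per-module functions it
wires together) and as CLI subcommands `simulate`, `preprocess`,
`pca`, `indices`, `calibrate`, `map`, `spatial`.

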