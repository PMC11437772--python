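# specklestress

Laser-speckle activity analysis and hypoxic-stress classification for
fruit-storage monitoring, with synthetic data generators for end-to-end
validation.

The package computes three scalar activity coefficients from grayscale
speckle video clips:

- **τ / τ\* / β** — relaxation time and stretch exponent of a stretched
  exponential `corr(t) = exp(-(t/τ)^β)` fitted to the frame-to-frame
  decorrelation curve (τ\* = ln τ),
- **tLASCA** — per-pixel temporal standard deviation over temporal mean,
  averaged over the image,
- **IM** — inertia moment `Σ GLCM[i,j]·(i−j)²` of the normalized
  co-occurrence matrix of time-adjacent gray levels in each pixel's time
  history.

It then assembles per-apple, per-epoch signal tables (speckle
coefficients for red/infrared laser channels, chlorophyll fluorescence,
CO₂ respiration rate), applies the modelling transforms (log of τ,
respiration first derivative, sphere-equivalent surface area, optional
CF normalization), produces ground-truth stress labels with a 2-of-3
robust change-detection rule, and trains gradient-boosted binary
classifiers over twelve predictor-set variants with repeated stratified
70/30 validation, four confusion metrics and normalized gain
importances.

Two simulators make everything testable without real data:

- `specklestress.simulate` — dynamic speckle video from a temporally
  correlated complex Gaussian field (squared modulus), so the intensity
  decorrelation follows the Siegert relation
  `|g1|² = exp(-2(Δt/τ_field)^β)` with a closed-form target
  `τ = τ_field·2^(−1/β)` for the estimators,
- `specklestress.synthesis` — experiment-level time courses with a
  baseline → stress plateau → recovery step structure, AR(1) noise,
  per-apple onset jitter and a configurable fraction of
  fluorescence-unresponsive apples.

## CLI

```sh
# simulate a speckle clip (multi-page TIFF + sidecar JSON + manifest)
specklestress simulate --out clip.tif --tau-field 0.5 --seed 1

# compute speckle coefficients for one or more clips
specklestress analyze-video clip.tif --out coeffs.csv --channel IR

# generate a synthetic experiment (epochs/phenotypes/truth CSVs)
specklestress synth-experiment --out-dir exp/ --n-apples 15 --seed 1

# transform + expert-label the epoch table
specklestress label --epochs exp/epochs.csv --phenotypes exp/phenotypes.csv \
    --out labeled.csv

# single variant, or the full 12-variant suite
specklestress train --data labeled.csv --variant 1 --out report.json --seed 1
specklestress evaluate --data labeled.csv --out reports.json --seed 1

# render report JSON to CSV
specklestress report --reports reports.json --out reports.csv
```

Every subcommand writes a run manifest (config digest, seed, input and
output paths, tool version) next to its outputs.

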