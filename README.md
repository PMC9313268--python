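# clearquant

Quantitative transparency assessment for optically cleared tissue, plus a
light-sheet image-stack preprocessing chain, exercisable end to end on
synthetic phantoms with known ground truth.

What it does:

- **phantom** — generates bright-field transmittance image pairs (blank
  illumination field and Beer–Lambert-attenuated sample image, with
  vignetting and Gaussian/Poisson detector noise) and SPIM-like fluorescence
  stacks (Gaussian nuclei, tubular vessels, sinusoidal stripe artifacts,
  salt-and-pepper impulse noise), retaining ground truth for recovery tests.
- **attenuation** — estimates attenuation coefficients `mu = ln(I0/I)/L`
  (1/mm) from region-mean intensities, using a randomized protocol: 3
  regions per run (each side 15% of the image side), 15 runs per image, 3
  images per sample = 135 individual measurements pooled into mean ± SEM.
- **group_stats** — per-condition mean ± SEM, one-way ANOVA, and
  Bonferroni-adjusted pairwise post-tests (pooled within-group variance,
  with a Welch switch).
- **stack_processing** — per-plane 3×3 median filter, directional Fourier
  notch destriping, linear (affine, clipped) contrast adjustment,
  maximum-intensity projection, and lossless volume export to multi-page
  TIFF or NRRD with voxel-spacing metadata.
- **pipeline** — glue for multi-condition synthetic experiments
  (generate → measure → compare).

## CLI

The `clearquant` entry point has four subcommands:

```sh
# synthesize a three-condition experiment (16-bit TIFF pairs + manifest CSV)
clearquant simulate --config experiment.json --seed 0 --out-dir sim/

# run the region-sampling protocol on every sample in the manifest
clearquant measure --manifest sim/manifest.csv --regions 3 --runs 15 \
    --fraction 0.15 --seed 0 --out-dir meas/

# ANOVA + Bonferroni across conditions; exit code 0 iff global p <= alpha
clearquant compare --measurements meas/measurements.csv \
    --summary meas/summary.csv --unit sample --alpha 0.001 --out-prefix cmp

# median -> destripe -> contrast on a volume, plus a projection
clearquant process-stack --input stack.tif --output clean.tif \
    --destripe --stripe-axis 2 --contrast --mip-axis 0
```

A `simulate` config file (JSON or YAML) lists conditions with per-condition
overrides:

```json
{
  "defaults": {"height": 512, "width": 512, "n_samples": 3, "n_images": 3,
               "thickness_mm": 2.0, "noise_sigma_frac": 0.02},
  "conditions": {"uncleared": {"mu": 4.0}, "babb": {"mu": 1.5},
                 "cubic": {"mu": 0.5}}
}
```

## Notes

- The displayed log-ratio is `ln(I0/I)/L`, the nonnegative orientation
  consistent with the forward model `I = I0 exp(-mu L)`; the sign-flipped
  reading `ln(I/I0)/L` differs only in sign.
- Regions may overlap; per-region coefficients use the log of the ratio of
  region means (robust to near-zero pixels), with intensities floored at
  1e-6 detector units and degenerate regions redrawn up to 10 times.
- At 2% Gaussian detector noise, recovery is accurate (≤ 5% relative error)
  for optical densities `mu*L` up to ≈ 4; beyond that the transmitted signal
  falls below the noise floor and zero-clipping biases the estimate low.
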