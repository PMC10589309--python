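# speckle-precision

Simulation and analysis toolkit for the **precision** of laser speckle
contrast imaging (LSCI).

LSCI maps tissue perfusion by imaging laser speckle and computing the
spatial contrast K = σ(I)/⟨I⟩ over small pixel neighbourhoods: the blurring
caused by moving red blood cells during the exposure lowers K, and
BFI = 1/K² serves as a blood-flow index.  While the *accuracy* of LSCI is
well studied, its *precision* — how much K fluctuates between statistically
equivalent measurements — is what limits the detection of fast dynamics
such as cardiac pulsatility or functional responses.  This package is for
researchers designing or analysing LSCI systems who want to quantify how
precision depends on

- the **speckle-to-pixel size ratio** (how many speckles a contrast
  neighbourhood samples),
- the **neighbourhood size** (5×5, 7×7, 50×50, ...),
- the **exposure time** relative to the decorrelation time, T/τ_c,
- **polarisation statistics** (coherence degree β = 1 vs 0.5), and
- **camera noise** (shot, read, quantization, saturation).

## What it does

- Synthesizes dynamic speckle from first principles: N moving point
  scatterers, each a spherical-wave source, superposed on a pixel grid as
  I = |Σ_n e^{ikr_n}/r_n|², with ordered (flow) or unordered (diffusive)
  motion, exposure integration, and a fast FFT-based generator for
  statistically independent frames.
- Applies a switchable camera pipeline (photo-electron scaling → Poisson
  shot noise → Gaussian read noise → full-well saturation → ADC) with
  presets for low/medium/high quality sensors.
- Measures precision as the mean relative per-pixel contrast error over
  non-overlapping neighbourhoods, Error = ⟨|K − K_ref|/K_ref⟩·100%.
- Evaluates closed-form contrast models K(T/τ_c; β, ρ, C) for three
  dynamics regimes (single/multiple scattering × ordered/unordered motion)
  and their absolute and relative flow sensitivities
  S_a = |dK/dv|, S_r = |x·dK/dx|/K with v = 1/τ_c.
- Estimates τ_c from the intensity autocorrelation g₂(τ) via the Siegert
  relation g₂ = 1 + β|g₁|², and scores pulsatile signal quality with a
  per-pixel spectral SNR.

## Worked example

Two independent fully developed speckle patterns summed incoherently (the
unpolarised-detection statistics) lose contrast by exactly 1/√2:

```bash
$ speckle-precision run polarisation_check --seed 1
{
 "contrast_ratio": 0.7064966304717964,
 "ci_low": 0.7055772938913896,
 "ci_high": 0.7074159670522033,
 "expected": 0.7071067811865475,
 "n_frames": 200,
 "mean_contrast_polarised": 1.0001656767725944,
 "mean_contrast_unpolarised": 0.706571464240551,
 "seed": 1,
 "config_hash": "301b9a546284"
}
```

The measured ratio of the whole-frame contrast (unpolarised over polarised,
0.7065 with a 95% CI of ±0.0009) sits on the theoretical 2^{-1/2}: removing
the polariser costs contrast *range*, but — as the error metrics show — not
measurement precision.

The same from Python, together with the precision story in one figure-free
table:

```python
import speckle_precision as sp

# error vs neighbourhood size at speckle FWHM 5 px, T/tau_c = 0
stack = sp.fast_speckle((250, 250), speckle_fwhm=5.0, n_frames=2000, seed=1)
for w in (5, 7, 50):
    rep = sp.per_pixel_error(sp.contrast_stack(stack, w), neighbourhood=w)
    print(f"{w}x{w}: {rep.error_percent:.1f}%")
# 5x5: 27.8%   7x7: 21.1%   50x50: 5.4%

# decimate to FWHM 0.5: smaller speckles, more precise measurements
dec = sp.rescale_speckle(stack, 10)
print(sp.per_pixel_error(sp.contrast_stack(dec, 5), neighbourhood=5).error_percent)
# 12.8
```

A 5×5 neighbourhood at a speckle-to-pixel ratio of 5 carries ~28% relative
error per measurement, dropping to ~13–14% at ratio 0.5 — small speckles
beat the classical "two pixels per speckle" advice when precision is the
goal.

Other experiments (`speckle-precision run --help`): `exposure_sweep`
(error vs T/τ_c from particle-simulated exposures), `camera_grid`
(per-noise-source error vs fill level for three camera tiers),
`sensitivity_curves` (S_a and S_r vs exposure for vessel/parenchyma
presets).  Each accepts `--config cfg.yaml`, `--seed N` and `--out dir`
and writes CSV tables with seed and config-hash provenance.

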