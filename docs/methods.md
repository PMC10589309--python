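# Methods

## Scope and model

`speckle-precision` studies the *precision* (per-measurement variability) of
laser speckle contrast imaging (LSCI), as opposed to its accuracy.  The
package simulates dynamic speckle from first principles, degrades it with a
configurable camera model, and measures how the spatial contrast
K = σ(I)/⟨I⟩ fluctuates as a function of the speckle-to-pixel size ratio,
the contrast neighbourhood, the exposure-to-decorrelation-time ratio
T/τ_c, the polarisation statistics and the camera noise sources.

### Particle-based speckle synthesis

Scatterers are treated as point sources of spherical waves.  The intensity
at a sensor pixel is

    I = |Σ_n exp(i·k·r_n)/r_n|²,    k = 2π/λ,

with r_n the particle-to-pixel distance and λ = 785 nm by default.  Frames
generated at intervals dt much shorter than τ_c are averaged in
non-overlapping blocks to emulate a finite exposure T.  All lengths are in
µm and times in µs.

Dynamics are introduced by displacing the particles between frames:
*ordered* motion translates every particle by v·dt (flow); *unordered*
motion adds zero-mean Gaussian steps of per-axis variance 2·D·dt
(diffusion).

**Boundary handling.** Particles leaving the box are re-wrapped to keep the
density (and hence the speckle statistics) stationary.  For ordered motion
a purely periodic wrap would be wrong in a subtle way: uniform translation
plus modular wrap makes the *entire configuration* recur exactly with
period L/|v| (box length over speed), which imprints a spurious long-time
correlation on every pixel — we measured per-pixel g₂(0) collapsing from
~2.0 to ~1.6 because each pixel revisits the same intensity trace a dozen
times within a simulation.  The package therefore wraps the flow-axis
coordinate periodically but re-randomises the transverse coordinates of a
wrapped particle: a scatterer leaving the illuminated volume is replaced by
a fresh one entering upstream, which is also the physically sensible
picture of flow through a vessel.  With this scheme g₂(0) ≈ 2 and the
long-lag tail is flat at 1 (to within estimator bias).

### Geometry and calibration by measurement

The speckle-to-pixel size ratio and the decorrelation time are *measured*
properties, not constructor arguments:

- `design_geometry` starts from the diffraction estimate
  speckle ≈ λ·z/D (z sensor distance, D lateral source extent) and bisects
  the distance until the measured autocovariance FWHM of a synthesized
  frame hits the target (default tolerance 3%).
- `calibrate_velocity` simulates a short ordered-motion stack, fits the
  pixel-averaged g₂(τ) with the Siegert relation 1 + β·|g₁|² (Gaussian g₁,
  the single-scattering ordered-motion shape), and rescales the speed using
  τ_c ∝ 1/|v|.  Two iterations land within a few percent of the target.

Defaults: 1000 particles in a cubic box of side 50λ, pixel pitch 5 µm.
The τ_c = 20 µs reference dynamics at a speckle-to-pixel ratio of 2 then
calibrate to a speed of ≈0.4 µm/µs.  The g₂ fit window is restricted to the
decaying part of the curve (down to 5% of the zero-lag amplitude): the tail
of a finite-series per-pixel estimate is dominated by normalisation bias,
which would otherwise drag the fitted β down.

### Fast statistical generator

For experiments that only need *statistically independent* instantaneous
frames (T/τ_c = 0), generating each frame from particles is wasteful.
`fast_speckle` filters a complex Gaussian field with a circular pupil in
the Fourier domain; the pupil radius is calibrated — deterministically,
from the expected autocovariance |IFFT(pupil)|² — so the intensity
autocovariance FWHM equals the requested speckle size.  β = 0.5
(unpolarised detection) is realised as the mean of two independent
intensity patterns.  Temporal experiments must use the particle method;
the fast path has no temporal correlation model.  Smaller speckle sizes
are derived by decimation (box-car filter + downsample of frames
synthesized at FWHM 5) rather than re-synthesized per size, so per-size
results share speckle realisations — the numerical analogue of closing an
aperture on a fixed scene.

### Camera model

Normalized frames are scaled so the sensor-average photo-electron count is
`fill`·capacity, then pass through Poisson shot noise, additive Gaussian
read noise, clipping at the full well, conversion to digital numbers at
(2^bits − 1)/capacity DN per electron, rounding, and clipping of the DN
range.  Each stage is independently switchable so error curves can be
decomposed by source.  Two conventions are worth stating explicitly:

- Conversion gain maps the full well exactly to the top of the DN range, so
  `fill` coincides with ⟨I⟩/I_max, the quantity one can read off a live
  histogram.
- Both clipping stages (electron-level and DN-level) belong to the
  `saturate` flag.  An unconditional DN clip would leak saturation error
  into the shot-only and read-only curves and defeat the decomposition —
  with fully developed speckle at fill 0.3 about 3–4% of pixels exceed the
  well because of the exponential intensity tail.
- Read noise is added before saturation clipping; dark current is zero.

Presets: low (QE 0.2, σ_r 30 e⁻, 8 bit, 1200 e⁻), medium (0.45, 13 e⁻,
8 bit, 12 400 e⁻ — a typical machine-vision CMOS), high (0.8, 1 e⁻, 16 bit,
30 000 e⁻ — scientific CMOS).  Because the light level is specified through
`fill`, the quantum efficiency only matters when converting photons, not
for any quantity the package reports; it is retained for fidelity of the
presets.

### Precision metric

`per_pixel_error` implements the mean relative per-pixel error

    Error = ⟨ |K(x,y,n) − K_ref| / K_ref ⟩ × 100%,

averaged over window positions and statistically independent frames.  Only
a stride-w subgrid of windows (anchored at the frame origin) enters the
average — overlapping neighbourhoods share pixels and would overstate the
number of independent samples.  K_ref is either the data-set mean contrast
(precision proper) or a noise-free reference map (camera-induced error).
The contrast uses the sample standard deviation (n−1); the population
estimator is available via `ddof=0` for sensitivity checks.  Window sizes
are unrestricted above 2 — the reference neighbourhoods are 5×5, 7×7 and
50×50, the last of which is even (the window centre then sits half a pixel
off the nominal grid, which is irrelevant to the error statistics).

### Contrast laws and sensitivity

Three dynamics regimes are covered, each a closed form in x = T/τ_c with
coherence degree β, dynamic scattering fraction ρ and noise offset C:
single-scattering ordered (large vessels, Gaussian g₁), multiple-ordered /
single-unordered (medium vessels, exponential g₁) and multiple-unordered
(parenchyma, stretched-exponential g₁).  Below x = 10⁻³ each bracket term
is replaced by its Taylor series: the closed forms are ratios of
exponentially small residuals to x², and lose all significant digits to
cancellation (the switch is continuity-tested at the boundary).

Flow sensitivity is defined against v = 1/τ_c: absolute S_a = |dK/dv| and
relative S_r = x·|dK/dx|/K.  Derivatives are central finite differences
with relative step 10⁻⁵ — the three regimes share one code path, and the
analytic derivatives (erf terms in the Gaussian regime) are error-prone;
a Richardson check (10× finer step) in the test suite bounds the
discretisation error below 0.1%.  `optimal_exposure` grid-searches S_r on
a log axis and refines the maximum; the saturating case (C = 0, ρ = 1,
S_r → 1/2 monotonically) is reported with a boundary flag instead of a
fake interior optimum.

The sensitivity presets pair the vessel classes with τ_c = 75/150/250 µs
and two parameterizations: simplified (ρ = 1, C = 0) and realistic
(C = 0.01 everywhere, ρ = 0.8 in parenchyma).

### Signal quality

The synthetic stand-in for cardiac pulsatility modulates the ordered-motion
speed as v(t) = v₀(1 + m·sin 2πf_c t).  Per-pixel SNR is the maximum
spectral magnitude in a cardiac band divided by the median magnitude in a
flanking plateau band (default 1.5×–3× the cardiac frequency; the plateau
definition is a package choice — "plateau" is not standardised), DC
excluded, summarised by the median over pixels.  `variation_ratio`
band-passes the K series by spectral masking (exactly invertible, no
filter transients) and reports σ(K)_band/⟨K⟩.

## Problem sizes

The error metrics are Monte-Carlo estimates whose sampling error shrinks
with the number of independent frames and the frame area.  The package
defaults, chosen to run in minutes on one CPU, are:

| experiment            | default scale                                   |
|-----------------------|--------------------------------------------------|
| speckle statistics    | 2 000 frames of 250×250, FWHM 5 decimated to 0.5 |
| exposure sweep        | 10 000 instantaneous frames of 64×64, dt = 2 µs  |
| τ_c validation        | 2 000 frames of 64×64, dt = 1 µs                 |
| camera grid           | exposures reused from the sweep stream           |
| polarisation check    | 200 independent frame pairs of 128×128           |

The experiment drivers use 300 particles instead of the 1000-particle
default of `ParticleCloud`: the pixel field is a sum of N random phasors
and is Gaussian to excellent approximation already at a few hundred terms,
while the cost of a frame is linear in N.  dt defaults to τ_c/20 = 1 µs for
validation stacks and τ_c/10 = 2 µs for the exposure sweep (the largest
interval that still resolves the dynamics).

All Monte-Carlo quantities inherit sampling error from these scales —
roughly 1–5% relative for the error metrics (thousands of independent
neighbourhoods) and ~5% for fitted τ_c.  The error *ratios* between
conditions are more stable than the absolute errors.

## What the synthetic data does and does not emulate

The generator reproduces fully developed speckle statistics (exponential
intensity, unit contrast), the speckle-size dependence of contrast
sampling, exposure-time blurring driven by particle motion, polarisation
statistics as a two-channel incoherent sum, and sensor noise.  It does not
model layered-tissue light transport, absorption, multiple-scattering path
statistics (regimes enter only through the closed-form contrast laws),
physiological waveforms beyond a sinusoid, specular reflections, or
fixed-pattern/dark-current camera effects.  Passing tests therefore
validate the estimation-statistics story — how precision depends on
sampling — not any claim about absolute in-vivo contrast values.

## Numerical choices and degenerate inputs

- Windows with zero mean intensity yield undefined K and are masked, not
  raised.
- The speckle-size estimator returns the lower bound 1 px (with a warning)
  when the autocovariance has no positive width — sub-pixel speckle cannot
  be sized from a pixel-sampled autocovariance; decimated sizes are
  reported as nominal (synthesis FWHM / decimation factor) alongside the
  measured value.
- The artefact mask flags pixels whose intensity leaves (0, DN_max) or
  contrast leaves (10⁻⁴, 0.99) at any time point, dilated by a Chebyshev
  radius of 2 px; the DN bound generalises from 255 to 2^bits − 1.
- `fast_speckle` rejects speckle sizes outside what a circular pupil can
  realise on the given grid (~1.1 px at the small end).
- All stochastic operations take explicit seeds; frame stacks carry their
  seed provenance, and experiment CSV rows carry the seed and a config
  hash.

## Known limitations

- The ordered-motion g₁ of the particle model is set by the source-volume
  coherence function (a sinc-like shape for a uniform box), not an exact
  Gaussian; the Gaussian Siegert fit therefore recovers a β̂ of ~0.85–0.9
  rather than 1 on polarised stacks.  τ_c is defined *by that fit*, which
  is also how the velocity calibration closes the loop, so exposure-ratio
  results are internally consistent.
- Per-pixel g₂ normalisation is biased low at long lags for finite series;
  the fit window restriction mitigates but does not remove this.
- Exposures cut consecutively from one stream are treated as independent;
  at T ≥ 5 τ_c the residual correlation between adjacent blocks is
  negligible but not zero.
- The even/odd window centring convention differs by half a pixel from
  implementations that centre even windows on a pixel; this has no effect
  on any aggregate statistic reported here.
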