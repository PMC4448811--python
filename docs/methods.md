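# Methods

## Pipeline

Every experiment follows one pipeline per stimulus:

1. **Synthesis** — a 1024×1024 luminance image at 60 px/deg (1 px per
   arc minute), so the image subtends ~17° of visual angle.
2. **Luminance rescaling** — an affine map of pixel values onto
   [1, 255]. A constant image maps to the midpoint 128 by convention.
3. **CSF prefiltering** (simulation 2; bypassed in simulation 3) — a
   radial gain in the Fourier domain.
4. **Population response** — *n* Gabor neurons, tunings drawn from the
   configured distributions, each placed uniformly at random among all
   pixel positions where its ±3σ₂ support fits inside the image, each
   responding with the inner product of image and receptive-field
   weights.
5. **Summaries** — total magnitude Σ|rᵢ| and population excess kurtosis
   m₄/m₂² − 3 (population moments, no small-sample correction; undefined
   — reported as NaN — for a zero-variance response vector). Per-image
   statistics are averaged across the images of a class; the raw signed
   sum is also recorded (it is ≈0 for zero-mean filters, which is why
   magnitude is defined on absolute responses).

## Stimuli

**Gratings.** `L = L̄(1 + c·cos(2π f u + ϕ))` with carrier coordinate
`u` along the orientation axis. The requested (frequency, orientation)
pair is snapped to the nearest integer-cycle point of the Fourier
lattice (default, switchable): the grating is then exactly periodic over
the image and all of its spectral energy sits in a single conjugate bin
pair. The snap changes the frequency by at most half a cycle per image
width (≈0.03 c/deg at this geometry) — negligible against the octave
spacing of the test grids, and it makes spectral assertions exact.

**Band-peaked noise.** Gaussian white noise is reshaped in the Fourier
domain to amplitude `H(f)/f`, where H is a raised cosine in log
frequency: flat at T = 0.9 within `|ln f − ln f₀| ≤ (1−β)/(2T)`, a
half-cosine roll-off out to `(1+β)/(2T)` (β = 0.5), zero beyond. Two
compositions with the 1/f base are implemented: `literal`
(multiplicative, the default — a band-limited spectrum) and `additive`
(`(1+H)/f`, a 1/f floor with a peak). The logarithm base only rescales
the band edges and is configurable (natural log by default). The DC
coefficient is set directly to the target mean luminance, since 1/f is
undefined at f = 0. Because the gain multiplies FFT coefficients bin by
bin, output/input amplitude ratios equal the applied gain to
floating-point precision — an invariant the tests assert exactly.

**Natural-image surrogates.** The same machinery with amplitude
`f^(−β)`, β drawn uniformly from [0.8, 1.2] per image unless fixed —
the spectral-slope range measured for natural scenes. Surrogates
reproduce the second-order (amplitude-spectrum) statistics of natural
images but none of their higher-order structure (edges, occlusions,
phase alignments). Results that depend only on the spectral envelope —
the tuning-curve shapes, the direction of the model comparison — are
meaningful on surrogates; absolute kurtosis values for real natural
images (which are themselves non-Gaussian) are expected to be much
higher, so surrogate runs understate them.

## Pre-cortical filter

No single standard formula exists for the CSF; the package uses the
Mannos–Sakrison family `(a + b·f)·exp(−(c·f)^d)`, normalized to unit
peak, with a = 0.0192, b = 0.26, c = 0.26, d = 1.1 — placing peak
sensitivity at ≈3.4 c/deg, in the 3–4 c/deg band consistent with
discomfort psychophysics. The DC gain is pinned at 1 so filtering never
shifts mean luminance. All four constants are plain configuration; any
non-negative band-pass gain can be substituted. Orientation- or
luminance-dependent CSF variation is out of scope.

## Receptive fields

σ₂/σ₁ = 2 always (elongation along the stripes). The default envelope
scale comes from fixing the half-amplitude spatial-frequency bandwidth
at 1.4 octaves, which gives σ₁ = 0.41609/f degrees; receptive fields
are therefore self-similar and σ₁·f is constant. A `literal` envelope
mode (σ₁ = 7.81/f, σ₂ = 15.61/f in consistent units) is retained for
comparison; it implies a ~0.07-octave bandwidth and supports of
hundreds of degrees at low preferred frequencies, so it cannot be used
for full-image replication runs — the bandwidth parametrization is the
default because it jointly satisfies the 1.4-octave and 2:1-aspect
specifications.

Weights are post-processed to zero mean and unit energy by default. Raw
cosine-phase Gabors respond to mean luminance (a pure DC artifact), and
raw response magnitude scales with envelope area ∝ 1/f², which would
confound frequency tuning of the population response with receptive-
field size; unit-energy normalization makes responses commensurable
across frequency. A `raw` mode preserves the literal weights.

## Tuning distributions

The shipped tables are constructed, not digitized (the source
physiological histograms are not available in tabular form); each is a
two-column CSV a user can replace outright:

* **Frequency** — discrete log-normal on half-octave centres
  0.375–12 c/deg, geometric mode 3 c/deg, σ = 0.8 octaves. The mode
  sits inside the 2–6 c/deg midrange band where cortical frequency
  preferences concentrate. The lowest centre is 0.375 c/deg because the
  ±3σ₂ support of a 1.4-octave neuron preferring 0.25 c/deg (±600 px)
  cannot fit a 1024-px image.
* **Orientation** — 15° bins, weight 1 + 0.5·cos 4θ: the cardinal
  (horizontal/vertical) over-representation seen in single-cell
  recordings.
* **Phase** — 45° bins, weight 1 + 0.7·cos 4ϕ: concentration at
  0°/90°/180°/270°, the even/odd symmetry classes.

Draws return bin centres. The fixed-grid alternative (frequencies 20
and 40 cycles/image ≈ 1.17 and 2.34 c/deg at this geometry;
orientations 10°, 55°, 100°, 145°; phases 0°, 90°) is exposed as
`FieldConfiguration`.

## Placement and pairing

Receptive-field centres are drawn independently per neuron, uniformly
over the valid region (no tiling). For the model comparison, the same
per-neuron-index uniform deviates are mapped into each population's own
valid region, pairing the two models positionally image by image; a
neuron index sees the same image region under both models up to the
(small) difference in support margins.

## Numerical choices

* The response engine groups neurons by (frequency, orientation),
  expresses each phase as a combination of one even and one odd
  quadrature patch, and computes window inner products as matrix
  products. Patches are cached across stimuli. The result agrees with
  the naive per-neuron path to double-precision rounding (asserted at
  1e-10 relative in the tests).
* Excess kurtosis uses the biased population form (scipy's
  `kurtosis(..., fisher=True, bias=True)`); it is scale-invariant and
  bounded below by −2.
* FFT frequency lattices use the half-open Nyquist convention of
  `numpy.fft.fftfreq`; "radial frequency" is the Euclidean norm of the
  2-D bin frequency in c/deg.
* Degenerate inputs: constant images rescale to 128; zero-variance
  response vectors yield NaN kurtosis; frequencies at or above Nyquist,
  supports exceeding the image, malformed distribution tables and
  unknown config keys all raise before any computation.

## Problem sizes

Default configuration matches the full-scale study (250 000 neurons per
stimulus, 100 surrogate images, 10 noise instances per centre
frequency). The shipped tests and the acceptance script run at 20 000
neurons per stimulus with 10 noise seeds per frequency and a 9-point
frequency grid {0.25, 0.5, 1, 2, 3, 4, 6, 8, 12} c/deg: peak locations
and kurtosis rankings are stable well below the full population size,
since every summary is an average over 2·10⁴ independent placements.
The 9-point grid includes 3 and 6 c/deg so midrange structure between
the octave-spaced points is expressible.

## Observed behaviour and limitations

At the reduced scale, total magnitude peaks at 2 c/deg for both
gratings and band-peaked noise, and the kurtosis minimum falls at
3 c/deg for gratings — midrange frequencies produce the largest, least
sparse population responses. The noise kurtosis minimum falls at
3 c/deg as well, one grid point above where discomfort for filtered
noise is maximal; the exact argmin position is sensitive to the CSF
shape and the frequency-tuning histogram, neither of which is uniquely
determined (see above), and to the band-limited (`literal`) noise
composition, which makes noise behave like a spectrally smeared grating.

The model is linear throughout: no rectification, contrast
normalization, divisive gain control, or response noise. It addresses
population sparseness only — lifetime sparseness of single neurons
across images is a different quantity — and makes no claim about
decoding or perceptual read-out.
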