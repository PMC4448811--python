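# v1sparse

A Gabor filter-bank model of primary visual cortex (V1) for studying why
some images are uncomfortable to look at. Certain stimuli — striped
gratings and noise with excess energy at midrange spatial frequencies —
reliably cause eye-strain, illusions and, in clinical populations,
migraine attacks and photosensitive seizures. One proposed cause is
metabolic: the visual system is adapted to encode natural scenes
*sparsely* (few strongly active neurons per image), and stimuli that
violate natural-image statistics evoke large, non-sparse population
responses that are costly to process.

`v1sparse` simulates that account. It is intended for visual
neuroscientists and vision researchers who want a reproducible,
configurable implementation of the population-response analysis:
stimulus synthesis, pre-cortical contrast-sensitivity filtering, a V1
population with physiologically shaped tuning distributions, and the two
summary statistics of the population response.

## The model

Each of *n* model neurons (250 000 by default) is a Gabor receptive field

```
G(x, y) = A · exp(−x_p²/2σ₁² − y_p²/2σ₂²) · cos(2π f x_p + ϕ)
x_p = x cosθ − y sinθ,   y_p = x sinθ + y cosθ
```

with preferred frequency *f* (cycles/degree), orientation *θ* and phase
*ϕ*. Envelopes are self-similar across frequency: σ₂ = 2σ₁ (receptive
fields twice as long along the stripes as across them) and σ₁ ∝ 1/f,
fixed by a 1.4-octave spatial-frequency bandwidth. Weights are zero-mean
and unit-energy by default. Tunings are drawn either from
physiology-shaped histograms (frequency unimodal over ~2–6 c/deg,
orientation cardinally biased, phase concentrated near 0°/90°; shipped as
editable CSV tables) or from the classic sparse-coding configuration of
16 fixed filters (2 frequencies × 4 orientations × 2 phases).

Each stimulus (1024×1024 px, 1 px per arc minute) is luminance-rescaled
to [1, 255], optionally filtered by a band-pass contrast sensitivity
function (CSF, unit peak near 3.4 c/deg), and presented to the
population; each neuron's response is the inner product of the image with
its receptive field placed at a random location. Two statistics summarize
the population response vector *r*:

* **total magnitude** Σ|rᵢ| — the overall size of the cortical response;
* **excess kurtosis** m₄/m₂² − 3 — the population-sparseness index: high
  for a zero-peaked, heavy-tailed response (sparse), low for a broadly
  activated population.

Stimulus classes: sine gratings; Gaussian noise shaped in the Fourier
domain to a 1/f amplitude spectrum with a raised radial cosine peak
H(f) at a centre frequency f₀ (flat top T = 0.9, roll-off β = 0.5 in log
frequency); and 1/f^β Gaussian surrogates (β ∈ [0.8, 1.2]) standing in
for natural images. An optional reader for headerless 16-bit raw
luminance images (van Hateren style) is included for ad-hoc scoring of
real natural images.

## Worked example

```python
from v1sparse import (GratingSpec, SurrogateNaturalSpec, make_grating,
                      make_surrogate_natural, rescale_luminance, apply_csf,
                      TuningDistributions, place_and_respond, summarize)

dist = TuningDistributions.physiological()

def respond(image, seed):
    image = apply_csf(rescale_luminance(image))
    return summarize(place_and_respond(image, dist, n=20_000, seed=seed))

grating = make_grating(GratingSpec(frequency=3.0, contrast=1.0))
natural = make_surrogate_natural(SurrogateNaturalSpec(seed=0))

for name, image in [("grating 3 c/deg", grating), ("1/f surrogate", natural)]:
    s = respond(image, seed=42)
    print(f"{name:16s} total |r| = {s.total_magnitude:12.0f}   "
          f"mean |r| = {s.mean_abs:7.2f}   excess kurtosis = {s.excess_kurtosis:6.2f}")
```

prints

```
grating 3 c/deg  total |r| =      5675539   mean |r| =  283.78   excess kurtosis =  10.66
1/f surrogate    total |r| =      1574456   mean |r| =   78.72   excess kurtosis =   1.73
```

The uncomfortable midrange grating drives a response ~3.6× larger in
total magnitude than the natural-image surrogate. (Kurtosis is most
informative *across* the frequency tuning curve, where its minimum —
the least sparse response — falls at midrange frequencies; a grating
still yields high absolute kurtosis because only the orientation-matched
subpopulation responds.) Run the full curves with the CLI:

```sh
v1sparse simulate --sim 2 --n-neurons 20000 --seed 1 --out results/sim2
v1sparse simulate --sim 3 --n-neurons 20000 --seed 1 --out results/sim3   # CSF off
v1sparse simulate --sim 1 --n-neurons 20000 --n-surrogates 10 --seed 1    # model comparison
```

Simulation 2 (with CSF) yields total magnitude peaking at 2 c/deg for
both gratings and filtered noise, and the excess-kurtosis minimum at
midrange frequencies (3 c/deg for gratings) — the frequency band the
discomfort literature identifies as most aversive. Simulation 1 shows
that physiologically distributed tunings produce markedly sparser
responses to 1/f surrogates than the classic 16-filter grid (mean excess
kurtosis ≈ 12 vs ≈ 1 at this scale) with a mean absolute response about
60% of the grid model's.

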