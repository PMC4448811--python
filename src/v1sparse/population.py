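"""Population responses and their summary statistics.

Each model neuron responds with the inner product of the image luminance
and its receptive-field weights over the ±3σ2 support, the receptive field
centred at a randomly drawn pixel where the support fits inside the image.
Two statistics summarize the population vector per stimulus: total
magnitude (the sum of absolute responses) and excess kurtosis
(m4/m2² − 3, the population-sparseness index: a heavy-tailed,
zero-peaked response distribution — few strongly active neurons — has
high kurtosis, a broadly activated population has low kurtosis).

The sampler groups neurons by (frequency, orientation) and expresses every
phase as a combination of one even and one odd quadrature Gabor, so each
group needs only two cached weight patches and the window inner products
run through BLAS. The result is float64-identical to evaluating
``neuron_response`` per neuron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .stimuli import StimulusImage
from .v1_model import NeuronParams, TuningDistributions, gabor_weights, \
    make_neuron, sample_tunings

_CHUNK_PIXELS = 40_000_000  # window-matrix budget per BLAS call (~320 MB)

# quadrature patch cache, shared across stimuli of a run:
# (f, θ, σ1, σ2, gain, r, resolution, normalize) -> patch bundle
_patch_cache: dict = {}


@dataclass(frozen=True)
class PopulationResponse:
    """Signed scalar responses of a sampled neuron population."""

    responses: np.ndarray
    stimulus_id: str = ""
    seed: int | None = None

    def __post_init__(self):
        r = np.asarray(self.responses, dtype=float)
        if not np.all(np.isfinite(r)):
            raise ValueError("population response contains non-finite values")
        object.__setattr__(self, "responses", r)

    @property
    def n(self) -> int:
        return self.responses.size


@dataclass(frozen=True)
class ResponseSummary:
    """Per-stimulus summary: magnitude, mean |r|, excess kurtosis."""

    total_magnitude: float
    mean_abs: float
    excess_kurtosis: float
    signed_sum: float
    n: int


# ---------------------------------------------------------------------------
# single-neuron response (reference path)
# ---------------------------------------------------------------------------

def neuron_response(image: StimulusImage, neuron: NeuronParams,
                    normalize: str = "unit-energy") -> float:
    """Inner product of image and receptive-field weights at (x, y)."""
    if neuron.x is None or neuron.y is None:
        raise ValueError("neuron has no receptive-field centre")
    r = neuron.support_radius_px(image.resolution)
    h, w = image.pixels.shape
    if not (r <= neuron.x <= w - 1 - r and r <= neuron.y <= h - 1 - r):
        raise ValueError(
            f"receptive-field support (±{r} px) extends outside the image "
            f"at centre ({neuron.x}, {neuron.y})")
    weights = gabor_weights(neuron, image.resolution, normalize=normalize)
    window = image.pixels[neuron.y - r:neuron.y + r + 1,
                          neuron.x - r:neuron.x + r + 1]
    return float(np.vdot(weights, window))


# ---------------------------------------------------------------------------
# fast grouped sampler
# ---------------------------------------------------------------------------

def _quadrature_patches(f, theta, sigma1, sigma2, gain, r, resolution,
                        normalize):
    key = (round(f, 9), round(theta, 9), round(sigma1, 12), round(sigma2, 12),
           gain, r, resolution, normalize)
    hit = _patch_cache.get(key)
    if hit is not None:
        return hit
    even = NeuronParams(f, theta, 0.0, sigma1, sigma2, gain)
    odd = NeuronParams(f, theta, 270.0, sigma1, sigma2, gain)  # cos(x+270°)=sin
    gc = gabor_weights(even, resolution, patch_radius=r, normalize="raw")
    gs = gabor_weights(odd, resolution, patch_radius=r, normalize="raw")
    if normalize == "unit-energy":
        gc = gc - gc.mean()
        gs = gs - gs.mean()
    basis = np.stack([gc.ravel(), gs.ravel()], axis=1)
    gram = basis.T @ basis  # [[Ecc, Ecs], [Ecs, Ess]]
    bundle = (basis, gram)
    _patch_cache[key] = bundle
    return bundle


def clear_patch_cache() -> None:
    _patch_cache.clear()


def _draw_locations(u, v, r, size):
    """Map per-neuron uniform deviates to valid integer RF centres."""
    span = size - 2 * r
    x = r + np.minimum((u * span).astype(np.int64), span - 1)
    y = r + np.minimum((v * span).astype(np.int64), span - 1)
    return x, y


def place_and_respond(image: StimulusImage,
                      tunings,
                      n: int | None = None,
                      seed: int = 0,
                      location_seed: int | None = None,
                      normalize: str = "unit-energy",
                      stimulus_id: str = "",
                      return_neurons: bool = False):
    """Sample a population, place it at random valid locations, respond.

    ``tunings`` is either a :class:`TuningDistributions` (n tunings drawn
    with ``seed``), or a list of :class:`NeuronParams` used as a pool (each
    neuron draws a tuning uniformly from the pool; if the pool length
    equals n the pool is used in order, one tuning per neuron).

    Receptive-field centres are drawn uniformly over all pixels where the
    ±3σ2 support fits. The per-neuron-index location deviates come from
    ``location_seed`` (default: ``seed``), so two populations built with
    different tunings but the same ``location_seed`` are positionally
    paired neuron-for-neuron.
    """
    size_y, size_x = image.pixels.shape
    if size_y != size_x:
        raise ValueError("place_and_respond expects a square image")
    size = size_x

    if isinstance(tunings, TuningDistributions):
        if n is None:
            raise ValueError("n is required when sampling from distributions")
        neurons = sample_tunings(tunings, n, seed)
    else:
        pool = list(tunings)
        if not pool:
            raise ValueError("empty tuning pool")
        if n is None or n == len(pool):
            neurons = pool
            n = len(pool)
        else:
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, len(pool), size=n)
            neurons = [pool[i] for i in idx]

    loc_rng = np.random.default_rng(seed if location_seed is None
                                    else location_seed)
    uv = loc_rng.random((n, 2))

    freqs = np.array([nr.frequency for nr in neurons])
    thetas = np.array([nr.orientation for nr in neurons])
    phases = np.array([nr.phase for nr in neurons])
    s1 = np.array([nr.sigma1 for nr in neurons])
    s2 = np.array([nr.sigma2 for nr in neurons])
    gains = np.array([nr.gain for nr in neurons])
    radii = np.ceil(3.0 * s2 * image.resolution).astype(np.int64)

    too_big = radii > (size - 1) // 2
    if np.any(too_big):
        fbad = freqs[too_big].min()
        raise ValueError(
            f"image of {size} px cannot contain the ±3σ2 support of a "
            f"neuron preferring {fbad:g} c/deg "
            f"(needs {2 * radii[too_big].max() + 1} px)")

    responses = np.empty(n)
    xs = np.empty(n, dtype=np.int64)
    ys = np.empty(n, dtype=np.int64)
    swv_cache: dict[int, np.ndarray] = {}

    group_keys = np.stack([freqs, thetas, s1, s2, gains, radii], axis=1)
    _, inverse = np.unique(group_keys, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        sel = np.flatnonzero(inverse == g)
        i0 = sel[0]
        r = int(radii[i0])
        basis, gram = _quadrature_patches(
            freqs[i0], thetas[i0], s1[i0], s2[i0], gains[i0], r,
            image.resolution, normalize)
        x, y = _draw_locations(uv[sel, 0], uv[sel, 1], r, size)
        xs[sel], ys[sel] = x, y

        ph = np.radians(phases[sel])
        coef = np.stack([np.cos(ph), -np.sin(ph)], axis=1)  # (G, 2)
        if normalize == "unit-energy":
            nrm = np.sqrt(np.einsum("gi,ij,gj->g", coef, gram, coef))
        else:
            nrm = np.ones(sel.size)

        win = 2 * r + 1
        if win not in swv_cache:
            swv_cache[win] = sliding_window_view(image.pixels, (win, win))
        swv = swv_cache[win]
        chunk = max(1, _CHUNK_PIXELS // (win * win))
        for c0 in range(0, sel.size, chunk):
            cs = slice(c0, c0 + chunk)
            w = swv[y[cs] - r, x[cs] - r].reshape(-1, win * win)
            dots = w @ basis  # (chunk, 2)
            responses[sel[cs]] = (dots * coef[cs]).sum(axis=1) / nrm[cs]

    resp = PopulationResponse(responses, stimulus_id=stimulus_id, seed=seed)
    if return_neurons:
        placed = [NeuronParams(nr.frequency, nr.orientation, nr.phase,
                               nr.sigma1, nr.sigma2, nr.gain,
                               int(xs[i]), int(ys[i]))
                  for i, nr in enumerate(neurons)]
        return resp, placed
    return resp


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def total_magnitude(resp: PopulationResponse) -> float:
    """Σ|r|: the total response magnitude across the population."""
    if resp.n < 1:
        raise ValueError("empty population")
    return float(np.abs(resp.responses).sum())


def excess_kurtosis(resp) -> float:
    """Population excess kurtosis m4/m2² − 3; NaN for zero variance."""
    r = resp.responses if isinstance(resp, PopulationResponse) \
        else np.asarray(resp, dtype=float)
    if r.size < 4:
        raise ValueError("excess kurtosis needs at least 4 responses")
    if np.var(r) == 0:
        return float("nan")
    return float(stats.kurtosis(r, fisher=True, bias=True))


def summarize(resp: PopulationResponse) -> ResponseSummary:
    mag = total_magnitude(resp)
    return ResponseSummary(
        total_magnitude=mag,
        mean_abs=mag / resp.n,
        excess_kurtosis=excess_kurtosis(resp),
        signed_sum=float(resp.responses.sum()),
        n=resp.n,
    )


def response_histogram(resp: PopulationResponse, bins=101,
                       value_range=None) -> pd.DataFrame:
    """Normalized response histogram as (bin_centre, probability) rows."""
    if resp.n < 1:
        raise ValueError("empty population")
    counts, edges = np.histogram(resp.responses, bins=bins, range=value_range)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({
        "bin_centre": centres,
        "probability": counts / counts.sum(),
    })
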