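"""Shared fixtures and independent oracle helpers.

The oracle functions here are deliberately written from scratch (plain
loops / direct formulas) so they stay independent of the package's
vectorized code paths.
"""

import math

import numpy as np
import pytest

from v1sparse.stimuli import StimulusImage


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_surrogate():
    from v1sparse.stimuli import SurrogateNaturalSpec, make_surrogate_natural, \
        rescale_luminance
    return rescale_luminance(
        make_surrogate_natural(SurrogateNaturalSpec(beta=1.0, seed=99),
                               size=256, resolution=60.0))


def radial_average_amplitude(pixels, resolution, n_bins=60):
    """Radially averaged 2-D Fourier amplitude: (bin centre c/deg, mean |F|).

    Naive binning oracle; excludes the DC bin.
    """
    size = pixels.shape[0]
    amp = np.abs(np.fft.fft2(pixels))
    f1 = np.fft.fftfreq(size, d=1.0 / resolution)
    fx, fy = np.meshgrid(f1, f1, indexing="xy")
    fr = np.hypot(fx, fy).ravel()
    amp = amp.ravel()
    mask = fr > 0
    fr, amp = fr[mask], amp[mask]
    edges = np.linspace(0, resolution / 2, n_bins + 1)
    centres, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (fr >= lo) & (fr < hi)
        if sel.sum() > 0:
            centres.append(0.5 * (lo + hi))
            means.append(amp[sel].mean())
    return np.array(centres), np.array(means)


def brute_force_gabor_response(image: StimulusImage, frequency, orientation,
                               phase, sigma1, sigma2, x0, y0, radius,
                               normalize=True):
    """Pixel-by-pixel Gabor inner product, written directly from the
    receptive-field formula with explicit loops."""
    px = image.pixels
    res = image.resolution
    th = math.radians(orientation)
    ph = math.radians(phase)
    weights = []
    values = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            xd, yd = dx / res, dy / res  # degrees
            xp = xd * math.cos(th) - yd * math.sin(th)
            yp = xd * math.sin(th) + yd * math.cos(th)
            w = math.exp(-xp**2 / (2 * sigma1**2)
                         - yp**2 / (2 * sigma2**2)) \
                * math.cos(2 * math.pi * frequency * xp + ph)
            weights.append(w)
            values.append(px[y0 + dy, x0 + dx])
    weights = np.array(weights)
    if normalize:
        weights = weights - weights.mean()
        weights = weights / math.sqrt(float((weights**2).sum()))
    return float(np.dot(weights, np.array(values)))
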