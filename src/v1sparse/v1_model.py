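"""Gabor receptive fields and tuning-parameter sampling.

A model neuron is a Gabor function: a cosine carrier at preferred
frequency f (c/deg), orientation θ and phase ϕ, windowed by an elliptical
Gaussian envelope elongated 2:1 along the stripe direction,

    G(x, y) = A · exp(−x_p²/2σ1² − y_p²/2σ2²) · cos(2π f x_p + ϕ),
    x_p = x cosθ − y sinθ,   y_p = x sinθ + y cosθ.

Two envelope parametrizations are provided. The default fixes the spatial
frequency bandwidth at 1.4 octaves and the aspect ratio σ2/σ1 at 2, giving
σ1 = 0.41609/f degrees — self-similar receptive fields whose bandwidth in
octaves is frequency-independent. The ``"literal"`` mode uses the raw
constants σ1 = 7.81/f, σ2 = 15.61/f in image units; under any consistent
unit reading these give a far narrower (~0.07 octave) bandwidth and
receptive fields too large to place in a 1024-px image at low preferred
frequencies, so the bandwidth parametrization is the replication default.

Tunings are drawn either from physiology-shaped histograms (frequency
unimodal over midrange c/deg, orientation cardinally biased, phase
concentrated at 0/90/180/270) shipped as plain CSV tables, or from the
fixed 16-filter grid of the classic sparse-coding model (two frequencies ×
four orientations × two phases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

LITERAL_SIGMA1 = 7.81
LITERAL_SIGMA2 = 15.61
DEFAULT_BANDWIDTH_OCTAVES = 1.4
DEFAULT_ASPECT = 2.0
SUPPORT_RADIUS_SIGMAS = 3.0  # receptive-field support is ±3σ2


def sigma1_for_bandwidth(frequency: float,
                         bandwidth_octaves: float = DEFAULT_BANDWIDTH_OCTAVES
                         ) -> float:
    """Envelope σ1 (degrees) giving a half-amplitude frequency bandwidth.

    The Fourier transform of the Gabor is Gaussian in frequency with
    σ_f = 1/(2πσ1); a full bandwidth of b octaves at half amplitude means
    f·(2^b−1)/(2^b+1) = σ_f·√(2 ln 2).
    """
    r = (2.0**bandwidth_octaves - 1.0) / (2.0**bandwidth_octaves + 1.0)
    sigma_f = frequency * r / math.sqrt(2.0 * math.log(2.0))
    return 1.0 / (2.0 * math.pi * sigma_f)


def envelope_sigmas(frequency: float, mode: str = "bandwidth",
                    bandwidth_octaves: float = DEFAULT_BANDWIDTH_OCTAVES,
                    aspect: float = DEFAULT_ASPECT) -> tuple[float, float]:
    """(σ1, σ2) in degrees for a preferred frequency in c/deg."""
    if frequency <= 0:
        raise ValueError("preferred frequency must be positive")
    if mode == "bandwidth":
        s1 = sigma1_for_bandwidth(frequency, bandwidth_octaves)
        return s1, aspect * s1
    if mode == "literal":
        return LITERAL_SIGMA1 / frequency, LITERAL_SIGMA2 / frequency
    raise ValueError(f"unknown envelope mode {mode!r}")


@dataclass(frozen=True)
class NeuronParams:
    """One model neuron's tuning and (optionally) its RF centre in pixels."""

    frequency: float          # preferred spatial frequency, c/deg
    orientation: float        # preferred orientation, degrees
    phase: float              # phase, degrees
    sigma1: float             # envelope width along the carrier axis, degrees
    sigma2: float             # envelope width along the stripe axis, degrees
    gain: float = 1.0
    x: int | None = None      # RF centre column, pixels
    y: int | None = None      # RF centre row, pixels

    def support_radius_px(self, resolution: float) -> int:
        """Half-width in pixels of the ±3σ2 receptive-field support."""
        return int(math.ceil(SUPPORT_RADIUS_SIGMAS * self.sigma2 * resolution))


def make_neuron(frequency: float, orientation: float, phase: float,
                envelope_mode: str = "bandwidth", gain: float = 1.0,
                x: int | None = None, y: int | None = None) -> NeuronParams:
    s1, s2 = envelope_sigmas(frequency, envelope_mode)
    return NeuronParams(frequency, orientation, phase, s1, s2, gain, x, y)


# ---------------------------------------------------------------------------
# receptive-field weights
# ---------------------------------------------------------------------------

def gabor_weights(params: NeuronParams, resolution: float,
                  patch_radius: int | None = None,
                  normalize: str = "unit-energy") -> np.ndarray:
    """Receptive-field weight array on a square pixel grid.

    The grid is centred on the neuron (offsets in pixels, converted to
    degrees through ``resolution``) with half-width ``patch_radius``
    (default: the ±3σ2 support). ``normalize="unit-energy"`` subtracts the
    mean and scales to unit sum of squares, removing the DC response of
    cosine-phase Gabors and the 1/f² envelope-area scaling of raw weights;
    ``"raw"`` returns the literal Gabor values.
    """
    r = params.support_radius_px(resolution) if patch_radius is None \
        else int(patch_radius)
    if r < 1:
        raise ValueError("patch radius must be at least 1 pixel")
    off = np.arange(-r, r + 1) / resolution  # degrees
    x, y = np.meshgrid(off, off, indexing="xy")
    th = math.radians(params.orientation)
    xp = x * math.cos(th) - y * math.sin(th)
    yp = x * math.sin(th) + y * math.cos(th)
    env = np.exp(-xp**2 / (2 * params.sigma1**2)
                 - yp**2 / (2 * params.sigma2**2))
    w = params.gain * env * np.cos(
        2 * np.pi * params.frequency * xp + math.radians(params.phase))
    if normalize == "raw":
        return w
    if normalize == "unit-energy":
        w = w - w.mean()
        nrm = math.sqrt(float((w**2).sum()))
        if nrm == 0:
            raise ValueError("degenerate receptive field: zero energy")
        return w / nrm
    raise ValueError(f"unknown normalization {normalize!r}")


# ---------------------------------------------------------------------------
# tuning distributions
# ---------------------------------------------------------------------------

def _load_table(source, value_col: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(source)
    if df.shape[1] < 2:
        raise ValueError("tuning table needs two columns (bin, probability)")
    vals = df.iloc[:, 0].to_numpy(dtype=float)
    prob = df.iloc[:, 1].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError("empty tuning table")
    if np.any(prob < 0) or prob.sum() <= 0:
        raise ValueError("tuning table probabilities must be non-negative "
                         "and sum to a positive value")
    return vals, prob / prob.sum()


@dataclass(frozen=True)
class TuningDistributions:
    """Discrete sampling distributions over (frequency, orientation, phase).

    Each distribution is a table of bin centres and probabilities; draws
    return bin-centre values. Tables are plain two-column CSVs so digitized
    physiological histograms can be dropped in without code changes.
    """

    frequencies: np.ndarray
    freq_probs: np.ndarray
    orientations: np.ndarray
    ori_probs: np.ndarray
    phases: np.ndarray
    phase_probs: np.ndarray

    @classmethod
    def from_tables(cls, freq_table, ori_table, phase_table
                    ) -> "TuningDistributions":
        fv, fp = _load_table(freq_table, "frequency_cdeg")
        if np.any(fv <= 0):
            raise ValueError("frequency bins must be positive")
        ov, op = _load_table(ori_table, "orientation_deg")
        pv, pp = _load_table(phase_table, "phase_deg")
        return cls(fv, fp, ov, op, pv, pp)

    @classmethod
    def physiological(cls) -> "TuningDistributions":
        """The shipped physiology-shaped default tables."""
        data = resources.files("v1sparse") / "data"
        return cls.from_tables(
            str(data / "spatial_frequency_tuning.csv"),
            str(data / "orientation_tuning.csv"),
            str(data / "phase_tuning.csv"),
        )

    def sample(self, n: int, rng: np.random.Generator
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        f = rng.choice(self.frequencies, size=n, p=self.freq_probs)
        o = rng.choice(self.orientations, size=n, p=self.ori_probs)
        p = rng.choice(self.phases, size=n, p=self.phase_probs)
        return f, o, p


def sample_tunings(dist: TuningDistributions, n: int, seed: int,
                   envelope_mode: str = "bandwidth") -> list[NeuronParams]:
    """Draw n neurons' (f, θ, ϕ) independently from the distributions."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    fs, os_, ps = dist.sample(n, rng)
    return [make_neuron(f, o, p, envelope_mode) for f, o, p in zip(fs, os_, ps)]


# ---------------------------------------------------------------------------
# the fixed 16-filter configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldConfiguration:
    """The classic sparse-coding filter grid: 2 frequencies × 4 orientations
    × 2 phases = 16 tunings, frequencies given in cycles per image."""

    frequencies_cpi: tuple[float, ...] = (20.0, 40.0)
    orientations: tuple[float, ...] = (10.0, 55.0, 100.0, 145.0)
    phases: tuple[float, ...] = (0.0, 90.0)


def field_tunings(config: FieldConfiguration = FieldConfiguration(),
                  image_size: int = 1024,
                  resolution: float = 60.0,
                  envelope_mode: str = "bandwidth") -> list[NeuronParams]:
    """Full cross product of the fixed grid, converted to c/deg.

    Cycles per image divide by the image extent in degrees
    (size/resolution) to give cycles per degree.
    """
    degrees = image_size / resolution
    out = []
    for fc in config.frequencies_cpi:
        f = fc / degrees
        for o in config.orientations:
            for p in config.phases:
                out.append(make_neuron(f, o, p, envelope_mode))
    return out
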