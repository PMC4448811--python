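"""Stimulus synthesis and raster I/O.

All stimulus classes used by the model are generated here: sine gratings,
Gaussian noise spectrally shaped to a 1/f amplitude profile with a
raised-cosine peak at a chosen centre frequency, and 1/f^beta Gaussian
surrogates whose amplitude spectra match the statistics of natural scenes.
Images are plain 2-D luminance arrays carrying a spatial calibration
(pixels per degree of visual angle); the default calibration is one pixel
per arc minute (60 px/deg).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio

log = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 60.0  # pixels per degree: 1 px per arc minute
DEFAULT_SIZE = 1024


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusImage:
    """A 2-D luminance image with spatial calibration.

    Parameters
    ----------
    pixels
        2-D float array of luminance values (arbitrary linear units).
    resolution
        Pixels per degree of visual angle.
    """

    pixels: np.ndarray
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"stimulus must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("stimulus contains non-finite luminance values")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (pixels per degree)")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in cycles per degree."""
        return self.resolution / 2.0


@dataclass(frozen=True)
class GratingSpec:
    """Sine grating: frequency (c/deg), orientation/phase (deg), contrast."""

    frequency: float
    orientation: float = 0.0
    phase: float = 0.0
    contrast: float = 1.0
    mean_luminance: float = 128.0

    def validate(self, resolution: float) -> None:
        if self.frequency <= 0:
            raise ValueError("grating frequency must be positive")
        if self.frequency >= resolution / 2.0:
            raise ValueError(
                f"grating frequency {self.frequency} c/deg is at or above the "
                f"Nyquist limit {resolution / 2.0} c/deg for {resolution} px/deg"
            )
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Band-peaked 1/f noise: raised-cosine peak at ``centre_frequency``.

    ``peak_mode`` selects how the raised-cosine gain H combines with the
    1/f base profile: ``"literal"`` multiplies (amplitude ∝ H(f)/f, a
    band-limited spectrum), ``"additive"`` adds the peak on top of the 1/f
    floor (amplitude ∝ (1+H(f))/f).
    """

    centre_frequency: float
    T: float = 0.9
    beta_roll: float = 0.5
    log_base: float = math.e
    peak_mode: str = "literal"
    seed: int = 0
    mean_luminance: float = 128.0

    def validate(self, resolution: float) -> None:
        if not 0.0 < self.T <= 1.0:
            raise ValueError("T must lie in (0, 1]")
        if not 0.0 <= self.beta_roll <= 1.0:
            raise ValueError("roll-off factor must lie in [0, 1]")
        if not 0.0 < self.centre_frequency < resolution / 2.0:
            raise ValueError(
                f"centre frequency must lie in (0, {resolution / 2.0}) c/deg"
            )
        if self.peak_mode not in ("literal", "additive"):
            raise ValueError("peak_mode must be 'literal' or 'additive'")
        if self.log_base <= 0 or self.log_base == 1.0:
            raise ValueError("log_base must be positive and != 1")


@dataclass(frozen=True)
class SurrogateNaturalSpec:
    """1/f^beta Gaussian surrogate for a natural image.

    ``beta`` is the spectral exponent of the radial amplitude falloff.
    If None, it is drawn uniformly from [0.8, 1.2] — the range spanned by
    natural scenes — using ``seed``.
    """

    beta: float | None = None
    seed: int = 0
    mean_luminance: float = 128.0

    def resolve_beta(self, rng: np.random.Generator) -> float:
        if self.beta is None:
            return float(rng.uniform(0.8, 1.2))
        if not 0.0 <= self.beta <= 2.0:
            raise ValueError("spectral exponent must lie in [0, 2]")
        return float(self.beta)


# ---------------------------------------------------------------------------
# frequency lattice helpers
# ---------------------------------------------------------------------------

def frequency_grid(size: int, resolution: float) -> np.ndarray:
    """Radial spatial frequency (c/deg) at every 2-D FFT bin.

    Uses the standard FFT lattice: bin spacing resolution/size c/deg, with
    the half-open Nyquist convention of ``np.fft.fftfreq``.
    """
    f1 = np.fft.fftfreq(size, d=1.0 / resolution)
    fx, fy = np.meshgrid(f1, f1, indexing="xy")
    return np.hypot(fx, fy)


# ---------------------------------------------------------------------------
# gratings
# ---------------------------------------------------------------------------

def make_grating(
    spec: GratingSpec,
    size: int = DEFAULT_SIZE,
    resolution: float = DEFAULT_RESOLUTION,
    snap_to_grid: bool = True,
) -> StimulusImage:
    """Generate a full-field sine grating.

    Orientation 0° modulates along x (vertical stripes); the carrier axis
    rotates clockwise with increasing orientation, matching the receptive-
    field convention. By default the (frequency, orientation) pair is
    snapped to the nearest integer-cycle Fourier lattice point so the
    grating is exactly periodic over the image and spectrally pure; the
    snap moves the frequency by at most half a cycle per image width.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    spec.validate(resolution)

    th = math.radians(spec.orientation)
    # target cycle counts across the image along x and y
    kx = spec.frequency * math.cos(th) * size / resolution
    ky = spec.frequency * math.sin(th) * size / resolution
    if snap_to_grid:
        kx, ky = round(kx), round(ky)
        if kx == 0 and ky == 0:
            # frequency below half a cycle per image: keep the dominant axis
            kx, ky = (1, 0) if abs(math.cos(th)) >= abs(math.sin(th)) else (0, 1)

    idx = np.arange(size)
    x, y = np.meshgrid(idx, idx, indexing="xy")
    carrier = np.cos(
        2.0 * np.pi * (kx * x + ky * y) / size + math.radians(spec.phase)
    )
    px = spec.mean_luminance * (1.0 + spec.contrast * carrier)
    return StimulusImage(px, resolution)


# ---------------------------------------------------------------------------
# raised radial cosine gain
# ---------------------------------------------------------------------------

def raised_cosine_gain(
    f,
    f0: float,
    T: float = 0.9,
    beta_roll: float = 0.5,
    log_base: float = math.e,
):
    """Raised-cosine gain H(f) in the log-frequency domain.

    Flat at T for |log f − log f0| ≤ (1−β)/(2T), a half-cosine roll-off out
    to (1+β)/(2T), zero beyond. ``log_base`` sets the logarithm used for
    the frequency axis (natural log by default).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("raised_cosine_gain requires f > 0 (log undefined)")
    if f0 <= 0:
        raise ValueError("centre frequency f0 must be positive")
    scale = math.log(log_base)
    d = np.abs(np.log(f) - math.log(f0)) / scale
    lo = (1.0 - beta_roll) / (2.0 * T)
    hi = (1.0 + beta_roll) / (2.0 * T)
    h = np.zeros_like(d)
    flat = d <= lo
    h[flat] = T
    trans = (d > lo) & (d <= hi)
    h[trans] = (T / 2.0) * (
        1.0 + np.cos(np.pi * T / beta_roll * (d[trans] - lo))
    )
    return h if h.ndim else float(h)


# ---------------------------------------------------------------------------
# spectrally shaped Gaussian noise
# ---------------------------------------------------------------------------

def _shape_white_noise(
    amplitude_profile: np.ndarray,
    size: int,
    resolution: float,
    seed: int,
    mean_luminance: float,
) -> StimulusImage:
    """White Gaussian noise reshaped to a target radial amplitude profile.

    The profile multiplies the FFT coefficients bin by bin, so the ratio of
    output to input amplitude equals the applied gain exactly at every
    non-DC bin. The DC coefficient is set so the image mean equals
    ``mean_luminance`` (the 1/f profile is undefined at f=0).
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    spec = np.fft.fft2(white) * amplitude_profile
    spec[0, 0] = mean_luminance * size * size
    out = np.fft.ifft2(spec).real
    return StimulusImage(out, resolution)


def make_filtered_noise(
    spec: NoiseSpec,
    size: int = DEFAULT_SIZE,
    resolution: float = DEFAULT_RESOLUTION,
) -> StimulusImage:
    """1/f-amplitude Gaussian noise with a raised-cosine spectral peak."""
    spec.validate(resolution)
    f = frequency_grid(size, resolution)
    with np.errstate(divide="ignore"):
        base = np.where(f > 0, 1.0 / np.where(f > 0, f, 1.0), 0.0)
    nz = f > 0
    h = np.zeros_like(f)
    h[nz] = raised_cosine_gain(
        f[nz], spec.centre_frequency, spec.T, spec.beta_roll, spec.log_base
    )
    if spec.peak_mode == "literal":
        gain = base * h
    else:  # additive peak on the 1/f floor
        gain = base * (1.0 + h)
    return _shape_white_noise(gain, size, resolution, spec.seed, spec.mean_luminance)


def make_surrogate_natural(
    spec: SurrogateNaturalSpec,
    size: int = DEFAULT_SIZE,
    resolution: float = DEFAULT_RESOLUTION,
) -> StimulusImage:
    """Gaussian surrogate with natural-scene 1/f^beta amplitude spectrum."""
    rng = np.random.default_rng(spec.seed)
    beta = spec.resolve_beta(rng)
    f = frequency_grid(size, resolution)
    gain = np.zeros_like(f)
    nz = f > 0
    gain[nz] = f[nz] ** (-beta)
    # noise drawn from the same stream after the (possible) beta draw
    noise_seed_rng = rng
    white = noise_seed_rng.standard_normal((size, size))
    spectrum = np.fft.fft2(white) * gain
    spectrum[0, 0] = spec.mean_luminance * size * size
    out = np.fft.ifft2(spectrum).real
    return StimulusImage(out, resolution)


# ---------------------------------------------------------------------------
# luminance scaling
# ---------------------------------------------------------------------------

def rescale_luminance(
    image: StimulusImage, lo: float = 1.0, hi: float = 255.0
) -> StimulusImage:
    """Affine-map pixel values so min → lo and max → hi.

    A constant image has no contrast to scale; it maps to the midpoint of
    the target range by convention.
    """
    px = image.pixels
    mn, mx = float(px.min()), float(px.max())
    if mx == mn:
        out = np.full_like(px, (lo + hi) / 2.0)
    else:
        out = lo + (px - mn) * (hi - lo) / (mx - mn)
    return replace(image, pixels=out)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(
    image: StimulusImage, path: str | Path, bit_depth: int = 16
) -> None:
    """Write a stimulus as grayscale PNG or PGM (8- or 16-bit).

    Pixel values are quantized linearly to the full range of the stored bit
    depth. The spatial calibration, which raster formats cannot carry, goes
    to a ``<name>.<ext>.json`` sidecar together with the scaling needed to
    recover the original luminance values.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    px = image.pixels
    mn, mx = float(px.min()), float(px.max())
    vmax = 2**bit_depth - 1
    scaled = np.zeros_like(px) if mx == mn else (px - mn) / (mx - mn) * vmax
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(path, np.round(scaled).astype(dtype))
    meta = {"resolution": image.resolution, "min": mn, "max": mx,
            "bit_depth": bit_depth}
    _sidecar_path(path).write_text(json.dumps(meta))


def read_image(
    path: str | Path, resolution: float | None = None
) -> StimulusImage:
    """Read a grayscale raster image; undo write_image quantization if a
    sidecar is present.

    Colour input is averaged to grayscale with a logged warning. The
    resolution comes from the sidecar, or the ``resolution`` argument, or
    the 60 px/deg default, in that order.
    """
    path = Path(path)
    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim == 3:
        log.warning("non-grayscale image %s: averaging %d channels", path,
                    arr.shape[2])
        arr = arr.mean(axis=2)
    side = _sidecar_path(path)
    res = resolution if resolution is not None else DEFAULT_RESOLUTION
    if side.exists():
        meta = json.loads(side.read_text())
        res = resolution if resolution is not None else meta["resolution"]
        vmax = 2 ** meta["bit_depth"] - 1
        if meta["max"] > meta["min"]:
            arr = meta["min"] + arr / vmax * (meta["max"] - meta["min"])
        else:
            arr = np.full_like(arr, meta["min"])
    return StimulusImage(arr, res)


def read_vanhateren_iml(
    path: str | Path,
    shape: tuple[int, int] = (1024, 1536),
    byteorder: str = ">",
    resolution: float = DEFAULT_RESOLUTION,
) -> StimulusImage:
    """Read a headerless 16-bit raw luminance image (van Hateren-style .iml).

    The format is a bare dump of ``shape[0]*shape[1]`` unsigned 16-bit
    integers, big-endian by default; neither the byte order nor any
    luminance scaling is standardized in raster metadata, so both are
    caller-configurable. Not required anywhere in the pipeline — the 1/f^β
    surrogate generator is the default natural-image source.
    """
    path = Path(path)
    data = np.fromfile(path, dtype=np.dtype(byteorder + "u2"))
    expected = shape[0] * shape[1]
    if data.size != expected:
        raise ValueError(
            f"{path}: expected {expected} 16-bit samples for shape {shape}, "
            f"found {data.size}"
        )
    return StimulusImage(data.reshape(shape).astype(float), resolution)
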