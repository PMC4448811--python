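"""Stimulus generators: gratings, band-peaked noise, 1/f surrogates, I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from v1sparse.stimuli import (GratingSpec, NoiseSpec, SurrogateNaturalSpec,
                              StimulusImage, frequency_grid, make_grating,
                              make_filtered_noise, make_surrogate_natural,
                              raised_cosine_gain, rescale_luminance,
                              read_image, write_image, read_vanhateren_iml)
from conftest import radial_average_amplitude


# ---------------------------------------------------------------------------
# raised radial cosine gain
# ---------------------------------------------------------------------------

class TestRaisedCosine:
    def test_flat_branch_equals_T_at_centre(self):
        assert raised_cosine_gain(3.0, 3.0) == pytest.approx(0.9, abs=0)

    def test_transition_midpoint_is_half_T(self):
        # |ln f − ln f0| = 1/(2T) puts the cosine argument at π/2
        f = 3.0 * math.exp(1.0 / (2 * 0.9))
        assert raised_cosine_gain(f, 3.0) == pytest.approx(0.45, abs=1e-12)

    def test_stop_band_is_zero(self):
        f = 3.0 * math.exp(0.9)  # 0.9 > (1+β)/(2T) = 0.8333
        assert raised_cosine_gain(f, 3.0) == 0.0

    @pytest.mark.parametrize("T,beta", [(0.9, 0.5), (0.7, 0.3), (1.0, 1.0)])
    def test_branches_agree_at_boundaries(self, T, beta):
        lo = (1 - beta) / (2 * T)
        hi = (1 + beta) / (2 * T)
        f_lo, f_hi = math.exp(lo), math.exp(hi)
        # flat formula vs transition formula at the inner boundary
        trans_at_lo = (T / 2) * (1 + math.cos(math.pi * T / beta * 0.0))
        assert abs(trans_at_lo - T) < 1e-9
        assert raised_cosine_gain(f_lo, 1.0, T, beta) == pytest.approx(
            T, abs=1e-9)
        # transition formula vs stop band at the outer boundary
        trans_at_hi = (T / 2) * (1 + math.cos(math.pi * T / beta * (hi - lo)))
        assert abs(trans_at_hi) < 1e-9
        assert raised_cosine_gain(f_hi, 1.0, T, beta) == pytest.approx(
            0.0, abs=1e-9)

    def test_log_base_rescales_band(self):
        # with base-10 logs, the transition midpoint sits at f0·10^(1/2T)
        f = 2.0 * 10 ** (1.0 / (2 * 0.9))
        assert raised_cosine_gain(f, 2.0, log_base=10.0) == pytest.approx(
            0.45, abs=1e-12)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            raised_cosine_gain(0.0, 3.0)
        with pytest.raises(ValueError):
            raised_cosine_gain(3.0, -1.0)


# ---------------------------------------------------------------------------
# gratings
# ---------------------------------------------------------------------------

class TestGrating:
    def test_zero_contrast_is_constant_mean(self):
        g = make_grating(GratingSpec(4.0, contrast=0.0, mean_luminance=99.0),
                         size=64, resolution=60.0)
        assert np.allclose(g.pixels, 99.0)

    def test_deterministic(self):
        spec = GratingSpec(2.0, orientation=30.0, phase=45.0)
        a = make_grating(spec, 128, 60.0)
        b = make_grating(spec, 128, 60.0)
        assert np.array_equal(a.pixels, b.pixels)

    def test_fft_peak_at_requested_frequency(self):
        g = make_grating(GratingSpec(4.0), size=512, resolution=60.0)
        amp = np.abs(np.fft.fft2(g.pixels))
        amp[0, 0] = 0.0
        iy, ix = np.unravel_index(np.argmax(amp), amp.shape)
        f1 = np.fft.fftfreq(512, d=1 / 60.0)
        # dominant peak on the x-axis at the bin nearest 4 c/deg
        assert f1[iy] == 0.0
        assert abs(abs(f1[ix]) - 4.0) <= 60.0 / 512

    @pytest.mark.parametrize("freq,ori", [(4.0, 0.0), (2.0, 90.0),
                                          (3.0, 37.0), (0.5, 120.0)])
    def test_band_purity(self, freq, ori):
        """≥99% of non-DC spectral energy in the bins adjacent to (f0, θ)."""
        g = make_grating(GratingSpec(freq, orientation=ori), 256, 60.0)
        amp2 = np.abs(np.fft.fft2(g.pixels)) ** 2
        amp2[0, 0] = 0.0
        iy, ix = np.unravel_index(np.argmax(amp2), amp2.shape)
        neighbourhood = 0.0
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                neighbourhood += amp2[(iy + dy) % 256, (ix + dx) % 256]
                # conjugate-symmetric partner
                neighbourhood += amp2[(-iy + dy) % 256, (-ix + dx) % 256]
        assert neighbourhood / amp2.sum() >= 0.99

    def test_mean_and_contrast(self):
        g = make_grating(GratingSpec(2.0, contrast=0.5, mean_luminance=100.0),
                         512, 60.0)
        assert g.pixels.mean() == pytest.approx(100.0, rel=1e-6)
        assert g.pixels.max() == pytest.approx(150.0, rel=1e-3)
        assert g.pixels.min() == pytest.approx(50.0, rel=1e-3)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_grating(GratingSpec(30.0), 128, 60.0)
        with pytest.raises(ValueError):
            make_grating(GratingSpec(-1.0), 128, 60.0)


# ---------------------------------------------------------------------------
# spectrally shaped noise
# ---------------------------------------------------------------------------

class TestFilteredNoise:
    def test_applied_gain_is_exact(self):
        """output/input Fourier amplitude equals the radial gain bin-by-bin."""
        spec = NoiseSpec(3.0, seed=7)
        size, res = 128, 60.0
        out = make_filtered_noise(spec, size, res)
        white = np.random.default_rng(7).standard_normal((size, size))
        fin = np.fft.fft2(white)
        fout = np.fft.fft2(out.pixels)
        f = frequency_grid(size, res)
        nz = f > 0
        gain = np.zeros_like(f)
        gain[nz] = raised_cosine_gain(f[nz], 3.0) / f[nz]
        ratio = np.abs(fout[nz]) / np.abs(fin[nz])
        assert np.allclose(ratio, gain[nz], atol=1e-8)

    def test_seed_determinism_and_distinctness(self):
        a = make_filtered_noise(NoiseSpec(3.0, seed=1), 64, 60.0)
        b = make_filtered_noise(NoiseSpec(3.0, seed=1), 64, 60.0)
        c = make_filtered_noise(NoiseSpec(3.0, seed=2), 64, 60.0)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_radial_peak_at_centre_frequency(self):
        out = make_filtered_noise(NoiseSpec(3.0, seed=5), 512, 60.0)
        centres, amps = radial_average_amplitude(out.pixels, 60.0, n_bins=60)
        # enhancement relative to the pure 1/f profile
        rel = np.where(centres > 0, amps * centres, 0.0)
        peak = centres[np.argmax(rel)]
        # the raised-cosine pass band of a 3 c/deg peak is ~[2.3, 4.0] c/deg
        assert 2.0 <= peak <= 4.2
        near_f0 = rel[np.argmin(np.abs(centres - 3.0))]
        assert near_f0 >= 0.8 * rel.max()
        assert near_f0 > rel[np.argmin(np.abs(centres - 1.0))]
        assert near_f0 > rel[np.argmin(np.abs(centres - 8.0))]

    def test_additive_mode_keeps_low_frequency_floor(self):
        lit = make_filtered_noise(NoiseSpec(6.0, seed=3, peak_mode="literal"),
                                  256, 60.0)
        add = make_filtered_noise(NoiseSpec(6.0, seed=3, peak_mode="additive"),
                                  256, 60.0)
        c_l, a_l = radial_average_amplitude(lit.pixels, 60.0)
        c_a, a_a = radial_average_amplitude(add.pixels, 60.0)
        low = c_l < 1.0  # far below the pass band of a 6 c/deg peak
        assert a_l[low].max() < 1e-8 * a_l.max()
        assert a_a[low].max() > 1e-3 * a_a.max()

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            NoiseSpec(3.0, T=0.0).validate(60.0)
        with pytest.raises(ValueError):
            NoiseSpec(3.0, beta_roll=1.5).validate(60.0)
        with pytest.raises(ValueError):
            NoiseSpec(40.0).validate(60.0)
        with pytest.raises(ValueError):
            NoiseSpec(3.0, peak_mode="bogus").validate(60.0)


# ---------------------------------------------------------------------------
# 1/f^beta surrogates
# ---------------------------------------------------------------------------

def spectral_slope(pixels, resolution, f_lo=1.0, f_hi=15.0):
    centres, amps = radial_average_amplitude(pixels, resolution, n_bins=80)
    sel = (centres >= f_lo) & (centres <= f_hi) & (amps > 0)
    slope = np.polyfit(np.log(centres[sel]), np.log(amps[sel]), 1)[0]
    return slope


class TestSurrogateNatural:
    @pytest.mark.parametrize("beta", [0.8, 1.0, 1.2])
    def test_spectral_slope_recovery(self, beta):
        img = make_surrogate_natural(SurrogateNaturalSpec(beta=beta, seed=11),
                                     512, 60.0)
        assert spectral_slope(img.pixels, 60.0) == pytest.approx(
            -beta, abs=0.05)

    def test_beta_zero_is_white(self):
        img = make_surrogate_natural(SurrogateNaturalSpec(beta=0.0, seed=4),
                                     512, 60.0)
        assert abs(spectral_slope(img.pixels, 60.0)) < 0.05

    def test_default_beta_draws_in_natural_range(self):
        for seed in range(12):
            rng = np.random.default_rng(seed)
            b = SurrogateNaturalSpec(seed=seed).resolve_beta(rng)
            assert 0.8 <= b <= 1.2

    def test_determinism(self):
        a = make_surrogate_natural(SurrogateNaturalSpec(seed=8), 64, 60.0)
        b = make_surrogate_natural(SurrogateNaturalSpec(seed=8), 64, 60.0)
        assert np.array_equal(a.pixels, b.pixels)


# ---------------------------------------------------------------------------
# luminance rescaling
# ---------------------------------------------------------------------------

class TestRescale:
    def test_range_mapping(self, rng):
        img = StimulusImage(rng.normal(2.0, 3.0, (32, 32)))
        out = rescale_luminance(img)
        assert out.pixels.min() == pytest.approx(1.0)
        assert out.pixels.max() == pytest.approx(255.0)

    def test_idempotent(self, rng):
        img = StimulusImage(rng.normal(size=(16, 16)))
        once = rescale_luminance(img)
        twice = rescale_luminance(once)
        assert np.allclose(once.pixels, twice.pixels)

    def test_constant_maps_to_midpoint(self):
        out = rescale_luminance(StimulusImage(np.full((8, 8), 7.0)))
        assert np.allclose(out.pixels, 128.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(a=st.floats(0.01, 100.0), b=st.floats(-50.0, 50.0),
           seed=st.integers(0, 100))
    def test_affine_invariance(self, a, b, seed):
        px = np.random.default_rng(seed).normal(size=(12, 12))
        base = rescale_luminance(StimulusImage(px))
        shifted = rescale_luminance(StimulusImage(a * px + b))
        assert np.allclose(base.pixels, shifted.pixels, atol=1e-8)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

class TestImageIO:
    @pytest.mark.parametrize("ext,depth", [("png", 8), ("png", 16),
                                           ("pgm", 8), ("pgm", 16)])
    def test_round_trip_quantized(self, tmp_path, ext, depth):
        img = make_grating(GratingSpec(3.0), 64, 60.0)
        path = tmp_path / f"g.{ext}"
        write_image(img, path, bit_depth=depth)
        back = read_image(path)
        tol = (img.pixels.max() - img.pixels.min()) / (2**depth - 1)
        assert back.resolution == img.resolution
        assert np.allclose(back.pixels, img.pixels, atol=tol)

    def test_16bit_dynamic_range_edges(self, tmp_path):
        px = np.zeros((4, 4))
        px[0, 0] = 65535.0
        path = tmp_path / "edges.pgm"
        write_image(StimulusImage(px), path, bit_depth=16)
        back = read_image(path)
        assert back.pixels.min() == 0.0
        assert back.pixels.max() == 65535.0

    def test_quantization_is_stable_on_requantize(self, tmp_path):
        img = make_surrogate_natural(SurrogateNaturalSpec(seed=3), 32, 60.0)
        p1 = tmp_path / "a.png"
        write_image(img, p1, bit_depth=16)
        first = read_image(p1)
        p2 = tmp_path / "b.png"
        write_image(first, p2, bit_depth=16)
        second = read_image(p2)
        assert np.allclose(first.pixels, second.pixels, atol=1e-6 *
                           np.ptp(first.pixels))

    def test_colour_input_converted_with_warning(self, tmp_path, caplog):
        import imageio.v3 as iio
        arr = np.zeros((8, 8, 3), dtype=np.uint8)
        arr[..., 0] = 30
        arr[..., 1] = 60
        arr[..., 2] = 90
        path = tmp_path / "rgb.png"
        iio.imwrite(path, arr)
        with caplog.at_level("WARNING"):
            img = read_image(path)
        assert np.allclose(img.pixels, 60.0)
        assert any("grayscale" in r.message for r in caplog.records)

    def test_unreadable_file_errors(self, tmp_path):
        with pytest.raises(Exception):
            read_image(tmp_path / "missing.png")

    def test_vanhateren_raw_decoding(self, tmp_path):
        """Synthetic headerless 16-bit raw file with known integers."""
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 65536, size=(1024, 1536), dtype=np.uint16)
        path = tmp_path / "synthetic.iml"
        truth.astype(">u2").tofile(path)
        img = read_vanhateren_iml(path)
        assert img.pixels.shape == (1024, 1536)
        assert np.array_equal(img.pixels, truth.astype(float))

    def test_vanhateren_wrong_size_errors(self, tmp_path):
        path = tmp_path / "short.iml"
        np.zeros(100, dtype=">u2").tofile(path)
        with pytest.raises(ValueError, match="expected"):
            read_vanhateren_iml(path)
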