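"""Spatial convolution (direct vs FFT), median, temporal kernels and LTI."""

import numpy as np
import pytest

from stimsynth import filtering as flt


def rand_frame(rng, h=16, w=16):
    return rng.random((h, w, 3))


class TestSpatialKernels:
    def test_gaussian_unit_sum(self):
        k = flt.make_spatial_kernel("gaussian", sigma=1.5)
        assert abs(k.weights.sum() - 1.0) < 1e-12
        assert k.weights.shape[0] % 2 == 1

    def test_dog_zero_integral(self):
        k = flt.make_spatial_kernel("dog", sigma_center=1.0, sigma_surround=2.0)
        assert abs(k.weights.sum()) < 1e-12

    def test_dog_requires_wider_surround(self):
        with pytest.raises(ValueError):
            flt.make_spatial_kernel("dog", sigma_center=2.0, sigma_surround=1.0)

    def test_freq_lowpass_passes_dc(self):
        k = flt.make_spatial_kernel("freq_lowpass", cutoff=0.1)
        assert k.transfer_grid((16, 16))[0, 0] == pytest.approx(1.0)

    def test_freq_highpass_blocks_dc(self):
        k = flt.make_spatial_kernel("freq_highpass", cutoff=0.1)
        assert k.transfer_grid((16, 16))[0, 0] == pytest.approx(0.0)

    def test_gabor_is_enveloped_carrier(self):
        k = flt.make_spatial_kernel("gabor", sigma=2.0, frequency=0.25, phase=0.0)
        c = k.weights.shape[0] // 2
        assert k.weights[c, c] == pytest.approx(1.0)  # cos(0) at the center
        assert abs(k.weights[0, 0]) < 1e-3

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            flt.make_spatial_kernel("gaussian", sigma=0.0)


class TestSpatialConvolution:
    def test_identity_kernel(self, rng):
        f = rand_frame(rng)
        k = flt.SpatialKernel("spatial", np.array([[1.0]]))
        assert np.array_equal(flt.convolve_direct(f, k), f)

    def test_dog_maps_constant_frame_to_zero(self):
        f = np.full((20, 20, 3), 0.6)
        k = flt.make_spatial_kernel("dog", sigma_center=1.0, sigma_surround=2.0)
        out = flt.convolve_direct(f, k)
        # zero-integral kernel: interior (away from the zero-padded border)
        r = k.weights.shape[0] // 2
        assert np.max(np.abs(out[r:-r, r:-r])) < 1e-12

    def test_box_stamps_impulse(self):
        f = np.zeros((9, 9, 3))
        f[4, 4, :] = 1.0
        k = flt.SpatialKernel("spatial", np.ones((3, 3)))
        out = flt.convolve_direct(f, k)
        assert np.all(out[3:6, 3:6, 0] == 1.0)
        assert out[:, :, 0].sum() == pytest.approx(9.0)

    def test_fft_equals_direct(self, rng):
        f = rand_frame(rng, 64, 64)
        k = flt.SpatialKernel("spatial", rng.standard_normal((9, 9)))
        d = flt.convolve_direct(f, k)
        g = flt.convolve_fft(f, k)
        assert np.max(np.abs(d - g)) < 1e-10

    def test_unit_transfer_is_identity(self, rng):
        f = rand_frame(rng)
        k = flt.make_spatial_kernel("freq_custom", transfer=lambda rho: np.ones_like(rho))
        assert np.max(np.abs(flt.convolve_fft(f, k) - f)) < 1e-12

    def test_tiny_cutoff_lowpass_flattens(self, rng):
        f = rand_frame(rng, 32, 32)
        k = flt.make_spatial_kernel("freq_lowpass", cutoff=0.005)
        out = flt.convolve_fft(f, k)
        assert out.var() < 0.05 * f.var()

    def test_direct_rejects_frequency_kernel(self, rng):
        k = flt.make_spatial_kernel("freq_lowpass", cutoff=0.1)
        with pytest.raises(ValueError):
            flt.convolve_direct(rand_frame(rng), k)

    def test_linearity_and_shift_invariance(self, rng):
        k = flt.SpatialKernel("spatial", rng.standard_normal((5, 5)))
        a, b = rand_frame(rng), rand_frame(rng)
        lhs = flt.convolve_direct(2.0 * a + 0.5 * b, k)
        rhs = 2.0 * flt.convolve_direct(a, k) + 0.5 * flt.convolve_direct(b, k)
        assert np.max(np.abs(lhs - rhs)) < 1e-12
        # shift invariance away from the zero-padded border
        shifted = np.roll(a, 3, axis=1)
        out_shift = flt.convolve_direct(shifted, k)
        shift_out = np.roll(flt.convolve_direct(a, k), 3, axis=1)
        assert np.max(np.abs(out_shift[4:-4, 6:-6] - shift_out[4:-4, 6:-6])) < 1e-12


class TestMedian:
    def test_window_one_is_identity(self, rng):
        f = rand_frame(rng)
        assert np.array_equal(flt.median_filter(f, 1), f)

    def test_removes_single_outlier(self):
        f = np.full((9, 9, 3), 0.4)
        f[4, 4, :] = 1.0
        assert np.all(flt.median_filter(f, 3) == 0.4)

    def test_even_window_rejected(self, rng):
        with pytest.raises(ValueError):
            flt.median_filter(rand_frame(rng), 4)


class TestTemporalKernels:
    def test_rectangular_taps(self):
        k = flt.make_temporal_kernel("rectangular", 5)
        assert np.allclose(k.taps, 0.2)

    def test_hann_3_is_central_spike(self):
        k = flt.make_temporal_kernel("hann", 3)
        assert np.allclose(k.taps, [0.0, 1.0, 0.0])

    @pytest.mark.parametrize("kind", ["triangular", "hamming", "hann", "exponential"])
    def test_windows_unit_sum(self, kind):
        k = flt.make_temporal_kernel(kind, 7)
        assert k.taps.sum() == pytest.approx(1.0)

    def test_cell_dog_zero_sum_biphasic(self):
        k = flt.make_temporal_kernel("cell_dog", 24)
        assert abs(k.taps.sum()) < 1e-12
        assert k.taps.max() > 0 and k.taps.min() < 0

    def test_exponential_base_validated(self):
        with pytest.raises(ValueError):
            flt.make_temporal_kernel("exponential", 5, a=1.2)


class TestTemporalConvolution:
    def test_delta_kernel_is_identity_stream(self, rng):
        k = flt.TemporalKernel([1.0])
        conv = flt.TemporalConvolver(k)
        for _ in range(4):
            f = rand_frame(rng, 8, 8)
            assert np.array_equal(flt.temporal_convolve(conv, k, f), f)

    def test_rectangular_on_constant_stream_reaches_one(self):
        L = 4
        k = flt.make_temporal_kernel("rectangular", L)
        conv = flt.TemporalConvolver(k)
        ones = np.ones((4, 4, 3))
        outs = [conv.step(ones) for _ in range(L + 2)]
        for t, out in enumerate(outs):
            expected = min(t + 1, L) / L  # zero prehistory ramps up
            assert np.allclose(out, expected)

    def test_exponential_step_response_partial_geometric_sums(self):
        a, L = 0.5, 6
        k = flt.make_temporal_kernel("exponential", L, a=a)
        norm = sum(a ** i for i in range(L))
        conv = flt.TemporalConvolver(k)
        ones = np.ones((2, 2, 3))
        for t in range(L + 3):
            out = conv.step(ones)
            expected = sum(a ** i for i in range(min(t + 1, L))) / norm
            assert np.allclose(out, expected, atol=1e-12)

    def test_hold_prestim_starts_full(self):
        k = flt.make_temporal_kernel("rectangular", 4)
        conv = flt.TemporalConvolver(k, prestim="hold")
        out = conv.step(np.ones((2, 2, 3)))
        assert np.allclose(out, 1.0)

    def test_causality_future_frames_do_not_matter(self, rng):
        k = flt.make_temporal_kernel("exponential", 5, a=0.7)
        stream = [rand_frame(rng, 4, 4) for _ in range(6)]
        perturbed = [f.copy() for f in stream]
        perturbed[4] += 10.0
        c1, c2 = flt.TemporalConvolver(k), flt.TemporalConvolver(k)
        for t in range(4):
            o1 = c1.step(stream[t])
            o2 = c2.step(perturbed[t])
            assert np.array_equal(o1, o2)


class TestLTI:
    def test_single_pole_geometric_impulse_response(self):
        sys = flt.LTISystem([0.5], [1.0], direct=0.0)
        impulse = np.zeros((1, 1, 3))
        impulse[:] = 1.0
        zero = np.zeros((1, 1, 3))
        outs = [flt.lti_step(sys, impulse)[0, 0, 0]]
        for _ in range(4):
            outs.append(flt.lti_step(sys, zero)[0, 0, 0])
        assert outs == pytest.approx([0.0, 0.5, 0.25, 0.125, 0.0625])

    def test_impulse_response_closed_form(self):
        sys = flt.LTISystem([0.6 + 0.2j, 0.6 - 0.2j], [1 - 0.5j, 1 + 0.5j], direct=0.3)
        h = sys.impulse_response(8)
        assert h[0] == pytest.approx(0.3)
        z, c = 0.6 + 0.2j, 1 - 0.5j
        for k in range(1, 8):
            assert h[k] == pytest.approx(2 * np.real(c * z ** k))

    def test_zero_input_gives_zero_output(self):
        sys = flt.LTISystem([0.9], [2.0], direct=1.0)
        zero = np.zeros((3, 3, 3))
        for _ in range(5):
            assert np.all(flt.lti_step(sys, zero) == 0.0)

    def test_unstable_pole_rejected_at_construction(self):
        with pytest.raises(ValueError, match="unstable"):
            flt.LTISystem([1.0], [1.0])

    def test_lti_matches_direct_convolution_for_exponential_sums(self, rng):
        sys = flt.LTISystem([0.7, 0.3], [0.8, -0.2], direct=0.5)
        L = 40
        kernel = flt.TemporalKernel(sys.impulse_response(L))
        conv = flt.TemporalConvolver(kernel)
        sys.reset()
        for _ in range(25):
            f = rand_frame(rng, 8, 8)
            assert np.max(np.abs(sys.step(f) - conv.step(f))) < 1e-8


class TestFitExponentials:
    def test_recovers_single_exponential(self):
        k = flt.make_temporal_kernel("exponential", 12, a=0.6)
        sys, residual = flt.fit_exponentials(k, 1)
        assert residual < 1e-8
        assert abs(sys.poles[0] - 0.6) < 1e-6

    def test_recovers_two_real_exponentials(self):
        taps = 0.7 * 0.8 ** np.arange(16) + 0.3 * 0.4 ** np.arange(16)
        sys, residual = flt.fit_exponentials(flt.TemporalKernel(taps), 2)
        assert residual < 1e-6
        assert sorted(np.round(np.abs(sys.poles), 4)) == pytest.approx([0.4, 0.8], abs=1e-4)

    def test_rectangular_window_fits_marginal_pole_and_is_rejected(self):
        # a truncated constant is "representable" only by z = 1, which the
        # stability contract rejects with the offending magnitude reported
        k = flt.make_temporal_kernel("rectangular", 10)
        with pytest.raises(ValueError, match="unstable"):
            flt.fit_exponentials(k, 1)

    def test_non_representable_kernel_reports_nonzero_residual(self):
        k = flt.make_temporal_kernel("hamming", 12)
        sys, residual = flt.fit_exponentials(k, 1)
        assert residual > 1e-3  # reported honestly, caller decides

    def test_growing_kernel_rejected_as_unstable(self):
        taps = 1.3 ** np.arange(10)
        with pytest.raises(ValueError, match="unstable"):
            flt.fit_exponentials(flt.TemporalKernel(taps), 1)

    def test_requires_enough_taps(self):
        with pytest.raises(ValueError):
            flt.fit_exponentials(flt.TemporalKernel([1.0, 0.5, 0.25]), 2)
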