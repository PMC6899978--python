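"""LTI gradient-system model: loading, synthesis, filtering, operators."""

import io

import numpy as np
import pytest
from scipy.fft import fft, ifft

from girfpulse import (TimeGrid, apply_girf, average_girfs, cutoff_frequency,
                       filter_matrix, ideal_girf, load_girf, save_girf,
                       synthetic_girf)
from girfpulse.girf import NO_CUTOFF, TransferFunction, _padded_length


@pytest.fixture
def grid():
    return TimeGrid(6.4e-6, 65)


class TestTransferFunction:
    def test_nonuniform_axis_rejected(self):
        f = np.array([0.0, 1.0, 3.0])
        with pytest.raises(ValueError):
            TransferFunction(f, np.ones(3, complex))

    def test_sample_zero_outside_band(self, lowpass_girf):
        vals = lowpass_girf.sample(np.array([1e9, -1e9]))
        assert np.all(vals == 0)


class TestSyntheticGirf:
    def test_magnitude_at_cutoff_and_dc(self):
        tf = synthetic_girf(3000.0, delay_s=10e-6, order=2, delta_f=100.0)
        h0 = tf.sample(np.array([0.0]))[0]
        hc = tf.sample(np.array([3000.0]))[0]
        assert abs(h0) == pytest.approx(1.0, abs=1e-12)
        assert abs(hc) == pytest.approx(2 ** -0.5, rel=1e-6)

    def test_zero_delay_real_even(self):
        tf = synthetic_girf(3000.0, delay_s=0.0)
        assert np.max(np.abs(tf.h.imag)) == 0
        np.testing.assert_allclose(tf.h, tf.h[::-1], rtol=1e-12)

    def test_cutoff_beyond_band_rejected(self):
        with pytest.raises(ValueError):
            synthetic_girf(60e3, bandwidth_hz=50e3)

    def test_sinusoid_scaled_and_delayed(self):
        """A narrowband tone through an LTI filter comes back scaled by
        |H(f0)| and shifted by the group delay."""
        f0 = 2500.0
        delay = 64e-6  # ten raster samples
        grid = TimeGrid(6.4e-6, 2049)
        tf = synthetic_girf(3750.0, delay_s=delay, delta_f=10.0)
        t = (np.arange(grid.n_intervals) + 0.5) * grid.tau
        sigma = np.ptp(t) / 12
        x = np.sin(2 * np.pi * f0 * t) * np.exp(-((t - t.mean()) / sigma) ** 2)
        y = apply_girf(x, tf, grid)
        mag = np.abs(tf.sample(np.array([f0]))[0])
        x_shifted = np.sin(2 * np.pi * f0 * (t - delay)) \
            * np.exp(-((t - delay - t.mean()) / sigma) ** 2)
        sl = slice(50, -20)  # interior, away from the window edges
        assert np.max(np.abs(y[sl] - mag * x_shifted[sl])) < 0.02


class TestApplyGirf:
    def test_identity_response(self, rng, grid):
        tf = ideal_girf()
        x = rng.normal(0, 1e-2, grid.n_intervals)
        y = apply_girf(x, tf, grid)
        assert np.max(np.abs(y - x)) <= 1e-12 * np.max(np.abs(x))

    def test_zero_input(self, lowpass_girf, grid):
        y = apply_girf(np.zeros(grid.n_intervals), lowpass_girf, grid)
        assert np.all(y == 0)

    def test_matches_time_domain_convolution(self, rng, grid, lowpass_girf):
        """Frequency-domain filtering equals direct convolution with the
        impulse response (inverse transform of H on the padded grid)."""
        n = grid.n_intervals
        x = rng.normal(0, 1e-2, n)
        npad = _padded_length(n)
        freqs = np.fft.fftfreq(npad, d=grid.tau)
        h_t = np.real(ifft(lowpass_girf.sample(freqs)))
        # circular convolution on the padded grid, truncated
        y_direct = np.real(ifft(fft(np.concatenate([x, np.zeros(npad - n)]))
                                * fft(h_t)))[:n]
        y = apply_girf(x, lowpass_girf, grid)
        assert np.max(np.abs(y - y_direct)) <= 1e-8 * max(np.max(np.abs(y)), 1)

    def test_linearity(self, rng, grid, lowpass_girf):
        x1 = rng.normal(0, 1e-2, grid.n_intervals)
        x2 = rng.normal(0, 1e-2, grid.n_intervals)
        lhs = apply_girf(2.5 * x1 - 0.7 * x2, lowpass_girf, grid)
        rhs = (2.5 * apply_girf(x1, lowpass_girf, grid)
               - 0.7 * apply_girf(x2, lowpass_girf, grid))
        assert np.max(np.abs(lhs - rhs)) <= 1e-10

    def test_shift_invariance_interior(self, grid, lowpass_girf):
        """Shifting a compact input well inside the window shifts the
        output identically (edge-safe region)."""
        n = grid.n_intervals
        x = np.zeros(n)
        x[10:14] = 1.0
        y1 = apply_girf(x, lowpass_girf, grid)
        y2 = apply_girf(np.roll(x, 6), lowpass_girf, grid)
        np.testing.assert_allclose(np.roll(y1, 6)[18:40], y2[18:40],
                                   atol=1e-9)


class TestFilterMatrix:
    def test_identity_matrix_for_unit_response(self, grid):
        op = filter_matrix(ideal_girf(), grid, cache=False)
        np.testing.assert_allclose(op.matrix, np.eye(grid.n_intervals),
                                   atol=1e-12)

    def test_columns_are_impulse_responses(self, grid, lowpass_girf):
        op = filter_matrix(lowpass_girf, grid, cache=False)
        for j in (0, 7, grid.n_intervals - 1):
            e = np.zeros(grid.n_intervals)
            e[j] = 1.0
            np.testing.assert_allclose(op.matrix[:, j],
                                       apply_girf(e, lowpass_girf, grid),
                                       atol=1e-10)

    def test_agrees_with_apply_girf_on_random_input(self, rng, grid,
                                                    lowpass_girf):
        op = filter_matrix(lowpass_girf, grid, cache=False)
        x = rng.normal(0, 1, grid.n_intervals)
        np.testing.assert_allclose(op.apply(x),
                                   apply_girf(x, lowpass_girf, grid),
                                   atol=1e-10)

    def test_adjoint_identity(self, rng, grid, lowpass_girf):
        op = filter_matrix(lowpass_girf, grid, cache=False)
        x = rng.normal(0, 1, grid.n_intervals)
        y = rng.normal(0, 1, grid.n_intervals)
        assert np.dot(op.apply(x), y) == pytest.approx(
            np.dot(x, op.apply_transpose(y)), rel=1e-12)

    def test_caching_does_not_change_results(self, rng, grid, lowpass_girf):
        x = rng.normal(0, 1, grid.n_intervals)
        y1 = filter_matrix(lowpass_girf, grid).apply(x)
        y2 = filter_matrix(lowpass_girf, grid).apply(x)
        np.testing.assert_array_equal(y1, y2)


class TestCutoff:
    def test_ideal_has_no_cutoff(self):
        assert cutoff_frequency(ideal_girf()) is NO_CUTOFF

    def test_closed_form_butterworth(self):
        # |H| = (1 + (f/fc)^(2n))^(-1/2) = 1/2  <=>  f = fc * 3^(1/(2n))
        for order in (1, 2, 4):
            tf = synthetic_girf(3000.0, order=order, delta_f=5.0)
            expected = 3000.0 * 3.0 ** (1.0 / (2 * order))
            assert cutoff_frequency(tf) == pytest.approx(expected, rel=1e-4)

    def test_synthetic_lowpass_emulates_measured_cutoffs(self):
        """Stand-ins for the measured y/z-axis responses have their
        half-magnitude points at the declared cutoffs."""
        for fc, expect in ((4200.0, 4200.0 * 3 ** 0.125),
                           (3750.0, 3750.0 * 3 ** 0.125)):
            tf = synthetic_girf(fc, order=4, delta_f=76.3)
            assert cutoff_frequency(tf) == pytest.approx(expect, rel=2e-3)


class TestAveraging:
    def test_mean_of_identical_is_identity(self, lowpass_girf):
        out = average_girfs([lowpass_girf, lowpass_girf])
        np.testing.assert_allclose(out.h, lowpass_girf.h)

    def test_mean_of_one_and_zero(self):
        f = np.arange(-5, 6) * 100.0
        a = TransferFunction(f, np.ones(11, complex))
        b = TransferFunction(f, np.zeros(11, complex))
        out = average_girfs([a, b])
        np.testing.assert_allclose(out.h, 0.5)

    def test_axis_mismatch_rejected(self, lowpass_girf):
        other = synthetic_girf(3000.0, delta_f=250.0)
        with pytest.raises(ValueError):
            average_girfs([lowpass_girf, other])


class TestGirfIO:
    def test_csv_round_trip(self, lowpass_girf):
        buf = io.StringIO()
        save_girf(buf, lowpass_girf)
        buf.seek(0)
        tf = load_girf(buf)
        np.testing.assert_array_equal(tf.f, lowpass_girf.f)
        np.testing.assert_array_equal(tf.h, lowpass_girf.h)

    def test_missing_imaginary_column_warns(self, caplog):
        text = "f_Hz,H_re\n-100.0,1.0\n0.0,1.0\n100.0,1.0\n"
        with caplog.at_level("WARNING"):
            tf = load_girf(io.StringIO(text))
        assert np.all(tf.h.imag == 0)
        assert any("imaginary" in r.message for r in caplog.records)

    def test_hermitian_symmetry_enforced(self):
        # asymmetric tabulated response gets symmetrized on load
        text = ("f_Hz,H_re,H_im\n-100.0,0.8,0.2\n0.0,1.0,0.0\n"
                "100.0,1.0,-0.4\n")
        tf = load_girf(io.StringIO(text))
        assert tf.h[2] == pytest.approx(np.conj(tf.h[0]))

    def test_mapping_source(self):
        f = np.arange(-5, 6) * 50.0
        h = np.exp(-2j * np.pi * f * 1e-5)
        tf = load_girf({"f_Hz": f, "H": h}, label="Hz")
        np.testing.assert_allclose(tf.h, h)
        assert tf.label == "Hz"

    def test_mat_container(self, tmp_path, lowpass_girf):
        from scipy.io import savemat
        path = tmp_path / "girf.mat"
        savemat(path, {"f_Hz": lowpass_girf.f,
                       "H_re": lowpass_girf.h.real,
                       "H_im": lowpass_girf.h.imag})
        tf = load_girf(str(path))
        np.testing.assert_allclose(tf.f, lowpass_girf.f)
        np.testing.assert_allclose(tf.h, lowpass_girf.h, atol=1e-12)
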