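"""Wavelet closed forms, oracle equivalence, and transform properties."""

import numpy as np
import pytest

from wavemi.cwt import (
    FrequencyGrid,
    MotherWavelet,
    Scalogram,
    bump_fourierdomain,
    cwt_forward,
    cwt_inverse,
    cwt_oracle,
    mexican_hat_timedomain,
    morlet_timedomain,
)


class TestClosedForms:
    def test_morlet_pointwise(self):
        sigma = 1.0
        assert morlet_timedomain(np.array([0.0]), sigma)[0] == pytest.approx(1 + 0j)
        assert abs(morlet_timedomain(np.array([sigma]), sigma)[0]) == \
            pytest.approx(np.exp(-0.5))
        # pure-oscillation limit: real part at t = 1/4 is cos(pi/2) = 0
        assert morlet_timedomain(np.array([0.25]), 1e9)[0].real == \
            pytest.approx(0.0, abs=1e-12)

    def test_mexican_hat_pointwise_and_admissibility(self):
        sigma = 1.0
        t = np.linspace(-40, 40, 400001)
        assert mexican_hat_timedomain(np.array([0.0]), sigma)[0] == 1.0
        assert mexican_hat_timedomain(np.array([sigma, -sigma]), sigma) == \
            pytest.approx([0.0, 0.0], abs=1e-15)
        integral = np.trapezoid(mexican_hat_timedomain(t, sigma), t)
        assert abs(integral) < 1e-6

    def test_morlet_mean_small_at_default_sigma(self):
        t = np.linspace(-40, 40, 400001)
        mean = np.trapezoid(morlet_timedomain(t, 1.0), t)
        assert abs(mean) < 1e-3

    def test_bump_pointwise(self):
        mu, sigma = 5.0, 0.6
        assert bump_fourierdomain(np.array([mu]), mu, sigma)[0] == 1.0
        edges = np.array([mu - sigma, mu + sigma, mu + 2 * sigma, 0.0])
        assert np.all(bump_fourierdomain(edges, mu, sigma) == 0.0)
        assert bump_fourierdomain(np.array([mu + sigma / 2]), mu, sigma)[0] == \
            pytest.approx(np.exp(-1.0 / 3.0))

    def test_bump_compact_support_is_exact_zero(self):
        mu, sigma = 5.0, 0.6
        sw = np.linspace(-2, 12, 2001)
        vals = bump_fourierdomain(sw, mu, sigma)
        outside = (sw <= mu - sigma) | (sw >= mu + sigma)
        assert np.all(vals[outside] == 0.0)
        assert np.all(vals[~outside] > 0.0)

    @pytest.mark.parametrize("func", [morlet_timedomain, mexican_hat_timedomain])
    def test_nonpositive_sigma_rejected(self, func):
        with pytest.raises(ValueError):
            func(np.zeros(3), 0.0)


class TestOracleEquivalence:
    def test_fast_path_matches_riemann_sum_on_chirp(self, wavelet):
        fs = 250.0
        t = np.arange(250) / fs  # 1 s chirp, 5 -> 25 Hz
        x = np.sin(2 * np.pi * (5 * t + 10 * t**2))
        freqs = [8.0, 12.0, 20.0, 30.0] if wavelet.kind == "bump" else \
            list(np.arange(6.0, 31.0, 2.0))
        sc = cwt_forward(x, fs, FrequencyGrid(np.array(freqs)), wavelet,
                         keep_complex=True)
        for i, f in enumerate(freqs):
            reference = cwt_oracle(x, fs, f, wavelet)
            err = np.abs(reference - sc.coeffs[i]).max() / np.abs(reference).max()
            assert err < 1e-6, f"{wavelet.kind} at {f} Hz: {err}"

    def test_oracle_zero_signal(self, wavelet):
        out = cwt_oracle(np.zeros(100), 250.0, 10.0, wavelet)
        assert np.allclose(out, 0.0)

    def test_oracle_delta_sifting(self):
        """Impulse at t0: coefficient at shift m is psi((t0-m*dt)/s) * dt/s,
        checked at shifts whose wavelet support excludes the boundaries."""
        fs, t0_idx = 250.0, 250
        x = np.zeros(500)
        x[t0_idx] = 1.0
        wav = MotherWavelet("morlet")
        freq = 20.0
        s = wav.scale_for(freq)  # support half-width 100 samples
        coeffs = cwt_oracle(x, fs, freq, wav)
        m = np.arange(210, 291)
        expected = morlet_timedomain((t0_idx - m) / fs / s, wav.sigma) / (fs * s)
        assert np.allclose(coeffs[m], expected, atol=1e-12)


class TestForward:
    def test_zero_signal_gives_zero_scalogram(self, tone_500):
        _, fs = tone_500
        sc = cwt_forward(np.zeros(200), fs, FrequencyGrid.linear(5, 15, step=1.0),
                         MotherWavelet("morlet"))
        assert np.all(sc.values == 0.0)

    def test_tone_peaks_on_its_grid_row(self, tone_500):
        x, fs = tone_500
        grid = FrequencyGrid.linear(5, 15, step=0.2)
        sc = cwt_forward(x, fs, grid, MotherWavelet("morlet"))
        peak_row = sc.values.mean(axis=1).argmax()
        assert abs(grid.freqs[peak_row] - 10.0) <= 0.2 + 1e-9

    @pytest.mark.parametrize("tone", [8.0, 10.0, 13.0, 20.0, 30.0])
    def test_scale_frequency_consistency(self, tone):
        fs = 250.0
        t = np.arange(500) / fs
        x = np.sin(2 * np.pi * tone * t)
        grid = FrequencyGrid.linear(6, 34, step=1.0)
        for kind in ("morlet", "mexican_hat"):
            sc = cwt_forward(x, fs, grid, MotherWavelet(kind))
            peak = grid.freqs[sc.values.mean(axis=1).argmax()]
            assert abs(peak - tone) <= 1.0 + 1e-9, kind

    def test_linearity_of_complex_coefficients(self):
        fs = 250.0
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 300))
        grid = FrequencyGrid.linear(8, 30, step=2.0)
        wav = MotherWavelet("morlet")
        cx = cwt_forward(x, fs, grid, wav, keep_complex=True).coeffs
        cy = cwt_forward(y, fs, grid, wav, keep_complex=True).coeffs
        cxy = cwt_forward(x + y, fs, grid, wav, keep_complex=True).coeffs
        assert np.allclose(cxy, cx + cy, atol=1e-10)

    def test_magnitude_shift_equivariance(self):
        fs = 250.0
        rng = np.random.default_rng(1)
        x = rng.standard_normal(400)
        shift = 50
        grid = FrequencyGrid.linear(8, 13, step=1.0)
        wav = MotherWavelet("morlet")
        a = cwt_forward(x, fs, grid, wav).values
        b = cwt_forward(np.roll(x, shift), fs, grid, wav).values
        # compare away from the boundary columns the mirror pad touches
        margin = 150
        assert np.allclose(a[:, margin:-margin - shift],
                           b[:, margin + shift:-margin], rtol=1e-3, atol=1e-6)

    def test_above_nyquist_rejected(self, tone_500):
        x, fs = tone_500
        with pytest.raises(ValueError, match="Nyquist"):
            cwt_forward(x, fs, FrequencyGrid.linear(10, 200, step=10.0),
                        MotherWavelet("morlet"))

    def test_pywt_cross_check_morlet_row_shape(self):
        """Independent library route: the magnitude profile of a chirp row
        agrees with pywt's complex-Morlet CWT up to a constant factor."""
        pywt = pytest.importorskip("pywt")
        fs = 250.0
        t = np.arange(500) / fs
        x = np.sin(2 * np.pi * (5 * t + 5 * t**2))  # 5 -> 25 Hz chirp
        sigma = 1.0
        freq = 10.0
        ours = cwt_forward(x, fs, FrequencyGrid(np.array([freq])),
                           MotherWavelet("morlet", sigma)).values[0]
        wav_name = f"cmor{2 * sigma**2}-1.0"
        scale = pywt.frequency2scale(wav_name, freq / fs)
        theirs = np.abs(pywt.cwt(x, [scale], wav_name,
                                 sampling_period=1 / fs)[0][0])
        interior = slice(100, 400)
        corr = np.corrcoef(ours[interior], theirs[interior])[0, 1]
        assert corr > 0.999


class TestInverse:
    def test_tone_reconstruction(self):
        fs = 250.0
        t = np.arange(500) / fs
        x = np.sin(2 * np.pi * 10 * t)
        for kind in ("morlet", "mexican_hat", "bump"):
            sc = cwt_forward(x, fs, FrequencyGrid.log(2, 50, 64),
                             MotherWavelet(kind), keep_complex=True)
            rec = cwt_inverse(sc)
            assert np.corrcoef(rec, x)[0, 1] > 0.95, kind

    def test_bandpassed_noise_reconstruction(self):
        from scipy.signal import butter, sosfiltfilt
        fs = 250.0
        rng = np.random.default_rng(5)
        sos = butter(4, [8, 30], btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(500))
        sc = cwt_forward(x, fs, FrequencyGrid.log(2, 50, 64),
                         MotherWavelet("morlet"), keep_complex=True)
        assert np.corrcoef(cwt_inverse(sc), x)[0, 1] > 0.9

    def test_zero_scalogram_gives_zero_signal(self):
        sc = cwt_forward(np.zeros(100), 250.0, FrequencyGrid.log(2, 50, 32),
                         MotherWavelet("morlet"), keep_complex=True)
        assert np.allclose(cwt_inverse(sc), 0.0)

    def test_sparse_grid_warns(self, tone_500):
        x, fs = tone_500
        sc = cwt_forward(x, fs, FrequencyGrid.log(2, 50, 6),
                         MotherWavelet("morlet"), keep_complex=True)
        with pytest.warns(RuntimeWarning, match="sparse"):
            cwt_inverse(sc)

    def test_magnitude_only_scalogram_rejected(self, tone_500):
        x, fs = tone_500
        sc = cwt_forward(x, fs, FrequencyGrid.log(2, 50, 32),
                         MotherWavelet("morlet"))
        with pytest.raises(ValueError, match="complex"):
            cwt_inverse(sc)


class TestTypes:
    def test_grid_validation(self):
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([3.0, 2.0]))
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([1.0, 1.0, 2.0]))

    def test_wavelet_validation(self):
        with pytest.raises(ValueError):
            MotherWavelet("haar")
        with pytest.raises(ValueError):
            MotherWavelet("morlet", sigma=-1.0)
        with pytest.raises(ValueError):
            MotherWavelet("bump", sigma=6.0, mu=5.0)  # support crosses zero

    def test_scalogram_shape_checked(self):
        with pytest.raises(ValueError):
            Scalogram("C3", np.array([1.0, 2.0]), np.arange(3) / 10.0,
                      np.zeros((3, 3)), MotherWavelet("morlet"))
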