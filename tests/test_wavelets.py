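"""Morlet family construction, edge validity, and the four spectral metrics
against closed-form / simulation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megprog import wavelets as wv


class TestFamily:
    @pytest.mark.parametrize("step,expected", [(0.05, 121), (0.25, 25),
                                               (0.1, 61)])
    def test_frequency_count(self, step, expected):
        fam = wv.build_wavelet_family(1, 64, 0.35, step, 250)
        assert fam.n_freqs == expected

    def test_log_grid_spacing(self):
        fam = wv.build_wavelet_family(1, 64, 0.35, 0.05, 250)
        assert np.allclose(np.diff(np.log2(fam.foi)), 0.05, atol=1e-9)
        assert (np.diff(fam.foi) > 0).all()

    def test_aliasing_rejected(self):
        with pytest.raises(wv.WaveletError):
            wv.build_wavelet_family(1, 130, 0.35, 0.05, 250)

    def test_kernel_half_power_bandwidth(self):
        """|H| drops to 1/sqrt(2) at the half-power halfwidth, and is close
        to 1/sqrt(2) at the octave band edges f*2**(+-b/2)."""
        fam = wv.build_wavelet_family(1, 64, 0.35, 0.05, 250)
        fi = int(np.argmin(abs(fam.foi - 10)))
        f = fam.foi[fi]
        n = 1 << 18
        mag = np.abs(np.fft.fft(fam.kernels[fi], n))
        freqs = np.fft.fftfreq(n, 1 / 250)
        peak = mag.max()

        def gain(at):
            return mag[np.argmin(abs(freqs - at))] / peak

        hw = fam.sigma_f[fi] * np.sqrt(np.log(2))
        assert gain(f + hw) == pytest.approx(1 / np.sqrt(2), abs=0.01)
        assert gain(f - hw) == pytest.approx(1 / np.sqrt(2), abs=0.01)
        for edge in (f * 2 ** 0.175, f * 2 ** -0.175):
            assert 0.55 < gain(edge) < 0.85   # asymmetry of the linear-f Gaussian

    def test_unit_peak_gain(self):
        """A unit complex exponential at the centre frequency comes back with
        unit coefficient amplitude (away from the edges)."""
        fam = wv.build_wavelet_family(4, 32, 0.35, 0.5, 250)
        fi = 1
        f = fam.foi[fi]
        t = np.arange(4000) / 250
        sig = np.cos(2 * np.pi * f * t)[None, None, :]
        coeffs, valid = wv.convolve_frequency(sig, fam, fi)
        # cosine = half-amplitude analytic exponential
        assert np.abs(coeffs[0, 0, valid]).mean() == pytest.approx(0.5,
                                                                   rel=0.02)


class TestConvolution:
    def test_frequency_selectivity(self):
        fam = wv.build_wavelet_family(4, 40, 0.35, 0.25, 250)
        t = np.arange(2500) / 250
        sig = np.cos(2 * np.pi * 10.0 * t)[None, None, :]
        coeffs, valid = wv.convolve_epochs(sig, fam)
        mean_amp = np.array([np.abs(coeffs[0, 0, fi, valid[fi]]).mean()
                             if valid[fi].any() else 0.0
                             for fi in range(fam.n_freqs)])
        assert fam.foi[np.argmax(mean_amp)] == pytest.approx(10.0, rel=0.05)

    def test_zero_signal(self):
        fam = wv.build_wavelet_family(4, 40, 0.35, 0.5, 250)
        coeffs, _ = wv.convolve_epochs(np.zeros((1, 2, 1000)), fam)
        assert np.abs(coeffs).max() < 1e-12

    def test_edge_invalidation_halfwidth(self):
        """Validity mask excludes exactly the kernel truncation halfwidth at
        both epoch edges; a frequency whose halfwidth exceeds half the epoch
        is flagged unusable (1 Hz on 10 s epochs at the default bandwidth)."""
        fam = wv.build_wavelet_family(1, 64, 0.35, 0.05, 250)
        n = 2500                                 # 10 s at 250 Hz
        fi = int(np.argmin(abs(fam.foi - 2.0)))  # usable low frequency
        sig = np.random.default_rng(0).standard_normal((1, 1, n))
        _, valid = wv.convolve_frequency(sig, fam, fi)
        h = fam.valid_halfwidth[fi]
        assert not valid[:h].any() and not valid[n - h:].any()
        assert valid[h:n - h].all()
        assert not wv.usable_frequencies(fam, n)[0]      # 1 Hz flagged

    def test_all_unusable_rejected(self):
        fam = wv.build_wavelet_family(1, 2, 0.35, 0.5, 250)
        with pytest.raises(wv.WaveletError):
            wv.convolve_epochs(np.zeros((1, 1, 100)), fam)


class TestPower:
    def test_white_noise_flat_density(self, rng):
        """White noise of variance sigma^2 has one-sided density
        2 sigma^2 / fs across the whole grid."""
        sigma = 1.7
        sig = sigma * rng.standard_normal((8, 2, 5000))
        fam = wv.build_wavelet_family(2, 64, 0.35, 0.1, 250)
        t = wv.compute_spectral_tensors(sig, fam, metrics=("power",))
        expected = 2 * sigma ** 2 / 250
        assert np.nanmean(t.psd) == pytest.approx(expected, rel=0.05)
        assert np.nanstd(np.nanmean(t.psd, axis=0)) < 0.15 * expected

    def test_sinusoid_integrated_power(self):
        """Hz-integrated power across the spectral peak recovers a^2/2."""
        a, f0 = 1.3, 16.0
        t = np.arange(5000) / 250
        sig = (a * np.cos(2 * np.pi * f0 * t))[None, None, :]
        fam = wv.build_wavelet_family(8, 32, 0.35, 0.02, 250)
        ten = wv.compute_spectral_tensors(sig, fam, metrics=("power",))
        integ = np.trapezoid(ten.psd[0], fam.foi)
        assert integ == pytest.approx(a ** 2 / 2, rel=0.10)

    def test_quadratic_scaling(self, rng):
        sig = rng.standard_normal((2, 2, 2000))
        fam = wv.build_wavelet_family(4, 32, 0.35, 0.5, 250)
        t1 = wv.compute_spectral_tensors(sig, fam, metrics=("power",))
        t2 = wv.compute_spectral_tensors(2 * sig, fam, metrics=("power",))
        assert np.allclose(t2.psd, 4 * t1.psd, rtol=1e-12)


class TestCovariance:
    def test_identical_sensors(self, rng):
        x = rng.standard_normal((2, 1, 2000))
        sig = np.concatenate([x, x], axis=1)
        fam = wv.build_wavelet_family(4, 32, 0.35, 0.5, 250)
        t = wv.compute_spectral_tensors(sig, fam, metrics=("cov",))
        for fi in range(fam.n_freqs):
            c = t.cov[fi]
            assert c[0, 1] == pytest.approx(c[0, 0], rel=1e-9)

    def test_independent_sensors_decorrelate(self, rng):
        sig = rng.standard_normal((4, 2, 4000))
        fam = wv.build_wavelet_family(4, 32, 0.35, 0.5, 250)
        t = wv.compute_spectral_tensors(sig, fam, metrics=("cov",))
        for fi in range(fam.n_freqs):
            c = t.cov[fi]
            r = c[0, 1] / np.sqrt(c[0, 0] * c[1, 1])
            # effective n is below n_obs (smoothing); generous 10x bound
            assert abs(r) < 10 / np.sqrt(t.n_obs[fi])

    def test_psd_gram(self, rng):
        sig = rng.standard_normal((2, 5, 1500))
        fam = wv.build_wavelet_family(4, 32, 0.35, 0.5, 250)
        t = wv.compute_spectral_tensors(sig, fam, metrics=("cov",))
        for fi in range(fam.n_freqs):
            w = np.linalg.eigvalsh(t.cov[fi])
            assert w.min() >= -1e-10 * np.trace(t.cov[fi])

    def test_congruence_under_mixing(self, rng):
        """cov(W x) = W cov(x) W^T for a linear sensor mixing W."""
        sig = rng.standard_normal((2, 3, 2000))
        w = rng.standard_normal((3, 3))
        mixed = np.einsum("ij,ejn->ein", w, sig)
        fam = wv.build_wavelet_family(8, 16, 0.35, 0.5, 250)
        t1 = wv.compute_spectral_tensors(sig, fam, metrics=("cov",))
        t2 = wv.compute_spectral_tensors(mixed, fam, metrics=("cov",))
        for fi in range(fam.n_freqs):
            assert np.allclose(t2.cov[fi], w @ t1.cov[fi] @ w.T, rtol=1e-8,
                               atol=1e-12)


def _two_sensor_tensors(x, y, fs=250.0, f_lo=8.0, f_hi=12.0,
                        metrics=("dwpli",)):
    sig = np.stack([x, y], axis=1)
    fam = wv.build_wavelet_family(f_lo, f_hi, 0.35, 0.5, fs)
    return wv.compute_spectral_tensors(sig, fam, metrics=metrics), fam


class TestDwpli:
    def test_perfect_quarter_cycle_lag(self):
        t = np.arange(4000) / 250
        x = np.cos(2 * np.pi * 10 * t)[None, :]
        y = np.sin(2 * np.pi * 10 * t)[None, :]
        ten, fam = _two_sensor_tensors(x, y, f_lo=10, f_hi=10.5)
        assert ten.dwpli[0][0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_identical_signals_missing(self, rng):
        x = rng.standard_normal((2, 3000))
        ten, _ = _two_sensor_tensors(x, x.copy(), f_lo=10, f_hi=10.5)
        assert np.isnan(ten.dwpli[0][0, 1])

    def test_independent_noise_debiased(self, rng):
        x = rng.standard_normal((4, 5000))
        y = rng.standard_normal((4, 5000))
        ten, _ = _two_sensor_tensors(x, y, f_lo=10, f_hi=10.5)
        assert abs(ten.dwpli[0][0, 1]) < 0.05

    def test_bounded_and_scale_invariant(self, rng):
        x = rng.standard_normal((2, 3000))
        y = 0.3 * x + rng.standard_normal((2, 3000))
        t1, _ = _two_sensor_tensors(x, y)
        t2, _ = _two_sensor_tensors(5.0 * x, 0.2 * y)
        assert np.nanmax(t1.dwpli) <= 1.0 + 1e-12
        m1, m2 = t1.dwpli[0][0, 1], t2.dwpli[0][0, 1]
        assert m1 == pytest.approx(m2, rel=1e-9)


class TestEnvCorr:
    def test_unit_diagonal(self, rng):
        x = rng.standard_normal((2, 3000))
        ten, _ = _two_sensor_tensors(x, rng.standard_normal((2, 3000)),
                                     metrics=("env",))
        assert np.allclose(np.diagonal(ten.env_corr, axis1=1, axis2=2), 1.0)

    def test_common_slow_modulator(self, rng):
        from scipy import signal as sps
        t_len = 6 * 3000
        sos = sps.butter(4, 0.5, btype="lowpass", fs=250, output="sos")
        mod = sps.sosfiltfilt(sos, rng.standard_normal(t_len))
        mod = np.exp(mod / mod.std()).reshape(6, 3000)
        sos10 = sps.butter(4, [9, 11], btype="bandpass", fs=250, output="sos")
        c1 = sps.sosfiltfilt(sos10, rng.standard_normal((6, 3000)), axis=-1)
        c2 = sps.sosfiltfilt(sos10, rng.standard_normal((6, 3000)), axis=-1)
        ten, _ = _two_sensor_tensors(mod * c1, mod * c2, f_lo=10, f_hi=10.5,
                                     metrics=("env",))
        assert ten.env_corr[0][0, 1] > 0.5

    def test_independent_carriers(self, rng):
        x = rng.standard_normal((4, 5000))
        y = rng.standard_normal((4, 5000))
        ten, _ = _two_sensor_tensors(x, y, f_lo=10, f_hi=10.5,
                                     metrics=("env",))
        assert abs(ten.env_corr[0][0, 1]) < 0.1

    def test_positive_rescaling_invariance(self, rng):
        x = rng.standard_normal((2, 3000))
        y = 0.5 * x + rng.standard_normal((2, 3000))
        t1, _ = _two_sensor_tensors(x, y, metrics=("env",))
        t2, _ = _two_sensor_tensors(7.0 * x, 0.01 * y, metrics=("env",))
        assert t1.env_corr[0][0, 1] == pytest.approx(t2.env_corr[0][0, 1],
                                                     rel=1e-6)


class TestNodeStrength:
    def test_hand_computed(self):
        m = np.array([[np.nan, 0.1, 0.2],
                      [0.1, np.nan, 0.3],
                      [0.2, 0.3, np.nan]])
        assert np.allclose(wv.node_strength(m), [0.15, 0.2, 0.25])

    @given(c=st.floats(-0.5, 0.5), n=st.integers(3, 8))
    @settings(max_examples=25, deadline=None)
    def test_constant_offdiagonal(self, c, n):
        m = np.full((n, n), c)
        assert np.allclose(wv.node_strength(m), c)

    def test_missing_excluded(self):
        m = np.array([[1.0, 0.2, np.nan],
                      [0.2, 1.0, 0.4],
                      [np.nan, 0.4, 1.0]])
        s = wv.node_strength(m)
        assert s[0] == pytest.approx(0.2)
        assert s[1] == pytest.approx(0.3)


class TestBatchedPower:
    def test_matches_streaming_path(self, tiny_cohort, tiny_family):
        lp = wv.cohort_log_power(tiny_cohort[:3], tiny_family)
        ref = wv.compute_spectral_tensors(tiny_cohort[1].signals, tiny_family,
                                          metrics=("power",))
        assert np.allclose(lp[1], ref.log_psd, equal_nan=True)
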