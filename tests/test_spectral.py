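"""Multitaper estimation: tapers, PSD, spectrogram, bands, ERS Z-scores."""

import numpy as np
import pytest

import paintrace as pt
from paintrace.spectral import BANDS, zscore_from_powers


class TestTapers:
    def test_default_count_rule(self):
        ts = pt.dpss_tapers(1000, TW=3.0)
        assert ts.K == 5

    @pytest.mark.parametrize("N,TW,K", [(256, 2.5, 4), (512, 3.0, 5), (1000, 3.0, 5), (5000, 4.0, 7)])
    def test_orthonormality(self, N, TW, K):
        ts = pt.dpss_tapers(N, TW, K)
        gram = ts.tapers @ ts.tapers.T
        assert np.abs(gram - np.eye(K)).max() < 1e-8

    def test_excess_tapers_warn(self):
        with pytest.warns(UserWarning):
            pt.dpss_tapers(256, TW=2.0, K=6)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            pt.dpss_tapers(4, TW=3.0, K=5)

    def test_concentration_ordering(self):
        """Taper 1 concentrates more energy in [-W, W] than taper K."""
        N, TW = 512, 3.0
        ts = pt.dpss_tapers(N, TW, 5)
        nfft = 8192
        spec = np.abs(np.fft.fft(ts.tapers, n=nfft, axis=1)) ** 2
        f = np.fft.fftfreq(nfft)  # cycles/sample
        W = TW / N
        inband = np.abs(f) <= W
        conc = spec[:, inband].sum(axis=1) / spec.sum(axis=1)
        assert conc[0] > conc[-1]
        assert conc[0] > 0.999


class TestPsd:
    def test_sinusoid_peak_location(self):
        fs, N = 1000.0, 1000
        t = np.arange(N) / fs
        est = pt.multitaper_psd(np.sin(2 * np.pi * 10 * t), fs, pt.dpss_tapers(N))
        W = 3.0 / (N / fs)
        assert abs(est.freqs[np.argmax(est.power)] - 10.0) <= W

    def test_quadratic_amplitude_scaling(self):
        x = np.random.default_rng(0).standard_normal(1000)
        ts = pt.dpss_tapers(1000)
        p1 = pt.multitaper_psd(x, 1000.0, ts).power
        p3 = pt.multitaper_psd(3.0 * x, 1000.0, ts).power
        assert np.allclose(p3, 9.0 * p1, rtol=1e-10)

    def test_positivity_and_length_check(self):
        x = np.random.default_rng(1).standard_normal(1000)
        est = pt.multitaper_psd(x, 1000.0, pt.dpss_tapers(1000))
        assert (est.power >= 0).all()
        with pytest.raises(ValueError):
            pt.multitaper_psd(x[:500], 1000.0, pt.dpss_tapers(1000))

    def test_white_noise_flatness(self):
        """Mean PSD over 200 white-noise draws is flat across 4-100 Hz."""
        rng = np.random.default_rng(2)
        ts = pt.dpss_tapers(1000)
        acc = np.zeros(501)
        for _ in range(200):
            acc += pt.multitaper_psd(rng.standard_normal(1000), 1000.0, ts).power
        freqs = np.fft.rfftfreq(1000, 1e-3)
        sel = (freqs >= 4) & (freqs < 100)
        assert acc[sel].max() / acc[sel].min() < 1.5


class TestSpectrogram:
    def test_column_count(self):
        x = np.zeros(10_000)
        est = pt.multitaper_spectrogram(x, 1000.0, 1.0, 0.05)
        assert est.power.shape[0] == 181
        assert est.times[0] == pytest.approx(0.5)

    def test_window_too_long(self):
        with pytest.raises(ValueError):
            pt.multitaper_spectrogram(np.zeros(500), 1000.0, 1.0, 0.05)

    def test_stationary_columns_equal_in_mean(self):
        rng = np.random.default_rng(3)
        acc = None
        for _ in range(100):
            est = pt.multitaper_spectrogram(rng.standard_normal(3000), 1000.0, 1.0, 0.25)
            tot = est.power.sum(axis=1)
            acc = tot if acc is None else acc + tot
        acc /= 100
        assert acc.max() / acc.min() < 1.1

    def test_chirp_ridge_increases(self):
        from scipy.signal import chirp

        t = np.arange(10_000) / 1000.0
        x = chirp(t, f0=5.0, t1=10.0, f1=40.0)
        est = pt.multitaper_spectrogram(x, 1000.0, 1.0, 0.25)
        ridge = est.freqs[np.argmax(est.power, axis=1)]
        assert (np.diff(ridge) >= 0).all()
        assert ridge[-1] > ridge[0] + 20


class TestBandPower:
    def test_band_edges_tile_4_to_100(self):
        edges = sorted((b.lo, b.hi) for b in BANDS.values())
        assert edges[0][0] == 4.0 and edges[-1][1] == 100.0
        for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
            assert hi1 == lo2

    def test_partition_sums_to_total(self):
        x = np.random.default_rng(4).standard_normal(1000)
        est = pt.multitaper_psd(x, 1000.0, pt.dpss_tapers(1000))
        total = est.power[(est.freqs >= 4) & (est.freqs < 100)].sum()
        parts = sum(pt.band_power(est, b) for b in pt.BAND_ORDER)
        assert parts == pytest.approx(total, abs=1e-10 * total)

    def test_zero_trace(self):
        est = pt.multitaper_psd(np.zeros(1000), 1000.0, pt.dpss_tapers(1000))
        assert all(pt.band_power(est, b) == 0.0 for b in pt.BAND_ORDER)

    def test_theta_sinusoid_dominates(self):
        """6-Hz tone on a 5-s epoch (W = 0.6 Hz) stays inside theta."""
        t = np.arange(5000) / 1000.0
        est = pt.multitaper_psd(np.sin(2 * np.pi * 6 * t), 1000.0, pt.dpss_tapers(5000))
        theta = pt.band_power(est, "theta")
        for b in ("alpha", "beta", "low_gamma", "high_gamma"):
            assert theta > 10.0 * pt.band_power(est, b)

    def test_empty_band_errors(self):
        est = pt.multitaper_psd(np.zeros(100), 10.0, pt.dpss_tapers(100))
        with pytest.raises(ValueError):
            pt.band_power(est, pt.BANDS["high_gamma"])


class TestZscore:
    def test_exact_zero_at_baseline_mean(self):
        base = np.array([1.0, 2.0, 3.0])
        assert zscore_from_powers(np.array([2.0]), base)[0] == 0.0

    def test_zero_dispersion_errors(self):
        with pytest.raises(ValueError):
            zscore_from_powers(np.array([1.0]), np.array([2.0, 2.0]))
        with pytest.raises(ValueError):
            zscore_from_powers(np.array([1.0]), np.array([2.0]))

    def test_null_session_mean_near_zero(self, null_session):
        z = pt.zscore_band_power(null_session, "theta").z
        assert abs(z.mean()) < 3.0 * z.std(ddof=1) / np.sqrt(z.size)

    def test_injected_theta_gain_positive(self, strong_session):
        z = pt.zscore_band_power(strong_session, "theta").z
        hs = z[strong_session.labels() == "HS"]
        assert hs.mean() > 0
        assert hs.mean() / (hs.std(ddof=1) / np.sqrt(hs.size)) > 3

    def test_epoch_outside_range_errors(self, null_session):
        with pytest.raises(ValueError):
            pt.zscore_band_power(null_session, "theta", response_epoch=(0.0, 6.0))
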