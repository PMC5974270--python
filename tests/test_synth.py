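"""Generator: intensity mapping, determinism, ERS/spiking/latency models."""

import numpy as np
import pytest

import paintrace as pt
from paintrace.synth import StimulusIntensity, n_modulated_units


class TestStimulusIntensity:
    def test_label_power_mapping_and_ordering(self):
        assert StimulusIntensity.NS.laser_power == 50
        assert StimulusIntensity.LS.laser_power == 150
        assert StimulusIntensity.HS.laser_power == 250
        assert StimulusIntensity.NS < StimulusIntensity.LS < StimulusIntensity.HS

    def test_parse(self):
        assert StimulusIntensity.parse("hs") is StimulusIntensity.HS
        with pytest.raises(ValueError):
            StimulusIntensity.parse("XL")


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_trials_per_class=10),
        dict(frac_modulated=1.5),
        dict(base_rate=-1.0),
        dict(ers_gain={"theta": {"HS": -2.0}}),
        dict(fs=1000.0, t_range=(-5.0, 5.0005)),
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        pt.SynthConfig(**kwargs)


class TestMakeSession:
    def test_balanced_counts_and_size(self, small_config):
        s = pt.make_session(small_config, "NS-HS", "naive", seed=0)
        labels = s.labels()
        assert s.n_trials == 30
        assert (labels == "NS").sum() == (labels == "HS").sum() == 15

    def test_default_config_gives_sixty_trials(self):
        cfg = pt.SynthConfig()
        assert 2 * cfg.n_trials_per_class == 60

    def test_seed_determinism_bitwise(self, small_config):
        a = pt.make_session(small_config, "NS-HS", "naive", seed=5)
        b = pt.make_session(small_config, "NS-HS", "naive", seed=5)
        c = pt.make_session(small_config, "NS-HS", "naive", seed=6)
        assert pt.session_checksum(a) == pt.session_checksum(b)
        assert pt.session_checksum(a) != pt.session_checksum(c)

    def test_invalid_pair_rejected(self, small_config):
        with pytest.raises(ValueError):
            pt.make_session(small_config, "NS-NS", "naive", seed=0)
        with pytest.raises(ValueError):
            pt.make_session(small_config, "NS-HS", "sham", seed=0)

    def test_trial_invariants(self, strong_session):
        cfg = strong_session.config
        for t in strong_session.trials:
            assert t.lfp.shape == (cfg.channels, cfg.n_samples)
            assert np.isfinite(t.lfp).all()
            if t.intensity is StimulusIntensity.NS:
                assert t.withdrawal_latency is None
                assert t.epoch_end == 5.0
            else:
                assert 0.0 < t.withdrawal_latency <= 5.0


class TestLfp:
    def test_sample_grid(self, small_config):
        lfp = pt.synth_lfp_trial("HS", "naive", small_config, seed=0)
        assert lfp.shape == (4, 10_000)
        t = small_config.time_grid()
        assert t[0] == -5.0 and t[-1] == pytest.approx(5.0 - 1.0 / small_config.fs)

    def test_ers_positive_z_for_hs(self, strong_session):
        """Gains > 1 in theta/high gamma drive positive ERS Z on HS trials."""
        labels = strong_session.labels()
        for band in ("theta", "high_gamma"):
            z = pt.zscore_band_power(strong_session, band).z
            hs = z[labels == "HS"]
            assert hs.mean() > 3.0 * hs.std(ddof=1) / np.sqrt(hs.size)

    def test_null_gains_zero_mean_z(self, null_config):
        """With every gain at 1 the 100-trial mean Z stays within 3 SE of 0."""
        from dataclasses import replace

        cfg = replace(null_config, n_trials_per_class=50)
        s = pt.make_session(cfg, "NS-HS", "naive", seed=3)
        pt.denoise_session(s)
        for band in ("theta", "high_gamma"):
            z = pt.zscore_band_power(s, band).z
            assert abs(z.mean()) < 3.0 * z.std(ddof=1) / np.sqrt(z.size)

    def test_gain_monotonicity(self, small_config):
        """Mean theta Z is strictly ordered along the gain grid {1, 2, 4, 8}."""
        from scipy.stats import spearmanr

        means = []
        for gain in (1.0, 2.0, 4.0, 8.0):
            cfg = pt.SynthConfig(
                n_trials_per_class=15, channels=4, n_units=8,
                ers_gain={"theta": {"NS": 1.0, "HS": gain}},
            )
            s = pt.make_session(cfg, "NS-HS", "naive", seed=17)
            pt.denoise_session(s)
            z = pt.zscore_band_power(s, "theta").z
            means.append(z[s.labels() == "HS"].mean())
        assert spearmanr([1, 2, 4, 8], means).statistic == 1.0


class TestSpikes:
    @pytest.mark.parametrize("frac,n,expect", [(0.25, 8, 2), (0.25, 10, 3), (0.2, 8, 2), (0.3, 10, 3), (0.0, 8, 0)])
    def test_modulated_unit_count_round_half_up(self, frac, n, expect):
        cfg = pt.SynthConfig(frac_modulated=frac, n_units=n)
        assert n_modulated_units(cfg) == expect

    def test_poisson_mean_matches_rate(self):
        """Unmodulated counts match the r*T Poisson mean within 3 SE."""
        cfg = pt.SynthConfig(n_units=1, frac_modulated=0.0, base_rate=4.0)
        counts = [len(pt.synth_spikes("NS", "naive", cfg, seed=s)[0]) for s in range(1000)]
        counts = np.asarray(counts, dtype=float)
        expected = 4.0 * 10.0
        assert abs(counts.mean() - expected) < 3.0 * counts.std(ddof=1) / np.sqrt(counts.size)

    def test_unit_gain_null(self):
        """modulated_rate_gain = 1 leaves epoch rates at baseline on average."""
        cfg = pt.SynthConfig(n_units=4, frac_modulated=1.0, modulated_rate_gain=1.0, base_rate=10.0)
        pre, post = [], []
        for s in range(200):
            for st in pt.synth_spikes("HS", "naive", cfg, seed=s):
                pre.append(np.sum(st < 0))
                post.append(np.sum((st >= 0) & (st < 5.0)))
        pre, post = np.array(pre, float), np.array(post, float)
        se = np.sqrt(pre.var(ddof=1) / pre.size + post.var(ddof=1) / post.size)
        assert abs(pre.mean() - post.mean()) < 3.0 * se

    def test_modulated_units_raise_rate_during_epoch(self):
        cfg = pt.SynthConfig(n_units=8, frac_modulated=0.25, modulated_rate_gain=4.0, base_rate=5.0)
        mod = np.array([0, 1])
        post = np.zeros(8)
        for s in range(100):
            sp = pt.synth_spikes("HS", "naive", cfg, seed=s, modulated_units=mod)
            post += [np.sum((st >= 0) & (st < 5)) for st in sp]
        assert post[:2].mean() > 2.0 * post[2:].mean()


class TestWithdrawal:
    def test_ns_absent(self, small_config):
        assert pt.synth_withdrawal("NS", small_config, seed=0) is None

    def test_truncation(self, small_config):
        draws = [pt.synth_withdrawal("HS", small_config, seed=s) for s in range(200)]
        assert all(0.0 < d <= 5.0 for d in draws)

    def test_hs_faster_than_ls(self, small_config):
        ls = np.array([pt.synth_withdrawal("LS", small_config, seed=s) for s in range(500)])
        hs = np.array([pt.synth_withdrawal("HS", small_config, seed=s + 500) for s in range(500)])
        assert hs.mean() < ls.mean()


def test_session_hdf5_roundtrip(tmp_path, strong_session):
    """Write/read preserves every trial bit-for-bit, config included."""
    p = pt.write_session(strong_session, tmp_path / "s.h5")
    back = pt.read_session(p)
    assert pt.session_checksum(back) == pt.session_checksum(strong_session)
    assert back.trials[0].denoised is not None


def test_config_yaml_roundtrip(tmp_path, small_config):
    p = pt.dump_config(small_config, tmp_path / "cfg.yaml")
    assert pt.load_config(p) == small_config
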