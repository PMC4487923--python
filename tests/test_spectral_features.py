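import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleepscore import (
    Channel,
    DEFAULT_BANDS,
    ScoringConfig,
    SignalVector,
    bandpass,
    compute_features,
    epoch_rms,
)
from sleepscore.core import SCORING_BAND_NAMES
from sleepscore.spectral_features import delta_feature, theta_feature

from conftest import make_signal

FS = 250.0


def tone(freq, duration_s=10.0, amplitude=1.0, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return make_signal(amplitude * np.sin(2 * np.pi * freq * t), fs=fs)


def rms(x):
    return np.sqrt(np.nanmean(np.asarray(x) ** 2))


class TestBandpass:
    @pytest.mark.parametrize("name", SCORING_BAND_NAMES)
    def test_passband_center_tone_retained(self, name):
        band = DEFAULT_BANDS[name]
        sig = tone((band.low + band.high) / 2)
        out = bandpass(sig, band, order=3)
        assert rms(out.samples) >= 0.95 * rms(sig.samples)

    @pytest.mark.parametrize("name", SCORING_BAND_NAMES)
    def test_stopband_tone_attenuated(self, name):
        band = DEFAULT_BANDS[name]
        sig = tone(3 * band.high)
        out = bandpass(sig, band, order=3)
        assert rms(out.samples) <= 0.10 * rms(sig.samples)

    def test_band_edge_at_nyquist_rejected(self):
        sig = tone(10.0, fs=50.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(sig, DEFAULT_BANDS["beta"], order=3)

    def test_all_nan_input_stays_nan(self):
        sig = make_signal(np.full(1000, np.nan))
        out = bandpass(sig, DEFAULT_BANDS["delta"], order=3)
        assert np.isnan(out.samples).all()

    def test_nan_runs_propagate_and_clean_runs_filter(self):
        x = tone(2.0, duration_s=20.0).samples.copy()
        x[1000:1500] = np.nan
        out = bandpass(make_signal(x), DEFAULT_BANDS["delta"], order=3)
        assert np.isnan(out.samples[1000:1500]).all()
        assert np.isfinite(out.samples[:1000]).all()
        assert np.isfinite(out.samples[1500:]).all()

    def test_output_length_preserved(self, rng):
        sig = make_signal(rng.standard_normal(997))
        out = bandpass(sig, DEFAULT_BANDS["theta"], order=3)
        assert len(out) == len(sig)


class TestEpochRms:
    def test_constant_signal_rms_is_magnitude(self):
        sig = make_signal(np.full(1000, -3.0), fs=250.0)
        np.testing.assert_allclose(epoch_rms(sig, 1.0), 3.0)

    def test_sinusoid_rms_is_amplitude_over_sqrt2(self):
        sig = tone(5.0, duration_s=8.0, amplitude=2.0)
        np.testing.assert_allclose(
            epoch_rms(sig, 4.0), 2.0 / np.sqrt(2), rtol=0.01
        )

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal(60 * 250)
        sig = make_signal(x)
        got = epoch_rms(sig, 4.0)
        n = 1000
        expected = []
        for i in range(len(x) // n):
            block = x[i * n : (i + 1) * n]
            expected.append(np.sqrt(sum(v * v for v in block) / n))
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_nan_sample_poisons_only_its_epoch(self):
        x = np.ones(3000)
        x[1500] = np.nan
        out = epoch_rms(make_signal(x), 4.0)  # 3 epochs of 1000 samples
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], 1.0)

    def test_trailing_partial_epoch_dropped(self):
        sig = make_signal(np.ones(2500), fs=250.0)
        assert epoch_rms(sig, 4.0).size == 2

    def test_signal_shorter_than_epoch_warns_and_returns_empty(self):
        sig = make_signal(np.ones(10), fs=250.0)
        with pytest.warns(UserWarning, match="shorter"):
            out = epoch_rms(sig, 4.0)
        assert out.size == 0


class TestFeatureFormulas:
    def test_delta_ratio_hand_values(self):
        assert delta_feature(
            np.array([2.0]), np.array([1.0]), np.array([1.0]), np.array([1.0])
        )[0] == 2.0

    def test_theta_ratio_hand_values(self):
        assert theta_feature(
            np.array([3.0]), np.array([1.0]), np.array([1.0])
        )[0] == 9.0

    def test_exp_of_zero_emg_rms_is_one(self, cfg):
        eeg = make_signal(np.random.default_rng(0).standard_normal(3000))
        emg = make_signal(np.zeros(3000), channel=Channel.EMG)
        table = compute_features(eeg, emg, cfg)
        np.testing.assert_allclose(table.emg_feature[~table.is_artifact], 1.0)


def state_epoch(freq, n=1000, fs=FS, noise=0.2, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t) + noise * rng.standard_normal(n)


class TestComputeFeatures:
    def test_delta_vs_theta_epochs_rank_correctly(self, cfg):
        eeg = make_signal(
            np.concatenate([state_epoch(2.5), state_epoch(7.5)])
        )
        emg = make_signal(
            0.1 * np.random.default_rng(1).standard_normal(2000),
            channel=Channel.EMG,
        )
        table = compute_features(eeg, emg, cfg)
        assert table.delta[0] > table.delta[1]
        assert table.theta[1] > table.theta[0]

    def test_artifact_epochs_have_all_nan_features(self, cfg, rng):
        x = rng.standard_normal(5000)
        x[0:10] = np.nan  # poison first epoch
        eeg = make_signal(x)
        emg = make_signal(rng.standard_normal(5000), channel=Channel.EMG)
        table = compute_features(eeg, emg, cfg)
        assert table.is_artifact[0]
        assert np.isnan(table.delta[0]) and np.isnan(table.theta[0])
        assert not table.is_artifact[1:].any()

    def test_zero_band_rms_flags_artifact_with_warning(self, cfg):
        eeg = make_signal(np.zeros(2000))
        emg = make_signal(
            np.random.default_rng(0).standard_normal(2000), channel=Channel.EMG
        )
        with pytest.warns(UserWarning, match="zero band RMS"):
            table = compute_features(eeg, emg, cfg)
        assert table.is_artifact.all()

    def test_epoch_count_floor_of_duration(self, cfg, rng):
        n = int(9.5 * cfg.epoch_length_s * cfg.fs)  # 9.5 epochs
        eeg = make_signal(rng.standard_normal(n))
        emg = make_signal(rng.standard_normal(n), channel=Channel.EMG)
        table = compute_features(eeg, emg, cfg)
        assert table.n_epochs == 9

    def test_precomputed_epoch_rms_emg(self, cfg, rng):
        n = int(8 * cfg.epoch_length_s * cfg.fs)
        eeg = make_signal(rng.standard_normal(n))
        emg_rms = make_signal(np.linspace(0.5, 2.0, 8), channel=Channel.EMG)
        table = compute_features(eeg, emg_rms, cfg, emg_is_epoch_rms=True)
        np.testing.assert_allclose(table.emg_rms, np.linspace(0.5, 2.0, 8))
        np.testing.assert_allclose(table.emg_feature, np.exp(table.emg_rms))

    def test_mismatched_durations_rejected(self, cfg, rng):
        eeg = make_signal(rng.standard_normal(10000))
        emg = make_signal(rng.standard_normal(5000), channel=Channel.EMG)
        with pytest.raises(ValueError, match="duration"):
            compute_features(eeg, emg, cfg)


class TestScalingProperties:
    @pytest.mark.parametrize("k", [0.1, 10.0])
    def test_gain_scales_delta_by_inverse_square_and_leaves_theta(self, cfg, rng, k):
        n = int(10 * cfg.epoch_length_s * cfg.fs)
        x = rng.standard_normal(n)
        emg = make_signal(np.abs(rng.standard_normal(n)) + 0.1, channel=Channel.EMG)
        base = compute_features(make_signal(x), emg, cfg)
        scaled = compute_features(make_signal(k * x), emg, cfg)
        np.testing.assert_allclose(scaled.delta_rms, k * base.delta_rms, rtol=1e-9)
        np.testing.assert_allclose(scaled.delta, base.delta / k**2, rtol=1e-9)
        np.testing.assert_allclose(scaled.theta, base.theta, rtol=1e-9)

    def test_oracle_equivalence_straight_line_reimplementation(self, cfg, rng):
        """Full table on 60 s of noise matches filter->square->mean->sqrt
        done longhand per block."""
        from scipy import signal as sps

        n = 60 * 250
        x = rng.standard_normal(n)
        emg_x = rng.standard_normal(n)
        table = compute_features(
            make_signal(x), make_signal(emg_x, channel=Channel.EMG), cfg
        )

        block = int(cfg.epoch_length_s * cfg.fs)
        oracle = {}
        for name in SCORING_BAND_NAMES:
            b = DEFAULT_BANDS[name]
            sos = sps.butter(3, [b.low, b.high], btype="bandpass", fs=250.0, output="sos")
            y = sps.sosfiltfilt(sos, x)
            oracle[name] = np.array(
                [
                    np.sqrt(np.mean(y[i * block : (i + 1) * block] ** 2))
                    for i in range(n // block)
                ]
            )
        np.testing.assert_allclose(table.delta_rms, oracle["delta"], rtol=1e-9)
        np.testing.assert_allclose(table.beta_rms, oracle["beta"], rtol=1e-9)
        np.testing.assert_allclose(
            table.delta,
            oracle["delta"] / (oracle["alpha"] * oracle["mu"] * oracle["beta"]),
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            table.theta,
            oracle["theta"] ** 2 / (oracle["delta"] * oracle["alpha"]),
            rtol=1e-9,
        )


def test_band_defaults_exact():
    expected = {
        "delta": (0.5, 5.0),
        "theta": (6.0, 9.0),
        "alpha": (10.0, 15.0),
        "mu": (16.0, 22.75),
        "beta": (23.0, 31.75),
        "broadband": (0.5, 31.75),
    }
    for name, (low, high) in expected.items():
        assert (DEFAULT_BANDS[name].low, DEFAULT_BANDS[name].high) == (low, high)


def test_config_defaults_match_tool_presets():
    cfg = ScoringConfig()
    assert (cfg.fs, cfg.filter_order) == (250.0, 3)
    assert (cfg.broadband_low, cfg.broadband_high) == (0.5, 31.75)
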