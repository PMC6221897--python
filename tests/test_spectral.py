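"""Filtering, analytic phase/amplitude, binned power and spectral features."""

import numpy as np
import pytest

import plvnet
from plvnet.spectral import GAMMA, LOW, BandConfig, InvalidBandError, InvalidBinError

from conftest import sinusoid_epochs

FULL_BIN = [(0.0, 2000.0)]


def _inner(x, fs, margin=0.5):
    m = int(margin * fs)
    return x[..., m:-m]


class TestBandpass:
    def test_inband_sinusoid_preserved(self):
        epochs = sinusoid_epochs(85.0)
        out = plvnet.bandpass(epochs, GAMMA)
        amp = np.sqrt(2) * _inner(out.data, epochs.sampling_rate).std()
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_sinusoid_rejected(self):
        epochs = sinusoid_epochs(10.0)
        out = plvnet.bandpass(epochs, GAMMA)
        assert _inner(out.data, epochs.sampling_rate).std() < 0.01

    def test_zero_in_zero_out(self):
        epochs = sinusoid_epochs(85.0, amps=[0.0])
        out = plvnet.bandpass(epochs, GAMMA)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_band_above_nyquist_rejected(self):
        epochs = sinusoid_epochs(10.0, fs=128.0)
        with pytest.raises(InvalidBandError):
            plvnet.bandpass(epochs, GAMMA)

    def test_zero_phase_no_group_delay(self):
        """Filtered in-band sinusoid stays phase-aligned with the input."""
        epochs = sinusoid_epochs(85.0)
        out = plvnet.bandpass(epochs, GAMMA)
        x = _inner(epochs.data[0, 0], epochs.sampling_rate)
        y = _inner(out.data[0, 0], epochs.sampling_rate)
        lag = np.argmax(np.correlate(y, x, mode="full")) - (x.size - 1)
        assert lag == 0

    def test_commutes_with_trial_reordering(self, small_epochs):
        from dataclasses import replace

        perm = np.array([2, 0, 1, 3] + list(range(4, small_epochs.n_trials)))
        direct = plvnet.bandpass(small_epochs, GAMMA).data[perm]
        reordered = plvnet.bandpass(replace(small_epochs, data=small_epochs.data[perm]), GAMMA).data
        np.testing.assert_allclose(direct, reordered, atol=1e-12)


class TestAnalyticPhase:
    def test_phase_slope_matches_frequency(self):
        epochs = sinusoid_epochs(80.0)
        ph = plvnet.analytic_phase(plvnet.bandpass(epochs, GAMMA), GAMMA)
        unwrapped = np.unwrap(ph.phase[0, 0])
        slope = np.polyfit(ph.times, unwrapped, 1)[0] / (2 * np.pi)
        assert slope == pytest.approx(80.0, rel=1e-3)

    def test_buffer_trimmed(self):
        epochs = sinusoid_epochs(80.0, buffer=0.5)
        ph = plvnet.analytic_phase(plvnet.bandpass(epochs, GAMMA), GAMMA)
        assert ph.times[0] == pytest.approx(0.0)
        assert ph.phase.shape[-1] == epochs.data.shape[-1] - int(epochs.sampling_rate)

    def test_sin_vs_cos_quarter_cycle_offset(self):
        fs, n = 1000.0, 3000
        t = (np.arange(n) - 500) / fs
        data = np.stack([np.cos(2 * np.pi * 80 * t), np.sin(2 * np.pi * 80 * t)])[None]
        epochs = sinusoid_epochs(80.0, n_trials=1)
        epochs.data = data
        ph = plvnet.analytic_phase(plvnet.bandpass(epochs, GAMMA), GAMMA)
        diff = np.angle(np.exp(1j * (ph.phase[0, 0] - ph.phase[0, 1])))
        np.testing.assert_allclose(diff, np.pi / 2, atol=0.01)

    def test_amplitude_modulation_leaves_phase_slope(self):
        fs = 1000.0
        epochs = sinusoid_epochs(80.0)
        t = epochs.times
        am = sinusoid_epochs(80.0)
        am.data = am.data * (1 + 0.5 * np.cos(2 * np.pi * 2 * t))
        ph_plain = plvnet.analytic_phase(plvnet.bandpass(epochs, GAMMA), GAMMA)
        ph_am = plvnet.analytic_phase(plvnet.bandpass(am, GAMMA), GAMMA)
        s0 = np.polyfit(ph_plain.times, np.unwrap(ph_plain.phase[0, 0]), 1)[0]
        s1 = np.polyfit(ph_am.times, np.unwrap(ph_am.phase[0, 0]), 1)[0]
        assert s1 == pytest.approx(s0, rel=1e-3)

    def test_phase_in_range(self, small_phases):
        assert np.all(small_phases.phase > -np.pi - 1e-12)
        assert np.all(small_phases.phase <= np.pi + 1e-12)


class TestBandPower:
    def test_unit_sinusoid_power_half(self):
        epochs = sinusoid_epochs(85.0)
        power = plvnet.band_power(plvnet.bandpass(epochs, GAMMA), FULL_BIN)
        assert power[0, 0, 0] == pytest.approx(0.5, rel=0.02)

    def test_zero_signal_zero_power(self):
        epochs = sinusoid_epochs(85.0, amps=[0.0])
        power = plvnet.band_power(plvnet.bandpass(epochs, GAMMA), FULL_BIN)
        assert power[0, 0, 0] == 0.0

    def test_amplitude_scaling_law(self):
        e1 = sinusoid_epochs(85.0, amps=[1.0])
        e2 = sinusoid_epochs(85.0, amps=[2.0])
        p1 = plvnet.band_power(plvnet.bandpass(e1, GAMMA), FULL_BIN)
        p2 = plvnet.band_power(plvnet.bandpass(e2, GAMMA), FULL_BIN)
        assert p2[0, 0, 0] == pytest.approx(4 * p1[0, 0, 0], rel=1e-9)

    def test_bin_outside_epoch_rejected(self):
        epochs = sinusoid_epochs(85.0)
        with pytest.raises(InvalidBinError):
            plvnet.band_power(plvnet.bandpass(epochs, GAMMA), [(1900.0, 2600.0)])


class TestZScore:
    def test_three_trial_hand_example(self):
        power = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        z = plvnet.zscore_across_trials(power)
        np.testing.assert_allclose(z.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_powers_zero_with_warning(self, caplog):
        power = np.full((4, 1, 1), 7.0)
        with caplog.at_level("WARNING"):
            z = plvnet.zscore_across_trials(power)
        np.testing.assert_array_equal(z, 0.0)
        assert "zero across-trial variance" in caplog.text

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        power = rng.uniform(1, 2, size=(6, 2, 3))
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            plvnet.zscore_across_trials(power)[perm],
            plvnet.zscore_across_trials(power[perm]),
            atol=1e-12,
        )

    def test_normalization_invariants(self, small_epochs):
        power = plvnet.band_power(plvnet.bandpass(small_epochs, GAMMA), [(-500.0, 0.0)])
        z = plvnet.zscore_across_trials(power)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            plvnet.zscore_across_trials(np.ones((2, 1, 1)))


class TestSpectralTilt:
    def test_equal_inputs_zero(self):
        z = np.ones((3, 2, 2))
        np.testing.assert_array_equal(plvnet.spectral_tilt(z, z), 0.0)

    def test_difference_and_antisymmetry(self):
        h = np.full((3, 1, 1), 1.0)
        l = np.full((3, 1, 1), -1.0)
        np.testing.assert_array_equal(plvnet.spectral_tilt(h, l), 2.0)
        np.testing.assert_array_equal(plvnet.spectral_tilt(l, h), -plvnet.spectral_tilt(h, l))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plvnet.spectral_tilt(np.ones((3, 1, 1)), np.ones((3, 1, 2)))


def test_spectral_features_pipeline(small_epochs, tmp_path):
    from plvnet.spectral import load_spectral_features, save_spectral_features

    bins = [(-500.0, 0.0), (0.0, 500.0)]
    feats = plvnet.spectral_features(small_epochs, bins)
    assert feats["hfa_z"].shape == (small_epochs.n_trials, 2, small_epochs.n_channels)
    np.testing.assert_allclose(feats["tilt"], feats["hfa_z"] - feats["low_z"], atol=1e-12)

    save_spectral_features(feats, bins, tmp_path / "spec.h5")
    back, back_bins = load_spectral_features(tmp_path / "spec.h5")
    np.testing.assert_array_equal(back["tilt"], feats["tilt"])
    assert back_bins == tuple(bins)


def test_band_config_validation():
    with pytest.raises(InvalidBandError):
        BandConfig("bad", 100.0, 70.0).validate(512.0)
    LOW.validate(256.0)  # valid band passes silently
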