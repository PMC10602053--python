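import numpy as np
import pytest

from sleepkit.core import LaserTrain, SignalRecording
from sleepkit.spectral import (
    BANDS,
    BandDefinition,
    PSD,
    band_power,
    emg_amplitude,
    laser_triggered_spectrogram,
    spectrogram,
    welch_psd,
)

FS = 1000.0


class TestWelchPSD:
    def test_tone_localized_at_8_hz(self):
        t = np.arange(int(10 * FS)) / FS
        psd = welch_psd(np.sin(2 * np.pi * 8.0 * t), FS)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(8.0)

    def test_parseval_on_white_noise(self, rng):
        """Integrated PSD approximates the variance (density scaling)."""
        errs = []
        for _ in range(100):
            x = rng.standard_normal(int(10 * FS))
            psd = welch_psd(x, FS)
            errs.append(np.sum(psd.power) * psd.df / x.var())
        assert np.mean(errs) == pytest.approx(1.0, rel=0.05)

    def test_zero_signal_gives_zero_psd(self):
        psd = welch_psd(np.zeros(int(4 * FS)), FS)
        assert (psd.power == 0).all()

    def test_short_trace_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            welch_psd(np.zeros(100), FS, window_s=2.0)

    def test_psd_nonnegative(self, rng):
        psd = welch_psd(rng.standard_normal(5000), FS)
        assert (psd.power >= 0).all()


class TestSpectrogram:
    def test_60s_trace_has_23_columns(self, rng):
        spec = spectrogram(rng.standard_normal(int(60 * FS)), FS)
        assert spec.power.shape[1] == 23

    def test_columns_equal_welch_of_slices(self, rng):
        x = rng.standard_normal(int(20 * FS))
        spec = spectrogram(x, FS)
        for k in (0, 3):
            sl = x[int(k * 2.5 * FS) : int((k * 2.5 + 5) * FS)]
            np.testing.assert_allclose(spec.power[:, k], welch_psd(sl, FS).power)

    def test_stationary_tone_columns_identical(self):
        t = np.arange(int(30 * FS)) / FS
        spec = spectrogram(np.sin(2 * np.pi * 8 * t), FS)
        assert np.abs(spec.power - spec.power[:, [0]]).max() < 1e-8

    def test_argmax_tracks_frequency_switch(self):
        t = np.arange(int(30 * FS)) / FS
        x = np.where(t < 15, np.sin(2 * np.pi * 8 * t), np.sin(2 * np.pi * 3 * t))
        spec = spectrogram(x, FS)
        first = spec.freqs[np.argmax(spec.power[:, 0])]
        last = spec.freqs[np.argmax(spec.power[:, -1])]
        assert first == pytest.approx(8.0)
        assert last == pytest.approx(3.0)


class TestBandPower:
    def test_flat_psd_delta_band_is_width_times_height(self):
        freqs = np.arange(0, 100.5, 0.5)
        psd = PSD(freqs=freqs, power=np.ones_like(freqs))
        assert band_power(psd, BANDS["delta"]) == pytest.approx(4.0)

    def test_additive_over_partition(self, rng):
        psd = welch_psd(rng.standard_normal(int(10 * FS)), FS)
        total = np.sum(psd.power) * psd.df
        parts = [
            BandDefinition("a", 0.25, 100.0),
            BandDefinition("b", 100.0, 300.0),
            BandDefinition("c", 300.0, 500.25),
        ]
        sub = sum(band_power(psd, b) for b in parts)
        # everything except the DC bin
        assert sub == pytest.approx(total - psd.power[0] * psd.df, rel=1e-10)

    def test_matches_trapezoid_within_bin_error(self, rng):
        x = rng.standard_normal(int(20 * FS))
        psd = welch_psd(x, FS)
        band = BANDS["emg"]
        mask = (psd.freqs >= band.lo_hz) & (psd.freqs < band.hi_hz)
        trapz = np.trapezoid(psd.power[mask], psd.freqs[mask])
        assert band_power(psd, band) == pytest.approx(trapz, rel=0.05)

    def test_band_outside_range_raises(self):
        psd = welch_psd(np.zeros(int(4 * FS)), FS)
        with pytest.raises(ValueError, match="exceeds"):
            band_power(psd, BandDefinition("x", 400.0, 600.0))


class TestEmgAmplitude:
    def test_zero_emg(self):
        assert emg_amplitude(np.zeros(int(4 * FS)), FS) == 0.0

    def test_homogeneous_degree_one(self, rng):
        x = rng.standard_normal(int(10 * FS))
        assert emg_amplitude(2 * x, FS) == pytest.approx(2 * emg_amplitude(x, FS), rel=1e-9)

    def test_white_noise_amplitude_tracks_band_fraction(self, rng):
        sigma = 40.0
        x = sigma * rng.standard_normal(int(60 * FS))
        frac = (100.0 - 5.0) / (FS / 2)  # fraction of white power in 5-100 Hz
        assert emg_amplitude(x, FS) == pytest.approx(sigma * np.sqrt(frac), rel=0.1)


class TestLaserTriggered:
    def _recording(self, rng, modulate=False, noise=0.0):
        t = np.arange(int(1800 * FS)) / FS
        laser = LaserTrain(onsets=np.array([300.0, 800.0, 1300.0]), duration_s=120.0)
        amp = np.ones_like(t)
        if modulate:
            for on, off in laser.intervals():
                amp[(t >= on) & (t < off)] = 2.0
        x = amp * np.sin(2 * np.pi * 8.0 * t) + noise * rng.standard_normal(t.size)
        emg = rng.standard_normal(t.size)
        rec = SignalRecording(
            {"EEG_frontal": x, "EEG_parietal": x, "EMG": emg}, fs=FS
        )
        return rec, laser

    def test_stationary_signal_normalizes_to_one(self, rng):
        """Normalization fixed point: a stationary signal maps to 1."""
        rec, laser = self._recording(rng)
        _, freqs, avg, courses, _ = laser_triggered_spectrogram(rec, laser)
        band = (freqs >= 7.5) & (freqs < 8.5)
        assert np.abs(avg[band] - 1.0).max() < 0.01

    def test_amplitude_doubling_quadruples_band_power(self, rng):
        rec, laser = self._recording(rng, modulate=True)
        _, _, _, courses, table = laser_triggered_spectrogram(rec, laser)
        theta = table[table.band == "theta"]
        ratio = theta["laser"].mean() / theta["baseline"].mean()
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_laser_epochs_excluded_from_normalizing_mean(self, rng):
        """The non-laser mean differs from the naive mean on modulated data."""
        rec, laser = self._recording(rng, modulate=True)
        _, freqs, avg, _, _ = laser_triggered_spectrogram(rec, laser)
        band = freqs == 8.0  # the tone bin; neighbours carry no power
        # baseline sits at 1.0 only because laser columns were excluded
        n_pre = int(120 / 2.5)
        baseline_level = avg[band][:, : n_pre - 2].mean()
        assert baseline_level == pytest.approx(1.0, abs=0.05)
        laser_level = avg[band][:, n_pre + 1 : n_pre + int(120 / 2.5) - 1].mean()
        assert laser_level == pytest.approx(4.0, rel=0.1)
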