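import numpy as np
import pytest

from sleepkit.core import BrainState, episodes
from sleepkit.spectral import BANDS, band_power, emg_amplitude, welch_psd
from sleepkit.synthetic import (
    SimConfig,
    block_hypnogram,
    rem_episode_truths,
    simulate_calcium,
    simulate_eeg_emg,
    simulate_hypnogram,
    simulate_photometry,
    simulate_pupil,
)


class TestHypnogramGenerator:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(seed=11, duration_s=3600.0)
        h1, _ = simulate_hypnogram(cfg)
        h2, _ = simulate_hypnogram(cfg)
        assert (h1.states == h2.states).all()

    def test_different_seeds_differ(self):
        h1, _ = simulate_hypnogram(SimConfig(seed=1, duration_s=3600.0))
        h2, _ = simulate_hypnogram(SimConfig(seed=2, duration_s=3600.0))
        assert (h1.states != h2.states).any()

    def test_forbidden_wake_to_rem_never_occurs(self):
        cfg = SimConfig(seed=3, duration_s=250_000.0)  # 1e5 epochs
        h, _ = simulate_hypnogram(cfg)
        prev, cur = h.states[:-1], h.states[1:]
        assert not ((prev == "W") & (cur == "R")).any()

    def test_bout_transition_frequencies_match_matrix(self):
        """Empirical bout-to-bout frequencies within 3 SE of the configured
        multinomial probabilities."""
        cfg = SimConfig(seed=7, duration_s=600_000.0)
        h, truth = simulate_hypnogram(cfg)
        ledger = truth.episode_ledger
        for s, row in cfg.transition.items():
            nexts = [
                ledger[i + 1][0]
                for i in range(len(ledger) - 1)
                if ledger[i][0] == s
            ]
            n = len(nexts)
            assert n > 100
            for target, p in row.items():
                if p == 0:
                    assert nexts.count(target) == 0
                    continue
                se = np.sqrt(p * (1 - p) / n)
                assert abs(nexts.count(target) / n - p) <= 3 * se

    def test_bout_durations_respect_floor(self):
        cfg = SimConfig(seed=9, duration_s=100_000.0)
        _, truth = simulate_hypnogram(cfg)
        for s, a, b in truth.episode_ledger[:-1]:
            assert b - a >= cfg.state_min_s[s] - 1e-9

    def test_absorbing_state_rejected(self):
        with pytest.raises(ValueError, match="absorbing"):
            SimConfig(transition={"W": {"N": 0.0, "R": 0.0},
                                  "N": {"W": 1.0, "R": 0.0},
                                  "R": {"W": 1.0, "N": 0.0}})

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            SimConfig(fs=20.0)


@pytest.fixture(scope="module")
def session():
    cfg = SimConfig(seed=13, duration_s=3000.0)
    h, truth = simulate_hypnogram(cfg)
    rec = simulate_eeg_emg(cfg, truth)
    return cfg, h, truth, rec


class TestEegEmg:

    def test_rem_psd_peaks_at_tonic_theta(self):
        cfg = SimConfig(seed=21, duration_s=1200.0, phasic_rate_per_min=0.0,
                        state_mean_s={"W": 30.0, "N": 60.0, "R": 120.0},
                        state_min_s={"W": 10.0, "N": 30.0, "R": 60.0})
        h, truth = simulate_hypnogram(cfg)
        rec = simulate_eeg_emg(cfg, truth)
        rem = rem_episode_truths(truth)
        assert rem, "no REM generated"
        seg = rec["EEG_parietal"][rem[0].sample_slice(rec.fs)]
        psd = welch_psd(seg, rec.fs)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(7.5, abs=0.5)
        assert len(truth.phasic_intervals) == 0

    def test_emg_amplitude_ratio_tracks_configured_rms(self):
        cfg = SimConfig(seed=17, duration_s=2000.0, ecg_enabled=False,
                        emg_rms_uV={"W": 100.0, "N": 20.0, "R": 20.0})
        h, truth = simulate_hypnogram(cfg)
        rec = simulate_eeg_emg(cfg, truth)
        amps = {}
        for s in "WN":
            eps = episodes(h, s)
            ep = max(eps, key=lambda e: e.duration_s)
            amps[s] = emg_amplitude(rec["EMG"][ep.sample_slice(rec.fs)], rec.fs)
        assert amps["W"] / amps["N"] == pytest.approx(5.0, rel=0.1)

    def test_ecg_disabled_empties_ledger(self):
        cfg = SimConfig(seed=13, duration_s=500.0, ecg_enabled=False)
        h, truth = simulate_hypnogram(cfg)
        simulate_eeg_emg(cfg, truth)
        assert truth.r_times.size == 0

    def test_phasic_intervals_inside_rem(self, session):
        cfg, h, truth, rec = session
        for a, b in truth.phasic_intervals:
            assert h.state_at(a) == "R" and h.state_at(b - 1e-3) == "R"

    def test_signal_generation_deterministic(self):
        cfg = SimConfig(seed=13, duration_s=300.0)
        h, t1 = simulate_hypnogram(cfg)
        r1 = simulate_eeg_emg(cfg, t1)
        _, t2 = simulate_hypnogram(cfg)
        r2 = simulate_eeg_emg(cfg, t2)
        np.testing.assert_array_equal(r1["EEG_parietal"], r2["EEG_parietal"])
        np.testing.assert_array_equal(r1["EMG"], r2["EMG"])


class TestPupil:
    def test_single_injected_saccade_single_peak(self):
        cfg = SimConfig(seed=19, duration_s=600.0)
        h, truth = block_hypnogram(600.0, blocks=(("R", 600.0),))
        truth.saccade_times = None
        cfg2 = SimConfig(seed=19, duration_s=600.0, saccade_rate_per_min=0.1)
        trace = simulate_pupil(cfg2, truth)
        from sleepkit.eye_movement import detect_ems

        events, _ = detect_ems(trace, h)
        tol = 2 / cfg.camera_fs
        for s in truth.saccade_times:
            assert sum(abs(e.t - s) <= tol for e in events) == 1

    def test_zero_saccade_rate_never_crosses_two_sd(self):
        """Bounded quasi-periodic jitter stays under the 2-SD criterion."""
        cfg = SimConfig(seed=23, duration_s=1200.0, saccade_rate_per_min=0.0)
        h, truth = block_hypnogram(1200.0, blocks=(("R", 1200.0),))
        trace = simulate_pupil(cfg, truth)
        from sleepkit.eye_movement import pupil_acceleration

        accel = pupil_acceleration(trace)
        valid = ~np.isnan(accel)
        assert accel[valid].max() <= 2 * accel[valid].std()


class TestCalcium:
    def test_zero_motion_config_gives_zero_ledger(self):
        cfg = SimConfig(seed=29, duration_s=60.0, motion_amp_px=0,
                        n_cells_per_subclass=2)
        h, truth = block_hypnogram(60.0)
        truth.phasic_intervals = np.zeros((0, 2))
        simulate_calcium(cfg, truth)
        assert (truth.motion_shifts == 0).all()

    def test_noiseless_state_means_order_matches_labels(self):
        """Construction oracle: configured subclass rates order the noiseless
        per-state trace means for every cell."""
        cfg = SimConfig(seed=31, duration_s=600.0, n_cells_per_subclass=3)
        h, truth = block_hypnogram(600.0)
        truth.phasic_intervals = np.zeros((0, 2))
        simulate_calcium(cfg, truth)
        codes = h.sample_states(truth.cell_traces.shape[1], cfg.ca_fs)
        order_of = {
            "R>N>W": "RNW", "R>W>N": "RWN", "Wake-max": "W", "NREM-max": "N",
        }
        ok = 0
        for lbl, trace in zip(truth.cell_labels, truth.cell_traces):
            means = {s: trace[codes == s].mean() for s in "WNR"}
            expected = order_of[lbl]
            top = max(means, key=means.get)
            ok += top == expected[0]
        assert ok == len(truth.cell_labels)

    def test_cells_exceeding_fov_rejected(self):
        with pytest.raises(ValueError, match="field of view"):
            cfg = SimConfig(seed=1, duration_s=30.0, n_cells_per_subclass=40)
            h, truth = block_hypnogram(30.0)
            truth.phasic_intervals = np.zeros((0, 2))
            simulate_calcium(cfg, truth)

    def test_movie_deterministic(self):
        cfg = SimConfig(seed=37, duration_s=30.0, n_cells_per_subclass=2)
        h, truth = block_hypnogram(30.0)
        truth.phasic_intervals = np.zeros((0, 2))
        m1, _ = simulate_calcium(cfg, truth)
        h2, truth2 = block_hypnogram(30.0)
        truth2.phasic_intervals = np.zeros((0, 2))
        m2, _ = simulate_calcium(cfg, truth2)
        np.testing.assert_array_equal(m1.frames, m2.frames)


class TestPhotometry:
    def test_ledger_filled_and_deterministic(self):
        cfg = SimConfig(seed=41, duration_s=300.0)
        h, truth = simulate_hypnogram(cfg)
        t, a, b = simulate_photometry(cfg, truth)
        assert truth.photometry_transient.size == t.size
        assert truth.bleach["tau_s"] == cfg.bleach_tau_s
        _, truth2 = simulate_hypnogram(cfg)
        t2, a2, b2 = simulate_photometry(cfg, truth2)
        np.testing.assert_array_equal(a, a2)
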