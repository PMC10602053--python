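import numpy as np
import pytest

from sleepkit.calcium import (
    MovieStack,
    RoiSet,
    activity_map,
    crosscorr_band_power,
    extract_dff,
    make_neuropil_rings,
    match_rois,
    motion_correct,
    phasic_event_activity,
    photometry_dff,
)
from sleepkit.core import BrainState, Episode
from sleepkit.phasic import PhasicEvent

from conftest import make_hypnogram


def loop_activity_map(frames):
    """Literal three-loop reference implementation of the activity map."""
    T, H, W = frames.shape
    fbar = frames.mean(axis=0)
    favg = frames.mean()
    out = np.zeros((H, W))
    for t in range(T):
        dev = (frames[t] - fbar) / (fbar + favg)
        sm = np.zeros((H, W))
        for i in range(H):
            for j in range(W):
                i2, j2 = min(i + 1, H - 1), min(j + 1, W - 1)
                sm[i, j] = (dev[i, j] + dev[i2, j] + dev[i, j2] + dev[i2, j2]) / 4
        out += sm
    return out / T


class TestActivityMap:
    def test_constant_movie_gives_zero_map(self):
        movie = MovieStack(np.full((10, 8, 8), 5.0))
        assert np.abs(activity_map(movie)).max() < 1e-12

    def test_flickering_pixel_dominates_its_neighborhood(self, rng):
        frames = np.full((50, 16, 16), 10.0, np.float32)
        frames[:, 7, 9] += 5 * rng.standard_normal(50)
        amap = np.abs(activity_map(MovieStack(frames)))
        peak = np.unravel_index(np.argmax(amap), amap.shape)
        assert abs(peak[0] - 7) <= 1 and abs(peak[1] - 9) <= 1

    def test_matches_loop_reference_on_random_stacks(self, rng):
        for _ in range(3):
            frames = rng.uniform(1, 10, size=(20, 16, 16)).astype(np.float32)
            vec = activity_map(MovieStack(frames))
            ref = loop_activity_map(frames.astype(np.float64))
            np.testing.assert_allclose(vec, ref, atol=1e-6)


class TestMotionCorrect:
    def _movie(self, rng, shifts=None, T=40):
        scene = rng.uniform(10, 50, size=(48, 48)).astype(np.float32)
        scene += 100 * np.exp(
            -((np.mgrid[0:48, 0:48][0] - 24) ** 2 + (np.mgrid[0:48, 0:48][1] - 20) ** 2) / 30
        )
        frames = np.stack([scene.copy() for _ in range(T)])
        if shifts is not None:
            for t, (dy, dx) in enumerate(shifts):
                frames[t] = np.roll(frames[t], (dy, dx), (0, 1))
        return MovieStack(frames)

    def test_zero_motion_recovers_zero_shifts(self, rng):
        movie = self._movie(rng)
        _, shifts, flagged = motion_correct(movie, patch=24, max_shift=6)
        assert (shifts == 0).all() and not flagged.any()

    def test_injected_shifts_recovered_exactly(self, rng):
        true = rng.integers(-3, 4, size=(40, 2))
        true[0] = 0
        movie = self._movie(rng, shifts=true)
        _, shifts, _ = motion_correct(movie, patch=24, max_shift=6)
        np.testing.assert_array_equal(shifts, true)

    def test_idempotent_after_correction(self, rng):
        true = rng.integers(-3, 4, size=(40, 2))
        true[0] = 0
        movie = self._movie(rng, shifts=true)
        corrected, _, _ = motion_correct(movie, patch=24, max_shift=6)
        _, residual, _ = motion_correct(corrected, patch=24, max_shift=6)
        assert (residual == 0).all()


def _simple_roi_movie(gain=0.0, noise=0.0, bleach=0.0, rate=0.3, T=400, seed=0):
    """One cell, known transient, uniform neuropil with weight map.

    ``bleach`` applies a global linear decay to the whole frame (a pure
    affine trend in every extracted trace).
    """
    rng = np.random.default_rng(seed)
    H = W = 32
    yy, xx = np.mgrid[0:H, 0:W]
    fp = np.exp(-((yy - 16) ** 2 + (xx - 16) ** 2) / 8.0)
    roi = fp > 0.3
    t = np.arange(T) / 20.0
    transient = np.convolve(
        rng.poisson(rate / 20, T).astype(float), np.exp(-np.arange(60) / 20.0)
    )[:T] * 20.0
    np_sig = 100.0 + 5 * np.sin(2 * np.pi * 0.05 * t)
    Tmap = np.ones((H, W))
    Tmap[roi] = gain if gain > 0 else 1.0
    frames = (
        5.0
        + Tmap[None] * np_sig[:, None, None]
        + fp[None] * (30.0 + transient)[:, None, None]
        + noise * rng.standard_normal((T, H, W))
    )
    frames *= (1 - bleach * t / t[-1])[:, None, None]
    movie = MovieStack(frames.astype(np.float32))
    rois = RoiSet(rois=[roi])
    return movie, rois, transient


class TestExtractDff:
    def test_zero_neuropil_noiseless_dff_proportional_to_transient(self):
        movie, rois, transient = _simple_roi_movie(gain=1.0)
        ts = extract_dff(movie, rois, c=1.0)
        r = np.corrcoef(ts.dff[0], transient)[0, 1]
        assert r > 0.995  # baseline division adds a slight time dependence

    def test_f_subt_identity_holds_exactly(self):
        movie, rois, _ = _simple_roi_movie(gain=1.0, noise=0.5)
        ts = extract_dff(movie, rois, c=0.8)
        np.testing.assert_allclose(ts.F_subt, ts.F - 0.8 * ts.F_np, atol=1e-5)
        # baseline affine in t
        d2 = np.diff(ts.B[0], 2)
        assert np.abs(d2).max() < 1e-8

    def test_pure_linear_bleach_absorbed_by_baseline(self):
        """No transients + global linear decay: the affine baseline fit
        removes the trend and ΔF/F stays within 1% of zero."""
        movie, rois, _ = _simple_roi_movie(gain=1.0, bleach=0.2, rate=0.0, T=800, seed=1)
        ts = extract_dff(movie, rois, c=1.0)
        assert np.abs(ts.dff[0]).max() < 0.01

    def test_implausible_c_warns(self):
        movie, rois, _ = _simple_roi_movie(gain=1.0)
        with pytest.warns(UserWarning, match="implausible"):
            extract_dff(movie, rois, c=2.0)

    def test_empty_ring_raises(self):
        movie, rois, _ = _simple_roi_movie()
        rois.rings = [np.zeros_like(rois.rois[0])]
        with pytest.raises(ValueError, match="ring"):
            extract_dff(movie, rois, c=1.0)

    def test_ring_excludes_all_rois_and_respects_valid_mask(self):
        H = W = 32
        yy, xx = np.mgrid[0:H, 0:W]
        r1 = (yy - 10) ** 2 + (xx - 10) ** 2 <= 9
        r2 = (yy - 16) ** 2 + (xx - 16) ** 2 <= 9
        valid = xx < 24
        rings = make_neuropil_rings([r1, r2], valid_mask=valid)
        for ring in rings:
            assert not (ring & (r1 | r2)).any()
            assert not (ring & ~valid).any()


class TestPhotometry:
    def test_perfectly_proportional_channels_give_zero_dff(self):
        t = np.arange(6000) / 100.0
        f405 = 70 + 10 * np.exp(-t / 600)
        f465 = 2.0 * f405
        dff = photometry_dff(f465, f405, fs=100.0)
        assert np.abs(dff).max() < 1e-9

    def test_shared_artifact_removed(self, rng):
        t = np.arange(60_000) / 100.0
        bleach = np.exp(-t / 900)
        signal = np.convolve(
            rng.poisson(0.005, t.size).astype(float), np.exp(-np.arange(300) / 150.0)
        )[: t.size]
        f465 = 100 + 30 * bleach + 5 * signal
        f405 = 70 + 20 * bleach
        base = photometry_dff(f465, f405, fs=100.0)
        artifact = 2.0 * np.sin(2 * np.pi * 0.01 * t)
        pert = photometry_dff(f465 + artifact, f405 + artifact, fs=100.0)
        assert np.corrcoef(base, pert)[0, 1] > 0.95

    def test_constant_405_is_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            photometry_dff(np.ones(1000) * 2, np.ones(1000), fs=100.0)


class TestMatchRois:
    def _rois(self, centers, shape=(64, 64)):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return [
            ((yy - cy) ** 2 + (xx - cx) ** 2 <= 12) for cy, cx in centers
        ]

    def test_translation_recovered_and_all_matched(self):
        a = RoiSet(rois=self._rois([(20, 20), (40, 28), (30, 45)]))
        b = RoiSet(rois=[np.roll(m, (3, -2), (0, 1)) for m in a.rois])
        pairs, tf = match_rois(a, b)
        assert pairs == [(0, 0), (1, 1), (2, 2)]
        assert (tf["dy"], tf["dx"]) == (3, -2) and tf["angle"] == 0.0

    def test_disjoint_sets_unmatched(self):
        a = RoiSet(rois=self._rois([(10, 10)]))
        b = RoiSet(rois=self._rois([(50, 50)]))
        pairs, _ = match_rois(a, b, max_shift=5)
        assert pairs == []

    def test_overlap_below_half_rejected(self):
        m = np.zeros((64, 64), bool)
        m[20:30, 20:30] = True  # 100 px
        shifted = np.roll(m, (0, 6), (0, 1))  # 40% overlap at identity
        anchor = np.zeros((64, 64), bool)
        anchor[40:60, 40:60] = True  # large anchor pins the transform
        a = RoiSet(rois=[m, anchor])
        b = RoiSet(rois=[shifted, anchor.copy()])
        pairs, tf = match_rois(a, b, max_shift=2)
        assert (0, 0) not in pairs and (1, 1) in pairs


class TestEventAndCrossCorr:
    def test_phasic_baseline_duration_equals_event_duration(self):
        fs = 20.0
        dff = np.zeros((3, 2000))
        dff[:, 1000:1030] = 1.0  # event at 50-51.5 s
        eps = [Episode(BrainState.REM, 0.0, 100.0)]
        ev = [PhasicEvent(50.0, 51.5, 0.1, 0.0, 0)]
        out = phasic_event_activity(dff, ev, eps, fs=fs)
        assert out.iloc[0]["mean_diff"] == pytest.approx(1.0)

    def test_event_without_baseline_room_skipped(self):
        fs = 20.0
        dff = np.ones((1, 2000))
        eps = [Episode(BrainState.REM, 50.0, 100.0)]
        ev = [PhasicEvent(50.2, 51.7, 0.1, 0.0, 0)]  # baseline would precede episode
        out = phasic_event_activity(dff, ev, eps, fs=fs)
        assert out.empty

    def test_crosscorr_peak_at_plus_five_seconds_for_leading_activity(self, rng):
        """ΔF/F equal to the band power shifted later by 5 s peaks at +5 s."""
        from sleepkit.spectral import BANDS

        fs_eeg, fs_ca = 200.0, 20.0
        dur = 400.0
        from scipy import signal as sps

        t = np.arange(int(dur * fs_eeg)) / fs_eeg
        amp = 1.0 + 0.5 * np.sin(2 * np.pi * 0.02 * t)
        sos = sps.butter(4, [10, 15], btype="bandpass", fs=fs_eeg, output="sos")
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(t.size))
        eeg = amp * carrier + 0.01 * rng.standard_normal(t.size)
        h = make_hypnogram("N" * int(dur / 2.5))
        tc = np.arange(int(dur * fs_ca)) / fs_ca
        lag = 5.0
        dff = (1.0 + 0.5 * np.sin(2 * np.pi * 0.02 * (tc + lag)))[None, :]
        out = crosscorr_band_power(dff, eeg, fs_eeg, h, BANDS["sigma"], fs=fs_ca)
        assert out["n_bouts"] == 1
        assert out["peak_lags_s"][0] == pytest.approx(5.0, abs=1.0)
        assert out["peak_values"][0] > 0.5
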