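"""Synthetic sleep-physiology sessions with ground-truth ledgers.

Every input the analysis stack consumes can be generated here: a semi-Markov
Wake/NREM/REM hypnogram, state-conditioned EEG (NREM δ plus spindle bursts,
REM θ with embedded phasic accelerations, wake pink broadband), EMG tone with
embedded ECG R-waves whose rate rises during phasic events, saccadic pupil
traces (optionally rendered to frames), a miniscope calcium movie whose cells
belong to known state subclasses, and a two-channel photometry pair.  Each
generator records what it injected in a :class:`GroundTruth` ledger so that
detector recall/precision and parameter recovery can be scored exactly.

The synthetic signals are stylized, not biophysical: spectra are shaped to
occupy the right bands at mouse-realistic amplitudes, which is what the
detection gates operate on.  Randomness is seeded per stage (a child seed is
derived from the master seed and a fixed stage id), so stages are
individually reproducible and identical seed + config gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal as sps

from .core import BrainState, Episode, Hypnogram, LaserTrain

__all__ = ["SimConfig", "GroundTruth", "simulate_hypnogram", "simulate_eeg_emg",
           "simulate_pupil", "render_pupil_frames", "simulate_calcium",
           "simulate_photometry", "simulate_session"]

_STAGES = {"hypnogram": 1, "eeg": 2, "emg": 3, "pupil": 4, "calcium": 5,
           "photometry": 6, "laser": 7}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Stage-local RNG derived from the master seed."""
    return np.random.default_rng([int(seed) % 2**31, _STAGES[stage]])


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic session.

    Defaults are mouse-realistic and sit inside the detection ranges of
    every analysis stage: tonic θ at 7.5 Hz accelerating to 9 Hz during
    phasic events (amplitude ×1.5, fixed 1.5 s duration), heart rate
    600 bpm rising to 660 bpm during phasic events with −80 μV R-waves,
    a 30 Hz pupil camera, and a 20 Hz miniscope.
    """

    seed: int = 0
    duration_s: float = 3600.0
    fs: float = 1000.0
    epoch_s: float = 2.5

    # semi-Markov state dynamics (exponential-with-floor durations, s)
    state_mean_s: dict = field(default_factory=lambda: {"W": 90.0, "N": 150.0, "R": 75.0})
    state_min_s: dict = field(default_factory=lambda: {"W": 10.0, "N": 30.0, "R": 20.0})
    #: embedded transition matrix; W→R is physiologically forbidden
    transition: dict = field(default_factory=lambda: {
        "W": {"N": 1.0, "R": 0.0},
        "N": {"W": 0.65, "R": 0.35},
        "R": {"W": 1.0, "N": 0.0},
    })
    #: multiplies the N→R hazard during laser intervals (1 = no effect)
    laser_nr_hazard_gain: float = 1.0

    # EEG composition (μV RMS unless stated)
    theta_tonic_hz: float = 7.5
    theta_phasic_hz: float = 9.0
    theta_amp_uV: float = 60.0  # sinusoid amplitude
    phasic_amp_gain: float = 1.5
    phasic_rate_per_min: float = 3.0
    phasic_duration_s: float = 1.5
    delta_rms_uV: float = 60.0
    spindle_rms_uV: float = 20.0
    spindle_rate_per_min: float = 6.0
    wake_broadband_rms_uV: float = 30.0
    rem_broadband_rms_uV: float = 8.0
    nrem_broadband_rms_uV: float = 12.0

    # EMG / ECG
    emg_rms_uV: dict = field(default_factory=lambda: {"W": 80.0, "N": 35.0, "R": 10.0})
    hr_tonic_bpm: float = 600.0
    hr_phasic_bpm: float = 660.0
    r_wave_amp_uV: float = -80.0
    ecg_enabled: bool = True

    # pupil
    camera_fs: float = 30.0
    saccade_rate_per_min: float = 3.0
    saccade_step_px: float = 15.0
    #: amplitudes (px) of the two slow quasi-periodic drift components;
    #: bounded drift keeps the 2-SD acceleration criterion false-positive free
    jitter_amp_px: tuple = (0.8, 0.4)
    jitter_freq_hz: tuple = (0.25, 0.6)

    # calcium imaging
    ca_fs: float = 20.0
    um_per_px: float = 1.2
    fov_px: int = 64
    n_cells_per_subclass: int = 5
    include_unmodulated: bool = False
    cell_sigma_px: float = 2.5
    transient_tau_s: float = 1.0
    transient_amp: float = 30.0
    #: resting (calcium-independent) brightness of each cell body
    cell_baseline: float = 30.0
    subclass_rates_hz: dict = field(default_factory=lambda: {
        "R>N>W": {"W": 0.02, "N": 0.12, "R": 0.45},
        "R>W>N": {"W": 0.12, "N": 0.02, "R": 0.45},
        "Wake-max": {"W": 0.45, "N": 0.05, "R": 0.12},
        "NREM-max": {"W": 0.05, "N": 0.45, "R": 0.12},
        # state-independent noise cells: no transients, sensor noise only
        "unmodulated": {"W": 0.0, "N": 0.0, "R": 0.0},
    })
    #: subclass whose rate is multiplied during phasic θ events (None = none)
    phasic_coupled_subclass: str | None = "R>W>N"
    phasic_rate_gain: float = 4.0
    neuropil_gain: float = 0.7
    neuropil_base: float = 100.0
    camera_dark: float = 5.0
    movie_noise: float = 1.0
    motion_amp_px: int = 2

    # photometry
    phot_fs: float = 100.0
    bleach_tau_s: float = 2000.0
    bleach_frac: float = 0.3

    def __post_init__(self) -> None:
        for s, row in self.transition.items():
            if sum(row.values()) <= 0:
                raise ValueError(f"state {s} is absorbing (transition row sums to 0)")
        if self.transition["W"].get("R", 0.0) != 0.0:
            raise ValueError("W->R transitions are forbidden")
        if self.fs < 4 * self.theta_phasic_hz:
            raise ValueError("fs too low for the theta band")
        for d in (self.state_mean_s, self.state_min_s):
            if any(v <= 0 for v in d.values()):
                raise ValueError("state durations must be positive")


@dataclass
class GroundTruth:
    """Ledger of everything the generators injected."""

    hypnogram: Hypnogram = None
    episode_ledger: list = field(default_factory=list)  # (state, start_s, end_s)
    laser: LaserTrain | None = None
    phasic_intervals: np.ndarray = None  # (n, 2) s
    r_times: np.ndarray = None
    saccade_times: np.ndarray = None
    cell_labels: list = field(default_factory=list)
    cell_traces: np.ndarray = None  # noiseless transients (n_cells, T)
    footprints: np.ndarray = None  # (n_cells, H, W)
    roi_masks: list = field(default_factory=list)
    motion_shifts: np.ndarray = None  # (T, 2) injected (dy, dx)
    neuropil_gain: float = None
    bleach: dict = field(default_factory=dict)
    photometry_transient: np.ndarray = None


# --------------------------------------------------------------- hypnogram


def simulate_hypnogram(
    cfg: SimConfig,
    laser: LaserTrain | None = None,
    seed: int | None = None,
) -> tuple[Hypnogram, GroundTruth]:
    """Semi-Markov hypnogram on the 2.5 s grid.

    Bout durations are exponential with a floor (discretized per epoch);
    after the floor, the per-epoch hazard of leaving is split across exit
    states by the transition row.  During laser intervals the N→R hazard is
    multiplied by ``laser_nr_hazard_gain``, which is how an optogenetic
    REM-induction effect is emulated (1.0 = no effect).
    """
    rng = stage_rng(cfg.seed if seed is None else seed, "hypnogram")
    n_epochs = int(round(cfg.duration_s / cfg.epoch_s))
    states = np.empty(n_epochs, dtype="U1")
    in_laser = np.zeros(n_epochs, bool)
    if laser is not None:
        t = np.arange(n_epochs) * cfg.epoch_s
        for on, off in laser.intervals():
            in_laser |= (t >= on) & (t < off)

    hazards = {}
    for s in "WNR":
        excess = max(cfg.state_mean_s[s] - cfg.state_min_s[s], cfg.epoch_s)
        base = cfg.epoch_s / excess
        hazards[s] = {t: base * p for t, p in cfg.transition[s].items() if p > 0}
    floors = {s: int(round(cfg.state_min_s[s] / cfg.epoch_s)) for s in "WNR"}

    u = rng.random(n_epochs)
    state = "N"
    age = 0
    ledger = []
    bout_start = 0
    for k in range(n_epochs):
        states[k] = state
        age += 1
        if age < floors[state]:
            continue
        h = dict(hazards[state])
        if state == "N" and in_laser[k] and "R" in h:
            h["R"] = min(h["R"] * cfg.laser_nr_hazard_gain, 1.0)
        total = 0.0
        nxt = None
        for tgt, hz in h.items():
            if u[k] < total + hz:
                nxt = tgt
                break
            total += hz
        if nxt is not None:
            ledger.append((state, bout_start * cfg.epoch_s, (k + 1) * cfg.epoch_s))
            state = nxt
            age = 0
            bout_start = k + 1
    ledger.append((state, bout_start * cfg.epoch_s, n_epochs * cfg.epoch_s))
    h = Hypnogram(states=states, epoch_s=cfg.epoch_s)
    truth = GroundTruth(hypnogram=h, episode_ledger=ledger, laser=laser)
    return h, truth


def block_hypnogram(
    duration_s: float,
    epoch_s: float = 2.5,
    blocks: tuple = (("N", 60.0), ("R", 30.0), ("W", 30.0)),
) -> tuple[Hypnogram, GroundTruth]:
    """Deterministic repeating-block hypnogram (a designed state schedule).

    Useful for recovery studies that need every state well sampled
    regardless of the seed; the ledger is filled like the stochastic
    generator's.
    """
    n_epochs = int(round(duration_s / epoch_s))
    states = np.empty(n_epochs, dtype="U1")
    ledger = []
    k = 0
    while k < n_epochs:
        for code, dur in blocks:
            ne = min(int(round(dur / epoch_s)), n_epochs - k)
            if ne == 0:
                break
            states[k : k + ne] = code
            ledger.append((code, k * epoch_s, (k + ne) * epoch_s))
            k += ne
    h = Hypnogram(states=states, epoch_s=epoch_s)
    return h, GroundTruth(hypnogram=h, episode_ledger=ledger)


def default_laser_train(cfg: SimConfig, duration_s: float = 120.0,
                        period_range_s: tuple = (780.0, 1020.0),
                        seed: int | None = None) -> LaserTrain:
    """Open-loop 120 s trains every 13–17 min, jittered, inside the session."""
    rng = stage_rng(cfg.seed if seed is None else seed, "laser")
    onsets = []
    t = duration_s + 60.0  # leave room for a full baseline interval
    while t + duration_s < cfg.duration_s:
        onsets.append(t)
        t += rng.uniform(*period_range_s)
    return LaserTrain(onsets=np.array(onsets), duration_s=duration_s, mode="open_loop")


# --------------------------------------------------------------- EEG / EMG


def _unit_rms(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-power noise, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    return _unit_rms(np.fft.irfft(spec, n))


def _bandlimited(n: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _unit_rms(sps.sosfiltfilt(sos, rng.standard_normal(n)))


def _draw_phasic_intervals(
    rem_eps: list[tuple[float, float]], cfg: SimConfig, rng
) -> np.ndarray:
    """Poisson phasic events of fixed duration within REM, clipped to bounds."""
    rate = cfg.phasic_rate_per_min / 60.0
    dur = cfg.phasic_duration_s
    out = []
    for start, end in rem_eps:
        t = start + 1.0  # skip the episode edge
        while True:
            t += rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if t + dur > end - 0.5:
                break
            out.append((t, t + dur))
            t += dur + 0.5  # refractory keeps events disjoint
    return np.array(out).reshape(-1, 2)


def _beat_times(duration_s: float, rate_of_t, rng) -> np.ndarray:
    """Quasi-periodic beat times from an instantaneous rate (bpm) function."""
    times = []
    t = rng.uniform(0, 0.1)
    while t < duration_s:
        times.append(t)
        t += 60.0 / rate_of_t(t)
    return np.array(times)


def _ecg_template(fs: float, amp: float) -> np.ndarray:
    """Biphasic R-wave: sharp negative peak of height ``amp`` plus rebound."""
    t = np.arange(int(0.024 * fs)) / fs - 0.012
    neg = np.exp(-0.5 * (t / 0.0025) ** 2)
    pos = 0.35 * np.exp(-0.5 * ((t - 0.007) / 0.004) ** 2)
    tpl = pos - neg
    return tpl * abs(amp) / abs(tpl.min())


def simulate_eeg_emg(
    cfg: SimConfig, truth: GroundTruth, seed: int | None = None
):
    """State-conditioned EEG and EMG for the hypnogram in ``truth``.

    Fills ``truth.phasic_intervals`` and ``truth.r_times``; returns a
    :class:`~sleepkit.core.SignalRecording` with EEG_frontal, EEG_parietal
    and EMG channels (μV).
    """
    from .core import SignalRecording

    h = truth.hypnogram
    master = cfg.seed if seed is None else seed
    rng = stage_rng(master, "eeg")
    rng_emg = stage_rng(master, "emg")
    n = int(round(h.duration_s * cfg.fs))
    codes = h.sample_states(n, cfg.fs)
    t = np.arange(n) / cfg.fs

    rem_eps = [(a, b) for s, a, b in truth.episode_ledger if s == "R"]
    phasic = _draw_phasic_intervals(rem_eps, cfg, rng)
    truth.phasic_intervals = phasic
    in_phasic = np.zeros(n, bool)
    for a, b in phasic:
        in_phasic[int(a * cfg.fs) : int(b * cfg.fs)] = True

    # REM theta: frequency-modulated sinusoid, phase-continuous
    freq = np.where(in_phasic, cfg.theta_phasic_hz, cfg.theta_tonic_hz)
    phase = 2 * np.pi * np.cumsum(freq) / cfg.fs
    amp = np.where(in_phasic, cfg.theta_amp_uV * cfg.phasic_amp_gain, cfg.theta_amp_uV)
    theta = amp * np.cos(phase)

    delta = cfg.delta_rms_uV * _bandlimited(n, cfg.fs, 1.5, 4.0, rng)
    sigma_carrier = _bandlimited(n, cfg.fs, 10.0, 15.0, rng)
    # spindle bursts: 0.5 s Hann envelopes at Poisson times within NREM
    env = np.zeros(n)
    burst = sps.windows.hann(int(0.5 * cfg.fs))
    rate = cfg.spindle_rate_per_min / 60.0
    tt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
    while tt < h.duration_s - 0.5:
        i = int(tt * cfg.fs)
        if codes[i] == "N":
            env[i : i + burst.size] += burst[: n - i]
        tt += rng.exponential(1.0 / rate)
    spindles = cfg.spindle_rms_uV * 2.0 * sigma_carrier * env

    pink1 = _pink(n, rng)
    pink2 = _pink(n, rng)

    is_w = codes == "W"
    is_n = codes == "N"
    is_r = codes == "R"
    eeg_par = (
        is_r * (theta + cfg.rem_broadband_rms_uV * pink1)
        + is_n * (delta + spindles + cfg.nrem_broadband_rms_uV * pink1)
        + is_w * (cfg.wake_broadband_rms_uV * pink1)
    )
    eeg_fro = (
        is_r * (0.6 * theta + cfg.rem_broadband_rms_uV * pink2)
        + is_n * (1.2 * delta + spindles + cfg.nrem_broadband_rms_uV * pink2)
        + is_w * (cfg.wake_broadband_rms_uV * pink2)
    )

    emg_rms = np.select([is_w, is_n, is_r],
                        [cfg.emg_rms_uV["W"], cfg.emg_rms_uV["N"], cfg.emg_rms_uV["R"]])
    emg = emg_rms * rng_emg.standard_normal(n)
    if cfg.ecg_enabled and cfg.r_wave_amp_uV != 0:
        def rate_of(tq: float) -> float:
            i = min(int(tq * cfg.fs), n - 1)
            return cfg.hr_phasic_bpm if in_phasic[i] else cfg.hr_tonic_bpm

        beats = _beat_times(h.duration_s, rate_of, rng_emg)
        tpl = _ecg_template(cfg.fs, cfg.r_wave_amp_uV)
        half = int(0.012 * cfg.fs)
        for b in beats:
            i = int(round(b * cfg.fs)) - half
            if 0 <= i and i + tpl.size <= n:
                emg[i : i + tpl.size] += tpl
        # ledger: time of the negative peak
        truth.r_times = beats
    else:
        truth.r_times = np.array([])

    return SignalRecording(
        channels={"EEG_frontal": eeg_fro, "EEG_parietal": eeg_par, "EMG": emg},
        fs=cfg.fs,
    )


# -------------------------------------------------------------------- pupil


def simulate_pupil(cfg: SimConfig, truth: GroundTruth, seed: int | None = None):
    """Saccadic pupil-position trace on the camera clock.

    Gaze is piecewise constant with step displacements at Poisson saccade
    times during REM, on top of a slow bounded quasi-periodic drift (the
    tracking jitter).  Fills ``truth.saccade_times``; returns a
    :class:`~sleepkit.eye_movement.PupilTrace`.
    """
    from .eye_movement import PupilTrace

    rng = stage_rng(cfg.seed if seed is None else seed, "pupil")
    h = truth.hypnogram
    n = int(round(h.duration_s * cfg.camera_fs))
    t = np.arange(n) / cfg.camera_fs

    rem_eps = [(a, b) for s, a, b in truth.episode_ledger if s == "R"]
    rate = cfg.saccade_rate_per_min / 60.0
    sacc = []
    for start, end in rem_eps:
        tt = start
        while rate > 0:
            tt += rng.exponential(1.0 / rate)
            if tt >= end - 0.2:
                break
            sacc.append(tt)
    sacc = np.array(sacc)
    truth.saccade_times = sacc

    x = np.full(n, 80.0)
    y = np.full(n, 60.0)
    for s in sacc:
        ang = rng.uniform(0, 2 * np.pi)
        i = int(round(s * cfg.camera_fs))
        x[i:] += cfg.saccade_step_px * np.cos(ang)
        y[i:] += cfg.saccade_step_px * np.sin(ang)
    for axis in (x, y):
        for a, f in zip(cfg.jitter_amp_px, cfg.jitter_freq_hz):
            axis += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return PupilTrace(t=t, x=x, y=y, valid=np.ones(n, bool))


def render_pupil_frames(
    x: np.ndarray, y: np.ndarray, shape: tuple[int, int] = (120, 160),
    radius: float = 10.0, bg: float = 200.0, pupil: float = 30.0,
) -> np.ndarray:
    """Render a dark pupil disk on a bright field for the contour detector."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    frames = np.empty((x.size, H, W), np.float32)
    for i in range(x.size):
        d2 = (xx - x[i]) ** 2 + (yy - y[i]) ** 2
        img = np.where(d2 <= radius**2, pupil, bg).astype(np.float32)
        frames[i] = ndimage.gaussian_filter(img, 1.0)
    return frames


# ------------------------------------------------------------------ calcium


def _place_cells(n_cells: int, fov: int, margin: int, min_dist: float, rng):
    """Cell centres on a shuffled centred grid, kept inside the lens aperture."""
    pitch = min_dist * 1.05
    n_side = int(fov // pitch) + 1
    offsets = (np.arange(n_side) - (n_side - 1) / 2) * pitch
    gy, gx = np.meshgrid(offsets, offsets, indexing="ij")
    grid = np.column_stack([gy.ravel(), gx.ravel()]) + fov / 2
    r_max = fov / 2 - margin
    grid = grid[np.hypot(*(grid - fov / 2).T) <= r_max]
    if grid.shape[0] < n_cells:
        raise ValueError("cells exceed the field of view at this density")
    rng.shuffle(grid)
    jitter = rng.uniform(-0.5, 0.5, size=(n_cells, 2))
    return grid[:n_cells] + jitter


def simulate_calcium(cfg: SimConfig, truth: GroundTruth, seed: int | None = None):
    """Miniscope movie with known cells, neuropil, vessel and motion.

    Pixel model: ``dark + T(x,y)·np_sig(t) + Σ footprint_i·trace_i + noise``
    where the neuropil transmissivity map ``T`` is 1 in clear tissue, the
    configured ``neuropil_gain`` under cell bodies and the blood vessel
    (both occlude local fluorescence the same way), and 0 off-lens — so the
    blood-vessel calibration ratio recovers the gain exactly.  Per-frame
    integer shifts from a clipped random walk are applied last (the motion
    ledger).  Returns ``(MovieStack, RoiSet)`` and fills the cell/motion
    entries of ``truth``.
    """
    from .calcium import MovieStack, RoiSet

    rng = stage_rng(cfg.seed if seed is None else seed, "calcium")
    h = truth.hypnogram
    T = int(round(h.duration_s * cfg.ca_fs))
    fov = cfg.fov_px
    codes = h.sample_states(T, cfg.ca_fs)

    labels = []
    for sub, cnt in (
        (s, cfg.n_cells_per_subclass)
        for s in ("R>N>W", "R>W>N", "Wake-max", "NREM-max")
    ):
        labels += [sub] * cnt
    if cfg.include_unmodulated:
        labels += ["unmodulated"] * cfg.n_cells_per_subclass
    n_cells = len(labels)
    truth.cell_labels = labels

    margin = int(2 * cfg.cell_sigma_px) + 2
    pos = _place_cells(n_cells, fov, margin, 4 * cfg.cell_sigma_px, rng)
    yy, xx = np.mgrid[0:fov, 0:fov]
    footprints = np.empty((n_cells, fov, fov), np.float32)
    roi_masks = []
    for i, (cy, cx) in enumerate(pos):
        g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * cfg.cell_sigma_px**2))
        g[g < 0.05] = 0
        footprints[i] = g
        roi_masks.append(g > 0.3)
    truth.footprints = footprints
    truth.roi_masks = roi_masks

    in_phasic = np.zeros(T, bool)
    if truth.phasic_intervals is not None:
        for a, b in truth.phasic_intervals:
            in_phasic[int(a * cfg.ca_fs) : int(b * cfg.ca_fs)] = True

    kernel = np.exp(-np.arange(int(6 * cfg.transient_tau_s * cfg.ca_fs)) /
                    (cfg.transient_tau_s * cfg.ca_fs))
    traces = np.empty((n_cells, T), np.float32)
    for i, lbl in enumerate(labels):
        rates = cfg.subclass_rates_hz[lbl]
        r = np.select([codes == "W", codes == "N", codes == "R"],
                      [rates["W"], rates["N"], rates["R"]]).astype(float)
        if cfg.phasic_coupled_subclass == lbl:
            r[in_phasic] *= cfg.phasic_rate_gain
        spikes = rng.poisson(r / cfg.ca_fs)
        traces[i] = np.convolve(spikes.astype(float), kernel)[:T] * cfg.transient_amp
    truth.cell_traces = traces

    # static scene: lens aperture, blood vessel stripe, transmissivity map
    lens = (yy - fov / 2) ** 2 + (xx - fov / 2) ** 2 <= (fov / 2 - 1) ** 2
    vessel = (np.abs(yy - 0.6 * xx - fov * 0.12) < 1.6) & lens
    Tmap = np.where(lens, 1.0, 0.0)
    Tmap[vessel] = cfg.neuropil_gain
    union = np.zeros((fov, fov), bool)
    for m in roi_masks:
        union |= m
    Tmap[union] = cfg.neuropil_gain
    truth.neuropil_gain = cfg.neuropil_gain

    np_sig = cfg.neuropil_base * (
        1.0 + 0.08 * _unit_rms(ndimage.gaussian_filter1d(rng.standard_normal(T), 2 * cfg.ca_fs))
        + 0.002 * traces.mean(axis=0)
    )
    # static spatial texture (out-of-focus vasculature/speckle); gives the
    # motion estimator unambiguous 2-D structure, as real tissue does
    texture = 1.0 + 0.15 * ndimage.gaussian_filter(rng.standard_normal((fov, fov)), 2.0)
    texture = np.clip(texture, 0.5, None)

    cell_img = np.einsum("ct,chw->thw", traces + cfg.cell_baseline, footprints * lens)
    movie = (
        cfg.camera_dark
        + (Tmap * texture)[None] * np_sig[:, None, None]
        + cell_img
        + cfg.movie_noise * rng.standard_normal((T, fov, fov))
    ).astype(np.float32)

    if cfg.motion_amp_px > 0:
        steps = rng.integers(-1, 2, size=(T, 2))
        shifts = np.clip(np.cumsum(steps, axis=0), -cfg.motion_amp_px, cfg.motion_amp_px)
        shifts[0] = 0
    else:
        shifts = np.zeros((T, 2), int)
    truth.motion_shifts = shifts
    for f in range(T):
        if shifts[f].any():
            movie[f] = np.roll(movie[f], (shifts[f][0], shifts[f][1]), (0, 1))

    # calibration regions are chosen clear of cell bodies and their tails
    clear = ~ndimage.binary_dilation(union, iterations=5)
    vessel_clear = vessel & clear
    dvessel = ndimage.distance_transform_edt(~vessel)
    near = lens & clear & (dvessel > 3) & (dvessel < 8)
    rois = RoiSet(
        rois=roi_masks,
        blood_vessel=vessel_clear,
        near_blood_vessel=near,
        off_lens=~ndimage.binary_dilation(lens, iterations=2),
        valid_mask=lens & ~vessel,
    )
    return MovieStack(movie, cfg.ca_fs, cfg.um_per_px), rois


def simulate_photometry(cfg: SimConfig, truth: GroundTruth, seed: int | None = None):
    """Two-channel photometry: 465 nm signal + bleach, 405 nm control.

    The 465 channel carries the population calcium transient on top of an
    exponential bleach; the 405 channel carries the same bleach shape and a
    shared slow motion artifact but no calcium signal.  Fills
    ``truth.bleach`` and ``truth.photometry_transient``; returns
    ``(t, f465, f405)``.
    """
    rng = stage_rng(cfg.seed if seed is None else seed, "photometry")
    h = truth.hypnogram
    T = int(round(h.duration_s * cfg.phot_fs))
    t = np.arange(T) / cfg.phot_fs
    codes = h.sample_states(T, cfg.phot_fs)

    rate = np.select([codes == "W", codes == "N", codes == "R"], [0.3, 0.1, 0.8])
    kernel = np.exp(-np.arange(int(6 * 1.5 * cfg.phot_fs)) / (1.5 * cfg.phot_fs))
    transient = np.convolve(rng.poisson(rate / cfg.phot_fs).astype(float), kernel)[:T]
    truth.photometry_transient = transient

    bleach = np.exp(-t / cfg.bleach_tau_s)
    artifact = 0.5 * ndimage.gaussian_filter1d(rng.standard_normal(T), cfg.phot_fs)
    f465 = 100.0 * (1 - cfg.bleach_frac + cfg.bleach_frac * bleach) + 8.0 * transient \
        + artifact + 0.2 * rng.standard_normal(T)
    f405 = 70.0 * (1 - cfg.bleach_frac + cfg.bleach_frac * bleach) + artifact \
        + 0.2 * rng.standard_normal(T)
    truth.bleach = {"tau_s": cfg.bleach_tau_s, "frac": cfg.bleach_frac}
    return t, f465, f405


# ------------------------------------------------------------------ session


def simulate_session(
    cfg: SimConfig,
    laser: LaserTrain | None = None,
    with_pupil: bool = False,
    with_calcium: bool = False,
    with_photometry: bool = False,
) -> dict:
    """Generate a coherent session: hypnogram, EEG/EMG and optional extras."""
    h, truth = simulate_hypnogram(cfg, laser)
    out = {"config": cfg, "hypnogram": h, "truth": truth}
    out["recording"] = simulate_eeg_emg(cfg, truth)
    if with_pupil:
        out["pupil"] = simulate_pupil(cfg, truth)
    if with_calcium:
        movie, rois = simulate_calcium(cfg, truth)
        out["movie"], out["rois"] = movie, rois
    if with_photometry:
        out["photometry"] = simulate_photometry(cfg, truth)
    return out


def rem_episode_truths(truth: GroundTruth) -> list[Episode]:
    """REM episodes of the ledger as :class:`Episode` objects."""
    return [
        Episode(state=BrainState.REM, start_s=a, end_s=b)
        for s, a, b in truth.episode_ledger
        if s == "R"
    ]
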