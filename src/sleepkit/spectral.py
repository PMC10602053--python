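"""Power spectral densities, spectrograms and band powers.

PSDs are estimated with Welch's method (Hann window, half-overlapping 2 s
segments, per-segment mean removal, no zero padding), in μV²/Hz.  The
spectrogram applies that estimator to sliding half-overlapping 5 s windows,
giving the 2.5 s time resolution on which hypnograms are scored.  Band power
is a midpoint Riemann sum of the PSD: bins whose centre frequency ``f``
satisfies ``lo <= f < hi`` contribute ``psd[f] * df``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import LaserTrain, SignalRecording

__all__ = [
    "BandDefinition",
    "BANDS",
    "PSD",
    "Spectrogram",
    "welch_psd",
    "spectrogram",
    "band_power",
    "emg_amplitude",
    "laser_triggered_spectrogram",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo_hz < self.hi_hz:
            raise ValueError("band requires 0 <= lo < hi")


#: Conventional rodent EEG bands plus the EMG integration range.
BANDS = {
    "delta": BandDefinition("delta", 0.5, 4.5),
    "theta": BandDefinition("theta", 6.0, 9.5),
    "sigma": BandDefinition("sigma", 10.0, 15.0),
    "gamma": BandDefinition("gamma", 50.0, 90.0),
    "emg": BandDefinition("emg", 5.0, 100.0),
}


@dataclass(frozen=True)
class PSD:
    freqs: np.ndarray
    power: np.ndarray  # μV²/Hz

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass(frozen=True)
class Spectrogram:
    times: np.ndarray  # window centres, s
    freqs: np.ndarray
    power: np.ndarray  # (n_freqs, n_times), μV²/Hz
    window_s: float
    step_s: float


def welch_psd(x: np.ndarray, fs: float, window_s: float = 2.0) -> PSD:
    """Welch PSD with Hann window and half-overlapping ``window_s`` segments."""
    x = np.asarray(x, float)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ValueError(
            f"trace of {x.size} samples shorter than one {window_s} s window"
        )
    freqs, pxx = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    return PSD(freqs=freqs, power=pxx)


def spectrogram(
    x: np.ndarray,
    fs: float,
    window_s: float = 5.0,
    psd_window_s: float = 2.0,
    step_s: float | None = None,
) -> Spectrogram:
    """Sliding-window PSD: half-overlapping ``window_s`` windows, Welch inside.

    ``step_s`` defaults to ``window_s / 2`` (half overlap); a smaller step
    (e.g. 0.5 s for 2.5 s windows, 80% overlap) raises temporal resolution.
    Incomplete trailing windows are dropped.  Column ``k`` equals
    ``welch_psd`` of the slice starting at ``k * step_s`` exactly.
    """
    x = np.asarray(x, float)
    step_s = window_s / 2.0 if step_s is None else step_s
    nwin = int(round(window_s * fs))
    nstep = int(round(step_s * fs))
    n_cols = (x.size - nwin) // nstep + 1
    if n_cols < 1:
        raise ValueError("trace shorter than one spectrogram window")
    idx = np.arange(nwin)[None, :] + nstep * np.arange(n_cols)[:, None]
    frames = x[idx]  # (n_cols, nwin)
    psd = welch_psd(frames, fs, psd_window_s)
    times = (np.arange(n_cols) * nstep + nwin / 2.0) / fs
    return Spectrogram(
        times=times,
        freqs=psd.freqs,
        power=psd.power.T,
        window_s=window_s,
        step_s=step_s,
    )


def band_power(psd: PSD | Spectrogram, band: BandDefinition) -> np.ndarray | float:
    """Midpoint Riemann sum of the PSD over ``[lo, hi)`` (μV²).

    For a :class:`Spectrogram`, returns the band power per column.
    """
    freqs = psd.freqs
    df = float(freqs[1] - freqs[0])
    if band.hi_hz > freqs[-1] + df / 2:
        raise ValueError(f"band {band.name} exceeds PSD range ({freqs[-1]} Hz)")
    mask = (freqs >= band.lo_hz) & (freqs < band.hi_hz)
    if isinstance(psd, Spectrogram):
        return psd.power[mask].sum(axis=0) * df
    out = np.sum(psd.power[..., mask], axis=-1) * df
    return float(out) if np.ndim(out) == 0 else out


def emg_amplitude(emg: np.ndarray, fs: float, window_s: float = 2.0) -> float:
    """EMG amplitude: sqrt of integrated 5–100 Hz EMG power (μV)."""
    return float(np.sqrt(band_power(welch_psd(emg, fs, window_s), BANDS["emg"])))


def _laser_mask(times: np.ndarray, laser: LaserTrain, window_s: float) -> np.ndarray:
    """True for spectrogram columns whose window overlaps a laser interval."""
    mask = np.zeros(times.size, bool)
    for on, off in laser.intervals():
        mask |= (times + window_s / 2 > on) & (times - window_s / 2 < off)
    return mask


def laser_triggered_spectrogram(
    rec: SignalRecording,
    laser: LaserTrain,
    pre_s: float = 120.0,
    post_s: float = 240.0,
    channel: str = "EEG_parietal",
    bands: dict[str, BandDefinition] | None = None,
):
    """Trial-averaged, normalized spectrogram around laser onsets.

    Each frequency row is normalized by its temporal mean over the columns
    *outside* laser intervals, so 1.0 means "at the recording's non-laser
    mean".  Returns ``(rel_times, freqs, avg, band_courses, trial_table)``
    where ``band_courses`` maps band name -> trial-averaged normalized power
    time course (Riemann sum over the normalized rows) and ``trial_table``
    holds per-trial mean band power in the laser interval vs the preceding
    equal-length baseline.
    """
    import pandas as pd

    bands = bands or {k: BANDS[k] for k in ("delta", "theta", "sigma", "gamma")}
    spec = spectrogram(rec[channel], rec.fs)
    off_mask = ~_laser_mask(spec.times, laser, spec.window_s)
    denom = spec.power[:, off_mask].mean(axis=1)
    # rows with negligible non-laser power carry no signal; zero them rather
    # than amplifying numerical leakage by a near-zero denominator
    dead = denom <= 1e-12 * denom.max()
    denom[dead] = 1.0
    norm = spec.power / denom[:, None]
    norm[dead] = 0.0

    n_pre = int(round(pre_s / spec.step_s))
    n_post = int(round(post_s / spec.step_s))
    trials = []
    for onset in laser.onsets:
        k = int(round(onset / spec.step_s))  # first window starting at onset
        if k - n_pre < 0 or k + n_post > norm.shape[1]:
            continue
        trials.append(norm[:, k - n_pre : k + n_post])
    if not trials:
        raise ValueError("no complete laser trials inside the spectrogram")
    stack = np.stack(trials)  # (n_trials, n_freqs, n_cols)
    avg = stack.mean(axis=0)
    rel_times = (np.arange(-n_pre, n_post) + 0.5) * spec.step_s

    df = float(spec.freqs[1] - spec.freqs[0])
    band_courses = {}
    rows = []
    n_laser = int(round(laser.duration_s / spec.step_s))
    for name, band in bands.items():
        fmask = (spec.freqs >= band.lo_hz) & (spec.freqs < band.hi_hz)
        per_trial = stack[:, fmask, :].sum(axis=1) * df  # (n_trials, n_cols)
        band_courses[name] = per_trial.mean(axis=0)
        laser_cols = slice(n_pre, n_pre + n_laser)
        base_cols = slice(n_pre - n_laser, n_pre)
        for t in range(per_trial.shape[0]):
            rows.append(
                {
                    "trial": t,
                    "band": name,
                    "baseline": per_trial[t, base_cols].mean(),
                    "laser": per_trial[t, laser_cols].mean(),
                }
            )
    return rel_times, spec.freqs, avg, band_courses, pd.DataFrame(rows)
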