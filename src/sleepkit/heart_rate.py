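"""Heart-rate extraction from nuchal EMG during REM sleep.

During REM atonia the ECG R-waves stand out of the quiet EMG as sharp
negative deflections.  Whether they can be isolated is decided per REM
episode from a *threshold curve*: the EMG is band-pass filtered 10–100 Hz,
and for thresholds rising from −100 to 0 μV the number of negative peaks
below each threshold is counted.  If R-waves clearly exceed the noise, the
curve jumps to a plateau (thresholds between the R-wave and noise
amplitudes) before sharply rising into the noise; an inflection point of the
smoothed curve in (−60, 0) μV — a concave-to-convex curvature change, with
evidence of a preceding plateau — accepts the episode and doubles as the
detection threshold.  Episodes without such an inflection are rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Episode
from .phasic import PhasicEvent, bandpass

__all__ = [
    "ThresholdCurve",
    "HeartbeatSeries",
    "threshold_curve",
    "select_threshold",
    "detect_r_waves",
    "heart_rate",
]

EMG_BAND = (10.0, 100.0)
REFRACTORY_S = 0.05  # mouse ceiling 1200 bpm
INFLECTION_RANGE = (-60.0, 0.0)
SMOOTH_LEN = 5


@dataclass(frozen=True)
class ThresholdCurve:
    thresholds: np.ndarray  # μV, increasing toward 0
    counts: np.ndarray  # negative peaks below each threshold


@dataclass(frozen=True)
class HeartbeatSeries:
    r_times: np.ndarray  # s, relative to episode start
    rate_bpm: np.ndarray  # per inter-beat interval (len = len(r_times) - 1)
    episode_id: int
    threshold_uV: float


def _negative_peaks(emg: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices and values of local minima separated by the refractory gap."""
    filt = bandpass(np.asarray(emg, float), fs, *EMG_BAND)
    idx, _ = sps.find_peaks(-filt, distance=max(1, int(round(REFRACTORY_S * fs))))
    return idx, filt[idx]


def threshold_curve(
    emg_rem: np.ndarray,
    fs: float,
    lo: float = -100.0,
    hi: float = 0.0,
    step: float = 1.0,
) -> ThresholdCurve:
    """Count negative peaks below each threshold on a 1 μV grid."""
    _, values = _negative_peaks(emg_rem, fs)
    thresholds = np.arange(lo, hi + step / 2, step)
    counts = (values[None, :] < thresholds[:, None]).sum(axis=1)
    return ThresholdCurve(thresholds=thresholds, counts=counts.astype(int))


def select_threshold(curve: ThresholdCurve) -> float | None:
    """Locate the plateau-to-noise inflection; None rejects the episode.

    The smoothed count curve's second difference must change sign from
    non-positive (plateau side) to positive inside (−60, 0) μV, and at the
    inflection at least half of the counted peaks must already lie below
    −60 μV (plateau evidence) — otherwise the curve is a featureless noise
    CDF and the episode is rejected.
    """
    c = np.convolve(curve.counts.astype(float), np.ones(SMOOTH_LEN) / SMOOTH_LEN, "same")
    d2 = np.diff(c, 2)  # d2[i] is curvature at thresholds[i + 1]
    thr = curve.thresholds[1:-1]
    in_range = (thr > INFLECTION_RANGE[0]) & (thr < INFLECTION_RANGE[1])
    i60 = int(np.searchsorted(curve.thresholds, INFLECTION_RANGE[0]))
    c60 = c[i60]
    if c60 <= 0:
        return None
    eps = 1e-9
    for i in np.flatnonzero(in_range):
        if d2[i] > eps and i > 0 and d2[i - 1] <= eps:
            if c60 >= 0.5 * c[i + 1]:
                return float(thr[i])
    return None


def detect_r_waves(
    emg_rem: np.ndarray, fs: float, threshold_uV: float
) -> np.ndarray:
    """R-wave times (s): negative peaks below the threshold, refractory-gated."""
    idx, values = _negative_peaks(emg_rem, fs)
    return idx[values < threshold_uV] / fs


def heart_rate(
    emg: np.ndarray,
    fs: float,
    episodes: list[Episode],
    phasic_events: list[PhasicEvent] | None = None,
) -> tuple[list[HeartbeatSeries], dict]:
    """Per-episode heartbeat series plus tonic/phasic mean rates.

    ``emg`` is the full-session EMG; episodes index into it.  Episodes whose
    threshold curve lacks an inflection are excluded (mirroring the exclusion
    of recordings with non-detectable R-waves).  Each inter-beat interval is
    assigned phasic if its midpoint falls inside a phasic θ event of the same
    episode, else tonic.
    """
    series: list[HeartbeatSeries] = []
    tonic_rates, phasic_rates = [], []
    summary_rows = []
    for ep_id, ep in enumerate(episodes):
        seg = np.asarray(emg, float)[ep.sample_slice(fs)]
        curve = threshold_curve(seg, fs)
        thr = select_threshold(curve)
        accepted = thr is not None
        n_beats = 0
        if accepted:
            r = detect_r_waves(seg, fs, thr)
            n_beats = r.size
            if r.size >= 2:
                ibi = np.diff(r)
                rate = 60.0 / ibi
                mid = ep.start_s + (r[:-1] + r[1:]) / 2.0
                is_phasic = np.zeros(mid.size, bool)
                for e in phasic_events or []:
                    is_phasic |= (mid >= e.start_s) & (mid < e.end_s)
                tonic_rates.append(rate[~is_phasic])
                phasic_rates.append(rate[is_phasic])
                series.append(
                    HeartbeatSeries(
                        r_times=r, rate_bpm=rate, episode_id=ep_id, threshold_uV=thr
                    )
                )
        summary_rows.append(
            {
                "episode_id": ep_id,
                "accepted": accepted,
                "threshold_uV": thr if accepted else np.nan,
                "n_beats": n_beats,
            }
        )
    if not series:
        warnings.warn("no REM episode passed the R-wave isolation criterion", stacklevel=2)
    tonic = np.concatenate(tonic_rates) if tonic_rates else np.array([])
    phasic = np.concatenate(phasic_rates) if phasic_rates else np.array([])
    summary = {
        "episodes": summary_rows,
        "mean_bpm_tonic": float(tonic.mean()) if tonic.size else np.nan,
        "mean_bpm_phasic": float(phasic.mean()) if phasic.size else np.nan,
        "n_accepted": len(series),
        "n_rejected": len(episodes) - len(series),
    }
    return series, summary
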