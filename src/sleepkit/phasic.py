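"""Phasic θ event detection during REM sleep.

Within REM sleep, θ oscillations intermittently accelerate and grow —
"phasic" REM, as opposed to the background "tonic" θ.  Events are detected
from the timing of θ troughs: the parietal EEG is band-pass filtered
5–12 Hz, troughs are found from the analytic-signal phase, and runs of
abnormally short smoothed inter-trough intervals mark candidate events.

The four gates, applied to the 11-point box-smoothed inter-trough interval
sequence, are:

1. the run is *continuously* (strictly) below the 10th percentile of all
   smoothed intervals,
2. the run spans at least 900 ms,
3. its minimum smoothed interval is below the 5th percentile, and
4. the mean θ amplitude over the run exceeds the mean amplitude over all of
   REM sleep.

Percentiles and the mean amplitude are pooled over all REM episodes of the
session that do not overlap laser stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Episode, LaserTrain
from .spectral import PSD, welch_psd

__all__ = [
    "PhasicEvent",
    "PhasicThresholds",
    "theta_troughs",
    "detect_phasic",
    "phasic_metrics",
    "laser_overlap_flags",
]


def laser_overlap_flags(episodes: list[Episode], laser: LaserTrain) -> list[bool]:
    """True for episodes overlapping any laser interval."""
    iv = laser.intervals()
    return [
        bool(np.any((iv[:, 0] < e.end_s) & (iv[:, 1] > e.start_s))) for e in episodes
    ]

THETA_BAND = (5.0, 12.0)
MIN_EVENT_S = 0.9
BOX_LEN = 11


@dataclass(frozen=True)
class PhasicEvent:
    start_s: float  # absolute time of first trough of the run
    end_s: float  # absolute time of last trough
    min_smoothed_iti_s: float
    mean_theta_amp: float  # μV
    episode_id: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PhasicThresholds:
    pct10_s: float
    pct5_s: float
    mean_rem_amp: float

    def __post_init__(self) -> None:
        if self.pct5_s > self.pct10_s:
            raise ValueError("5th percentile cannot exceed 10th percentile")


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def theta_troughs(
    eeg_rem: np.ndarray, fs: float, min_amp_uV: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """θ trough times and instantaneous amplitude for one REM episode.

    Returns ``(trough_times_s, amplitude, filtered)``.  The analytic-signal
    phase uses the peak = 0 rad convention, so troughs sit at ±π; they are
    found as local minima of the wrapped phase with value < −3 rad (one per
    cycle).  Times are relative to the start of the trace.
    """
    x = np.asarray(eeg_rem, float)
    min_len = int(3 * fs / THETA_BAND[0])  # filter warm-up
    if x.size < min_len:
        warnings.warn("episode shorter than filter warm-up; skipped", stacklevel=2)
        return np.array([]), np.array([]), np.zeros_like(x)
    filt = bandpass(x, fs, *THETA_BAND)
    analytic = sps.hilbert(filt)
    phase = np.angle(analytic)
    amp = np.abs(analytic)
    p = phase
    is_min = np.zeros(p.size, bool)
    is_min[1:-1] = (p[1:-1] < p[:-2]) & (p[1:-1] <= p[2:]) & (p[1:-1] < -3.0)
    # a trough needs an actual oscillation; a flat trace has none
    is_min &= amp > min_amp_uV
    troughs = np.flatnonzero(is_min)
    return troughs / fs, amp, filt


def _smooth_shrinking(x: np.ndarray, width: int = BOX_LEN) -> np.ndarray:
    """Box filter with window shrinking at the edges (centred, width 11)."""
    half = width // 2
    n = x.size
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        a, b = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[b] - csum[a]) / (b - a)
    return out


def detect_phasic(
    rem_traces: list[np.ndarray],
    fs: float,
    episodes: list[Episode] | None = None,
    thresholds: PhasicThresholds | None = None,
    laser_overlap: list[bool] | None = None,
) -> tuple[list[PhasicEvent], PhasicThresholds | None]:
    """Detect phasic θ events across a session's REM episodes.

    ``rem_traces`` holds one parietal-EEG trace per REM episode.  If
    ``thresholds`` is omitted, the percentile/amplitude thresholds are pooled
    over the supplied episodes that do not overlap laser stimulation
    (``laser_overlap`` flags; all False by default).  ``episodes`` (if given)
    provides absolute start times and ids for the returned events.
    """
    per_ep = []
    for trace in rem_traces:
        tt, amp, _ = theta_troughs(trace, fs)
        iti = np.diff(tt)
        smoothed = _smooth_shrinking(iti) if iti.size else iti
        per_ep.append((tt, amp, iti, smoothed))

    if thresholds is None:
        keep = [
            i
            for i in range(len(per_ep))
            if not (laser_overlap and laser_overlap[i])
        ]
        all_smoothed = np.concatenate(
            [per_ep[i][3] for i in keep if per_ep[i][3].size] or [np.array([])]
        )
        all_amp = np.concatenate(
            [per_ep[i][1] for i in keep if per_ep[i][1].size] or [np.array([])]
        )
        if all_smoothed.size < 1:
            warnings.warn("too few theta troughs to form thresholds", stacklevel=2)
            return [], None
        thresholds = PhasicThresholds(
            pct10_s=float(np.percentile(all_smoothed, 10)),
            pct5_s=float(np.percentile(all_smoothed, 5)),
            mean_rem_amp=float(all_amp.mean()),
        )

    events: list[PhasicEvent] = []
    for ep_i, (tt, amp, iti, smoothed) in enumerate(per_ep):
        if smoothed.size == 0:
            continue
        t_offset = episodes[ep_i].start_s if episodes else 0.0
        below = smoothed < thresholds.pct10_s  # strictly smaller
        # runs of consecutive below-threshold intervals
        edges = np.diff(np.concatenate([[0], below.view(np.int8), [0]]))
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)  # exclusive, in interval index
        for a, b in zip(starts, stops):
            # intervals a..b-1 -> troughs a..b
            t_start, t_end = tt[a], tt[b]
            if t_end - t_start < MIN_EVENT_S:
                continue
            min_iti = float(smoothed[a:b].min())
            if min_iti >= thresholds.pct5_s:
                continue
            i0, i1 = int(round(t_start * fs)), int(round(t_end * fs)) + 1
            mean_amp = float(amp[i0:i1].mean())
            if mean_amp <= thresholds.mean_rem_amp:
                continue
            events.append(
                PhasicEvent(
                    start_s=t_start + t_offset,
                    end_s=t_end + t_offset,
                    min_smoothed_iti_s=min_iti,
                    mean_theta_amp=mean_amp,
                    episode_id=ep_i,
                )
            )
    return events, thresholds


def phasic_metrics(
    events: list[PhasicEvent],
    rem_traces: list[np.ndarray],
    fs: float,
    episodes: list[Episode] | None = None,
    laser_overlap: list[bool] | None = None,
    psd_window_s: float = 2.0,
) -> dict:
    """Event frequency (events / min of REM) and tonic vs phasic PSDs.

    Frequency is reported overall and split by laser-on/off episode sets when
    ``laser_overlap`` is given.  The phasic PSD pools events whose duration
    is at least the PSD window (2 s); shorter events still count toward the
    frequency.  The tonic PSD pools the remaining REM samples.
    """
    total_min = sum(tr.size for tr in rem_traces) / fs / 60.0
    out: dict = {"events_per_min": len(events) / total_min if total_min else np.nan}
    if laser_overlap is not None:
        for label, flag in (("on", True), ("off", False)):
            idx = {i for i, f in enumerate(laser_overlap) if f == flag}
            mins = sum(rem_traces[i].size for i in idx) / fs / 60.0
            n_ev = sum(1 for e in events if e.episode_id in idx)
            out[f"events_per_min_laser_{label}"] = n_ev / mins if mins else np.nan

    nperseg = int(psd_window_s * fs)
    phasic_chunks, tonic_chunks = [], []
    for i, trace in enumerate(rem_traces):
        t_offset = episodes[i].start_s if episodes else 0.0
        mask = np.zeros(trace.size, bool)
        for e in events:
            if e.episode_id != i:
                continue
            a = int(round((e.start_s - t_offset) * fs))
            b = int(round((e.end_s - t_offset) * fs))
            if e.duration_s >= psd_window_s:
                phasic_chunks.append(trace[a:b])
            mask[a:b] = True
        for seg in _contiguous(~mask):
            if seg.stop - seg.start >= nperseg:
                tonic_chunks.append(trace[seg])

    out["phasic_psd"] = _pooled_psd(phasic_chunks, fs, psd_window_s)
    out["tonic_psd"] = _pooled_psd(tonic_chunks, fs, psd_window_s)
    return out


def _contiguous(mask: np.ndarray) -> list[slice]:
    edges = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    return [
        slice(a, b)
        for a, b in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1))
    ]


def _pooled_psd(chunks: list[np.ndarray], fs: float, window_s: float) -> PSD | None:
    psds = [welch_psd(c, fs, window_s) for c in chunks]
    if not psds:
        return None
    weights = np.array([c.size for c in chunks], float)
    power = np.average([p.power for p in psds], axis=0, weights=weights)
    return PSD(freqs=psds[0].freqs, power=power)
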