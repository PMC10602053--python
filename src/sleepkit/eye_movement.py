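"""Pupil localization and rapid eye-movement (EM) detection during REM.

Head-fixed mice sleep with open eyes, so the pupil can be tracked with an
infrared camera (30 Hz).  Each frame is inverted, smoothed, and binarized;
the largest connected component is taken as the pupil and its centroid as
the position.  Pupil speed is the Euclidean frame-to-frame displacement and
acceleration its frame difference; rapid EMs are positive acceleration peaks
exceeding 2 standard deviations of the acceleration pooled over all REM
samples of the recording.  EMs separated by less than 250 ms form bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from skimage import filters, measure

from .core import BrainState, Hypnogram, episodes

__all__ = [
    "PupilTrace",
    "EyeMovementEvent",
    "pupil_center",
    "track_pupil",
    "detect_ems",
    "group_bursts",
    "em_statistics",
]

CAMERA_FS = 30.0
BURST_GAP_S = 0.25
MIN_SEPARATION_S = 0.1
MIN_PUPIL_AREA = 20  # px²


@dataclass(frozen=True)
class PupilTrace:
    t: np.ndarray  # s, camera clock
    x: np.ndarray  # px
    y: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            object.__setattr__(self, "valid", np.ones(self.t.size, bool))

    @property
    def fs(self) -> float:
        return float(1.0 / np.median(np.diff(self.t)))


@dataclass(frozen=True)
class EyeMovementEvent:
    t: float  # s
    peak_acceleration: float  # px/frame²
    burst_id: int | None = None


def pupil_center(
    frame: np.ndarray,
    threshold: float,
    smooth_sigma: float = 1.0,
    min_area: int = MIN_PUPIL_AREA,
) -> tuple[float, float] | None:
    """Centroid (x, y) of the pupil in one grayscale frame, or None.

    The frame is inverted (the pupil is dark), Gaussian-smoothed, and
    binarized at ``threshold`` (applied to the inverted image); the largest
    connected component above ``min_area`` is the pupil.
    """
    img = np.asarray(frame, float)
    if img.size == 0:
        return None
    inv = img.max() - img
    sm = filters.gaussian(inv, sigma=smooth_sigma, preserve_range=True)
    binary = sm > threshold
    labels = measure.label(binary)
    if labels.max() == 0:
        return None
    regions = measure.regionprops(labels)
    best = max(regions, key=lambda r: r.area)
    if best.area < min_area:
        return None
    cy, cx = best.centroid
    return float(cx), float(cy)


def track_pupil(
    frames: np.ndarray, threshold: float, fs: float = CAMERA_FS, **kwargs
) -> PupilTrace:
    """Run :func:`pupil_center` over a (t, h, w) frame stack."""
    xs, ys, valid = [], [], []
    for frame in frames:
        c = pupil_center(frame, threshold, **kwargs)
        if c is None:
            xs.append(np.nan), ys.append(np.nan), valid.append(False)
        else:
            xs.append(c[0]), ys.append(c[1]), valid.append(True)
    n = len(xs)
    return PupilTrace(
        t=np.arange(n) / fs,
        x=np.array(xs),
        y=np.array(ys),
        valid=np.array(valid, bool),
    )


def pupil_acceleration(trace: PupilTrace) -> np.ndarray:
    """Acceleration (px/frame²) at each frame; NaN where undefined/invalid."""
    dx = np.diff(trace.x)
    dy = np.diff(trace.y)
    speed = np.hypot(dx, dy)  # px/frame, at half-steps
    accel = np.full(trace.t.size, np.nan)
    accel[1:-1] = np.diff(speed)
    bad = ~trace.valid
    # acceleration at i uses frames i-1, i, i+1: invalid if any is
    pad = np.flatnonzero(bad)
    for i in pad:
        accel[max(0, i - 1) : i + 2] = np.nan
    return accel


def detect_ems(trace: PupilTrace, h: Hypnogram) -> tuple[list[EyeMovementEvent], float]:
    """Rapid EMs: positive acceleration peaks > 2 SD within REM.

    The SD is computed across all valid REM samples of the recording (so the
    criterion is invariant to rescaling the trace).  Peaks must be separated
    by at least 100 ms and never span invalid (blink) gaps.  Returns the
    events and the SD used.
    """
    accel = pupil_acceleration(trace)
    rem = np.zeros(trace.t.size, bool)
    for e in episodes(h, BrainState.REM):
        rem |= (trace.t >= e.start_s) & (trace.t < e.end_s)
    if not rem.any():
        warnings.warn("no REM sleep in hypnogram; no EMs detected", stacklevel=2)
        return [], np.nan
    pool = accel[rem & ~np.isnan(accel)]
    if pool.size == 0:
        return [], np.nan
    sd = float(pool.std())
    # numerically-zero acceleration (e.g. constant-velocity drift) must not
    # trigger on float noise; the floor scales with the trace so detections
    # stay invariant to rescaling
    floor = 1e-9 * max(np.nanmax(np.abs(trace.x)), np.nanmax(np.abs(trace.y)), 1e-300)
    a = np.where(np.isnan(accel), -np.inf, accel)
    distance = max(1, int(round(MIN_SEPARATION_S * trace.fs)))
    peaks, _ = sps.find_peaks(a, height=max(2.0 * sd, floor), distance=distance)
    peaks = peaks[rem[peaks]]
    return [
        EyeMovementEvent(t=float(trace.t[i]), peak_acceleration=float(accel[i]))
        for i in peaks
    ], sd


def group_bursts(events: list[EyeMovementEvent]) -> list[EyeMovementEvent]:
    """Group EMs into bursts: consecutive gaps strictly < 250 ms, transitively.

    Singleton groups are not bursts (``burst_id`` stays None).  Returns new
    event objects; the partition is order-independent.
    """
    ev = sorted(events, key=lambda e: e.t)
    out: list[EyeMovementEvent] = []
    group: list[EyeMovementEvent] = []
    burst_id = 0

    def flush(group: list[EyeMovementEvent]) -> None:
        nonlocal burst_id
        if len(group) >= 2:
            out.extend(
                EyeMovementEvent(e.t, e.peak_acceleration, burst_id) for e in group
            )
            burst_id += 1
        else:
            out.extend(EyeMovementEvent(e.t, e.peak_acceleration, None) for e in group)

    for e in ev:
        if group and e.t - group[-1].t < BURST_GAP_S:
            group.append(e)
        else:
            flush(group)
            group = [e]
    if group:
        flush(group)
    return out


def em_statistics(
    events: list[EyeMovementEvent], h: Hypnogram
) -> dict:
    """EM and burst frequencies per minute of REM, and per-episode latency
    to the first EM from REM onset."""
    grouped = group_bursts(events)
    rem_eps = episodes(h, BrainState.REM)
    rem_min = sum(e.duration_s for e in rem_eps) / 60.0
    n_bursts = len({e.burst_id for e in grouped if e.burst_id is not None})
    latencies = []
    for ep in rem_eps:
        ts = [e.t for e in events if ep.start_s <= e.t < ep.end_s]
        latencies.append(min(ts) - ep.start_s if ts else np.nan)
    return {
        "ems_per_min": len(events) / rem_min if rem_min else np.nan,
        "bursts_per_min": n_bursts / rem_min if rem_min else np.nan,
        "latency_to_first_em_s": latencies,
    }
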