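"""Closed-loop REM sleep detection.

The online detector watches three features computed every 2.5 s from the
trailing 5 s of signal: EEG δ power, the θ/δ power ratio, and the EMG
amplitude.  REM onset is declared when δ power and EMG amplitude are below
their thresholds while θ/δ surpasses a *hard* threshold; the detection stays
active until θ/δ drops below a *soft* threshold or the EMG exceeds its
threshold (hysteresis).  Thresholds are calibrated from previously scored
recordings of the same animal.

The quoted onset/offset logic is fixed; how thresholds are derived from the
calibration recording is a package choice, exposed via ``CalibrationConfig``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import BrainState, Hypnogram, SignalRecording
from .spectral import BANDS, band_power, spectrogram

__all__ = [
    "ClosedLoopThresholds",
    "CalibrationConfig",
    "feature_stream",
    "calibrate",
    "detect_rem_stream",
    "validate_detections",
    "laser_coin_flip",
]


@dataclass(frozen=True)
class ClosedLoopThresholds:
    delta_max: float  # μV²
    emg_max: float  # μV
    thdelta_hard: float  # unitless ratio
    thdelta_soft: float

    def __post_init__(self) -> None:
        if not (0 < self.thdelta_soft <= self.thdelta_hard):
            raise ValueError("need 0 < soft <= hard theta/delta threshold")
        if self.delta_max <= 0 or self.emg_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class CalibrationConfig:
    """Tuning constants for threshold calibration.

    ``emg_sd_k`` (k₁) widens the NREM EMG mean.  The hard θ/δ threshold is
    the ``rem_thd_percentile``-th percentile of the REM θ/δ distribution
    (percentiles rather than mean − k·SD because band-power ratios are
    heavily right-skewed), floored at the NREM 95th percentile;
    ``soft_fraction`` (f) sets the soft threshold as a fraction of the hard
    one.
    """

    emg_sd_k: float = 1.0
    rem_thd_percentile: float = 5.0
    soft_fraction: float = 0.6
    eeg_channel: str = "EEG_parietal"


def feature_stream(
    rec: SignalRecording, eeg_channel: str = "EEG_parietal", epoch_s: float = 2.5
) -> dict[str, np.ndarray]:
    """Causal per-epoch features: δ power, θ/δ ratio, EMG amplitude.

    The feature for epoch ``k`` is computed from the 5 s window *ending* at
    the end of epoch ``k`` (the trailing two epochs), so a decision at the
    end of epoch ``k`` uses only past samples.  Epoch 0 has no features
    (NaN).
    """
    spec_eeg = spectrogram(rec[eeg_channel], rec.fs, window_s=2 * epoch_s)
    spec_emg = spectrogram(rec["EMG"], rec.fs, window_s=2 * epoch_s)
    delta = band_power(spec_eeg, BANDS["delta"])
    theta = band_power(spec_eeg, BANDS["theta"])
    emg = np.sqrt(band_power(spec_emg, BANDS["emg"]))
    n_epochs = int(rec.duration_s / epoch_s)
    out = {
        "delta": np.full(n_epochs, np.nan),
        "thdelta": np.full(n_epochs, np.nan),
        "emg": np.full(n_epochs, np.nan),
    }
    n = min(delta.size, n_epochs - 1)
    out["delta"][1 : n + 1] = delta[:n]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["thdelta"][1 : n + 1] = np.where(delta[:n] > 0, theta[:n] / delta[:n], np.inf)
    out["emg"][1 : n + 1] = emg[:n]
    out["t"] = (np.arange(n_epochs) + 1) * epoch_s  # decision times
    return out


def calibrate(
    rec: SignalRecording,
    h: Hypnogram,
    cfg: CalibrationConfig | None = None,
) -> ClosedLoopThresholds:
    """Derive detection thresholds from a scored calibration recording."""
    cfg = cfg or CalibrationConfig()
    feats = feature_stream(rec, cfg.eeg_channel, h.epoch_s)
    n = min(len(h), feats["delta"].size)
    valid = ~np.isnan(feats["delta"][:n])
    states = h.states[:n]
    masks = {}
    for st in (BrainState.WAKE, BrainState.NREM, BrainState.REM):
        m = (states == st.value) & valid
        if not m.any():
            raise ValueError(f"calibration data contains no {st.name} epochs: {st.name}")
        masks[st] = m

    delta_n = feats["delta"][:n][masks[BrainState.NREM]]
    emg_n = feats["emg"][:n][masks[BrainState.NREM]]
    thd_r = feats["thdelta"][:n][masks[BrainState.REM]]
    thd_n = feats["thdelta"][:n][masks[BrainState.NREM]]

    delta_max = float(delta_n.mean())
    emg_max = float(emg_n.mean() + cfg.emg_sd_k * emg_n.std())
    hard = float(np.percentile(thd_r, cfg.rem_thd_percentile))
    hard = max(hard, float(np.percentile(thd_n, 95)))
    soft = cfg.soft_fraction * hard
    return ClosedLoopThresholds(
        delta_max=delta_max, emg_max=emg_max, thdelta_hard=hard, thdelta_soft=soft
    )


def detect_rem_stream(
    rec: SignalRecording,
    thresholds: ClosedLoopThresholds,
    eeg_channel: str = "EEG_parietal",
    epoch_s: float = 2.5,
) -> list[tuple[float, float]]:
    """Run the streaming REM detector; returns (onset_s, offset_s) pairs.

    Onset: δ < delta_max, EMG < emg_max, θ/δ > hard.  Offset: θ/δ < soft or
    EMG > emg_max.  Times are the 2.5 s decision times (epoch ends).
    """
    feats = feature_stream(rec, eeg_channel, epoch_s)
    events: list[tuple[float, float]] = []
    active = False
    onset = 0.0
    for k in range(feats["t"].size):
        d, thd, e, t = (
            feats["delta"][k],
            feats["thdelta"][k],
            feats["emg"][k],
            feats["t"][k],
        )
        if np.isnan(d):
            continue
        if not active:
            if d < thresholds.delta_max and e < thresholds.emg_max and thd > thresholds.thdelta_hard:
                active = True
                onset = t
        else:
            if thd < thresholds.thdelta_soft or e > thresholds.emg_max:
                active = False
                events.append((onset, t))
    if active:
        events.append((onset, float(feats["t"][-1])))
    return events


def validate_detections(
    detections: list[tuple[float, float]],
    h: Hypnogram,
    min_bout_s: float = 0.0,
) -> dict:
    """Compare streamed detections against a scored hypnogram.

    Per true REM bout: hit (any detection onset inside the bout) and onset
    latency.  Returns hit fraction, median latency over hits, and the false
    detection count (detections whose onset lies outside every REM bout).
    """
    from .core import episodes

    bouts = [e for e in episodes(h, BrainState.REM) if e.duration_s >= min_bout_s]
    onsets = np.array([d[0] for d in detections])
    hits, latencies = [], []
    for b in bouts:
        inside = onsets[(onsets >= b.start_s) & (onsets < b.end_s)]
        if inside.size:
            hits.append(True)
            latencies.append(float(inside.min() - b.start_s))
        else:
            hits.append(False)
    in_any = np.zeros(onsets.size, bool)
    for e in episodes(h, BrainState.REM):
        in_any |= (onsets >= e.start_s) & (onsets < e.end_s)
    if not bouts:
        warnings.warn("hypnogram contains no REM bouts to validate against", stacklevel=2)
    return {
        "n_bouts": len(bouts),
        "hit_fraction": float(np.mean(hits)) if bouts else np.nan,
        "median_latency_s": float(np.median(latencies)) if latencies else np.nan,
        "latencies_s": latencies,
        "n_false_detections": int((~in_any).sum()),
    }


def laser_coin_flip(n_episodes: int, seed: int) -> np.ndarray:
    """Seeded 50% laser-on assignment across detected REM episodes."""
    return np.random.default_rng(seed).random(n_episodes) < 0.5
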