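"""Domain types for sleep-state analysis.

The coordinate system for everything in this package is the *hypnogram*: a
sequence of manually scored brain states (Wake, NREM, REM) on a uniform epoch
grid, conventionally 2.5 s per epoch.  Signals (EEG/EMG in microvolts),
laser-event trains, pupil traces and calcium traces are all aligned to this
grid.  Timestamps are 0-based seconds; epoch ``k`` covers the half-open
interval ``[t0 + k*epoch_s, t0 + (k+1)*epoch_s)``; signal sample ``i`` maps to
time ``i / fs``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BrainState",
    "Hypnogram",
    "SignalRecording",
    "LaserTrain",
    "Episode",
    "episodes",
    "laser_trials",
]


class BrainState(str, enum.Enum):
    """Brain state of one scored epoch.

    ``UNDEF`` marks unscored/artifact epochs and never enters statistics.
    """

    WAKE = "W"
    NREM = "N"
    REM = "R"
    UNDEF = "U"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_VALID_CODES = frozenset(s.value for s in BrainState)


@dataclass(frozen=True)
class Hypnogram:
    """Scored brain states on a uniform epoch grid.

    Parameters
    ----------
    states
        Array of single-letter state codes (``W``/``N``/``R``/``U``).
    epoch_s
        Epoch duration in seconds (default 2.5).
    t0
        Time of the first epoch's left edge, seconds.
    """

    states: np.ndarray
    epoch_s: float = 2.5
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(
            [s.value if isinstance(s, BrainState) else str(s) for s in self.states],
            dtype="U1",
        )
        if arr.size < 1:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        bad = set(arr.tolist()) - _VALID_CODES
        if bad:
            raise ValueError(f"unknown state codes: {sorted(bad)}")
        object.__setattr__(self, "states", arr)

    def __len__(self) -> int:
        return int(self.states.size)

    @property
    def duration_s(self) -> float:
        return len(self) * self.epoch_s

    @property
    def times(self) -> np.ndarray:
        """Left edge of each epoch, seconds."""
        return self.t0 + np.arange(len(self)) * self.epoch_s

    def state_at(self, t: float) -> str:
        """State code of the epoch containing time ``t``."""
        k = int(np.floor((t - self.t0) / self.epoch_s))
        if not 0 <= k < len(self):
            raise IndexError(f"time {t} s outside hypnogram")
        return str(self.states[k])

    def mask(self, state: BrainState | str) -> np.ndarray:
        code = state.value if isinstance(state, BrainState) else str(state)
        return self.states == code

    def sample_states(self, n_samples: int, fs: float) -> np.ndarray:
        """Expand epoch codes to a per-sample state array of length ``n_samples``."""
        idx = np.minimum(
            (np.arange(n_samples) / fs / self.epoch_s).astype(np.int64),
            len(self) - 1,
        )
        return self.states[idx]


@dataclass(frozen=True)
class SignalRecording:
    """Named sampled traces (conventionally EEG_frontal, EEG_parietal, EMG) in μV."""

    channels: dict[str, np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channels:
            raise ValueError("recording has no channels")
        chans = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {v.size for v in chans.values()}
        if len(lengths) != 1:
            raise ValueError(f"channels have inconsistent lengths: {lengths}")
        object.__setattr__(self, "channels", chans)

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def __getitem__(self, name: str) -> np.ndarray:
        if name in self.channels:
            return self.channels[name]
        # case-insensitive substring fallback (EDF label dialects vary)
        matches = [k for k in self.channels if name.lower() in k.lower()]
        if len(matches) == 1:
            return self.channels[matches[0]]
        raise KeyError(f"channel {name!r} not found (have {list(self.channels)})")


@dataclass(frozen=True)
class LaserTrain:
    """Optogenetic stimulation trials: onset times and per-trial duration."""

    onsets: np.ndarray
    duration_s: float
    mode: str = "open_loop"

    def __post_init__(self) -> None:
        arr = np.asarray(self.onsets, dtype=float)
        if arr.size and np.any(np.diff(arr) <= 0):
            raise ValueError("laser onsets must be strictly increasing")
        if self.duration_s <= 0:
            raise ValueError("trial duration must be positive")
        if arr.size and np.any(np.diff(arr) < self.duration_s):
            raise ValueError("laser trials overlap")
        if self.mode not in ("open_loop", "closed_loop"):
            raise ValueError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "onsets", arr)

    def __len__(self) -> int:
        return int(self.onsets.size)

    def intervals(self) -> np.ndarray:
        """(n, 2) array of [onset, offset] in seconds."""
        return np.column_stack([self.onsets, self.onsets + self.duration_s])


@dataclass(frozen=True)
class Episode:
    """A maximal run of one brain state, boundaries on the epoch grid.

    For NREM, brief wake intrusions (microarousals, wake episodes no longer
    than the bridging limit) may be absorbed; those epochs are flagged in
    ``microarousal_mask`` and the episode duration includes them.
    """

    state: BrainState
    start_s: float
    end_s: float
    microarousal_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("episode must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def sample_slice(self, fs: float) -> slice:
        return slice(int(round(self.start_s * fs)), int(round(self.end_s * fs)))


def _runs(codes: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal runs as (code, start_idx, stop_idx) with stop exclusive."""
    out: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, codes.size + 1):
        if i == codes.size or codes[i] != codes[start]:
            out.append((str(codes[start]), start, i))
            start = i
    return out


def episodes(
    h: Hypnogram,
    state: BrainState | str,
    bridge_microarousal_s: float = 0.0,
) -> list[Episode]:
    """Segment a hypnogram into maximal episodes of one state.

    When ``state`` is NREM and ``bridge_microarousal_s > 0``, NREM runs
    separated by wake runs of at most that duration are merged into one
    episode; the wake gap is kept inside the episode (flagged per-epoch in
    ``microarousal_mask``) so episode durations include microarousals.
    Bridging never mutates the hypnogram itself.
    """
    code = state.value if isinstance(state, BrainState) else str(state)
    if bridge_microarousal_s < 0:
        raise ValueError("bridge_microarousal_s must be >= 0")
    runs = [r for r in _runs(h.states)]
    target = [(i, r) for i, r in enumerate(runs) if r[0] == code]
    if not target:
        return []

    groups: list[list[tuple[str, int, int]]] = []
    bridge = bridge_microarousal_s if code == BrainState.NREM.value else 0.0
    for i, run in target:
        if groups and bridge > 0:
            prev = groups[-1][-1]
            # gap runs between previous target run and this one
            gap = runs[[j for j, r in enumerate(runs) if r is prev][0] + 1 : i]
            gap_ok = (
                len(gap) > 0
                and all(g[0] == BrainState.WAKE.value for g in gap)
                and sum((g[2] - g[1]) for g in gap) * h.epoch_s <= bridge
            )
            if gap_ok:
                groups[-1].extend(gap)
                groups[-1].append(run)
                continue
        groups.append([run])

    eps = []
    for grp in groups:
        a, b = grp[0][1], grp[-1][2]
        mask = h.states[a:b] == BrainState.WAKE.value
        eps.append(
            Episode(
                state=BrainState(code),
                start_s=h.t0 + a * h.epoch_s,
                end_s=h.t0 + b * h.epoch_s,
                microarousal_mask=mask,
            )
        )
    return eps


def laser_trials(
    h: Hypnogram,
    laser: LaserTrain,
    pre_s: float,
    post_s: float,
) -> pd.DataFrame:
    """Onset-aligned state sequences for each laser trial.

    Returns one row per trial with the onset time, the state at t = 0 (the
    sorting key used when stacking trials), and the aligned per-epoch state
    sequence covering ``[-pre_s, +post_s)``.  Trials truncated at the
    recording edges are dropped.
    """
    if pre_s < 0 or post_s < 0:
        raise ValueError("pre_s and post_s must be >= 0")
    n_pre = int(round(pre_s / h.epoch_s))
    n_post = int(round(post_s / h.epoch_s))
    rows = []
    for onset in laser.onsets:
        k = int(np.floor((onset - h.t0) / h.epoch_s))
        if k - n_pre < 0 or k + n_post > len(h):
            continue
        seq = h.states[k - n_pre : k + n_post].copy()
        rows.append({"onset_s": float(onset), "state_at_onset": str(h.states[k]), "states": seq})
    if not rows:
        warnings.warn("no complete laser trials inside the recording", stacklevel=2)
        return pd.DataFrame(columns=["onset_s", "state_at_onset", "states"])
    return pd.DataFrame(rows)
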