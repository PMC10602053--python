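"""File formats.

* Raw signals: EDF (read via :mod:`mne`, written by a small built-in 16-bit
  EDF encoder) or CSV with a header row naming the channels and a sampling
  rate provided either as a sidecar file ``<name>.fs`` or as an ``fs`` column.
* Hypnograms: plain text ``.hypno`` — a header line ``epoch_s=2.5`` followed
  by one single-letter state code (W/N/R/U) per line.
* Laser trains: CSV with columns ``onset_s,duration_s`` (constant duration).

All signal amplitudes are in μV.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BrainState, Hypnogram, LaserTrain, SignalRecording

__all__ = [
    "read_recording",
    "write_recording_csv",
    "write_recording_edf",
    "read_hypnogram",
    "write_hypnogram",
    "read_laser_train",
    "write_laser_train",
]

REQUIRED_CHANNELS = ("EEG_frontal", "EEG_parietal", "EMG")


class FormatError(ValueError):
    pass


class MissingChannelError(KeyError):
    pass


# ---------------------------------------------------------------- recordings


def read_recording(
    path: str | os.PathLike,
    format: str | None = None,
    required: tuple[str, ...] = REQUIRED_CHANNELS,
) -> SignalRecording:
    """Read a multichannel recording from EDF or CSV.

    ``format`` defaults to the file extension.  Channel names are resolved
    case-insensitively by substring, so EDF label dialects like ``EEG EEG1``
    still resolve.  Raises :class:`MissingChannelError` naming the first
    channel that cannot be resolved.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        rec = _read_csv(path)
    elif fmt == "edf":
        rec = _read_edf(path)
    else:
        raise FormatError(f"unknown recording format {fmt!r}")
    for name in required:
        matches = [k for k in rec.channels if name.lower() in k.lower()]
        if not matches:
            raise MissingChannelError(name)
    return rec


def _read_csv(path: Path) -> SignalRecording:
    df = pd.read_csv(path)
    if "fs" in df.columns:
        fs = float(df["fs"].iloc[0])
        df = df.drop(columns=["fs"])
    else:
        sidecar = path.with_suffix(".fs")
        if not sidecar.exists():
            raise FormatError(
                "CSV recording needs sampling rate: 'fs' column or '.fs' sidecar"
            )
        fs = float(sidecar.read_text().strip())
    channels = {c: df[c].to_numpy(float) for c in df.columns}
    lengths = {len(v) for v in channels.values()}
    if len(lengths) != 1:
        raise FormatError(f"inconsistent channel lengths {lengths}")
    return SignalRecording(channels=channels, fs=fs)


def write_recording_csv(rec: SignalRecording, path: str | os.PathLike) -> None:
    path = Path(path)
    df = pd.DataFrame(rec.channels)
    df.to_csv(path, index=False)
    path.with_suffix(".fs").write_text(f"{rec.fs:g}\n")


def _read_edf(path: Path) -> SignalRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    channels = {name: data[i] for i, name in enumerate(raw.ch_names)}
    return SignalRecording(channels=channels, fs=float(raw.info["sfreq"]))


def write_recording_edf(rec: SignalRecording, path: str | os.PathLike) -> None:
    """Write a recording as EDF (16-bit, 1 s data records).

    Requires an integer sampling rate; a trailing partial second is dropped.
    Quantization resolution is ``(phys_max - phys_min) / 65535`` per channel.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_rec = rec.n_samples // fs
    if n_rec * fs != rec.n_samples:
        warnings.warn("EDF writer dropped a trailing partial second", stacklevel=2)
    names = list(rec.channels)
    ns = len(names)

    header = bytearray()

    def fixed(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header += fixed("0", 8)  # version
    header += fixed("X X X X", 80)  # patient id
    header += fixed("Startdate X X X X", 80)  # recording id
    header += fixed("01.01.00", 8)
    header += fixed("00.00.00", 8)
    header += fixed(str(256 * (ns + 1)), 8)
    header += fixed("", 44)
    header += fixed(str(n_rec), 8)
    header += fixed("1", 8)  # record duration, s
    header += fixed(str(ns), 4)

    phys_min, phys_max, scaled = [], [], []
    for name in names:
        x = rec.channels[name][: n_rec * fs]
        lo = float(np.floor(x.min())) if x.size else -1.0
        hi = float(np.ceil(x.max())) if x.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round((x - lo) / (hi - lo) * 65535.0 - 32768.0)
        scaled.append(dig.astype("<i2"))

    for field, width in (
        ([n[:16] for n in names], 16),
        (["" for _ in names], 80),  # transducer
        (["uV" for _ in names], 8),
        ([f"{v:g}" for v in phys_min], 8),
        ([f"{v:g}" for v in phys_max], 8),
        (["-32768" for _ in names], 8),
        (["32767" for _ in names], 8),
        (["" for _ in names], 80),  # prefiltering
        ([str(fs) for _ in names], 8),
        (["" for _ in names], 32),  # reserved
    ):
        for value in field:
            header += fixed(value, width)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            for ch in scaled:
                fh.write(ch[r * fs : (r + 1) * fs].tobytes())


# ----------------------------------------------------------------- hypnogram


def read_hypnogram(path: str | os.PathLike) -> Hypnogram:
    lines = Path(path).read_text().splitlines()
    epoch_s, t0 = 2.5, 0.0
    codes: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line:
            key, _, val = line.partition("=")
            key = key.strip()
            if key == "epoch_s":
                epoch_s = float(val)
            elif key == "t0":
                t0 = float(val)
            else:
                raise FormatError(f"line {lineno}: unknown header key {key!r}")
            continue
        if line not in ("W", "N", "R", "U"):
            raise FormatError(f"line {lineno}: unknown state code {line!r}")
        codes.append(line)
    if not codes:
        raise FormatError("hypnogram file contains no epochs")
    return Hypnogram(states=np.array(codes, dtype="U1"), epoch_s=epoch_s, t0=t0)


def write_hypnogram(h: Hypnogram, path: str | os.PathLike) -> None:
    lines = [f"epoch_s={h.epoch_s:g}"]
    if h.t0:
        lines.append(f"t0={h.t0:g}")
    lines.extend(str(s) for s in h.states)
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------- laser train


def read_laser_train(path: str | os.PathLike, mode: str = "open_loop") -> LaserTrain:
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError("laser train file contains no trials")
    durations = df["duration_s"].unique()
    if len(durations) != 1:
        raise FormatError("laser trials must share one duration")
    return LaserTrain(
        onsets=df["onset_s"].to_numpy(float),
        duration_s=float(durations[0]),
        mode=mode,
    )


def write_laser_train(laser: LaserTrain, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"onset_s": laser.onsets, "duration_s": laser.duration_s}
    ).to_csv(path, index=False)


# convenience re-export used by CLI and drivers
def state_enum(code: str) -> BrainState:
    return BrainState(code)
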