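"""Generate one synthetic polysomnography session and export it to disk.

Writes an EDF recording, a .hypno hypnogram, the laser train and the
ground-truth ledgers (phasic intervals, R-wave and saccade times) under
results/session/, so that the downstream drivers can be run on files as a
user would on real data.
"""

import sys
from pathlib import Path

import pandas as pd

from sleepkit import io as skio
from sleepkit.synthetic import SimConfig, default_laser_train, simulate_hypnogram, simulate_eeg_emg, simulate_pupil

OUT = Path(__file__).resolve().parents[1] / "results" / "session"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed, duration_s=5400.0)
    laser = default_laser_train(cfg, seed=seed)
    h, truth = simulate_hypnogram(cfg, laser)
    rec = simulate_eeg_emg(cfg, truth)
    pupil = simulate_pupil(cfg, truth)

    skio.write_hypnogram(h, OUT / "session.hypno")
    skio.write_recording_edf(rec, OUT / "session.edf")
    skio.write_laser_train(laser, OUT / "laser.csv")
    pd.DataFrame(truth.phasic_intervals, columns=["start_s", "end_s"]).to_csv(
        OUT / "truth_phasic.csv", index=False
    )
    pd.DataFrame({"t_s": truth.r_times}).to_csv(OUT / "truth_rwaves.csv", index=False)
    pd.DataFrame({"t_s": truth.saccade_times}).to_csv(OUT / "truth_saccades.csv", index=False)
    pd.DataFrame(
        {"t_s": pupil.t, "x_px": pupil.x, "y_px": pupil.y, "valid": pupil.valid.astype(int)}
    ).to_csv(OUT / "pupil.csv", index=False)

    frac = {s: float((h.states == s).mean()) for s in "WNR"}
    print(f"session: {h.duration_s/60:.0f} min, state fractions "
          f"W {frac['W']:.2f} / N {frac['N']:.2f} / R {frac['R']:.2f}, "
          f"{len(laser)} laser trials, {len(truth.phasic_intervals)} phasic events")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
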