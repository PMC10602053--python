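"""End-to-end recovery and calibration studies on synthetic ground truth.

Each study generates a fresh synthetic session from a seed, runs the
corresponding analysis stage, and scores it against the generator's ledger.
They are the package's own validation battery: the acceptance tests and the
``scripts/acceptance.py`` entry point both call these functions.

Problem sizes are chosen to give stable estimates on a single CPU within a
few minutes per study (session durations of 1–3 h for signal-level studies,
200 simulated datasets for bootstrap calibration, a 64×64×6000-frame movie
for the imaging study).
"""

from __future__ import annotations

import numpy as np

from .phasic import PhasicEvent, detect_phasic
from .synthetic import (
    SimConfig,
    block_hypnogram,
    default_laser_train,
    rem_episode_truths,
    simulate_calcium,
    simulate_eeg_emg,
    simulate_hypnogram,
    simulate_photometry,
    simulate_pupil,
)

__all__ = [
    "closed_loop_study",
    "phasic_study",
    "heart_rate_study",
    "em_study",
    "bootstrap_calibration_study",
    "bootstrap_power_study",
    "calcium_study",
    "classifier_specificity_study",
    "photometry_study",
]


def _interval_overlap(a0, a1, b0, b1) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def _match_events(truth_iv: np.ndarray, events: list[PhasicEvent]):
    """Recall/precision with >= 50% overlap (of the shorter interval) as hit."""
    def hit(a, b, c, d):
        return _interval_overlap(a, b, c, d) >= 0.5 * min(b - a, d - c)

    recall_hits = sum(
        any(hit(a, b, e.start_s, e.end_s) for e in events) for a, b in truth_iv
    )
    prec_hits = sum(
        any(hit(a, b, e.start_s, e.end_s) for a, b in truth_iv) for e in events
    )
    recall = recall_hits / len(truth_iv) if len(truth_iv) else np.nan
    precision = prec_hits / len(events) if events else np.nan
    return recall, precision


# ------------------------------------------------------------- closed loop


def closed_loop_study(seed: int, cal_duration_s: float = 5400.0,
                      test_duration_s: float = 5400.0) -> dict:
    """Calibrate on one synthetic session, stream-detect REM on another."""
    from .state_online import calibrate, detect_rem_stream, validate_detections

    cfg_cal = SimConfig(seed=seed * 2 + 1, duration_s=cal_duration_s)
    h_cal, truth_cal = simulate_hypnogram(cfg_cal)
    # re-draw until the calibration session contains every state
    tries = 0
    while not all((h_cal.states == s).any() for s in "WNR"):
        tries += 1
        cfg_cal = SimConfig(seed=seed * 2 + 1 + 1000 * tries, duration_s=cal_duration_s)
        h_cal, truth_cal = simulate_hypnogram(cfg_cal)
    rec_cal = simulate_eeg_emg(cfg_cal, truth_cal)
    thresholds = calibrate(rec_cal, h_cal)

    cfg = SimConfig(seed=seed * 2 + 2, duration_s=test_duration_s)
    h, truth = simulate_hypnogram(cfg)
    rec = simulate_eeg_emg(cfg, truth)
    detections = detect_rem_stream(rec, thresholds)
    report = validate_detections(detections, h, min_bout_s=30.0)
    report["thresholds"] = thresholds
    return report


# ------------------------------------------------------------ phasic theta


def phasic_study(seed: int, duration_s: float = 7200.0) -> dict:
    """Detector recall/precision vs the injected phasic-event ledger."""
    cfg = SimConfig(seed=seed, duration_s=duration_s)
    h, truth = simulate_hypnogram(cfg)
    rec = simulate_eeg_emg(cfg, truth)
    eps = rem_episode_truths(truth)
    traces = [rec["EEG_parietal"][e.sample_slice(rec.fs)] for e in eps]
    events, thr = detect_phasic(traces, rec.fs, episodes=eps)
    recall, precision = _match_events(truth.phasic_intervals, events)

    # purely tonic REM must yield zero events
    cfg0 = SimConfig(seed=seed + 1, duration_s=duration_s / 2, phasic_rate_per_min=0.0)
    h0, truth0 = simulate_hypnogram(cfg0)
    rec0 = simulate_eeg_emg(cfg0, truth0)
    eps0 = rem_episode_truths(truth0)
    traces0 = [rec0["EEG_parietal"][e.sample_slice(rec0.fs)] for e in eps0]
    events0, _ = detect_phasic(traces0, rec0.fs, episodes=eps0)
    return {
        "recall": recall,
        "precision": precision,
        "n_true": len(truth.phasic_intervals),
        "n_detected": len(events),
        "tonic_false_events": len(events0),
        "thresholds": thr,
    }


# -------------------------------------------------------------- heart rate


def heart_rate_study(seed: int, duration_s: float = 7200.0,
                     n_noise_episodes: int = 100) -> dict:
    """Tonic/phasic rate recovery plus noise-only rejection rate."""
    from .heart_rate import heart_rate, select_threshold, threshold_curve

    cfg = SimConfig(seed=seed, duration_s=duration_s)
    h, truth = simulate_hypnogram(cfg)
    rec = simulate_eeg_emg(cfg, truth)
    eps = rem_episode_truths(truth)
    # ledger phasic intervals, assigned to their episode ids, isolate the
    # heart-rate stage from phasic-detector error
    ledger_events = []
    for a, b in truth.phasic_intervals:
        ep_id = next(i for i, e in enumerate(eps) if e.start_s <= a < e.end_s)
        ledger_events.append(PhasicEvent(a, b, 0.0, 0.0, ep_id))
    _, summary = heart_rate(rec["EMG"], rec.fs, eps, ledger_events)

    rng = np.random.default_rng([seed, 99])
    rejected = 0
    emg_sd = cfg.emg_rms_uV["R"]
    for _ in range(n_noise_episodes):
        noise = emg_sd * rng.standard_normal(int(30.0 * cfg.fs))
        if select_threshold(threshold_curve(noise, cfg.fs)) is None:
            rejected += 1
    return {
        "mean_bpm_tonic": summary["mean_bpm_tonic"],
        "mean_bpm_phasic": summary["mean_bpm_phasic"],
        "tonic_rel_err": abs(summary["mean_bpm_tonic"] - cfg.hr_tonic_bpm) / cfg.hr_tonic_bpm,
        "phasic_rel_err": abs(summary["mean_bpm_phasic"] - cfg.hr_phasic_bpm) / cfg.hr_phasic_bpm,
        "n_accepted": summary["n_accepted"],
        "noise_rejection_rate": rejected / n_noise_episodes,
    }


# ------------------------------------------------------------ eye movement


def em_study(seed: int, duration_s: float = 14400.0) -> dict:
    """Saccade recall, false positives per REM minute, rescale invariance."""
    from .eye_movement import PupilTrace, detect_ems

    cfg = SimConfig(seed=seed, duration_s=duration_s)
    h, truth = simulate_hypnogram(cfg)
    trace = simulate_pupil(cfg, truth)
    events, sd = detect_ems(trace, h)
    tol = 2.0 / cfg.camera_fs
    sacc = truth.saccade_times
    hits = sum(any(abs(e.t - s) <= tol for e in events) for s in sacc)
    fp = sum(not any(abs(e.t - s) <= tol for s in sacc) for e in events)
    rem_min = float((h.states == "R").sum()) * h.epoch_s / 60.0

    scaled = PupilTrace(trace.t, trace.x * 11.0, trace.y * 11.0, trace.valid)
    events2, _ = detect_ems(scaled, h)
    invariant = [e.t for e in events] == [e.t for e in events2]
    return {
        "recall": hits / sacc.size if sacc.size else np.nan,
        "fp_per_min": fp / rem_min if rem_min else np.nan,
        "n_true": int(sacc.size),
        "n_detected": len(events),
        "rescale_invariant": bool(invariant),
    }


# ---------------------------------------------------------------- bootstrap


def _trial_dataset(seed: int, gain: float, n_trials: int) -> dict:
    from .transitions import aligned_trial_states

    duration = n_trials * 900.0 + 400.0
    cfg = SimConfig(seed=seed, duration_s=duration, laser_nr_hazard_gain=gain)
    laser = default_laser_train(cfg, seed=seed)
    h, _ = simulate_hypnogram(cfg, laser)
    return aligned_trial_states(h, laser)


def bootstrap_calibration_study(
    seed: int, n_datasets: int = 200, B: int = 2000, n_trials: int = 100,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the N→R transition bootstrap under a null simulator."""
    from .transitions import bootstrap_transition_test

    rejections = 0
    for i in range(n_datasets):
        trials = _trial_dataset(seed * 100_000 + i, 1.0, n_trials)
        res = bootstrap_transition_test(trials, "N", "R", B=B, seed=seed + i)
        rejections += res.p_sentinel or res.p_value < alpha
    # 95% binomial CI half-width around alpha
    half = 1.96 * np.sqrt(alpha * (1 - alpha) / n_datasets)
    return {
        "type_i_rate": rejections / n_datasets,
        "n_datasets": n_datasets,
        "ci_lo": alpha - half,
        "ci_hi": alpha + half,
    }


def bootstrap_power_study(
    seed: int, n_datasets: int = 50, B: int = 2000, n_trials: int = 100,
    hazard_gain: float = 2.0, alpha: float = 0.05,
) -> dict:
    """Rejection rate when the laser multiplies the N→R hazard."""
    from .transitions import bootstrap_transition_test

    rejections = 0
    for i in range(n_datasets):
        trials = _trial_dataset(seed * 100_000 + 50_000 + i, hazard_gain, n_trials)
        res = bootstrap_transition_test(trials, "N", "R", B=B, seed=seed + i)
        rejections += res.p_sentinel or res.p_value < alpha
    return {"power": rejections / n_datasets, "n_datasets": n_datasets}


# ------------------------------------------------------------------ calcium


def calcium_study(seed: int, duration_s: float = 300.0) -> dict:
    """Full miniscope pipeline recovery on a designed-schedule session."""
    from .calcium import classify_subclasses, extract_dff, motion_correct

    cfg = SimConfig(seed=seed, duration_s=duration_s)
    h, truth = block_hypnogram(duration_s)
    truth.phasic_intervals = np.zeros((0, 2))
    movie, rois = simulate_calcium(cfg, truth)
    corrected, shifts, flagged = motion_correct(movie)
    ts = extract_dff(corrected, rois)
    labels = classify_subclasses(ts, h)

    modulated = [i for i, lbl in enumerate(truth.cell_labels) if lbl != "unmodulated"]
    corrs = [
        float(np.corrcoef(ts.dff[i], truth.cell_traces[i])[0, 1]) for i in modulated
    ]
    acc = float(
        np.mean([labels.label[i] == truth.cell_labels[i] for i in modulated])
    )
    return {
        "motion_exact": bool((shifts == truth.motion_shifts).all()),
        "motion_error_frames": int((shifts != truth.motion_shifts).any(axis=1).sum()),
        "c_recovered": ts.c,
        "c_rel_err": abs(ts.c - cfg.neuropil_gain) / cfg.neuropil_gain,
        "min_trace_corr": min(corrs),
        "mean_trace_corr": float(np.mean(corrs)),
        "subclass_accuracy": acc,
        "n_cells": len(modulated),
    }


def classifier_specificity_study(seed: int, n_cells: int = 200,
                                 duration_s: float = 300.0) -> dict:
    """False-modulation rate of the subclass ANOVA on pure-noise ΔF/F."""
    from .calcium import classify_subclasses

    h, _ = block_hypnogram(duration_s)
    rng = np.random.default_rng([seed, 7])
    dff = 0.05 * rng.standard_normal((n_cells, int(duration_s * 20)))
    labels = classify_subclasses(dff, h, fs=20.0)
    spec = float((labels.label == "unmodulated").mean())
    return {"specificity": spec, "n_cells": n_cells}


# --------------------------------------------------------------- photometry


def photometry_study(seed: int, duration_s: float = 3600.0) -> dict:
    """Bleach removal and transient recovery for the 405-regression ΔF/F."""
    from scipy import stats as sstats

    from .calcium import photometry_dff

    cfg = SimConfig(seed=seed, duration_s=duration_s)
    h, truth = simulate_hypnogram(cfg)
    t, f465, f405 = simulate_photometry(cfg, truth)
    dff = photometry_dff(f465, f405, cfg.phot_fs)
    slope, *_ = sstats.linregress(t / 60.0, dff)  # %/min on the 0-1 scale
    corr = float(np.corrcoef(dff, truth.photometry_transient)[0, 1])
    return {
        "trend_pct_per_min": abs(slope) * 100.0,
        "transient_corr": corr,
    }
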