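"""Laser-aligned brain-state statistics.

Hypnograms are downsampled to 10 s epochs (majority vote over the four
2.5 s sub-epochs, ties broken with priority REM > NREM > Wake so that rare
states survive), and all laser trials are aligned at the laser onset
(t = 0 s).  For a state pair X→Y the cumulative transition probability
P(X→Y | t ≤ d) is q/p, where p counts trials in X at onset and q those that
first entered Y within d seconds; the maintenance curve P(X→X | t ≤ d) is
the fraction of X trials that have not yet left X by d.  Baseline curves are
computed identically from the 120 s interval preceding each onset,
re-anchored at its start.

Significance of a laser effect is assessed with a two-sided bootstrap over
trials pooled across animals: each draw resamples the m trials with
replacement, recomputes both curves, and takes the difference of the areas
under them, normalized so that the full [0, 120] s × [0, 1] rectangle has
area 1.  Equal-tail P-values are reported, uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Hypnogram, LaserTrain

__all__ = [
    "TransitionCurveSet",
    "BootstrapResult",
    "downsample_states",
    "aligned_trial_states",
    "cumulative_transition",
    "bootstrap_transition_test",
    "compare_cohorts",
    "transition_graph",
    "state_percentage_timecourse",
]

EPOCH_10S = 10.0
#: tie-break priority for majority-vote downsampling (rarest state wins)
_PRIORITY = {"R": 3, "N": 2, "W": 1, "U": 0}


def downsample_states(states: np.ndarray, factor: int = 4) -> np.ndarray:
    """Majority-vote downsampling of state codes by ``factor``.

    Ties are broken by priority R > N > W > U.  Trailing epochs that do not
    fill a group are dropped.
    """
    states = np.asarray(states, dtype="U1")
    n = states.size // factor
    out = np.empty(n, dtype="U1")
    for i in range(n):
        grp = states[i * factor : (i + 1) * factor]
        codes, counts = np.unique(grp, return_counts=True)
        best = max(zip(codes, counts), key=lambda t: (t[1], _PRIORITY[t[0]]))
        out[i] = best[0]
    return out


def aligned_trial_states(
    h: Hypnogram, laser: LaserTrain, horizon_s: float = 120.0
) -> dict[str, np.ndarray]:
    """Laser- and baseline-interval state matrices on the 10 s grid.

    Returns ``{"laser": (m, n) codes, "baseline": (m, n)}`` with
    ``n = horizon_s / 10``; row k of ``laser`` starts at onset k, row k of
    ``baseline`` at onset k − horizon_s.  Trials truncated at the recording
    edges are dropped.
    """
    factor = int(round(EPOCH_10S / h.epoch_s))
    n_sub = int(round(horizon_s / h.epoch_s))
    laser_rows, base_rows = [], []
    for onset in laser.onsets:
        k = int(round((onset - h.t0) / h.epoch_s))
        if k - n_sub < 0 or k + n_sub > len(h):
            continue
        laser_rows.append(downsample_states(h.states[k : k + n_sub], factor))
        base_rows.append(downsample_states(h.states[k - n_sub : k], factor))
    if not laser_rows:
        return {"laser": np.empty((0, 0), "U1"), "baseline": np.empty((0, 0), "U1")}
    return {"laser": np.array(laser_rows), "baseline": np.array(base_rows)}


def transition_indicators(
    states: np.ndarray, x: str, y: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial cumulative indicators on the d grid (0, 10, …, horizon).

    Returns ``(x_at_onset, indicator)`` where ``indicator[k, di]`` is 1 if
    trial k has transitioned to ``y`` within ``d = 10·di`` seconds (for
    maintenance, x == y: 1 if the trial is *still* in ``x`` through d).
    A trial entering ``y`` during epoch j (covering [10j, 10(j+1))) counts as
    transitioned within d = 10·j.
    """
    states = np.asarray(states, dtype="U1")
    m, n = states.shape
    x_at_onset = states[:, 0] == x
    nd = n + 1
    ind = np.zeros((m, nd), dtype=float)
    if x == y:
        in_x = states == x
        stay = np.minimum.accumulate(in_x, axis=1)
        ind[:, 0] = in_x[:, 0]
        for di in range(1, nd):
            ind[:, di] = stay[:, min(di, n - 1)]
    else:
        in_y = states == y
        if n > 1:
            entered = np.maximum.accumulate(in_y[:, 1:], axis=1)
            for di in range(1, nd):
                ind[:, di] = entered[:, min(di - 1, n - 2)]
    return x_at_onset, ind


@dataclass(frozen=True)
class TransitionCurveSet:
    pair: tuple[str, str]
    d: np.ndarray  # s
    baseline: np.ndarray | None
    laser: np.ndarray | None
    p_baseline: int
    p_laser: int
    q_baseline: np.ndarray | None
    q_laser: np.ndarray | None

    @property
    def defined(self) -> bool:
        return self.baseline is not None and self.laser is not None


def _curve(states: np.ndarray, x: str, y: str):
    x_mask, ind = transition_indicators(states, x, y)
    p = int(x_mask.sum())
    if p == 0:
        return None, 0, None
    q = ind[x_mask].sum(axis=0)
    return q / p, p, q


def cumulative_transition(
    trials: dict[str, np.ndarray], x: str, y: str, horizon_s: float = 120.0
) -> TransitionCurveSet:
    """Baseline and laser cumulative transition curves for one pair.

    ``trials`` is the output of :func:`aligned_trial_states`.  If no trial
    starts in ``x`` the curve is flagged undefined (None), never zero.
    """
    nd = trials["laser"].shape[1] + 1 if trials["laser"].size else int(horizon_s / 10) + 1
    d = np.arange(nd) * EPOCH_10S
    laser_curve, p_l, q_l = _curve(trials["laser"], x, y) if trials["laser"].size else (None, 0, None)
    base_curve, p_b, q_b = _curve(trials["baseline"], x, y) if trials["baseline"].size else (None, 0, None)
    return TransitionCurveSet(
        pair=(x, y),
        d=d,
        baseline=base_curve,
        laser=laser_curve,
        p_baseline=p_b,
        p_laser=p_l,
        q_baseline=q_b,
        q_laser=q_l,
    )


@dataclass(frozen=True)
class BootstrapResult:
    pair: tuple[str, str]
    statistic: float  # normalized AUC difference, laser − baseline
    distribution: np.ndarray  # B draws
    ci: tuple[float, float]  # 2.5th–97.5th percentile
    p_value: float  # equal-tail; = 1/B when a tail is empty (see p_sentinel)
    p_sentinel: bool  # True → report as "P < 1/B"
    B: int
    seed: int
    n_redraws: int = 0

    def p_label(self) -> str:
        return f"< {1.0 / self.B:g}" if self.p_sentinel else f"{self.p_value:g}"


def _auc(curves: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Trapezoidal AUC over d, normalized by the [0, horizon]×[0, 1] area."""
    return np.trapezoid(curves, d, axis=-1) / (d[-1] - d[0])


def bootstrap_statistics(
    trials: dict[str, np.ndarray],
    x: str,
    y: str,
    B: int,
    rng: np.random.Generator,
    max_redraw_rounds: int = 100,
) -> tuple[np.ndarray, int]:
    """Sampling distribution of the normalized laser−baseline AUC difference."""
    xm_l, ind_l = transition_indicators(trials["laser"], x, y)
    xm_b, ind_b = transition_indicators(trials["baseline"], x, y)
    m = xm_l.size
    nd = ind_l.shape[1]
    d = np.arange(nd) * EPOCH_10S
    wl = ind_l * xm_l[:, None]
    wb = ind_b * xm_b[:, None]

    stats = np.empty(B)
    todo = np.arange(B)
    n_redraws = 0
    for _ in range(max_redraw_rounds):
        S = rng.integers(0, m, size=(todo.size, m))
        p_l = xm_l[S].sum(axis=1)
        p_b = xm_b[S].sum(axis=1)
        ok = (p_l > 0) & (p_b > 0)
        if ok.any():
            sel = S[ok]
            q_l = wl[sel].sum(axis=1)
            q_b = wb[sel].sum(axis=1)
            cl = q_l / p_l[ok][:, None]
            cb = q_b / p_b[ok][:, None]
            stats[todo[ok]] = _auc(cl, d) - _auc(cb, d)
        todo = todo[~ok]
        n_redraws += int((~ok).sum())
        if todo.size == 0:
            break
    else:
        raise RuntimeError(f"bootstrap could not complete draws for pair {x}->{y}")
    return stats, n_redraws


def bootstrap_transition_test(
    trials: dict[str, np.ndarray],
    x: str,
    y: str,
    B: int = 10_000,
    seed: int = 0,
) -> BootstrapResult:
    """Two-sided bootstrap test of a laser effect on one transition pair.

    Trials are pooled across animals and resampled with replacement; draws
    in which no resampled trial starts in ``x`` are redrawn (logged in
    ``n_redraws``).
    """
    if trials["laser"].shape[0] < 2:
        raise ValueError("bootstrap needs at least 2 trials")
    rng = np.random.default_rng(seed)
    stats, n_redraws = bootstrap_statistics(trials, x, y, B, rng)
    curves = cumulative_transition(trials, x, y)
    if not curves.defined:
        raise ValueError(f"pair {x}->{y}: no trials start in {x}")
    point = float(_auc(curves.laser, curves.d) - _auc(curves.baseline, curves.d))
    n_le = int((stats <= 0).sum())
    n_ge = int((stats >= 0).sum())
    sentinel = min(n_le, n_ge) == 0
    p = max(2.0 * min(n_le, n_ge) / B, 1.0 / B) if sentinel else min(
        2.0 * min(n_le, n_ge) / B, 1.0
    )
    return BootstrapResult(
        pair=(x, y),
        statistic=point,
        distribution=stats,
        ci=(float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5))),
        p_value=p,
        p_sentinel=sentinel,
        B=B,
        seed=seed,
        n_redraws=n_redraws,
    )


def compare_cohorts(
    res_a: BootstrapResult, res_b: BootstrapResult
) -> BootstrapResult:
    """Cohort comparison: difference of the two cohorts' per-draw statistics."""
    if res_a.B != res_b.B:
        raise ValueError("cohort results need equal B")
    diff = res_a.distribution - res_b.distribution
    n_le = int((diff <= 0).sum())
    n_ge = int((diff >= 0).sum())
    sentinel = min(n_le, n_ge) == 0
    p = 1.0 / res_a.B if sentinel else min(2.0 * min(n_le, n_ge) / res_a.B, 1.0)
    return BootstrapResult(
        pair=res_a.pair,
        statistic=res_a.statistic - res_b.statistic,
        distribution=diff,
        ci=(float(np.percentile(diff, 2.5)), float(np.percentile(diff, 97.5))),
        p_value=p,
        p_sentinel=sentinel,
        B=res_a.B,
        seed=res_a.seed,
    )


def transition_graph(
    curve_sets: list[TransitionCurveSet],
    bootstrap_results: dict[tuple[str, str], BootstrapResult] | None = None,
    alpha: float = 0.05,
):
    """Relative-change table: AUC_laser / AUC_baseline per observed pair.

    A ratio of 1 means no laser effect.  Pairs with no trials starting in X,
    no observed transitions, or zero baseline AUC are omitted (with a note).
    """
    import pandas as pd

    rows, notes = [], []
    for cs in curve_sets:
        name = f"{cs.pair[0]}->{cs.pair[1]}"
        if not cs.defined:
            notes.append(f"{name}: undefined (no trials in {cs.pair[0]} at onset)")
            continue
        if cs.pair[0] != cs.pair[1] and cs.laser.max() == 0 and cs.baseline.max() == 0:
            notes.append(f"{name}: omitted (transition never observed)")
            continue
        auc_b = float(_auc(cs.baseline, cs.d))
        auc_l = float(_auc(cs.laser, cs.d))
        if auc_b == 0:
            notes.append(f"{name}: omitted (zero baseline AUC)")
            continue
        row = {"pair": name, "ratio": auc_l / auc_b}
        if bootstrap_results and cs.pair in bootstrap_results:
            br = bootstrap_results[cs.pair]
            row["p_value"] = br.p_value
            row["significant"] = br.p_sentinel or br.p_value < alpha
        rows.append(row)
    return pd.DataFrame(rows), notes


def state_percentage_timecourse(
    trial_states: np.ndarray,
    epoch_s: float = 2.5,
    pre_s: float | None = None,
    laser_s: float | None = None,
):
    """Percentage of trials in each state versus trial time.

    ``trial_states`` is an (m, n_epochs) code matrix of onset-aligned trials
    (2.5 s grid).  Returns a DataFrame (time_s, W, N, R percentages, summing
    to 100 over scored states) and, when ``pre_s``/``laser_s`` are given,
    per-trial mean percentages in the laser interval vs the preceding
    equal-length baseline for downstream paired tests.
    """
    import pandas as pd

    trial_states = np.asarray(trial_states, dtype="U1")
    m, n = trial_states.shape
    t = np.arange(n) * epoch_s - (pre_s or 0.0)
    scored = trial_states != "U"
    denom = scored.sum(axis=0).astype(float)
    denom[denom == 0] = np.nan
    tc = {"time_s": t}
    for code in "WNR":
        tc[code] = (trial_states == code).sum(axis=0) / denom * 100.0
    timecourse = pd.DataFrame(tc)

    per_trial = None
    if pre_s is not None and laser_s is not None:
        k0 = int(round(pre_s / epoch_s))
        nk = int(round(laser_s / epoch_s))
        rows = []
        for i in range(m):
            base = trial_states[i, k0 - nk : k0]
            las = trial_states[i, k0 : k0 + nk]
            for code in "WNR":
                rows.append(
                    {
                        "trial": i,
                        "state": code,
                        "baseline_pct": float((base == code).mean() * 100.0),
                        "laser_pct": float((las == code).mean() * 100.0),
                    }
                )
        per_trial = pd.DataFrame(rows)
    return timecourse, per_trial
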