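"""Fiber-photometry ΔF/F and the miniscope single-cell pipeline.

The miniscope pipeline, run in this order:

1. **Motion correction** — each frame is spatially high-pass filtered
   (frame minus a low-pass blurred copy of itself); the integer (x, y) shift
   maximizing the 2D cross-correlation between the frame and a high-contrast
   reference patch is estimated and undone on the raw stack.
2. **Activity map** — ``M = <<(f − f̄)/(f̄ + f_avg)>_w>_t`` where ``f̄`` is
   the pixel's temporal mean, ``f_avg`` the movie-wide mean, ``<·>_w`` a
   spatial 2×2 box filter, and ``<·>_t`` the temporal mean.  Pixels with
   strong temporal variation light up; ROIs are drawn on this map.
3. **Trace extraction** — per ROI, the raw trace ``F(t)`` is the pixel mean;
   the neuropil trace ``F_np(t)`` is the mean over a bordering 10 μm ring at
   ~5 μm offset (excluding all ROIs); ``F_subt = F − c·F_np`` with the
   session-wide correction factor
   ``c = (F_bv − F_off) / (F_near_bv − F_off)`` estimated from a blood
   vessel, a nearby vessel-free region, and an off-lens region.  The
   baseline ``B(t)`` is an affine fit to the samples of ``F_subt`` at or
   below its session 20th percentile, and ``ΔF/F = (F_subt − B)/B``.
4. **Classification** — per cell, a one-way ANOVA of ΔF/F across brain
   states (Tukey HSD post hoc); REM-max cells split into R>N>W vs R>W>N.

Fiber photometry uses the isosbestic 405 nm channel as a bleaching/motion
control: both channels are low-pass filtered at 2 Hz (4th-order
Butterworth), the 405 signal is regressed onto the 465 signal, and
``ΔF/F = (465 − fit) / fit``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps, stats

from .core import BrainState, Episode, Hypnogram, episodes
from .phasic import PhasicEvent

__all__ = [
    "MovieStack",
    "RoiSet",
    "RoiTraceSet",
    "SUBCLASSES",
    "motion_correct",
    "activity_map",
    "make_neuropil_rings",
    "extract_dff",
    "photometry_dff",
    "match_rois",
    "classify_subclasses",
    "align_to_transitions",
    "time_normalized_sequences",
    "phasic_event_activity",
    "crosscorr_band_power",
]

SUBCLASSES = ("R>N>W", "R>W>N", "Wake-max", "NREM-max", "unmodulated")


@dataclass(frozen=True)
class MovieStack:
    frames: np.ndarray  # (T, H, W), arbitrary fluorescence units
    fs: float = 20.0
    um_per_px: float = 1.2

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("movie must be (T, H, W)")
        if self.fs <= 0:
            raise ValueError("frame rate must be positive")
        object.__setattr__(self, "frames", np.asarray(self.frames, np.float32))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class RoiSet:
    """ROI masks plus the calibration regions for neuropil correction."""

    rois: list[np.ndarray]  # boolean masks, (H, W)
    blood_vessel: np.ndarray | None = None
    near_blood_vessel: np.ndarray | None = None
    off_lens: np.ndarray | None = None
    rings: list[np.ndarray] = field(default_factory=list)
    #: usable tissue (e.g. the lens aperture); rings never leave it
    valid_mask: np.ndarray | None = None

    def union(self) -> np.ndarray:
        out = np.zeros_like(self.rois[0], bool)
        for r in self.rois:
            out |= r
        return out


@dataclass(frozen=True)
class RoiTraceSet:
    F: np.ndarray  # (n_rois, T)
    F_np: np.ndarray
    F_subt: np.ndarray
    B: np.ndarray
    dff: np.ndarray
    c: float
    fs: float


# ------------------------------------------------------------ motion


def _highpass(frames: np.ndarray, sigma: float) -> np.ndarray:
    lp = ndimage.gaussian_filter(frames, sigma=(0, sigma, sigma))
    return frames - lp


def _best_patch(img: np.ndarray, patch: int) -> tuple[int, int]:
    """Top-left corner of the patch with highest local variance."""
    var = ndimage.uniform_filter(img.astype(float) ** 2, patch) - (
        ndimage.uniform_filter(img.astype(float), patch) ** 2
    )
    h, w = img.shape
    half = patch // 2
    inner = var[half : h - half, half : w - half]
    r, c = np.unravel_index(np.argmax(inner), inner.shape)
    return r, c  # top-left of patch


def motion_correct(
    movie: MovieStack,
    max_shift: int = 8,
    hp_sigma: float = 6.0,
    patch: int = 40,
    reference: tuple[int, int] | None = None,
) -> tuple[MovieStack, np.ndarray, np.ndarray]:
    """Rigid, integer-pixel motion correction.

    Returns ``(corrected_movie, shifts, flagged)`` where ``shifts[t]`` is the
    estimated (dy, dx) displacement of frame t relative to the reference and
    ``flagged[t]`` marks frames whose estimate hit the ``max_shift`` bound
    (left unshifted).  ``reference`` optionally fixes the patch corner.
    """
    hp = _highpass(movie.frames.astype(np.float32), hp_sigma)
    mean_hp = hp.mean(axis=0)
    r0, c0 = reference if reference is not None else _best_patch(mean_hp, patch)
    H, W = mean_hp.shape
    r0 = int(np.clip(r0, max_shift, H - patch - max_shift))
    c0 = int(np.clip(c0, max_shift, W - patch - max_shift))
    ref = mean_hp[r0 : r0 + patch, c0 : c0 + patch]
    ref = ref - ref.mean()

    T = movie.shape[0]
    shifts = np.zeros((T, 2), int)
    flagged = np.zeros(T, bool)
    search = hp[
        :, r0 - max_shift : r0 + patch + max_shift, c0 - max_shift : c0 + patch + max_shift
    ]
    kernel = ref[::-1, ::-1]
    for t in range(T):
        corr = sps.fftconvolve(search[t] - search[t].mean(), kernel, mode="valid")
        dy, dx = np.unravel_index(np.argmax(corr), corr.shape)
        dy -= max_shift
        dx -= max_shift
        if abs(dy) >= max_shift or abs(dx) >= max_shift:
            flagged[t] = True
            continue
        shifts[t] = (dy, dx)
    # the stack-mean reference sits at the mean displacement; re-anchor so
    # the first (unflagged) frame defines zero shift
    ok = np.flatnonzero(~flagged)
    if ok.size:
        shifts[~flagged] -= shifts[ok[0]]
    corrected = movie.frames.copy()
    for t in range(T):
        if not flagged[t] and (shifts[t] != 0).any():
            corrected[t] = np.roll(corrected[t], (-shifts[t][0], -shifts[t][1]), (0, 1))
    return MovieStack(corrected, movie.fs, movie.um_per_px), shifts, flagged


# ------------------------------------------------------------ activity map


def activity_map(movie: MovieStack) -> np.ndarray:
    """Pixel-wise activity map highlighting temporally fluctuating pixels.

    The 2×2 box filter averages pixels (i..i+1, j..j+1) with edge
    replication at the bottom/right border.
    """
    f = movie.frames.astype(np.float64)
    fbar = f.mean(axis=0)
    favg = float(f.mean())
    dev = (f - fbar) / (fbar + favg)
    p = np.pad(dev, ((0, 0), (0, 1), (0, 1)), mode="edge")
    smoothed = (p[:, :-1, :-1] + p[:, 1:, :-1] + p[:, :-1, 1:] + p[:, 1:, 1:]) / 4.0
    return smoothed.mean(axis=0)


# ------------------------------------------------------------ traces / ΔF/F


def make_neuropil_rings(
    rois: list[np.ndarray],
    um_per_px: float = 1.2,
    offset_um: float = 5.0,
    width_um: float = 10.0,
    valid_mask: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Bordering neuropil ring per ROI: ``offset`` to ``offset+width`` from
    the ROI perimeter, excluding every ROI's pixels and anything outside
    ``valid_mask`` (e.g. the off-lens margin)."""
    union = np.zeros_like(rois[0], bool)
    for r in rois:
        union |= r
    keep = ~union if valid_mask is None else (~union & valid_mask)
    rings = []
    for roi in rois:
        dist = ndimage.distance_transform_edt(~roi) * um_per_px
        ring = (dist >= offset_um) & (dist < offset_um + width_um) & keep
        rings.append(ring)
    return rings


def extract_dff(
    movie: MovieStack,
    rois: RoiSet,
    baseline_percentile: float = 20.0,
    c: float | None = None,
) -> RoiTraceSet:
    """ROI traces with neuropil, baseline and ΔF/F correction.

    ``c`` defaults to the blood-vessel calibration ratio; the calibration
    regions must then be present in ``rois``.
    """
    f = movie.frames
    T = f.shape[0]
    flat = f.reshape(T, -1)

    def region_trace(mask: np.ndarray) -> np.ndarray:
        return flat[:, mask.ravel()].mean(axis=1)

    if c is None:
        for name in ("blood_vessel", "near_blood_vessel", "off_lens"):
            if getattr(rois, name) is None:
                raise ValueError(f"calibration region {name!r} missing")
        bv = float(region_trace(rois.blood_vessel).mean())
        near = float(region_trace(rois.near_blood_vessel).mean())
        off = float(region_trace(rois.off_lens).mean())
        if near - off == 0:
            raise ValueError("degenerate calibration: near-vessel equals off-lens")
        c = (bv - off) / (near - off)
    if not 0 < c < 1.5:
        warnings.warn(f"implausible neuropil correction factor c={c:.3g}", stacklevel=2)

    if not rois.rings:
        rois.rings = make_neuropil_rings(
            rois.rois, movie.um_per_px, valid_mask=rois.valid_mask
        )
    n = len(rois.rois)
    F = np.empty((n, T))
    F_np = np.empty((n, T))
    for i, (roi, ring) in enumerate(zip(rois.rois, rois.rings)):
        if not ring.any():
            raise ValueError(f"ROI {i}: neuropil ring empty after exclusions")
        F[i] = region_trace(roi)
        F_np[i] = region_trace(ring)
    F_subt = F - c * F_np

    t = np.arange(T) / movie.fs
    B = np.empty_like(F_subt)
    for i in range(n):
        x = F_subt[i]
        thresh = np.percentile(x, baseline_percentile)
        low = x <= thresh
        slope, intercept = np.polyfit(t[low], x[low], 1)
        B[i] = slope * t + intercept
    dff = (F_subt - B) / B
    return RoiTraceSet(F=F, F_np=F_np, F_subt=F_subt, B=B, dff=dff, c=float(c), fs=movie.fs)


def photometry_dff(
    f465: np.ndarray, f405: np.ndarray, fs: float, lp_hz: float = 2.0
) -> np.ndarray:
    """Isosbestic-corrected photometry ΔF/F.

    Both channels are low-pass filtered at ``lp_hz`` (4th-order Butterworth,
    zero phase), the 405 channel is linearly regressed onto the 465 channel,
    and ΔF/F = (465 − fit)/fit.
    """
    f465 = np.asarray(f465, float)
    f405 = np.asarray(f405, float)
    if f465.shape != f405.shape:
        raise ValueError("channel length mismatch")
    sos = sps.butter(4, lp_hz, btype="lowpass", fs=fs, output="sos")
    a = sps.sosfiltfilt(sos, f465)
    b = sps.sosfiltfilt(sos, f405)
    if np.ptp(b) == 0:
        raise ValueError("405 nm channel is constant; regression degenerate")
    slope, intercept, *_ = stats.linregress(b, a)
    fit = slope * b + intercept
    return (a - fit) / fit


# ------------------------------------------------------------ ROI matching


def _transform_mask(mask: np.ndarray, angle_deg: float, dy: int, dx: int) -> np.ndarray:
    out = mask.astype(float)
    if angle_deg:
        out = ndimage.rotate(out, angle_deg, reshape=False, order=0)
    out = np.roll(out, (dy, dx), axis=(0, 1))
    return out > 0.5


def match_rois(
    session_a: RoiSet,
    session_b: RoiSet,
    max_rotation_deg: float = 10.0,
    rotation_step_deg: float = 1.0,
    max_shift: int = 10,
    min_overlap: float = 0.5,
) -> tuple[list[tuple[int, int]], dict]:
    """Match ROIs across two sessions via a rigid transform.

    A coarse grid over rotations (preferring small angles) with the best
    translation per rotation (found by cross-correlating the binary ROI
    union maps) maximizes total ROI overlap; ROI pairs overlapping by at
    least ``min_overlap`` of the smaller ROI are then matched greedily,
    one-to-one.  Returns the (a_index, b_index) pairs and the transform.
    """
    ua = session_a.union().astype(float)
    ub = session_b.union().astype(float)
    angles = sorted(
        np.arange(-max_rotation_deg, max_rotation_deg + rotation_step_deg / 2, rotation_step_deg),
        key=abs,
    )
    best = {"score": -1.0, "angle": 0.0, "dy": 0, "dx": 0}
    for ang in angles:
        ra = ndimage.rotate(ua, ang, reshape=False, order=0) if ang else ua
        corr = sps.fftconvolve(ub, ra[::-1, ::-1], mode="same")
        H, W = corr.shape
        cy, cx = H // 2, W // 2
        win = corr[cy - max_shift : cy + max_shift + 1, cx - max_shift : cx + max_shift + 1]
        dy, dx = np.unravel_index(np.argmax(win), win.shape)
        score = float(win[dy, dx])
        dy -= max_shift
        dx -= max_shift
        if score > best["score"] + 1e-9:
            best = {"score": score, "angle": float(ang), "dy": int(dy), "dx": int(dx)}
    if best["score"] <= 0:
        return [], best

    moved = [
        _transform_mask(r, best["angle"], best["dy"], best["dx"]) for r in session_a.rois
    ]
    candidates = []
    for i, ma in enumerate(moved):
        for j, mb in enumerate(session_b.rois):
            inter = np.logical_and(ma, mb).sum()
            if inter == 0:
                continue
            frac = inter / min(ma.sum(), mb.sum())
            if frac >= min_overlap:
                candidates.append((frac, i, j))
    pairs: list[tuple[int, int]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for frac, i, j in sorted(candidates, reverse=True):
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return sorted(pairs), best


# ------------------------------------------------------------ classification


def _state_samples(dff: np.ndarray, h: Hypnogram, fs: float) -> dict[str, np.ndarray]:
    codes = h.sample_states(dff.shape[-1], fs)
    return {s: dff[..., codes == s] for s in "WNR"}


def classify_subclasses(
    traces: RoiTraceSet | np.ndarray,
    h: Hypnogram,
    fs: float | None = None,
    alpha: float = 0.05,
    require_posthoc: bool = True,
) -> pd.DataFrame:
    """Assign each cell a brain-state subclass from its ΔF/F distribution.

    Per cell: one-way ANOVA of ΔF/F with brain state (W/N/R) as factor; if
    not significant at ``alpha`` the cell is *unmodulated*, otherwise the
    state with the highest mean names the class, with the Tukey HSD
    post-hoc comparison against the runner-up state required to confirm it
    (``require_posthoc=False`` drops that confirmation and labels by the
    raw argmax); REM-max cells split on NREM vs Wake means.

    ΔF/F is averaged within each scored epoch first — the brain-state
    factor is only defined on the epoch grid, and epoch means are far less
    autocorrelated than raw samples, keeping the ANOVA's false-positive
    rate near ``alpha`` for slowly decaying calcium indicators.
    """
    if isinstance(traces, RoiTraceSet):
        dff, fs = traces.dff, traces.fs
    else:
        dff = np.asarray(traces, float)
        if fs is None:
            raise ValueError("fs required when passing a bare ΔF/F array")
    per_epoch = int(round(h.epoch_s * fs))
    n_ep = min(dff.shape[1] // per_epoch, len(h))
    ep_mean = dff[:, : n_ep * per_epoch].reshape(dff.shape[0], n_ep, per_epoch).mean(-1)
    ep_codes = h.states[:n_ep]
    rows = []
    for i in range(dff.shape[0]):
        groups = {s: ep_mean[i, ep_codes == s] for s in "WNR"}
        for s, g in groups.items():
            if g.size == 0:
                raise ValueError(f"state {s} absent from the session")
        fstat, p = stats.f_oneway(groups["W"], groups["N"], groups["R"])
        means = {s: float(g.mean()) for s, g in groups.items()}
        if p >= alpha:
            label = "unmodulated"
            tukey_p = np.nan
        else:
            order = sorted("WNR", key=lambda s: -means[s])
            top, second = order[0], order[1]
            res = stats.tukey_hsd(groups["W"], groups["N"], groups["R"])
            idx = {"W": 0, "N": 1, "R": 2}
            tukey_p = float(res.pvalue[idx[top], idx[second]])
            if require_posthoc and tukey_p >= alpha:
                label = "unmodulated"
            elif top == "R":
                label = "R>N>W" if means["N"] >= means["W"] else "R>W>N"
            elif top == "W":
                label = "Wake-max"
            else:
                label = "NREM-max"
        rows.append(
            {
                "cell": i,
                "label": label,
                "anova_p": float(p),
                "tukey_top_p": tukey_p,
                "mean_W": means["W"],
                "mean_N": means["N"],
                "mean_R": means["R"],
            }
        )
    df = pd.DataFrame(rows)
    counts = df[df.label != "unmodulated"].label.value_counts()
    total = int(counts.sum())
    df.attrs["proportions"] = {k: v / total for k, v in counts.items()} if total else {}
    return df


# ------------------------------------------------------ transition alignment


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def find_transitions(
    h: Hypnogram,
    x: str,
    y: str,
    min_pre_s: float | None = None,
    bridge_ma_s: float = 10.0,
) -> list[float]:
    """Times of X→Y transitions whose preceding X episode is long enough.

    Defaults mirror the inclusion rules: preceding NREM or Wake episodes
    must last ≥ 60 s (NREM may be interrupted by microarousals ≤ 10 s);
    preceding REM episodes ≥ 10 s.
    """
    if min_pre_s is None:
        min_pre_s = 10.0 if x == "R" else 60.0
    eps = episodes(h, x, bridge_ma_s if x == "N" else 0.0)
    out = []
    for e in eps:
        k = int(round((e.end_s - h.t0) / h.epoch_s))
        if k >= len(h):
            continue
        if h.states[k] == y and e.duration_s >= min_pre_s:
            out.append(e.end_s)
    return out


def align_to_transitions(
    traces: RoiTraceSet | np.ndarray,
    h: Hypnogram,
    pair: tuple[str, str],
    labels: pd.DataFrame | None = None,
    fs: float | None = None,
    window_s: tuple[float, float] = (-60.0, 30.0),
    bin_s: float = 10.0,
    alpha: float = 0.05,
) -> dict:
    """Transition-aligned, z-scored ΔF/F with per-subclass bin statistics.

    ΔF/F is z-scored per cell over the whole recording, aligned at each
    qualifying X→Y transition, averaged over transitions, and binned at
    ``bin_s``.  Per subclass: one-way rm ANOVA over bins (cells as
    subjects), then Holm-corrected paired t-tests of each bin against the
    first (−60…−50 s baseline) bin.
    """
    import pingouin as pg
    from statsmodels.stats.multitest import multipletests

    if isinstance(traces, RoiTraceSet):
        dff, fs = traces.dff, traces.fs
    else:
        dff = np.asarray(traces, float)
    z = _zscore_rows(dff)
    times = find_transitions(h, *pair)
    n_pre = int(round(-window_s[0] * fs))
    n_post = int(round(window_s[1] * fs))
    segs = []
    for t0 in times:
        k = int(round((t0 - h.t0) * fs))
        if k - n_pre < 0 or k + n_post > z.shape[1]:
            continue
        segs.append(z[:, k - n_pre : k + n_post])
    if not segs:
        warnings.warn(f"no qualifying {pair[0]}->{pair[1]} transitions", stacklevel=2)
        return {"n_transitions": 0}
    mean_cell = np.stack(segs).mean(axis=0)  # (n_cells, n_samples)
    per_bin = int(round(bin_s * fs))
    n_bins = mean_cell.shape[1] // per_bin
    binned = mean_cell[:, : n_bins * per_bin].reshape(mean_cell.shape[0], n_bins, per_bin).mean(-1)
    bin_t = window_s[0] + (np.arange(n_bins) + 0.5) * bin_s

    out = {"n_transitions": len(segs), "bin_times_s": bin_t, "binned": binned}
    groups = (
        {lbl: labels.index[labels.label == lbl].to_numpy() for lbl in labels.label.unique()}
        if labels is not None
        else {"all": np.arange(binned.shape[0])}
    )
    stats_out = {}
    for lbl, cells in groups.items():
        sub = binned[cells]
        if sub.shape[0] < 3:
            continue
        long = pd.DataFrame(
            {
                "dff": sub.ravel(),
                "bin": np.tile(np.arange(n_bins), sub.shape[0]),
                "cell": np.repeat(np.arange(sub.shape[0]), n_bins),
            }
        )
        aov = pg.rm_anova(data=long, dv="dff", within="bin", subject="cell",
                          correction=True)
        # Greenhouse-Geisser-corrected p when sphericity is violated
        pcols = [c for c in aov.columns if c.replace("-", "_") in ("p_GG_corr", "p_gg_corr")]
        p_rm = float(aov[pcols[0]].iloc[0]) if pcols and np.isfinite(
            aov[pcols[0]].iloc[0]
        ) else float(aov[[c for c in aov.columns if c.replace("-", "_") == "p_unc"][0]].iloc[0])
        pvals = [
            stats.ttest_rel(sub[:, b], sub[:, 0]).pvalue if b else 1.0
            for b in range(n_bins)
        ]
        rej, p_holm, *_ = multipletests(pvals[1:], alpha=alpha, method="holm")
        sig = np.zeros(n_bins, bool)
        sig[1:] = rej & (p_rm < alpha)
        stats_out[lbl] = {
            "rm_anova_p": p_rm,
            "holm_p": np.concatenate([[np.nan], p_holm]),
            "significant_bins": sig,
            "mean": sub.mean(axis=0),
            "sem": sub.std(axis=0, ddof=1) / np.sqrt(sub.shape[0]),
        }
    out["subclass_stats"] = stats_out
    return out


def time_normalized_sequences(
    traces: RoiTraceSet | np.ndarray,
    h: Hypnogram,
    fs: float | None = None,
    bins_per_state: int = 10,
    rem_split_s: float = 30.0,
) -> dict:
    """NREM→REM→Wake sequences with per-episode time normalization.

    Each NREM, REM, and Wake episode in a qualifying sequence is divided
    into ``bins_per_state`` equal bins; sequences are grouped by REM episode
    duration (short < ``rem_split_s`` ≤ long).  Returns per-group per-cell
    mean profiles of length ``3 * bins_per_state``.
    """
    if isinstance(traces, RoiTraceSet):
        dff, fs = traces.dff, traces.fs
    else:
        dff = np.asarray(traces, float)
    z = _zscore_rows(dff)
    rem_eps = episodes(h, BrainState.REM)
    groups: dict[str, list[np.ndarray]] = {"short": [], "long": []}
    for rem in rem_eps:
        k_pre = int(round((rem.start_s - h.t0) / h.epoch_s)) - 1
        k_post = int(round((rem.end_s - h.t0) / h.epoch_s))
        if k_pre < 0 or k_post >= len(h):
            continue
        if h.states[k_pre] != "N" or h.states[k_post] != "W":
            continue
        nrem = [e for e in episodes(h, "N", 10.0) if abs(e.end_s - rem.start_s) < 1e-9]
        wake = [e for e in episodes(h, "W") if abs(e.start_s - rem.end_s) < 1e-9]
        if not nrem or not wake:
            continue
        profile = []
        ok = True
        for ep in (nrem[0], rem, wake[0]):
            a = int(round(ep.start_s * fs))
            b = int(round(ep.end_s * fs))
            if b - a < bins_per_state:
                ok = False
                break
            idx = np.linspace(a, b, bins_per_state + 1).astype(int)
            profile.append(
                np.stack(
                    [z[:, idx[i] : idx[i + 1]].mean(axis=1) for i in range(bins_per_state)],
                    axis=1,
                )
            )
        if not ok:
            continue
        key = "short" if rem.duration_s < rem_split_s else "long"
        groups[key].append(np.concatenate(profile, axis=1))
    return {
        k: (np.stack(v).mean(axis=0) if v else None) for k, v in groups.items()
    } | {"n_short": len(groups["short"]), "n_long": len(groups["long"])}


def phasic_event_activity(
    traces: RoiTraceSet | np.ndarray,
    events: list[PhasicEvent],
    rem_episodes: list[Episode],
    labels: pd.DataFrame | None = None,
    fs: float | None = None,
) -> pd.DataFrame:
    """Per-subclass paired contrast of ΔF/F in phasic events vs baseline.

    For each cell and event, the mean ΔF/F during the event is compared with
    the immediately preceding tonic interval of equal duration; events with
    no room for a baseline inside their REM episode are skipped.  Per
    subclass, a paired t-test across cells tests the mean difference.
    """
    if isinstance(traces, RoiTraceSet):
        dff, fs = traces.dff, traces.fs
    else:
        dff = np.asarray(traces, float)
    ep_start = {i: e.start_s for i, e in enumerate(rem_episodes)}
    ev_means, base_means = [], []
    for e in events:
        d = e.duration_s
        if e.start_s - d < ep_start.get(e.episode_id, -np.inf):
            continue
        a = int(round(e.start_s * fs))
        b = int(round(e.end_s * fs))
        a0 = int(round((e.start_s - d) * fs))
        if a0 < 0 or b > dff.shape[1] or b <= a:
            continue
        ev_means.append(dff[:, a:b].mean(axis=1))
        base_means.append(dff[:, a0:a].mean(axis=1))
    if not ev_means:
        return pd.DataFrame(columns=["label", "n_cells", "t", "p", "mean_diff"])
    ev = np.stack(ev_means).mean(axis=0)
    base = np.stack(base_means).mean(axis=0)
    groups = (
        {lbl: labels.index[labels.label == lbl].to_numpy() for lbl in labels.label.unique()}
        if labels is not None
        else {"all": np.arange(dff.shape[0])}
    )
    rows = []
    for lbl, cells in groups.items():
        if cells.size < 2:
            continue
        t, p = stats.ttest_rel(ev[cells], base[cells])
        rows.append(
            {
                "label": lbl,
                "n_cells": int(cells.size),
                "t": float(t),
                "p": float(p),
                "mean_diff": float((ev[cells] - base[cells]).mean()),
            }
        )
    return pd.DataFrame(rows)


def crosscorr_band_power(
    traces: RoiTraceSet | np.ndarray,
    eeg: np.ndarray,
    eeg_fs: float,
    h: Hypnogram,
    band,
    labels: pd.DataFrame | None = None,
    fs: float | None = None,
    min_bout_s: float = 120.0,
    max_lag_s: float = 30.0,
) -> dict:
    """Cross-correlation between per-cell ΔF/F and an EEG band power.

    Band power is computed per NREM bout (duration ≥ 120 s, microarousals
    bridged) from 2.5 s windows stepped by 0.5 s (80 % overlap), each row of
    the spectrogram normalized by its mean over the whole recording; ΔF/F is
    averaged over the same windows.  The cross-correlation, normalized by
    ``sd(s)·sd(d)·n``, is averaged over bouts; per cell the max-|value| peak
    within ±30 s is taken and per subclass tested against 0 with a
    one-sample t-test.  Positive lag ⇔ ΔF/F leads the power.
    """
    from .spectral import spectrogram as _specgram

    if isinstance(traces, RoiTraceSet):
        dff, fs = traces.dff, traces.fs
    else:
        dff = np.asarray(traces, float)
    step_s = 0.5
    spec = _specgram(eeg, eeg_fs, window_s=2.5, psd_window_s=2.5, step_s=step_s)
    norm = spec.power / spec.power.mean(axis=1, keepdims=True)
    fmask = (spec.freqs >= band.lo_hz) & (spec.freqs < band.hi_hz)
    df = float(spec.freqs[1] - spec.freqs[0])
    power = norm[fmask].sum(axis=0) * df  # per column
    win_starts = np.arange(power.size) * step_s

    bouts = [e for e in episodes(h, "N", 10.0) if e.duration_s >= min_bout_s]
    if not bouts:
        warnings.warn("no NREM bout >= 120 s", stacklevel=2)
        return {"n_bouts": 0}
    max_lag = int(round(max_lag_s / step_s))
    acc = None
    n_bouts = 0
    for b in bouts:
        cols = np.flatnonzero(
            (win_starts >= b.start_s) & (win_starts + 2.5 <= b.end_s)
        )
        if cols.size < 2 * max_lag + 2:
            continue
        s = power[cols]
        # ΔF/F averaged over the same windows
        d_cols = np.stack(
            [
                dff[
                    :,
                    int(round(win_starts[c] * fs)) : int(round((win_starts[c] + 2.5) * fs)),
                ].mean(axis=1)
                for c in cols
            ],
            axis=1,
        )
        s0 = s - s.mean()
        cc_rows = []
        for i in range(d_cols.shape[0]):
            d0 = d_cols[i] - d_cols[i].mean()
            denom = s.std() * d_cols[i].std() * s.size
            full = sps.correlate(s0, d0, mode="full") / (denom if denom else 1.0)
            mid = s.size - 1
            cc_rows.append(full[mid - max_lag : mid + max_lag + 1])
        cc = np.stack(cc_rows)
        acc = cc if acc is None else acc + cc
        n_bouts += 1
    if n_bouts == 0:
        warnings.warn("no NREM bout long enough for the lag range", stacklevel=2)
        return {"n_bouts": 0}
    cc = acc / n_bouts
    lags = np.arange(-max_lag, max_lag + 1) * step_s
    peak_idx = np.argmax(np.abs(cc), axis=1)
    peaks = cc[np.arange(cc.shape[0]), peak_idx]
    peak_lags = lags[peak_idx]

    groups = (
        {lbl: labels.index[labels.label == lbl].to_numpy() for lbl in labels.label.unique()}
        if labels is not None
        else {"all": np.arange(dff.shape[0])}
    )
    tests = {}
    for lbl, cells in groups.items():
        if cells.size < 2:
            continue
        t, p = stats.ttest_1samp(peaks[cells], 0.0)
        tests[lbl] = {"t": float(t), "p": float(p), "mean_peak": float(peaks[cells].mean())}
    return {
        "n_bouts": n_bouts,
        "lags_s": lags,
        "crosscorr": cc,
        "peak_values": peaks,
        "peak_lags_s": peak_lags,
        "subclass_tests": tests,
    }
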