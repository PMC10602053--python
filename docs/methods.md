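# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `sleepkit`, and what the synthetic-data validation does and does not
establish about real recordings.

## Coordinate system

All analyses are anchored to the hypnogram: manually scored brain states
(Wake `W`, NREM `N`, REM `R`, plus `U` for unscored epochs, which never enter
statistics) on a uniform 2.5 s epoch grid. Epochs are half-open intervals
`[t, t + 2.5)`; signal sample `i` of a channel sampled at `fs` maps to time
`i / fs`; all timestamps are 0-based seconds. The 2.5 s resolution comes from
the scoring spectrogram: sliding half-overlapping 5 s windows.

For episode-duration analyses, NREM episodes may absorb *microarousals* —
wake intrusions of at most 10 s — so that a brief movement does not split one
consolidated NREM bout into two. Bridging is applied only when segmenting
episodes; the stored hypnogram is never mutated.

## Spectral estimation

PSDs use Welch's method: Hann window, half-overlapping 2 s segments,
per-segment mean removal (prevents DC leakage into the δ band), no zero
padding, density scaling (μV²/Hz). The spectrogram applies that estimator to
half-overlapping 5 s windows; incomplete trailing windows are dropped rather
than padded, so trial averages carry no edge bias. Band power is a midpoint
Riemann sum: bins whose centre frequency satisfies `lo ≤ f < hi` contribute
`psd·df`. With the conventional bands — δ 0.5–4.5, θ 6–9.5, σ 10–15,
γ 50–90 Hz — the half-open convention makes band powers exactly additive
over adjacent bands. EMG amplitude is the square root of the integrated
5–100 Hz EMG power.

Laser-triggered spectrograms normalize each frequency row by its temporal
mean over the *non-laser* columns only; rows whose non-laser mean is below
1e−12 of the largest row mean carry no signal and are zeroed instead of
amplified (a pure-tone synthetic signal otherwise produces astronomically
scaled empty bins; real EEG never has exact zeros, so this floor is inert on
data).

## Closed-loop REM detection

The online detector evaluates, every 2.5 s, three features from the trailing
5 s of signal (so decisions are strictly causal): EEG δ power, θ/δ power
ratio, and EMG amplitude. Onset is declared when δ power and EMG amplitude
are below their thresholds and θ/δ exceeds a *hard* threshold; the detection
persists until θ/δ falls below a *soft* threshold or the EMG exceeds its
threshold. This onset/offset logic is fixed; only the calibration that
produces the thresholds is configurable.

Calibration from a scored recording of the same animal:

| threshold | default rule | rationale |
|---|---|---|
| `delta_max` | mean NREM δ power | NREM is the δ-dominated state |
| `emg_max` | mean NREM EMG amplitude + 1·SD | atonia bound with slack |
| `thdelta_hard` | REM 5th percentile of θ/δ, floored at the NREM 95th percentile | see below |
| `thdelta_soft` | 0.6 × hard | hysteresis |

The hard threshold uses a percentile rather than mean − k·SD because θ/δ is
a ratio of band powers and heavily right-skewed: in calibration experiments
a mean − 0.5·SD rule left ~30% of REM epochs *below* the threshold, whereas
the 5th-percentile rule puts ≥ 95% of calibration REM epochs above it by
construction while the NREM-95th-percentile floor keeps NREM out.

## Phasic θ events

Within REM, θ accelerates and grows transiently ("phasic" REM). Detection is
purely timing-based, from θ troughs: the parietal EEG is band-passed 5–12 Hz
(4th-order Butterworth, zero-phase — filtfilt preserves trough timing),
the analytic signal gives phase (peak = 0 rad, troughs at ±π) and amplitude,
and troughs are local minima of the wrapped phase below −3 rad, one per
cycle. Troughs additionally require an instantaneous amplitude above 0.5 μV —
a flat trace has no oscillation, and without the floor numerical noise in a
constant signal produces phantom troughs.

Inter-trough intervals are smoothed per episode with an 11-point box filter
(shrinking symmetric window at episode edges). Four gates define an event:
a run of smoothed intervals strictly below the session 10th percentile,
spanning ≥ 900 ms; minimum smoothed interval below the 5th percentile; and
mean θ amplitude over the run above the session-mean REM amplitude.
Percentiles (linear interpolation) and the amplitude mean pool all REM
episodes of the session that do not overlap laser stimulation. The first
two gates depend only on timing, so they are exactly invariant to amplitude
rescaling; the amplitude gate scales covariantly.

Event frequency is reported per minute of REM; phasic/tonic PSDs pool events
of at least the 2 s PSD window (shorter events still count toward the
frequency).

## Heart rate from nuchal EMG

ECG R-waves contaminate the nuchal EMG and stand out during REM atonia.
Per REM episode, the EMG is band-passed 10–100 Hz and local minima separated
by a 50 ms refractory gap (mouse ceiling 1200 bpm; the rate can therefore
never exceed the cap) are counted below each threshold on a 1 μV grid from
−100 to 0 μV. If R-waves separate from noise, this count curve rises to a
plateau before sharply rising into the noise; the episode is accepted iff
the 5-point-smoothed curve has a concave-to-convex inflection (second
difference changing from ≤ 0 to > 0) inside (−60, 0) μV *and* at least half
of the peaks counted at the inflection already lie below −60 μV (plateau
evidence — a pure-noise CDF has its inflection with no preceding plateau and
is rejected). The inflection location doubles as the detection threshold.
Note the 10–100 Hz band-pass attenuates a narrow −80 μV R-deflection to
roughly −60 μV, which is why the acceptance range extends to −60 μV.

Each inter-beat interval contributes a rate of 60/IBI bpm and is assigned
phasic if its midpoint falls inside a phasic θ event, else tonic.

## Rapid eye movements

Pupil position comes from inverted, Gaussian-smoothed, binarized frames: the
largest connected component above a 20 px² area floor is the pupil and its
centroid the position (head-fixed mice sleep with open eyes, so REM tracking
is possible). Speed is the Euclidean frame-to-frame displacement on the
30 Hz camera clock (px/frame, never resampled) and acceleration its frame
difference. Rapid EMs are positive acceleration peaks above 2 SD of the
acceleration pooled over all valid REM samples of the recording — an
SD-relative criterion, so detections are invariant to rescaling the trace
(an absolute floor of 1e−9 of the position magnitude guards the degenerate
all-zero-acceleration case without breaking that invariance). Peaks must be
100 ms apart (below the burst gap, so burst structure is preserved) and may
not span blink gaps. Bursts are transitive groups of EMs with consecutive
gaps strictly below 250 ms; singletons are not bursts.

## Transition probabilities and the bootstrap

Hypnograms are downsampled to 10 s epochs by majority vote over the four
2.5 s sub-epochs, ties broken R > N > W so that the rare state the analysis
targets survives. Trials are aligned at laser onset; the baseline is the
120 s interval preceding the onset, re-anchored at its own start.

For a pair X→Y, `P(X→Y | t ≤ d) = q/p` with p the trials in X at t = 0 and q
those that entered Y within d seconds (the cumulative probability requires
q/p; the transposed form sometimes written is treated as a typo).
"Entered Y" counts the first entry regardless of intervening states, which
makes the maintenance curve P(X→X | t ≤ d) — the fraction still in X — its
natural complement. A consequence worth noting: even though direct W→R
scoring transitions never occur, the cumulative W→R curve can be positive
through W→N→R sequences within the 120 s horizon.

The bootstrap resamples the m pooled trials with replacement (each draw
keeps a trial's baseline and laser interval together, preserving their
pairing), recomputes both curves, and takes the difference of the areas
under them, normalized so the 120 s × [0, 1] rectangle has area 1. Equal-tail
P-values are twice the smaller tail of the sampling distribution; when one
tail is empty the result is reported as P < 1/B. Draws in which no resampled
trial starts in X are redrawn (logged). P-values are not corrected for
multiple comparisons. Resampling pools trials across animals; a hierarchical
mouse-then-trial option exists but is off by default. The relative-change
graph reports AUC_laser/AUC_baseline per pair (1 = no change), omitting
never-observed pairs and pairs with zero baseline area.

### Power at desk scale

The bootstrap is calibrated: under a no-effect simulator its type-I error at
α = 0.05 sits inside the 95% binomial CI over 200 simulated datasets
(B = 2000, m = 100 trials). Its *power* to detect a doubling of the N→R
hazard at m = 100 trials is only ≈ 0.4–0.5: with the baseline REM pressure
the generator emulates (P(N→R within 120 s) ≈ 0.18), doubling the hazard
moves the normalized AUC difference by ≈ 0.10 while its sampling SD at
m = 100 is ≈ 0.06. Detecting that effect with 90% power needs roughly 400
trials — or a larger effect, which is what strong optogenetic induction
produces. The package reports the measured power honestly rather than
enlarging the effect or the trial count.

## Calcium imaging

**Motion.** Frames are spatially high-pass filtered (each frame minus a
σ = 6 px Gaussian blur of itself); integer shifts maximize the
cross-correlation between each high-passed frame and a high-contrast
reference patch (default 40 px, auto-selected as the highest-variance patch
of the mean high-pass image; small patches can straddle a single elongated
structure such as a vessel and become ambiguous along it). Because the
stack-mean reference sits at the *mean* displacement, estimates are
re-anchored so the first unflagged frame defines zero shift. Shifts beyond
the configured bound flag the frame instead of moving it.

**Activity map.** `M = ⟨⟨(f − f̄)/(f̄ + f_avg)⟩_w⟩_t` with `f̄` the pixel's
temporal mean, `f_avg` the movie mean, `⟨·⟩_w` a 2×2 box filter (pixels
(i..i+1, j..j+1), edge-replicated at the bottom/right border) and `⟨·⟩_t`
the temporal mean — implemented exactly in that order and verified against
a literal three-loop reference.

**Traces.** Per ROI, `F(t)` is the pixel-mean; `F_np(t)` the mean over a
10 μm-wide ring at ~5 μm offset from the ROI perimeter, excluding every
ROI's pixels and any invalid region (off-lens margin, blood vessel) — rings
that leak into the dark off-lens margin systematically under-estimate the
neuropil and corrupt the subtraction. The session correction factor
`c = (F_bv − F_off) / (F_near − F_off)` comes from a blood vessel, a nearby
clear region and an off-lens region; `F_subt = F − c·F_np` holds exactly in
the stored traces. The baseline `B(t)` is an affine regression on the
samples of `F_subt` at or below its session-wide 20th percentile (sample-wise,
not windowed), and `ΔF/F = (F_subt − B)/B`. Geometry is parameterized by
pixel size (default 1.2 μm/px). `c` outside (0, 1.5) warns.

**Photometry.** Both channels are low-pass filtered at 2 Hz (4th-order
Butterworth, zero-phase), the isosbestic 405 nm signal is regressed onto the
465 nm signal, and ΔF/F is the residual divided by the fit — removing
bleaching and any artifact common to both channels.

**Subclasses.** Per cell, a one-way ANOVA of ΔF/F across W/N/R decides
whether the cell is state-modulated (α = 0.05); modulated cells are labelled
by their highest-mean state, REM-max cells split by NREM-vs-wake means
(R>N>W vs R>W>N). Two deliberate choices harden this against
pseudo-replication: (i) ΔF/F is averaged within each 2.5 s scored epoch
before testing — the state factor only exists on the epoch grid, and raw
20 Hz samples of a slow indicator are so autocorrelated that the per-sample
ANOVA false-modulates ~15% of null cells; (ii) the Tukey HSD comparison
between the top state and the runner-up must also be significant
(`require_posthoc=False` disables this and labels by raw argmax). On
pure-noise ΔF/F the resulting false-modulation rate is ~1–3%. A caveat
remains: cells whose ΔF/F carries *any* systematic state-dependent residual
(e.g. imperfect neuropil subtraction) will be flagged by any consistent test
given enough samples; the calibration null is therefore defined on noise
traces, not on movie-extracted cells.

**Aligned statistics.** Transition-aligned ΔF/F is z-scored per cell over
the whole recording (the parameter-free window), aligned at transitions
whose preceding episode passes the inclusion rules (NREM/wake ≥ 60 s with
microarousals bridged; REM ≥ 10 s for REM→wake), averaged over transitions,
binned at 10 s, and tested per subclass with a repeated-measures ANOVA over
bins (Greenhouse–Geisser corrected when sphericity fails) followed by
Holm-corrected paired t-tests of each bin against the −60…−50 s baseline
bin. The time-normalized NREM→REM→wake variant divides each episode into 10
bins (configurable) and splits sequences at a 30 s REM duration. Phasic
contrasts compare each event with the immediately preceding tonic interval
of exactly equal duration (events with no room are skipped) via per-subclass
paired t-tests. Cross-correlations between ΔF/F and a band power use NREM
bouts ≥ 120 s (microarousals bridged), 2.5 s windows stepped by 0.5 s, each
spectrogram row normalized by its recording mean; the correlation is
normalized by sd(s)·sd(d)·n and the per-cell max-|peak| within ±30 s is
tested against zero. Sign convention: positive lag ⇔ ΔF/F leads the power.

## Synthetic data

The generator produces every input with a ground-truth ledger. All stages
draw from per-stage RNGs derived from the master seed, so identical seed and
config give bit-identical output and each stage is individually
reproducible.

*Hypnogram*: semi-Markov chain on the 2.5 s grid; bout durations are
exponential with a floor (per-epoch hazard after the floor), embedded
transition matrix with W→R forbidden. Defaults (light-phase mouse):
mean/min durations W 90/10 s, N 150/30 s, R 75/20 s; N→R probability 0.35;
R exits only to W. These give ~10% REM time and an inter-REM interval of
~10 min. A laser train can multiply the N→R hazard during stimulation
(gain 1 = null simulator).

*EEG/EMG* (1 kHz, μV): NREM = 1.5–4 Hz band-limited noise (60 μV RMS) plus
0.5 s spindle bursts (10–15 Hz) plus broadband; REM = phase-continuous
frequency-modulated θ sinusoid, 7.5 Hz/60 μV tonic stepping to 9 Hz/×1.5
amplitude inside phasic intervals (Poisson, 3/min of REM, fixed 1.5 s
duration — comfortably above the 900 ms gate); wake = pink broadband.
EMG = white noise at state RMS (W 80, N 35, R 10 μV — chosen so the state
separation survives the ECG artifact's contribution to the 5–100 Hz
amplitude) plus a biphasic ECG template with −80 μV negative peaks at
600 bpm tonic / 660 bpm during phasic events.

*Pupil* (30 Hz): piecewise-constant gaze with 15 px steps at Poisson saccade
times during REM (3/min) on top of a slow two-component sinusoidal drift
(0.8/0.4 px at 0.25/0.6 Hz). The drift is deliberately *bounded*: its
acceleration never exceeds 2 SD of itself, so the detector's false-positive
floor is structural, mirroring the smoothness of real tracking jitter
rather than white measurement noise. An optional renderer draws the dark
pupil disk on a bright field for the contour detector.

*Miniscope* (64×64 px, 20 Hz): cells are Gaussian footprints (σ 2.5 px) on
a shuffled in-lens grid; per-cell AR(1) transients (τ = 1 s) driven by
state-dependent Poisson rates per subclass (R>N>W, R>W>N, Wake-max,
NREM-max at 0.45 Hz in their preferred state vs 0.02–0.12 elsewhere; one
subclass's rate is ×4 inside phasic events); "unmodulated" cells are
state-independent noise cells (no transients). Pixel model:
`dark + T(x,y)·texture(x,y)·np(t) + Σ footprint·(F0 + transient) + noise`,
where the transmissivity map `T` is 1 in clear tissue, `neuropil_gain`
(0.7) under cell bodies and the blood-vessel stripe, and 0 off-lens — so
the blood-vessel calibration ratio recovers the gain by construction, and
the neuropil cancels exactly in `F − c·F_np`. The static smooth texture
(out-of-focus structure) gives the motion estimator unambiguous 2-D
contrast, as real tissue does; without it a lone straight vessel makes
shifts along its axis degenerate. Cells have resting brightness F0 = 30 so
the ΔF/F denominator is well separated from zero. Motion is a ±1-step
random walk clipped at ±2 px, applied by integer roll.

*Photometry* (100 Hz): 465 = shared exponential bleach + population
transient + artifact + noise; 405 = same bleach shape + the shared artifact
only.

### What the synthetic validation shows — and does not

Passing the recovery battery shows the *algorithms* are implemented
correctly and recover known ground truth under stylized but
parametrically realistic signals. It does not certify performance on real
data: real EEG spectra are broadband and nonstationary, real EMG contains
movement artifacts that mimic R-waves, real pupil video has specular
highlights and eyelid occlusion, and real miniscope movies have overlapping
neurons, dendritic crosstalk and non-rigid motion. Thresholds that are
self-calibrating (percentile gates, SD-relative criteria, the inflection
rule) transfer; fixed constants (the −3 rad trough criterion, the 900 ms
gate, band edges) are the field's published conventions and are not tuned
here.

## Validation battery sizes

Signal-level studies run on 1.5–4 h synthetic sessions; the bootstrap
calibration uses 200 datasets of 100 trials at B = 2000 and the power study
50 datasets; the imaging study uses one 64×64×6000-frame movie on a
designed repeating N(60 s)/R(30 s)/W(30 s) schedule (so every state is well
sampled regardless of seed) plus 200 noise cells for specificity. The whole
battery completes in a few minutes on one CPU.
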