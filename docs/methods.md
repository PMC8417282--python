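# Methods

This note documents the models and procedures behind `thetadyn`, the
assumptions they make, and the design decisions that were genuinely open.

## Problem setting

The package analyzes local field potentials (LFPs) recorded simultaneously
from hippocampal CA1 and the anterior cingulate cortex (ACC) of rats
performing a delayed spatial alternation task on a T-maze.  A session is a
continuous 16-lead recording (4 leads per area per hemisphere, 1 kHz) with
an animal position trace and a trial event log.  Trials are separated by a
delay in a sequester box, drawn uniformly from 5-45 s, and split into
*short* (< 20 s) and *long* (>= 20 s) categories.  The 20 s boundary itself
is assigned to *long* so the two categories partition the delay range; the
half-open convention `[start, end)` is used for all time intervals, and
event times are seconds from session start.

Two cohorts are compared: chronically hyperglycemic animals (the "STZ"
group, after the streptozotocin protocol that induces the phenotype) and
vehicle controls.  The pipeline quantifies four families of effects:

1. **Spectral state.**  Per-lead spectrograms (1000 ms Hamming windows,
   200 ms overlap, mean removal per window, one-sided PSD) give 1 Hz
   frequency resolution and one frame per 800 ms.  Session PSDs are frame
   means normalized to unit sum over a stated range: 1-100 Hz for spectral
   summaries, 1-50 Hz for decoding features (both exposed; the narrower
   decoding range avoids any influence of residual 60 Hz line noise).
   Band powers are means over inclusive frequency bins: delta 1-4 Hz,
   theta 6-13 Hz, and configurable gamma bands defaulting to slow gamma
   25-55 Hz and fast gamma 65-100 Hz — conventional rodent CA1 choices
   that exclude the 60 Hz line.  The session theta/delta (TD) ratio is the
   ratio of session-mean band powers, not the mean of per-frame ratios;
   the per-frame series is kept for peri-event analyses.  Line noise is
   removed by a zero-phase 4th-order Butterworth band-stop at 58-62 Hz
   (attenuation at 60 +- 0.5 Hz far exceeds 20 dB; passband ripple below
   0.01 dB at 50 Hz).

2. **Phase-amplitude coupling.**  The modulation index (MI) bins the
   instantaneous phase of a slow band (zero-phase FIR band-pass + Hilbert
   transform) into 18 equal bins, averages the fast band's Hilbert
   envelope per bin, normalizes to a distribution P, and reports
   (ln 18 − H(P)) / ln 18.  MI is 0 for phase-independent amplitude and 1
   when all amplitude mass falls in one bin; the 18-bin convention follows
   the standard entropy-based MI estimator.  FIR length is 3 cycles of the
   band's low edge, but never shorter than 6 / (band width) seconds — the
   second bound matters for gamma bands, where a 3-cycle filter would have
   a transition band wider than the band itself and smear modulation
   sidebands into neighboring comodulogram cells.  Comodulograms default
   to phase centers 2-12 Hz (2 Hz bands) and amplitude centers 20-100 Hz
   (20 Hz bands); the amplitude bandwidth must exceed twice the fastest
   phase frequency for the AM sidebands to pass.  MI is computed over the
   entire session and averaged over an area's leads to one value per
   session per area.

3. **Inter-area coherence.**  Magnitude-squared coherence
   C_xy(f) = |P_xy(f)|² / (P_xx(f) P_yy(f)) from Welch-averaged spectra
   (1000 ms Hamming segments, 50% overlap), restricted to ipsilateral
   ACC x HPC lead pairs.  Per-trial theta coherence is C_xy averaged over
   6-13 Hz on the window spanning the last 10 s of the delay plus the
   first 2 s of the trial run — a contiguous 12 s giving ~23 segments —
   then averaged over all ipsilateral pairs.  Trials with delays shorter
   than 10 s use the full available delay and are flagged.  The
   concatenated-window estimate was chosen over averaging sub-window
   estimates because it keeps the estimator's bias (≈ 1/n_segments)
   uniform across trials.  A session's *difference score* is mean
   error-trial theta coherence over mean correct-trial theta coherence;
   the delay-split variant requires at least 3 trials in each
   (outcome x delay) cell and reports excluded sessions.  Peri-event
   cohereograms pool 1 s segments across trials at each 500 ms step and
   form the coherence from ensemble-summed cross and auto spectra — a
   per-trial Welch estimate inside a 1 s step would be degenerate (one
   segment, C ≡ 1).

4. **Spectral-phenotype decoding.**  Each lead's normalized 1-50 Hz PSD is
   one feature vector; classes are (area x group).  A linear SVM (C = 1,
   one-vs-one multi-class ensemble) is trained on a balanced random draw
   per class and classifies all held-out leads; train/held-out
   disjointness is asserted on every iteration.  The training-size sweep
   uses sizes 5, 15, ..., 85; the label-permutation null establishes the
   empirical chance level (25% for four balanced classes) and the error
   breakdown (wrong group / wrong area / both).  Posterior probabilities
   come from Platt-style sigmoid calibration fitted on the training set by
   3-fold internal cross-validation — a stated convention, since a
   max-margin classifier has no native posterior.  Leave-one-subject-out
   and leave-one-session-out designs draw 40 training leads per class from
   the remaining units; the default repeat count is 100 per held-out unit
   and is configurable.

5. **Group statistics.**  Kruskal-Wallis H (midranks, tie correction,
   chi-square reference with k−1 df) and classical equal-variance one-way
   ANOVA F are implemented from sums of squares / rank sums directly so
   they can be validated against independent oracles.  Running F-series
   compare event-aligned trial ensembles (e.g., TD ratio around trial
   start) at 500 ms steps with a Bonferroni threshold of alpha / n_steps.
   Because the session spectrogram hop is 800 ms, peri-event band power
   uses its own dedicated estimator (1000 ms windows advancing in 500 ms
   steps) so both printed resolutions are honored in their own contexts.
   Speed-power correlations pair each lead's per-frame band power with
   running speed linearly interpolated onto frame times.

## Synthetic sessions

The generator exists so every stage can be verified against planted
ground truth.  A lead's trace is

    x(t) = noise_amp * pink(t)
         + a_d(t) cos(phi_d(t))
         + a_t(t) * theta_wave(t) * [1 + kappa_dt cos(phi_d(t))]
         + sum_g A_g [1 + kappa_g cos(phi_carrier(t))] cos(phi_g(t))

with `a_t(t) = theta_amp (1 + beta_t v(t))` and
`a_d(t) = delta_amp max(0, 1 + beta_d v(t))`, where v is running speed
normalized to [0, 1].  Oscillator phases integrate a jittered
instantaneous frequency (Gaussian jitter low-pass filtered to a 0.1 s
correlation time); the 1/f background is spectrally shaped white noise.

**Frequency jitter.**  The jitter SD defaults to 1.0 Hz for delta/theta
and gamma oscillators.  This value is load-bearing: with nearly
monochromatic oscillators (jitter ≈ 0.1 Hz) two *independent* 8 Hz
sources remain mutually phase-locked across a 12 s trial window and show
Welch theta coherence near 0.34, which would make the planted coherence
mixing weight unobservable.  At 1.0 Hz jitter the independent-pair
baseline drops to ≈ 0.06, so measured coherence tracks the planted
mixing, and the theta band acquires a realistic ~2 Hz width.

**Inter-area coherence.**  All leads of a hemisphere mix a shared theta
phase with a private one: `theta_wave = Re[lambda e^{i phi_shared} +
(1-lambda) e^{i phi_private}]`; the PAC carrier phase is the argument of
the same mixture.  On error trials, lambda is shifted by
`coherence_outcome_shift` (times `coherence_long_delay_mult` on long
delays) during the trial's analysis window, then clipped to [0, 1].  The
control preset lowers lambda on errors (difference scores < 1); the STZ
preset raises it with a 1.5x long-delay multiplier (scores > 1) —
matching the direction, not the magnitude, of the phenomenon the pipeline
measures.

**Behavior.**  Delays are i.i.d. uniform on [5, 45] s; outcomes are
Bernoulli with P(correct | group, delay category) — presets 0.90/0.85
(control short/long) and 0.85/0.60 (STZ), so only the long-delay cell
separates the groups.  Positions are sampled at 25 Hz on a single uniform
grid; the animal sits at the sequester box during delays and traverses
the maze circuit (a polyline built from the 63.5 cm stem and 74 cm arm
dimensions, ≈ 3 m per lap) at a position-dependent speed peaking
mid-stem (40 cm/s default, group-independent by construction).  Position
samples are exactly on the maze path: tracking noise is not modeled.

**Randomness.**  Every stream derives from the master seed through a
named `SeedSequence` per (group, subject, session, lead), so cohorts are
bit-reproducible and adding sessions or leads never perturbs existing
ones.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: volume conduction and shared reference
artifacts, non-stationary oscillator amplitudes beyond speed coupling,
sharp-wave ripples, movement and chewing artifacts, electrode drift
across sessions, within-group animal heterogeneity (all subjects of a
group share one phenotype), and any spike activity.  Recovery results
demonstrate estimator correctness on the assumed generative structure,
not robustness to real-data nuisances.

## Default preset magnitudes

Amplitudes are arbitrary units on a common scale with the ~unit-variance
1/f background (noise_amp 0.5).  The hippocampal presets plant a strong
TD-ratio gap (control theta/delta amplitude 1.0/0.35; STZ 0.55/0.85),
elevated STZ PAC (theta->slow-gamma kappa 0.45 vs 0.15), weaker STZ
delta-speed coupling (beta_d −0.25 vs −0.8), and higher STZ baseline
theta mixing (lambda 0.60 vs 0.45).  ACC presets are intermediate with a
steeper 1/f exponent (1.3 vs 1.0) so area separates spectrally as well as
group.  Gamma amplitudes (0.3 slow, 0.25 fast) keep the gamma-band SNR
near unity so planted modulation is visible above the envelope noise
floor.  All numbers are package defaults chosen once to represent clearly
detectable effects of the kinds the pipeline measures; they are not fits
to any animal.

## Problem sizes

Tests and the acceptance script run on deliberately small cohorts chosen
as the smallest sizes at which every planted effect is reliably
recovered: 6 sessions (3 subjects per group, 1 session each, 20 trials)
for recovery checks, 120 leads per class of synthetic spectra for the
decoding protocol, and 150-200 s signals for coupling estimates.  The
full paper-scale defaults (3 + 5 subjects, 4 sessions each, 30 trials)
remain the `presets.yaml` cohort defaults for library use.

## Numerical choices and degenerate inputs

- Zero-phase filtering: Butterworth band-stop via forward-backward
  second-order sections; FIR band-pass via FFT convolution of symmetric
  taps (exactly zero phase, group delay compensated by `mode="same"`).
- MI uses natural logs with 0·log 0 ≡ 0; all-zero amplitude raises.
- Coherence estimates are clipped to [0, 1]; a single Welch segment is
  rejected rather than returning the degenerate C ≡ 1.
- TD ratios require strictly positive delta power; zero-variance series
  raise in correlations rather than returning NaN.
- Sessions round-trip bit-exactly: signals as little-endian float32 with
  a JSON sidecar, tables as CSV with `%.17g` floats parsed back in
  round-trip mode.
- Ties in `delay_category` at exactly 20 s go to *long* (see above).

## Known limitations

- Posterior calibration needs at least 3 training leads per class; the
  sweep silently reports no posteriors below that size.
- The ~23-segment per-trial coherence estimator has an upward bias of
  roughly 1/23 ≈ 0.04; difference scores are ratios of equally biased
  quantities, which cancels only approximately when trial counts differ.
- Maze linearization assumes the supplied polyline is a fair model of the
  animal's path; samples beyond the distance tolerance are excluded, not
  projected.
- The Kruskal-Wallis p-value uses the chi-square approximation, which is
  crude below ~5 observations per group (the exact-permutation oracle in
  the test suite quantifies the gap at n = 3 + 3).
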