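# Methods

## The experiment being modeled

A session presents 30 n-back trials (10 each of n = 1, 2, 3 in
pseudo-random order). A trial shows 22 letters, one every 2 s (500 ms on
screen), so a trial lasts 44 s; the participant presses a key whenever the
current letter equals the one n positions back (a *target*). Sequences are
generated so that every trial contains 3 ± 1 targets: the target count is
drawn uniformly from {2, 3, 4} and letter streams (uppercase consonants)
are rejection-sampled until a brute-force rescan yields exactly that count.
Chained targets (e.g. three identical letters under 1-back) are allowed —
nothing in the paradigm forbids them. Each trial is preceded by 5 s of
instruction and followed by 15 s of rest; after half of the trials
(15, chosen pseudo-randomly per session) an extra 10 s of resting cross is
appended and kept as a dedicated *relax* trial, so that the rest-state
class comes from genuinely task-free periods rather than from post-trial
recovery. A 150 s break follows trial 15. Total: 30 × 64 s + 15 × 10 s +
150 s = 2220 s = 37 min.

Sample indexing is 0-based with half-open windows; an onset t maps to
index `round(t × fs)` at fs = 25 Hz, which is exact for the protocol's
integral-second timings.

## Signal model of the simulator

The recording is 8 channels × {HbO, HbR} at 25 Hz, in arbitrary
concentration-change units (only relative amplitudes matter, as in any
fNIRS system that reports changes from an unknown baseline).

**Hemodynamics.** Each task trial contributes a neural drive that ramps
linearly from 0 at trial onset to the condition amplitude at
`onset_ramp_s` (default 44 s, i.e. the drive grows over the whole trial).
The ramp models workload building up while the memory buffer fills and
while sustained effort accumulates; it is what makes windows taken directly
at trial onset carry little signal and later windows carry a steady
positive HbO slope. With `onset_ramp_s = 0` the drive is a pure boxcar.
The drive is convolved with a canonical hemodynamic response function — a
difference of two gamma densities with the positive lobe peaking at 6 s,
an undershoot peaking at 16 s, and undershoot-to-lobe area ratio 1/6 —
normalized so that a long unit boxcar plateaus at amplitude 1. Default HbO
amplitudes are 0.2 / 0.5 / 1.0 for 1-/2-/3-back (configuration, not
constants): activity is clearly visible mainly at the highest load, and the
1↔2 contrast is smaller than the 2↔3 contrast, mirroring the behavioral
difficulty profile. HbR is −0.3 × the HbO response plus its own noise; the
two chromophores are strongly anticorrelated in real recordings but the
coupling coefficient is not identifiable from published group curves, so
−0.3 is a conventional round value. The response is added to a
configurable subset of channels (default 6 of 8) with per-subject channel
gains drawn once from U(0.8, 1.2), so channels differ and feature
selection has a real ranking problem.

**Noise.** Sinusoids at 1.1 Hz (heart beat, amplitude 0.4), 0.25 Hz
(respiration, 0.2) and 0.1 Hz (Mayer waves, 0.3) with random phase per
channel and chromophore; a linear drift with slope drawn from
U(−5·10⁻⁴, 5·10⁻⁴) per second; white Gaussian sensor noise with σ = 0.05.
Amplitudes are on the same arbitrary scale as the responses and are set so
that raw traces are oscillation-dominated (as real fNIRS is) while the
preprocessed slope features remain informative.

**Motion artifacts.** Spike transients (exponential decay, τ = 0.5 s,
amplitude 2.0 ± 50%, ~1/min) and baseline steps (amplitude 1.0 ± 50%,
~0.2/min) at Poisson times shared across channels (the optode holder moves
as a whole) with per-channel coupling factors in U(0.5, 1.5).

**Behavior.** Each target is missed with probability 0.057 / 0.167 / 0.337
for 1-/2-/3-back; each non-target draws a false alarm with per-letter
probability 0.0074 / 0.010 / 0.0237 (group mean wrong-reaction counts of
roughly 1.4 / 1.9 / 4.5 per condition spread over ~190 non-target letters).

**What the generator does not emulate.** Spatial structure beyond
per-channel gains (no cortical geometry, no photon transport or
Beer-Lambert inversion — the simulator emits concentration changes
directly), pulse-wave morphology (the heart beat is a pure tone),
non-stationary vigilance or habituation effects, inter-subject variability
beyond the seed, and any coupling between behavioral errors and the
hemodynamics. Passing tests therefore show that the analysis chain
recovers the structure this model puts in — monotone condition amplitudes,
late-trial information, noise at known frequencies — not that it would
reach any particular accuracy on human recordings.

## Preprocessing

Stages run per channel and chromophore on the continuous session, in fixed
order, before trial segmentation (trials are cut afterwards from the
cleaned record):

1. **Moving-average detrend.** Subtract from each sample the mean of the
   ±120 s surrounding it (window truncated at the edges). Implemented with
   a cumulative sum (O(N)); the unit tests compare it against the O(N·W)
   direct computation. This removes drift and most Mayer-wave-scale trend
   (pass band above ≈ 1/240 Hz is progressively retained).
2. **Zero-phase elliptic low-pass**, cutoff 0.5 Hz, order 6, 0.5 dB
   passband ripple, 40 dB stopband attenuation, applied forward-backward
   (`sosfiltfilt`): analysis is offline, so the phase distortion of a
   single pass is unnecessary; the squared magnitude response gives
   ≈ 5·10⁻⁵ power gain at the 1.1 Hz heart band. Ripple/attenuation are
   conventional values; the design order refers to the designed filter,
   applied twice.
3. **Wavelet motion-artifact removal.** Daubechies-5 decomposition, 5
   levels, `periodization` extension (orthonormal and length-preserving,
   so zeroing coefficients can only decrease signal energy — Parseval).
   Within each detail level the scale is estimated robustly as
   1.4826 × MAD (so artifacts do not inflate it) and any coefficient whose
   two-sided Gaussian tail probability falls below α = 0.1 is zeroed; the
   approximation level is untouched, so slow hemodynamics survive.
   α → 0 is the identity.

## Features, selection, classification

Features are OLS slopes of each channel's HbO and HbR trace within the
analysis window (16 per window), in concentration units per second. Slopes
are invariant to window offsets (baseline level), which is why trials need
no baseline normalization before classification.

Mutual information between each feature and the labels is estimated from
Gaussian Parzen densities: per-class bandwidth by Silverman's rule
(0.9 · min(σ, IQR/1.34) · n^(−1/5), with a small floor when a class is
degenerate), the marginal as the prior-weighted mixture of the class
densities, entropies integrated by the trapezoid rule on a 512-point grid
spanning the data range ± 3 bandwidths. MI is kept in nats — the unit is
immaterial because only the ranking is used — clipped to
[0, H(labels)] against integration noise, and zero-variance features score
0 instead of erroring so that pathological folds stay total. The top 8 of
16 features are kept; ties break toward the lower feature index for
determinism. Selection sees training rows only; the cross-validation
harness passes it the training indices and a poisoning test verifies that
corrupting held-out rows cannot change the fitted fold model.

The classifier is LDA with pooled within-class covariance plus a ridge of
10⁻⁶ × trace(Σ)/d (absolute floor 10⁻¹²): with 8 features and folds that
can have ~9 training trials per class, the pooled covariance is close to
singular, and in the noise-free limit it is exactly singular. Multiclass
problems train one model per unordered class pair and predict by majority
vote; vote ties fall back to the summed signed discriminant margins, then
to the lowest class label — deterministic and exhaustively checked against
an independent re-derivation of the rule in the tests.

**Blocked cross-validation.** Instances of each class are grouped by trial
(all windows of a trial stay together), trials are split in temporal order
into 10 contiguous blocks per class (sizes differing by at most one), and
fold f evaluates on block f of every class. This keeps temporally adjacent
— hence autocorrelated — windows out of opposite sides of the split and
balances classes per fold. With 10 trials per class each fold holds out
exactly one trial per class.

**Sweeps.** The offset sweep classifies 10 s task windows at a given trial
offset against the 15 dedicated relax probes (scenarios 1-, 2-, 3-back vs
relax and the 4-class problem; relax enters unbalanced, 15 vs 10, and the
chance level is reported per scenario). The window-length sweep tiles each
trial with non-overlapping windows from trial start (floor(44/L) per
trial, all inheriting the trial label) and runs the three pairwise
scenarios plus the 3-class problem. Grand averages baseline each trial by
the mean of the 10 s before its onset and average within condition;
trials without a full pre-trial baseline (the session's first trial) are
skipped with a warning.

## Problem sizes and determinism

All stochastic end-to-end checks (null calibration with equal amplitudes;
recovery of the amplitude ordering and of the offset effect) use 20
simulated subjects of one full 37 min session each — enough for the
orderings to be stable while a complete run of the acceptance script stays
around a minute. Every random draw descends from a single integer seed:
the simulator from its config seed, session timelines from their own seed,
and the acceptance script derives all of these from its `--seed` argument,
so reruns are bit-identical.

## Known limitations

- The simulator's noise is stationary and sinusoidal; real physiological
  noise is broadband and amplitude-modulated, so absolute accuracies here
  do not transfer to human data.
- Default accuracies are higher than one should expect from real
  recordings; the amplitude/noise defaults were chosen for a clearly
  structured test bed, and all of them are configuration.
- The moving-average detrend needs ±120 s of context and is inherently
  offline; an online system would need a causal replacement.
- MI is estimated per feature (univariate); jointly informative feature
  sets are not modeled, matching the method being implemented rather than
  improving on it.
- The CSV reader accepts a column map for externally named corpora but has
  only been exercised against files this package writes.
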