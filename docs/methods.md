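# Methods

This note records the models, conventions, and design choices behind
srmkit, in the order a session flows: levels and stimuli, the corpus,
spatial rendering, the adaptive procedures, the simulated listeners, and
the statistics.

## Digital levels

A software-only battery has no sound-level meter, so physical level is a
declared convention: `LevelConvention` assigns a dB SPL value to a signal
of digital rms 1.0 (default 100 dB SPL). All task levels (65 dB SPL
speech targets, 75 dB SPL FM carriers, 80 dB peSPL clicks) are realized
relative to that reference, and a +20 dB request multiplies rms by exactly
10. Peak-equivalent SPL follows the standard audiological definition: the
click's peak amplitude equals the peak of a sinusoid whose rms sits at the
stated level.

## Stimuli

**Tones and FM.** The FM depth parameter is the total peak-to-peak
frequency excursion: instantaneous frequency is
`carrier + (depth/2)·sin(2π·rate·t + φ₀)`, so a 500 Hz carrier with 6 Hz
depth sweeps 497–503 Hz. Phase is the closed-form integral of that
expression, not a numerical cumulative sum. In the dichotic variant the
right-ear modulator is sign-inverted, so the two ears' frequency
deviations cancel sample by sample. Carriers are re-drawn uniformly from
460–550 Hz per interval, not per trial.

**Ripple noise.** TM/SM/STM stimuli are dense log-spaced random-phase tone
complexes (40 components per octave across 0.4–8 kHz, ≥100 total). Each
component's gain in dB follows
`M·sin(2π·Ω·log₂(f/f_lo) + 2π·w·t + φ)` with spectral density Ω
(cycles/octave), temporal rate w (Hz), and a ripple phase φ randomized per
stimulus; depth M is mid-to-peak on the dB scale. With the sign convention
above a joint spectrotemporal modulation drifts in one fixed direction;
the direction is a documented default, not a claim about any particular
hardware implementation. Depth 0 reduces to statistically flat noise.
Depth-recovery QC: `fit_tm_depth` (sinusoid fit to the dB Hilbert
envelope) recovers M within ±0.5 dB for 1–10 dB depths; `fit_sm_depth`
integrates the Welch spectrum into 1/12-octave bands and divides out the
analytic sinc attenuation of band averaging.

**Clicks and gaps.** The gap markers are truncated-Gaussian envelopes in a
4 ms window. The Gaussian σ is solved numerically so the *truncated*
envelope's equivalent rectangular duration — ∫e²dt / max e² — is exactly
2.0 ms (σ ≈ 1.142 ms; the untruncated closed form σ√π would give σ ≈
1.128 ms). The gap is the silence between the two truncation windows
(offset-to-onset), which makes gap 0 well defined: two abutting windows.
`measure_erd` uses the rectified waveform as the envelope by default
because the clicks are monophasic low-pass pulses, for which the
analytic-signal magnitude is biased; an `analytic` mode exists for
carrier-borne stimuli.

**Instantaneous-frequency measurement.** The FFT-based analytic signal
assumes periodicity, so FM verification synthesizes a buffer spanning
whole modulator cycles (1 s at 2 Hz) and trims 2 % edges; inside that
window the numerical phase derivative matches the closed form to well
under 0.1 Hz. At the 400 ms task duration the same measurement shows
edge leakage of a few Hz — a property of the measurement, not the
stimulus.

## Corpus

Synthetic word tokens are schematic signals, not speech: harmonic
complexes on a talker-specific fundamental (105 + 14·talker Hz) with
word-specific spectral peaks and a slow pitch contour, gated by a
raised-cosine window. Their contract is the factorial structure (8 × 4 ×
8 per talker), a fixed slot grid (0.1 s pads, six equal 0.3 s slots,
exactly 2.0 s total), rms 0.1 after post-processing, and mutual
distinguishability (pairwise normalized cross-correlation peaks < 0.9).
Passing tests therefore demonstrate the *machinery* — selection rules,
leveling, spatialization, scoring — and say nothing about speech
intelligibility, prosody, or informational masking with real talkers,
which require recorded corpora dropped in through the manifest schema.
Post-processing (band-pass then rms normalization) is idempotent to within
1e-6 rms and < 0.1 dB in-band. An English word pack ships alongside the
Spanish default. Per-slot durations of recorded corpora are not
reproduced; only the total duration and pads are contractual.

## Spatial rendering

The fixture HRIR is a spherical-head sketch: a windowed-sinc fractional
delay per ear implementing the Woodworth ITD `(a/c)(θ + sin θ)` (a =
0.0875 m, c = 343 m/s; 0.38 ms at 45°), split evenly between leading and
lagging ear, plus a broadband interaural level difference of 6·sin θ dB.
It is deliberately schematic — no pinna cues, no spectral ILD — and is
labeled as such; measured HRIRs load from `hrir_<azimuth>.wav`. Sources
are leveled in mono *before* convolution, and the full convolution is
trimmed to the input length starting at the 0° kernel's group delay, so
scenes rendered at different azimuths stay sample-aligned and mixing is
exactly linear.

## Adaptive procedures

**Two-stage staircase.** 2-down/1-up with ascending steps 1.5× descending,
measured in the adapted domain: multiplicative factors for gap and FM
depth (stage 1: 2^(1/2), stage 2: 2^(1/10)), additive dB for modulation
depth (0.5 then 0.1 dB). The asymmetry targets the equilibrium
p²·Δdown = (1−p²)·Δup, i.e. p = √(ratio/(1+ratio)) ≈ 77.5 % correct at
ratio 1.5. Stage 1 ends at the third reversal; the movement that produces
that reversal already uses stage-2 steps (the procedure text leaves this
open; this is the documented choice). The track finishes at the ninth
reversal and the threshold is the geometric mean of the last six reversal
values. Reversals record the pre-step value. Values clip at task bounds
(gap ≥ one sample, FM depth ≤ 400 Hz, modulation depth in [0.01, 40] dB);
a clipped move still counts for direction bookkeeping. A configurable
hard cap (default 200 trials) guards non-converging responders and is
flagged on the state when hit.

**Convergence in simulation.** The converged percent correct of a
finite-step staircase depends mildly on the listener's psychometric slope
relative to the step sizes: steep observers quantize. The package's
reference simulated listener uses a logistic with spread 0.5 on the log
axis — a width of a few staircase steps, representative of psychophysical
slopes the procedure was designed around — under which 500 simulated
tracks sit at the 77.5 % point within the stated ±2.5 points. Much
steeper synthetic observers (spread ≲ 0.2) converge 2–5 points lower;
that bias is a property of fixed-step staircases generally, not of this
implementation.

**Progressive track.** The schedule is fixed: masker level 57, 57, 59,
59, …, 75, 75 dB SPL against a 65 dB SPL target — ten TMR values from +8
to −10 dB, two trials each, 20 trials. Threshold = errors − 10 dB. On
this schedule a deterministic threshold-rule observer with any *even*
threshold in {−10, …, +8} is recovered exactly; odd thresholds cannot be,
because each level is visited twice and error counts are therefore even —
the heuristic's resolution is the 2 dB grid. The boundary cases are 0
errors → −10 dB and 20 errors → +10 dB.

**Masker selection.** The target callsign is fixed ("Carlos"); target
color, number, and talker are uniform draws. The two maskers are drawn
without repetition so the three sentences share no callsign, color,
number, or talker. Every random draw descends from one explicit seed per
trial, so a session is bit-reproducible from (config, participant,
session, seed).

## Simulated listeners

Observers act on trial *parameters* (gap ms, depth, TMR dB), not rendered
audio: they test the procedures, not the ear. The logistic observer has a
midpoint and spread on the adapted axis (log for gap/FM), guess rate 0.5
for four-interval trials and 1/32 for the response grid, and a lapse rate;
an incorrect grid draw picks uniformly among the 31 wrong cells. The step
observer is deterministic (correct iff at-or-easier-than threshold) and
serves as the enumeration oracle. Cohorts draw one midpoint offset per
participant (between-subject SD) plus an independent per-session
perturbation (within-subject SD); with deterministic observers and no
within-session noise, test–retest r is exactly 1, and with the logistic
observers the realized r matches the variance-ratio prediction
σ²_between / (σ²_between + σ²_within + σ²_procedure), where the procedural
variance is itself estimated by simulation at fixed observer parameters.

## Statistics

Group t tests are pooled-variance Student tests computed from summary
statistics, matching the df pattern n₁+n₂−2 of the published comparisons;
Cohen's d = |Δmean| / pooled SD. The Fisher z comparison is
(atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)). Bland–Altman uses the
session-2-minus-session-1 sign convention; COR = 1.96 × sample SD of the
differences. The JZS Bayes factor integrates the standard
inverse-gamma(1/2, r²/2) mixture over effect-size variance numerically
(scale 0.707) with the effective sample size n₁n₂/(n₁+n₂); it is intended
for order-of-magnitude statements only. Holm correction delegates to
statsmodels. HHIA scoring sums 25 items at 0/2/4 points without
sub-scales.

## Problem sizes

The default verification runs use a 3-talker corpus (768 sentences, the
minimum for the no-repetition rule), 500 staircase tracks for the
convergence estimate, 60 paired progressive tracks for SRM recovery, and
cohorts of 100–300 simulated participants for the reliability statistics —
sizes at which the Monte Carlo error is small against each test's stated
tolerance.

## Known limitations

Synthetic tokens carry no linguistic content, so speech-specific effects
(intelligibility differences between languages, informational masking)
are out of reach. The fixture HRIR has no spectral pinna cues, so any
model listener operating on rendered audio (itself out of scope) would
under-use elevation and front/back cues. The familiarization tone tasks
use level-staircase defaults that are this package's own choice. No
Bayesian adaptive procedures (QUEST-family) are provided.
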