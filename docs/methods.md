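# Methods

This note records the model behind `sleeprr`, the choices made where the
method leaves room, and what the synthetic validation does and does not
demonstrate.

## Signal model and assumptions

The observed signal is modeled as *y(t) = r(t) + n(t)*: a quasi-periodic
breathing-sound component *r* (cycle period 3–5 s in sleeping adults,
each cycle containing an inspiration burst and an expiration burst of
0.3–1 s separated by an inspiratory pause, followed by a rest phase) and
zero-mean background noise *n*. Only *y* is observed; the method never
separates the two. Breath sounds are broadband, so all detection runs on
energy envelopes rather than on spectral structure, and the recording is
decimated from the acquisition rate (nominally 44.1 kHz) to a working
rate of 4 kHz before any windowed statistic — the envelopes of interest
live on 0.1–3 s scales, so this loses nothing and makes every pass
cheap.

## Amplitude-contrast reduction

The loudness of individual breaths in a whole-night recording spans an
order of magnitude. Three amplitude-domain stages shrink that contrast;
each is an odd function of the sample value, so the waveform's sign
structure is untouched:

| stage | form | constants |
|---|---|---|
| signed entropy | H = −y·ln\|y\| (0 at y = 0) | — |
| cut/boost | \|H\| > av: a·H + sign(H)·b·av; else c·H | a = 0.4, b = 0.6, c = 1.5 |
| soft limiter | H·(1 − l + l·\|H\|^N) | l = 0.85, N = 20 |

Conventions that the printed formulas leave open, resolved here:

* The entropy transform is sign-preserving (positive samples give
  positive H). A literal reading of the usual sign-factor notation
  would require the logarithm of a negative number and would contradict
  the cut stage's separate treatment of positive and negative H.
* `av` is the mean of |H| over the processing block, and the branch
  condition compares |H| to it. The signed mean of a near-symmetric
  acoustic signal is ≈ 0, which would send essentially every sample to
  the "strong" branch and defeat the purpose of the stage.
* `av` defaults to one block spanning the whole recording
  (configurable block length for whole-night material).
* The discontinuity of the cut stage at |H| = av is kept as defined;
  no smoothing.
* |H|^N is used in the limiter so that an odd user-supplied N cannot
  flip signs; for the default even N = 20 this is identical.

With input normalized to [−1, 1] the limiter fixes 0 and ±1 in place
and attenuates mid-range magnitudes by nearly 1 − l.

## The two characteristic waveforms

**TCW** — the sliding-window variance
c(t, δ) = ∫ y² dτ − (1/W)(∫ y dτ)² over [t − δ, t + δ]. The window is
realized as the inclusive sample range [i − r, i + r], r = round(δ·fs);
integrals are Riemann sums × 1/fs, and the variance identity uses the
realized window length W = (2r+1)/fs so that a constant signal yields
exactly zero. δ defaults to half the expected breathing cycle, clipped
to [1.5, 3] s (the scale-choice heuristic `suggest_scales`); the
moment scale defaults to 0.1 s, about a tenth of a breath phase.

**CMW** — the local second moment of the TCW,
I(t, δ, l) = ∫ (τ−t)² c(τ, δ) dτ over [t − l, t + l], and its
normalized form n = I / ∫ c dτ. The normalized CMW is the second moment
of a probability density obtained from the local TCW mass: it equals
l²/3 wherever the TCW is constant *or linear*, lies in [0, l²] always,
and rises above the l²/3 baseline where the TCW has positive curvature
relative to its level — i.e. at TCW valleys. Since the rest phase
between breaths is an energy valley, normalized-CMW maxima are sharp,
amplitude-free markers of the rest phase. Both raw and normalized forms
are computed; segmentation consumes the normalized one by default.

### Numerics

* Both waveforms use prefix ("integral") sums: O(n) regardless of the
  window scales, additions and multiplications only.
* CMW window integrals use composite Simpson weights (exact for cubic
  integrands). Plain Riemann sums would bias the constant-TCW value by
  ≈ l/(3·fs); Simpson makes the constant and linear closed forms hold
  to rounding error, which the test suite asserts at 1e−9.
* Prefix sums accumulate in extended precision with a block-local index
  origin (block length 512·window) so that the cancellation in the
  τ²·c sums stays ≈ 5×10⁷ dynamic range, comfortably inside
  long-double headroom; the implementation matches brute-force
  per-window evaluation to 1e−9 relative error.
* TCW values are clamped at 0 (round-off negatives), and a normalized
  CMW window whose TCW mass falls below 1e−12 (dead silence) is
  defined as the constant-input limit l²/3.
* The first/last half-window has no defined value; trims are reflected
  in the trace's start time.

## Segmentation

Candidate markers are the strict local maxima of the normalized CMW
(plateaus contribute their midpoint). A sliding prominence filter keeps,
within a window centered on each candidate, only the largest one — ties
break toward the earlier time. The window is 2δ wide for the standalone
operation; the pipeline narrows it to 1.6δ (a candidate must beat rivals
within ±0.8δ ≈ ±0.4 cycle) so that consecutive breaths whose spacing
jitters below one nominal period are never pitted against each other.

Two readings of the final segment-point rule are implemented, because
the method description does not fix whether segment points sit at TCW
minima or CMW maxima:

* `mode="cmw_maxima"` (pipeline default): boundaries are the prominent
  normalized-CMW maxima. On synthetic data these sit in the rest phase
  robustly across scales.
* `mode="tcw_minima"`: boundaries are the prominent TCW minima, each
  retained only if a prominent CMW maximum lies within a computation
  window [t − w/2, t + w/2] (w = δ by default). This reading is fragile
  when 2δ approaches one cycle period — the TCW window then spans a
  whole cycle and its minima migrate from the rest phase to
  amplitude-transition points — so it is not the default.

**Computation-window adjustment.** The pipeline additionally computes a
short-window activity envelope: the TCW of the *unpreprocessed* signal
at δ = 0.05 s, after clipping amplitude outliers at the 98th percentile
(so a click's above-threshold footprint reflects its duration, not its
loudness). Thresholding it at 1.5× its noise floor (5th percentile)
partitions time into sound bursts and quiet runs; above-threshold
stretches shorter than 0.3 s — briefer than any genuine breath phase —
do not break a quiet run, which is what makes the segmentation immune
to mouth clicks and movement artifacts. The quiet runs then adjust the
candidates:

* runs at least 6 s long are breathing pauses: candidates inside are
  artifacts of the value-blind prominence filter and are dropped, and
  one boundary is placed at the pause onset plus half a typical rest,
  the same mid-rest convention an ordinary boundary follows (so the
  pause formula below recovers the true pause duration);
* ordinary rest-sized runs attract the candidates they contain (plus
  any within 0.5 s of their edges) to the run center, collapsing
  duplicates; the typical rest length is the median length of the runs
  occupied by prominent maxima, and runs shorter than 0.65× that are
  classified as intra-cycle inspiratory pauses, never boundaries;
* candidates inside sound bursts are dropped — a cycle boundary cannot
  lie inside a breath sound.

With the adjustment enabled, boundary placement is driven by the
(amplitude-threshold-free) quiet-run geometry wherever silence contrast
exists, with the CMW maxima selecting and scoring the runs; with it
disabled (`activity_half_s=None`), placement falls back to the pure
two-waveform extrema logic. Boundaries closer than 1.5 s (the shortest
plausible cycle spacing) are merged, keeping the stronger candidate.
Everything is deterministic.

RR is the count of segment points per tumbling half-open minute
[60k, 60(k+1)); a trailing partial minute is reported separately and
never scaled up.

## Apnea analysis

* T_RR = RR_stable − 10·RR_stable/60 (a 10 s pause costs
  10·RR_stable/60 cycles per minute); minutes with RR strictly below
  T_RR are flagged.
* pause(i) = max(0, dd(i) − 60/RR_stable) for each inter-boundary
  interval; the clamp makes the formula total (a short cycle is not a
  negative pause).
* pause ≥ 10 s → apnea; 5 s ≤ pause < 10 s → hypopnea (the lower edge
  is configurable; clinical definitions of hypopnea need airflow or
  desaturation data this tool does not have).
* AHI = apnea events per monitored hour (a flag includes hypopneas);
  severity bands <5 normal, [5, 15) mild, [15, 30) moderate, ≥30
  severe — the open band edges are assigned upward.
* RR_stable defaults to 60/median(dd) in the pipeline: the median
  inter-breath interval is finer-grained than integer per-minute counts
  (whose quantization biases pause estimates by ~0.5 s) and is robust
  to the long intervals contributed by pauses. The per-minute median
  estimator (`estimate_rr_stable`, zero minutes excluded) and a user
  override are also provided.

## Synthetic data generator

`generate_breathing` emulates the statistical structure the method
assumes, with defaults chosen as the study conditions:

| parameter | default | rationale |
|---|---|---|
| cycle period | 4 s (3–5 s range) | sleeping-adult breathing |
| inspiration / expiration burst | 0.8 s each | middle of the 0.3–1 s phase range |
| inspiratory pause | 0.4 s | keeps the burst complex at half the cycle |
| period jitter | ±5% uniform per cycle | breathing is quasi-periodic, not strictly periodic |
| amplitude jitter | 10:1 log-uniform per cycle | the weak-cycles-between-heavy-cycles pattern |
| expiration gain | 0.6× inspiration | expiration is audibly weaker at a nose microphone |
| SNR | 10 dB | reference-burst power over background-noise power |
| sample rate | 4 kHz | the working rate |

Bursts are 200–1500 Hz band-limited white noise under a raised-cosine
envelope; true boundaries are recorded at each rest-phase midpoint.
When a cycle would start inside a scheduled apnea gap, the cycle clock
jumps forward by exactly the gap duration, so the effective pause
equals the scheduled one up to period jitter (removing partially
overlapping cycles instead would stretch a 31 s scheduled pause to
~35 s and make pause-recovery checks meaningless). Everything is
reproducible from the seed.

The generator does **not** emulate: snoring, body-movement noise other
than brief clicks, room reverberation, non-stationary noise floors,
gradual RR drift, or the spectral structure of real airflow sounds.
Passing the synthetic checks therefore demonstrates the pipeline's
envelope logic and bookkeeping, not clinical performance.

**Scoring.** Detected boundaries are matched to true ones greedily by
increasing time difference, one-to-one, within a tolerance (default
1 s — the manual reference this mirrors was matched by eye, so any
defensible one-to-one rule serves); success rate =
100 × matched / true count, rounded to two decimals, with unmatched
detections counted as false positives.

## Validation study and the preprocessing comparison

The acceptance suite runs a scaled-down segmentation study: 30
five-minute recordings with per-recording cycle periods drawn uniformly
from [3, 5] s (fixed seeds), 10:1 amplitude jitter, 10 dB SNR — about
2,200 cycles, sized to keep the whole suite inside a normal CI run.
The full pipeline with per-recording scale choice recovers ≈ 99% of
boundaries (the suite asserts ≥ 95%).

With the silence adjustment enabled, the with- and without-preprocessing
arms coincide exactly: boundary placement is governed by quiet-run
geometry computed from the raw signal, which the amplitude-domain
preprocessing does not touch. The benefit of contrast reduction
therefore shows where amplitude enters the decision — the value-based
prominence contest of the envelope-only detector — and most strongly
when one universal scale must serve heterogeneous recordings. The suite
measures exactly that: envelope-only detection at a universal δ = 2.0 s
(half the mean cycle) scores several points higher with preprocessing
than without (≈ 88% vs ≈ 85%), matching the direction of the original
comparison, while under per-recording matched scales the envelope-only
arms differ by a fraction of a point in the other direction
(preprocessing lifts the noise floor, slightly blurring TCW valleys).
No single configuration shows both the ≥ 95% absolute rate and a
non-vacuous preprocessing gain on this generator.

## Known limitations

* The silence adjustment presumes the rest phase is acoustically
  quieter than the bursts at the activity envelope's scale; recordings
  with continuous airflow sound (no rest contrast) degrade to the
  envelope-only path.
* Rest-vs-pause run classification assumes the inspiratory pause is
  shorter than ~0.65 of the rest phase; cycle geometries violating this
  (very long intra-cycle pauses) will double-count.
* Apnea pauses shorter than the 6 s quiet-run threshold rely on the
  ordinary dd-based formula alone; pauses in the 6–10 s range are
  scored as hypopnea via the same formula.
* AHI here counts acoustic events only; it is not a clinical AHI
  (no airflow, effort, or oximetry channels).
* All validation is synthetic; no claim is made about detection rates
  on real recordings.
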