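# sleeprr

Sleep respiratory-rate (RR) detection and obstructive-sleep-apnea (OSA)
event extraction from breathing-sound audio, built on the
characteristic-moment-waveform method.

Obstructive sleep apnea — repeated breathing pauses of at least 10 s
during sleep — is routinely diagnosed with polysomnography, which is
expensive and uncomfortable. A single microphone taped near the nose is
a far cheaper alternative, but whole-night recordings mix heavy and
barely audible breaths, so naive envelope thresholds lose the weak
cycles. This package implements an amplitude-robust pipeline for such
recordings, aimed at researchers in biomedical acoustics and sleep
monitoring.

## Method

For a recorded breathing-sound signal *y(t)* the pipeline computes:

1. **Amplitude-contrast reduction.** A signed entropy transform
   *H(t) = −y·ln|y|*, a piecewise cut/boost around the mean level
   *av = mean(|H|)* (strong part → *a·H ± b·av* with *a* = 0.4,
   *b* = 0.6; weak part → *c·H* with *c* = 1.5), and a soft limiter
   *y* = *H*·(1 − l + l·|H|^N) with *l* = 0.85, *N* = 20.
2. **Time characteristic waveform (TCW).** The sliding-window variance
   *c(t, δ) = ∫ y² dτ − 2δ ȳ(t)²* over *[t−δ, t+δ]*, with
   *δ* ≈ half a breathing cycle (1.5–3 s). Computed with prefix sums in
   O(n), independent of the scale.
3. **Characteristic moment waveform (CMW).** The local second moment
   *I(t, δ, l) = ∫ (τ−t)² c(τ, δ) dτ* over *[t−l, t+l]* (*l* = 0.1 s),
   optionally normalized by *∫ c dτ*. The normalized CMW equals *l²/3*
   where the TCW is flat and spikes where the TCW has a valley — the
   rest phase between breaths.
4. **Breath-cycle segmentation.** Prominent CMW maxima (one winner per
   sliding window) mark cycle segment points; a short-window activity
   envelope re-centers each boundary in its rest phase and handles
   breathing pauses. Cycle counts per minute form the RR series.
5. **Apnea analysis.** With the stable rate *RR_stable*, minutes with
   *RR < T_RR = RR_stable − 10·RR_stable/60* are flagged, each
   inter-cycle interval *dd(i)* yields a pause
   *dd(i) − 60/RR_stable*, pauses ≥ 10 s are apnea events (5–10 s
   hypopnea), and the apnea–hypopnea index AHI = events/hour is banded
   (<5 normal, 5–15 mild, 15–30 moderate, ≥30 severe).

A seeded synthetic breathing-sound generator (quasi-periodic cycles of
3–5 s, 0.3–1 s inspiration/expiration bursts, log-uniform amplitude
jitter, background noise, scheduled apnea gaps) provides annotated
recordings for validation.

## Worked example

Simulate five minutes of breathing at 12 cycles/min with two inserted
pauses (15 s and 31 s) and run the detector:

```python
import sleeprr as s

spec = s.SynthSpec(duration_s=300, cycle_period_s=5.0, seed=7,
                   apnea_schedule=((60.0, 15.0), (150.0, 31.0)))
signal, truth = s.generate_breathing(spec)
result = s.detect(signal, s.PipelineConfig(estimated_cycle_s=5.0))
print(result.summary())
```

prints (reformatted):

```
n_cycles: 50            rr_series: [12, 9, 6, 12, 11]
rr_stable: 11.93        t_rr: 9.94
n_apnea: 2              n_hypopnea: 0
ahi: 24.0               severity: "moderate"
```

All 50 true cycle boundaries are recovered
(`s.evaluate_success_rate(result.segmentation, truth)` reports a
100.00% success rate with 0 false positives), the two apnea events come
back with pause estimates of 14.8 s and 30.6 s, and minutes 1–2 (RR 9
and 6) fall below the threshold T_RR ≈ 9.9. The AHI of 24/h is high
only because two events were packed into a 5-minute clip.

The same pipeline is available from the shell:

```sh
sleeprr simulate --out rec.wav --duration 300 --period 5 --seed 7 \
        --apnea 60 15 --apnea 150 31
sleeprr detect rec.wav --out-dir out/
sleeprr evaluate out/rec_boundaries.csv rec.boundaries.csv
```

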