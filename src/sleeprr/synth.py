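"""Synthetic sleep-breathing audio with ground-truth annotations.

Real whole-night recordings of breathing sounds are rarely shareable, so
this module generates audio with the statistical structure the detection
method assumes: a quasi-periodic train of breathing cycles (nominal
period 3–5 s), each built as

    inspiration burst | inspiratory pause | expiration burst | rest,

where a burst is band-limited white noise (breath sounds are broadband)
shaped by a raised-cosine envelope.  Per-cycle amplitudes are drawn
log-uniformly across a configurable max-to-min ratio to reproduce the
weak-cycles-between-heavy-cycles pattern seen in practice, zero-mean
background noise is added at a configurable SNR, and scheduled apnea
gaps silence the cycles they cover.  The true cycle boundaries (rest
midpoints) and inserted events come back as :class:`GroundTruth`,
standing in for manual cycle counting.

Everything is exactly reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioSignal
from .segmentation import SegmentationResult

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "generate_breathing",
    "evaluate_success_rate",
    "success_rate_from_counts",
    "SuccessReport",
]

#: Burst pass band in Hz; broadband airflow noise at the 4 kHz working rate.
BURST_BAND_HZ = (200.0, 1500.0)


@dataclass(frozen=True)
class SynthSpec:
    """Simulator configuration; the seed fixes the output exactly.

    ``amplitude_jitter`` is the max-to-min ratio of per-cycle burst
    amplitudes (log-uniform).  ``snr_db`` is the ratio of mean
    inspiration-burst power (at the reference amplitude, i.e. before the
    per-cycle jitter) to background-noise power.  ``period_jitter`` is
    the fractional uniform jitter of each cycle's period, making the
    train quasi-periodic rather than strictly periodic.
    ``apnea_schedule`` holds ``(start_s, gap_s)`` pairs; cycles
    overlapping a gap are replaced by background noise only.
    """

    duration_s: float = 300.0
    cycle_period_s: float = 4.0
    insp_dur_s: float = 0.8
    exp_dur_s: float = 0.8
    insp_pause_s: float = 0.4
    amplitude_jitter: float = 10.0
    snr_db: float = 10.0
    period_jitter: float = 0.05
    exp_gain: float = 0.6
    apnea_schedule: tuple[tuple[float, float], ...] = ()
    sample_rate: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "apnea_schedule", tuple((float(a), float(b)) for a, b in self.apnea_schedule)
        )
        if self.duration_s <= 0 or self.cycle_period_s <= 0:
            raise ValueError("duration_s and cycle_period_s must be positive")
        for name in ("insp_dur_s", "exp_dur_s"):
            d = getattr(self, name)
            if not 0.3 <= d <= 1.0:
                raise ValueError(f"{name}={d} outside the physiological range [0.3, 1] s")
        if self.insp_pause_s < 0:
            raise ValueError("insp_pause_s must be >= 0")
        if self.insp_dur_s + self.exp_dur_s + self.insp_pause_s >= self.cycle_period_s:
            raise ValueError("breath phases must fit inside the cycle period")
        if self.amplitude_jitter < 1:
            raise ValueError("amplitude_jitter is a max/min ratio, must be >= 1")
        if not 0 <= self.period_jitter < 0.5:
            raise ValueError("period_jitter must be in [0, 0.5)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        for start, gap in self.apnea_schedule:
            if gap <= 0 or start < 0 or start + gap > self.duration_s:
                raise ValueError(f"apnea ({start}, {gap}) outside the recording")


@dataclass(frozen=True)
class GroundTruth:
    """True cycle boundaries (rest-phase midpoints, seconds) and inserted
    (kind, start_s, gap_s) events."""

    cycle_boundaries: np.ndarray
    events: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "cycle_boundaries", np.asarray(self.cycle_boundaries, dtype=np.float64)
        )
        if self.cycle_boundaries.size and np.any(np.diff(self.cycle_boundaries) <= 0):
            raise ValueError("ground-truth boundaries must be strictly increasing")


def _band_noise(rng: np.random.Generator, n: int, fs: int) -> np.ndarray:
    """Unit-RMS band-limited white noise of length n."""
    lo, hi = BURST_BAND_HZ
    hi = min(hi, 0.45 * fs)
    x = rng.standard_normal(n)
    if n > 30:  # filtfilt needs padding room; very short bursts stay white
        sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        x = sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(x * x))
    return x / rms if rms > 0 else x


def _raised_cosine(n: int) -> np.ndarray:
    return np.hanning(n) if n > 1 else np.ones(n)


def generate_breathing(spec: SynthSpec) -> tuple[AudioSignal, GroundTruth]:
    """Synthesize one recording and its ground truth.

    Cycles are laid out sequentially; cycle k has period
    ``T·(1 + period_jitter·u)`` with ``u ~ U(-1, 1)``.  A cycle whose
    span overlaps a scheduled apnea gap is skipped (time still passes),
    so the gap contains background noise only.  The true boundary of a
    generated cycle is the midpoint of its rest phase.
    """
    fs = spec.sample_rate
    n = int(round(spec.duration_s * fs))
    rng = np.random.default_rng(spec.seed)
    # mean power of a reference inspiration burst: unit-RMS noise times the
    # raised-cosine envelope, mean(env^2) = 3/8
    noise_rms = float(np.sqrt(3.0 / 8.0) * 10.0 ** (-spec.snr_db / 20.0))
    audio = noise_rms * rng.standard_normal(n)

    log_jit = np.log(spec.amplitude_jitter)
    boundaries: list[float] = []
    t = 0.0
    while True:
        # when a cycle would start inside a scheduled gap, breathing stops
        # for exactly the gap duration and then resumes with a fresh cycle,
        # so the effective pause equals the scheduled one (up to jitter)
        for g0, gs in spec.apnea_schedule:
            if g0 <= t < g0 + gs:
                t += gs
                break
        period = spec.cycle_period_s * (1.0 + spec.period_jitter * rng.uniform(-1.0, 1.0))
        if t + period > spec.duration_s:
            break
        amp = float(np.exp(rng.uniform(0.0, 1.0) * log_jit - 0.5 * log_jit))
        insp = _band_noise(rng, int(round(spec.insp_dur_s * fs)), fs)
        exp = _band_noise(rng, int(round(spec.exp_dur_s * fs)), fs)
        i_start = int(round(t * fs))
        _add_burst(audio, i_start, amp * insp * _raised_cosine(insp.size))
        e_start = int(round((t + spec.insp_dur_s + spec.insp_pause_s) * fs))
        _add_burst(audio, e_start, spec.exp_gain * amp * exp * _raised_cosine(exp.size))
        rest_start = t + spec.insp_dur_s + spec.insp_pause_s + spec.exp_dur_s
        boundaries.append(0.5 * (rest_start + t + period))
        t += period

    events = tuple(
        ("apnea" if gap >= 10.0 else "hypopnea", start, gap)
        for start, gap in spec.apnea_schedule
    )
    return (
        AudioSignal(audio, fs),
        GroundTruth(np.asarray(boundaries), events),
    )


def _add_burst(audio: np.ndarray, start: int, burst: np.ndarray) -> None:
    stop = min(start + burst.size, audio.size)
    if start < audio.size:
        audio[start:stop] += burst[: stop - start]


@dataclass(frozen=True)
class SuccessReport:
    """Boundary-detection score against ground truth."""

    success_rate: float  # percent, rounded to two decimals
    matched: int
    n_truth: int
    n_detected: int
    false_positives: int


def evaluate_success_rate(
    detected: SegmentationResult | np.ndarray,
    truth: GroundTruth | np.ndarray,
    tol_s: float = 1.0,
) -> SuccessReport:
    """Score detected boundaries against the truth.

    Matching is greedy nearest-first and one-to-one: candidate pairs
    within ``tol_s`` are taken in order of increasing time difference,
    each true and each detected boundary used at most once (the manual
    reference was matched by eye, so any defensible one-to-one rule
    serves).  The success rate is ``100·matched/n_truth`` rounded to two
    decimals; unmatched detections count as false positives.
    """
    if tol_s <= 0:
        raise ValueError("tol_s must be positive")
    det = np.asarray(
        detected.boundaries if isinstance(detected, SegmentationResult) else detected,
        dtype=np.float64,
    )
    tru = np.asarray(
        truth.cycle_boundaries if isinstance(truth, GroundTruth) else truth,
        dtype=np.float64,
    )
    if tru.size == 0:
        raise ValueError("ground truth has no boundaries to score against")
    pairs = []
    for i, td in enumerate(det):
        j0 = np.searchsorted(tru, td - tol_s)
        j1 = np.searchsorted(tru, td + tol_s, side="right")
        for j in range(j0, j1):
            pairs.append((abs(td - tru[j]), i, j))
    pairs.sort()
    used_d = np.zeros(det.size, dtype=bool)
    used_t = np.zeros(tru.size, dtype=bool)
    matched = 0
    for _, i, j in pairs:
        if not used_d[i] and not used_t[j]:
            used_d[i] = used_t[j] = True
            matched += 1
    rate = success_rate_from_counts(matched, tru.size)
    return SuccessReport(
        success_rate=rate,
        matched=matched,
        n_truth=int(tru.size),
        n_detected=int(det.size),
        false_positives=int(det.size - matched),
    )


def success_rate_from_counts(segmented: int, manual: int) -> float:
    """Success rate (%) = 100 × segmented cycle count / manual count,
    rounded to two decimals."""
    if manual <= 0:
        raise ValueError("manual count must be positive")
    return round(100.0 * segmented / manual, 2)


def write_truth_csv(truth: GroundTruth, boundaries_path: str | Path, events_path: str | Path | None = None) -> None:
    """Write ground-truth boundary times (and optionally events) as CSV."""
    import csv

    with open(boundaries_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "time_s"])
        w.writerows(enumerate(truth.cycle_boundaries))
    if events_path is not None:
        with open(events_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["kind", "start_s", "gap_s"])
            w.writerows(truth.events)
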