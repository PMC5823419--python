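"""Apnea/hypopnea event detection from the RR series and cycle intervals.

Clinically an obstructive apnea is a breathing pause of at least 10 s.
Translated to the respiratory-rate scale, a 10 s pause in a minute costs
``10·RR_stable/60`` cycles, so minutes with

    RR < T_RR = RR_stable − 10·RR_stable/60

are apnea-suspect (``RR_stable`` is the subject's normal sleeping rate,
estimated here as the median of the nonzero per-minute RR values).  The
event-level analysis works directly on the inter-boundary intervals
``dd(i)``: since every segmented part contains one breath, the pause
hidden in a long interval is

    pause(i) = dd(i) − 60/RR_stable   (clamped at 0),

and pauses of at least 10 s are apnea events while shorter but still
abnormal pauses (default ≥ 5 s) are scored as hypopnea.  The
Apnea-Hypopnea Index (AHI) is events per monitored hour; severity bands
are <5 normal, 5–15 mild, 15–30 moderate, ≥30 severe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import SegmentationResult

__all__ = [
    "ApneaEvent",
    "ApneaReport",
    "estimate_rr_stable",
    "rr_threshold",
    "flag_low_rr_minutes",
    "pause_times",
    "classify_events",
    "compute_ahi",
    "apnea_report",
]

APNEA_MIN_PAUSE_S = 10.0
DEFAULT_HYPOPNEA_MIN_PAUSE_S = 5.0


@dataclass(frozen=True)
class ApneaEvent:
    kind: str  # "apnea" | "hypopnea"
    start_s: float
    pause_s: float


@dataclass(frozen=True)
class ApneaReport:
    """Summary of apnea analysis for one recording."""

    rr_stable: float
    t_rr: float
    events: tuple[ApneaEvent, ...]
    ahi: float
    severity: str
    monitored_hours: float
    flagged_minutes: tuple[int, ...] = ()

    @property
    def n_apnea(self) -> int:
        return sum(1 for e in self.events if e.kind == "apnea")

    @property
    def n_hypopnea(self) -> int:
        return sum(1 for e in self.events if e.kind == "hypopnea")


def estimate_rr_stable(rr_series: np.ndarray) -> float:
    """Median of the nonzero per-minute RR values.

    Zero-count minutes (no detected breathing) are excluded so silent
    stretches do not drag the stable rate down.  Raises on an empty or
    all-zero series; callers may override with a known value instead.
    """
    rr = np.asarray(rr_series, dtype=np.float64)
    rr = rr[rr > 0]
    if rr.size == 0:
        raise ValueError("cannot estimate a stable RR from an empty/all-zero series")
    return float(np.median(rr))


def rr_threshold(rr_stable: float) -> float:
    """Apnea RR threshold T_RR = RR_stable − 10·RR_stable/60.

    A 10 s pause costs 10·RR_stable/60 cycles in a minute; the exact
    value is returned and should be rounded only for display.
    """
    if rr_stable <= 0:
        raise ValueError(f"rr_stable must be positive, got {rr_stable}")
    return rr_stable - 10.0 * rr_stable / 60.0


def flag_low_rr_minutes(rr_series: np.ndarray, t_rr: float) -> np.ndarray:
    """Indices of minutes with RR strictly below the threshold."""
    rr = np.asarray(rr_series, dtype=np.float64)
    return np.flatnonzero(rr < t_rr)


def pause_times(dd: np.ndarray, rr_stable: float) -> np.ndarray:
    """Per-interval breathing-pause durations, pause(i) = max(0, dd(i) − 60/RR_stable).

    A stable cycle (dd = 60/RR_stable) gives a zero pause; intervals
    shorter than a stable cycle are clamped to zero rather than reported
    as negative pauses.
    """
    if rr_stable <= 0:
        raise ValueError(f"rr_stable must be positive, got {rr_stable}")
    return np.maximum(0.0, np.asarray(dd, dtype=np.float64) - 60.0 / rr_stable)


def classify_events(
    pauses: np.ndarray,
    hypo_min: float = DEFAULT_HYPOPNEA_MIN_PAUSE_S,
    start_times: np.ndarray | None = None,
) -> tuple[ApneaEvent, ...]:
    """Classify each pause: ≥10 s apnea, [hypo_min, 10) s hypopnea, else normal.

    ``start_times`` (optional, same length) gives each interval's start —
    usually the boundary opening the interval; NaN is used if absent.
    Normal intervals produce no event.
    """
    p = np.asarray(pauses, dtype=np.float64)
    if start_times is None:
        starts = np.full(p.size, np.nan)
    else:
        starts = np.asarray(start_times, dtype=np.float64)
        if starts.size != p.size:
            raise ValueError("start_times must align with pauses")
    events = []
    for start, pause in zip(starts, p):
        if pause >= APNEA_MIN_PAUSE_S:
            events.append(ApneaEvent("apnea", float(start), float(pause)))
        elif pause >= hypo_min:
            events.append(ApneaEvent("hypopnea", float(start), float(pause)))
    return tuple(events)


def compute_ahi(
    events: tuple[ApneaEvent, ...],
    monitored_hours: float,
    include_hypopneas: bool = False,
) -> tuple[float, str]:
    """Events per monitored hour and the OSA severity band.

    By default only apnea events are counted (hypopneas can be included
    with the flag, as clinical AHI does).  Bands: <5 normal, [5, 15)
    mild, [15, 30) moderate, ≥30 severe.
    """
    if monitored_hours <= 0:
        raise ValueError(f"monitored_hours must be positive, got {monitored_hours}")
    n = sum(1 for e in events if include_hypopneas or e.kind == "apnea")
    ahi = n / monitored_hours
    if ahi < 5:
        severity = "normal"
    elif ahi < 15:
        severity = "mild"
    elif ahi < 30:
        severity = "moderate"
    else:
        severity = "severe"
    return ahi, severity


def apnea_report(
    segmentation: SegmentationResult,
    rr_stable: float | None = None,
    hypo_min: float = DEFAULT_HYPOPNEA_MIN_PAUSE_S,
    include_hypopneas: bool = False,
    monitored_hours: float | None = None,
) -> ApneaReport:
    """Full apnea analysis of a segmentation result.

    ``rr_stable`` defaults to the median-of-nonzero-minutes estimate;
    ``monitored_hours`` to the covered duration.  Each event's start is
    the boundary opening the long interval.
    """
    if rr_stable is not None:
        rr_stable_eff = rr_stable
    elif segmentation.dd.size:
        # 60 / median inter-breath interval: finer-grained than the integer
        # per-minute counts and robust to the long intervals of pauses
        rr_stable_eff = 60.0 / float(np.median(segmentation.dd))
    else:
        rr_stable_eff = estimate_rr_stable(segmentation.rr_series)
    t_rr = rr_threshold(rr_stable_eff)
    pauses = pause_times(segmentation.dd, rr_stable_eff)
    events = classify_events(pauses, hypo_min, start_times=segmentation.boundaries[:-1])
    hours = (
        monitored_hours
        if monitored_hours is not None
        else segmentation.total_duration / 3600.0
    )
    ahi, severity = compute_ahi(events, hours, include_hypopneas)
    flagged = tuple(int(i) for i in flag_low_rr_minutes(segmentation.rr_series, t_rr))
    return ApneaReport(
        rr_stable=float(rr_stable_eff),
        t_rr=float(t_rr),
        events=events,
        ahi=float(ahi),
        severity=severity,
        monitored_hours=float(hours),
        flagged_minutes=flagged,
    )
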