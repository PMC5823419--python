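"""Breath-cycle segmentation and per-minute respiratory-rate counting.

The segmentation runs in five steps on the two envelopes computed by
:mod:`sleeprr.waveform`:

1. all strict local maxima of the CMW (plateaus contribute their
   midpoint);
2. prominence filtering — within a sliding window centered on each
   candidate (width ``2·δ`` by default), only the largest maximum
   survives, so at most one marker remains per breathing cycle;
3. local minima of the TCW, filtered the same way (smallest minimum per
   window) — the rest phase between breaths is an energy minimum;
4. cycle segment points, under one of two readings (see
   :func:`segment_cycles`): the prominent normalized-CMW maxima, which
   spike at TCW valleys and hence in the rest phase (default), or the
   prominent TCW minima validated by a nearby CMW maximum; either way
   an optional computation-window adjustment against a short-window
   activity envelope re-centers boundaries in their rest phase and
   handles breathing pauses, and near-duplicates are merged;
5. the per-minute count of segment points is the respiratory rate (RR)
   series.

Everything here is deterministic: identical input and configuration give
identical boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .waveform import CharacteristicWaveform, ScaleParams

__all__ = [
    "SegmentationResult",
    "local_extrema_indices",
    "cmw_maxima",
    "prominent_maxima",
    "tcw_minima",
    "segment_cycles",
    "rr_per_minute",
]

#: Shortest plausible interval between breath-cycle boundaries (seconds);
#: a full cycle is at least ~2 s given 0.3–1 s inspiration/expiration phases.
DEFAULT_MIN_SEPARATION = 1.5


def _prominence_keep_py(t: np.ndarray, v: np.ndarray, half: float) -> np.ndarray:
    """Keep mask for the sliding-window prominence rule.

    Candidate i survives iff it is the earliest attainer of the maximum
    value among candidates within ``[t_i - half, t_i + half]``.  Uses a
    monotone deque over the time-sorted candidates, O(k) total; on ties
    the earlier candidate stays at the front, so tie-breaking toward the
    earlier time is automatic.
    """
    k = t.size
    keep = np.zeros(k, dtype=np.bool_)
    dq = np.empty(k, dtype=np.int64)  # indices, values non-increasing
    head = 0
    tail = 0  # deque is dq[head:tail]
    nxt = 0  # next candidate to admit on the right
    for i in range(k):
        hi_t = t[i] + half
        while nxt < k and t[nxt] <= hi_t:
            # strict pop keeps the earlier of equal values in front
            while tail > head and v[dq[tail - 1]] < v[nxt]:
                tail -= 1
            dq[tail] = nxt
            tail += 1
            nxt += 1
        lo_t = t[i] - half
        while head < tail and t[dq[head]] < lo_t:
            head += 1
        if head < tail and dq[head] == i:
            keep[i] = True
    return keep


try:  # numba shaves the deque loop to native speed on long noisy traces
    from numba import njit

    _prominence_keep = njit(cache=False)(_prominence_keep_py)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _prominence_keep = _prominence_keep_py


@dataclass(frozen=True)
class SegmentationResult:
    """Ordered breath-cycle boundaries and derived bookkeeping.

    ``boundaries`` are segment-point times in seconds (strictly
    increasing); ``dd`` the inter-boundary intervals
    ``dd[i] = boundaries[i+1] - boundaries[i]``; ``rr_series`` the
    per-minute boundary counts on tumbling 60 s windows (full minutes
    only, the trailing partial minute is in ``rr_partial``).
    """

    boundaries: np.ndarray
    dd: np.ndarray
    rr_series: np.ndarray
    scales: ScaleParams
    total_duration: float = 0.0
    rr_partial: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundaries", np.asarray(self.boundaries, dtype=np.float64))
        object.__setattr__(self, "dd", np.asarray(self.dd, dtype=np.float64))
        object.__setattr__(self, "rr_series", np.asarray(self.rr_series, dtype=np.int64))
        if self.boundaries.size and np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return int(self.boundaries.size)


def local_extrema_indices(values: np.ndarray, mode: str = "max") -> np.ndarray:
    """Indices of strict local maxima (or minima) with plateau handling.

    A run of equal values is a maximum when the nearest distinct values
    on both sides are smaller; the run contributes its midpoint sample.
    Runs touching either edge of the array are never extrema.
    """
    v = np.asarray(values, dtype=np.float64)
    if mode == "min":
        v = -v
    elif mode != "max":
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
    n = v.size
    if n < 3:
        return np.empty(0, dtype=np.intp)
    # run-length encode equal-value plateaus
    change = np.flatnonzero(np.diff(v) != 0.0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [n - 1]))  # inclusive
    run_vals = v[starts]
    if starts.size < 3:
        return np.empty(0, dtype=np.intp)
    interior = slice(1, starts.size - 1)
    is_max = (run_vals[1:-1] > run_vals[:-2]) & (run_vals[1:-1] > run_vals[2:])
    mids = (starts[interior] + ends[interior]) // 2
    return mids[is_max]


def cmw_maxima(cmw: CharacteristicWaveform) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: times and values of all strict local maxima of the CMW."""
    if cmw.kind not in ("cmw_raw", "cmw_normalized"):
        raise ValueError(f"expected a CMW trace, got kind={cmw.kind!r}")
    if len(cmw) < 3:
        raise ValueError("CMW trace too short for extremum detection (< 3 samples)")
    idx = local_extrema_indices(cmw.values, "max")
    return cmw.times[idx], cmw.values[idx]


def prominent_maxima(
    times: np.ndarray,
    values: np.ndarray,
    scales: ScaleParams,
    window_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 2: sliding-window prominence filter.

    A candidate survives iff it is the largest within the window of width
    ``window_s`` (default ``2·delta``) centered on it, i.e. no larger
    candidate lies within half that width; ties break toward the earlier
    time.  Exactly one inspiratory marker per cycle is expected, so the
    window defaults to about one breathing cycle.
    """
    t = np.asarray(times, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("maxima must be sorted by time")
    half = (window_s if window_s is not None else 2.0 * scales.delta) / 2.0
    keep = _prominence_keep(t, v, half)
    return t[keep], v[keep]


def tcw_minima(
    tcw: CharacteristicWaveform,
    scales: ScaleParams | None = None,
    window_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 3: prominent local minima of the TCW.

    Same prominence filtering as :func:`prominent_maxima`, applied to
    ``-TCW`` (the smallest minimum per window survives).  Returns times
    and the TCW values at them.
    """
    if tcw.kind != "tcw":
        raise ValueError(f"expected a TCW trace, got kind={tcw.kind!r}")
    sc = scales or tcw.scales
    idx = local_extrema_indices(tcw.values, "min")
    t, v = prominent_maxima(tcw.times[idx], -tcw.values[idx], sc, window_s)
    return t, -v


def _nearest_within(sorted_ref: np.ndarray, query: np.ndarray, tol: float) -> np.ndarray:
    """Boolean mask: does each query time have a reference time within tol?"""
    if sorted_ref.size == 0 or query.size == 0:
        return np.zeros(query.size, dtype=bool)
    pos = np.searchsorted(sorted_ref, query)
    left = np.abs(query - sorted_ref[np.clip(pos - 1, 0, sorted_ref.size - 1)])
    right = np.abs(sorted_ref[np.clip(pos, 0, sorted_ref.size - 1)] - query)
    return np.minimum(left, right) <= tol


def _merge_close(
    cand_t: np.ndarray, cand_v: np.ndarray, min_separation: float, prefer: str
) -> np.ndarray:
    """Collapse boundaries closer than min_separation, keeping the one
    with the lower (prefer='low') or higher (prefer='high') value."""
    times: list[float] = []
    vals: list[float] = []
    for t, v in zip(cand_t, cand_v):
        if times and t - times[-1] < min_separation:
            better = v < vals[-1] if prefer == "low" else v > vals[-1]
            if better:
                times[-1], vals[-1] = t, v
        else:
            times.append(float(t))
            vals.append(float(v))
    return np.asarray(times)


def _quiet_runs(
    activity: CharacteristicWaveform, threshold: float, min_burst_s: float = 0.0
) -> list[tuple[float, float]]:
    """Maximal time intervals where the activity envelope stays below threshold.

    Above-threshold stretches shorter than ``min_burst_s`` do not break a
    quiet run: a genuine breath phase lasts at least ~0.3 s, so anything
    briefer (mouth clicks, movement artifacts) is treated as part of the
    surrounding quiet.
    """
    below = activity.values < threshold
    if not below.any():
        return []
    b = below.astype(np.int8)
    starts = np.flatnonzero(np.diff(np.concatenate(([0], b))) == 1)
    stops = np.flatnonzero(np.diff(np.concatenate((b, [0]))) == -1)
    t = activity.times
    runs = [(float(t[s]), float(t[e])) for s, e in zip(starts, stops)]
    if min_burst_s > 0 and len(runs) > 1:
        merged = [runs[0]]
        for a, e in runs[1:]:
            if a - merged[-1][1] < min_burst_s:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((a, e))
        runs = merged
    return runs


def _activity_adjust(
    cand_t: np.ndarray,
    cand_v: np.ndarray,
    activity: CharacteristicWaveform,
    act_ratio: float,
    long_quiet_s: float,
    snap_radius_s: float = 0.0,
    min_burst_s: float = 0.3,
    ref_t: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Silence-aware boundary adjustment for breathing pauses.

    The activity envelope (short-window TCW of the *unpreprocessed*
    signal, where silence keeps its full contrast) is thresholded at
    ``act_ratio`` times its noise floor (5th percentile).  Three rules
    follow from it:

    * a quiet run at least ``long_quiet_s`` long is a breathing pause,
      not a rest phase: candidates inside it are artifacts of the
      value-blind prominence filter and are dropped, and the boundary
      closing the cycle that precedes the pause is placed at the quiet
      onset plus half a typical rest (the same mid-rest convention an
      ordinary boundary follows);
    * a candidate in (or, for rest-sized runs, within ``snap_radius_s``
      of) an ordinary quiet run snaps to the run center — the
      geometric mid-rest — collapsing duplicates within one run;
    * candidates in the sound-burst region bordering a pause (within a
      guard zone of two typical rests around it) are dropped: a cycle
      boundary inside a burst next to a pause is always spurious.

    The typical rest duration is the median length of the ordinary
    quiet runs that contain candidates (the runs the detector itself
    marks as rests).
    """
    av = activity.values
    floor = float(np.quantile(av, 0.05))
    thr = act_ratio * floor
    runs = _quiet_runs(activity, thr, min_burst_s)
    if not runs:
        return cand_t, cand_v
    starts = np.asarray([a for a, _ in runs])

    def _containing(t: float) -> int:
        k = int(np.searchsorted(starts, t)) - 1  # last run starting <= t
        if 0 <= k < len(runs) and runs[k][0] <= t <= runs[k][1]:
            return k
        return -1

    # the typical rest is estimated from the runs the PROMINENT maxima
    # occupy (about one per cycle, almost always the rest phase); feeding
    # every raw maximum here would count intra-cycle pauses as rests
    marker_t = cand_t if ref_t is None else np.asarray(ref_t, dtype=np.float64)
    occupied = {_containing(t) for t in marker_t} - {-1}
    occ_lens = [
        runs[k][1] - runs[k][0]
        for k in occupied
        if runs[k][1] - runs[k][0] < long_quiet_s
    ]
    rest_typ = float(np.quantile(occ_lens, 0.75)) if occ_lens else 0.0
    rest_min = 0.65 * rest_typ  # shorter runs are intra-cycle pauses, not rests
    half_rest = 0.5 * rest_typ
    long_runs = [(a, b) for a, b in runs if b - a >= long_quiet_s]
    # assign each candidate to the run containing it, or the nearest
    # rest-sized run within snap_radius_s (envelope smearing can push the
    # CMW spike just past a rest-phase edge); -1 = unassigned
    assign = np.full(cand_t.size, -1, dtype=np.intp)
    for i, t in enumerate(cand_t):
        k = int(np.searchsorted(starts, t)) - 1
        best_k, best_d = -1, np.inf
        for j in (k, k + 1):
            if 0 <= j < len(runs):
                a, b = runs[j]
                d = max(a - t, t - b)  # <= 0 inside
                radius = (
                    snap_radius_s if rest_min <= b - a < long_quiet_s else 0.0
                )
                if (d <= 0 or d <= radius) and d < best_d:
                    best_k, best_d = j, d
        assign[i] = best_k
    big_v = (np.max(cand_v) if cand_v.size else 0.0) + 1.0
    # unassigned candidates sit inside a sound burst, where a cycle
    # boundary cannot lie: dropped
    t_out: list[float] = []
    v_out: list[float] = []
    t0 = activity.start_time
    for k, (a, b) in enumerate(runs):
        members = np.flatnonzero(assign == k)
        if b - a >= long_quiet_s:
            # breathing pause: candidates inside were dropped with the
            # assignment; close the preceding cycle at mid-rest depth
            if a > t0:  # a pause at the very start closes no cycle
                t_out.append(a + half_rest)
                v_out.append(big_v)  # model boundary outranks survivors
        elif members.size and b - a >= rest_min:
            # ordinary rest phase: snap to the run center, collapsing
            # multiple candidates into one
            t_out.append(0.5 * (a + b))
            v_out.append(float(np.max(cand_v[members])))
        # candidates in sub-rest quiet runs (e.g. the inspiratory pause
        # inside a cycle) are never boundaries: dropped
    t_all = np.asarray(t_out)
    v_all = np.asarray(v_out)
    order = np.argsort(t_all, kind="stable")
    return t_all[order], v_all[order]


def segment_cycles(
    tcw: CharacteristicWaveform,
    cmw: CharacteristicWaveform,
    scales: ScaleParams | None = None,
    mode: str = "cmw_maxima",
    w: float | None = None,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    window_s: float | None = None,
    activity: CharacteristicWaveform | None = None,
    act_ratio: float = 1.5,
    long_quiet_s: float = 6.0,
    snap_radius_s: float = 0.0,
    total_duration: float | None = None,
) -> SegmentationResult:
    """Step 4 (+5): derive breath-cycle boundaries from the two envelopes.

    Two readings of the segment-point rule are provided:

    ``mode="cmw_maxima"`` (default) — boundaries are the prominent maxima
    of the normalized CMW, which spike where the TCW has a valley
    (positive curvature over a small mass), i.e. in the rest phase
    between breaths.  If an ``activity`` envelope is supplied (a
    short-window TCW of the raw signal), candidates falling inside
    quiet runs longer than ``long_quiet_s`` — breathing pauses — are
    replaced by a single model boundary at the pause onset plus half a
    typical rest (see :func:`_silence_adjust`).

    ``mode="tcw_minima"`` — boundaries are the prominent TCW minima,
    each retained only if a prominent CMW maximum lies within
    ``[t - w/2, t + w/2]`` (computation window, default ``w = delta``).

    In both modes boundaries closer than ``min_separation`` are merged
    (keeping the stronger candidate) and an empty outcome is reported
    with a warning, not an exception.
    """
    sc = scales or tcw.scales
    w_eff = w if w is not None else sc.delta
    if total_duration is not None:
        duration = total_duration
    else:
        # assume the trace was trimmed symmetrically from a signal starting at 0
        duration = float(2.0 * tcw.start_time + len(tcw) / tcw.sample_rate)
    if len(cmw) >= 3:
        raw_t, raw_v = cmw_maxima(cmw)
        mx_t, mx_v = prominent_maxima(raw_t, raw_v, sc, window_s)
    else:
        raw_t = raw_v = mx_t = mx_v = np.empty(0)
    if mode == "tcw_minima":
        cand_t, cand_v = tcw_minima(tcw, sc, window_s)
        retained = _nearest_within(mx_t, cand_t, w_eff / 2.0)
        cand_t, cand_v = cand_t[retained], cand_v[retained]
        boundaries = _merge_close(cand_t, cand_v, min_separation, prefer="low")
    elif mode == "cmw_maxima":
        if activity is not None and raw_t.size:
            # adjust on ALL strict maxima so a rest phase can fire even when
            # the raw prominence winner was displaced (e.g. by a click),
            # then let the adjusted candidates fight the prominence contest
            cand_t, cand_v = _activity_adjust(
                raw_t, raw_v, activity, act_ratio, long_quiet_s, snap_radius_s,
                ref_t=mx_t,
            )
            cand_t, cand_v = prominent_maxima(cand_t, cand_v, sc, window_s)
        else:
            cand_t, cand_v = mx_t, mx_v
        boundaries = _merge_close(cand_t, cand_v, min_separation, prefer="high")
    else:
        raise ValueError(f"unknown segmentation mode {mode!r}")
    if boundaries.size == 0:
        warnings.warn("no breath-cycle boundaries found", stacklevel=2)
    dd = np.diff(boundaries) if boundaries.size else np.empty(0)
    rr, partial = rr_per_minute(boundaries, duration)
    return SegmentationResult(
        boundaries, dd, rr, sc, total_duration=duration, rr_partial=partial
    )


def rr_per_minute(
    boundaries: np.ndarray, total_duration: float
) -> tuple[np.ndarray, int]:
    """Step 5: boundary counts on tumbling half-open minutes [60k, 60(k+1)).

    Returns the counts for complete minutes and, separately, the raw
    count in the trailing partial minute (not scaled up).  A boundary
    exactly at a window edge belongs to the later window.
    """
    b = np.asarray(boundaries, dtype=np.float64)
    if b.size and (b.min() < 0 or b.max() > total_duration):
        raise ValueError("boundaries outside [0, total_duration]")
    n_full = int(total_duration // 60)
    counts = np.zeros(n_full, dtype=np.int64)
    if b.size and n_full:
        mins = np.floor(b / 60.0).astype(np.intp)
        inside = mins < n_full
        np.add.at(counts, mins[inside], 1)
    partial = int(np.count_nonzero(b >= 60.0 * n_full))
    return counts, partial
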