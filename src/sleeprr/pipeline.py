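"""End-to-end detection pipeline: audio → envelopes → boundaries → report.

This ties the per-stage modules together under one configuration object:
resample to the working rate, normalize, reduce amplitude contrast,
extract TCW and CMW, segment breath cycles, count the per-minute RR and
score apnea/hypopnea events.  The CLI is a thin wrapper around
:func:`detect`.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import audio_io
from .apnea import ApneaReport, apnea_report
from .audio_io import AudioSignal
from .preprocess import PreprocessConfig, preprocess
from .segmentation import (
    DEFAULT_MIN_SEPARATION,
    SegmentationResult,
    segment_cycles,
)
from .waveform import CharacteristicWaveform, ScaleParams, cmw, suggest_scales, tcw

__all__ = ["PipelineConfig", "DetectionResult", "detect"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the full pipeline; defaults are the recommended constants.

    When ``scales`` is not given, ``estimated_cycle_s`` feeds the
    scale-choice heuristic (δ = half cycle, clipped to [1.5, 3] s);
    absent both, δ = 2.5 s is used, the single setting that covers 3–5 s
    cycles once the contrast-reduction preprocessing is applied.
    """

    working_rate: int = audio_io.DEFAULT_WORKING_RATE
    apply_preprocess: bool = True
    preprocess_config: PreprocessConfig = field(default_factory=PreprocessConfig)
    scales: ScaleParams | None = None
    estimated_cycle_s: float | None = None
    normalized_cmw: bool = True
    #: Step-4 computation window width (seconds); None → delta.
    w: float | None = None
    min_separation: float = DEFAULT_MIN_SEPARATION
    #: Step-2 prominence window width (seconds); None → 1.6·delta (a
    #: candidate must beat rivals within ±0.8δ ≈ ±0.4 cycle, short enough
    #: not to pit consecutive breaths against each other when their
    #: spacing jitters below one nominal period).
    suppression_window_s: float | None = None
    rr_stable: float | None = None
    hypo_min: float = 5.0
    include_hypopneas: bool = False
    #: Segment-point rule; see :func:`sleeprr.segmentation.segment_cycles`.
    mode: str = "cmw_maxima"
    #: Half-window (s) of the short activity envelope used for
    #: breathing-pause handling; None disables silence adjustment.  Kept
    #: well below the shortest breath phase (0.3 s) so that sub-phase
    #: clicks stay distinguishable from genuine bursts by duration.
    activity_half_s: float | None = 0.05
    act_ratio: float = 1.5
    long_quiet_s: float = 6.0
    snap_radius_s: float = 0.5

    def resolve_scales(self) -> ScaleParams:
        if self.scales is not None:
            return self.scales
        if self.estimated_cycle_s is not None:
            return suggest_scales(self.estimated_cycle_s)
        return ScaleParams(delta=2.5, moment_l=0.1)


@dataclass(frozen=True)
class DetectionResult:
    """Everything the pipeline produced for one recording."""

    segmentation: SegmentationResult
    report: ApneaReport | None
    tcw: CharacteristicWaveform
    cmw: CharacteristicWaveform
    config: PipelineConfig

    def summary(self) -> dict:
        d = {
            "n_cycles": self.segmentation.n_cycles,
            "rr_series": self.segmentation.rr_series.tolist(),
            "rr_partial_minute": self.segmentation.rr_partial,
            "total_duration_s": self.segmentation.total_duration,
        }
        if self.report is not None:
            d.update(
                rr_stable=self.report.rr_stable,
                t_rr=self.report.t_rr,
                ahi=self.report.ahi,
                severity=self.report.severity,
                monitored_hours=self.report.monitored_hours,
                n_apnea=self.report.n_apnea,
                n_hypopnea=self.report.n_hypopnea,
            )
        return d

    def write_outputs(self, out_dir: str | Path, stem: str = "detection") -> dict:
        """Write boundaries/RR/events CSVs plus a summary JSON; returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seg = self.segmentation
        paths = {
            "boundaries": out / f"{stem}_boundaries.csv",
            "rr": out / f"{stem}_rr.csv",
            "events": out / f"{stem}_events.csv",
            "summary": out / f"{stem}_summary.json",
        }
        with open(paths["boundaries"], "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["index", "time_s", "dd_s"])
            for i, t in enumerate(seg.boundaries):
                w.writerow([i, f"{t:.4f}", f"{seg.dd[i - 1]:.4f}" if i else ""])
        with open(paths["rr"], "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["minute_index", "rr"])
            w.writerows(enumerate(seg.rr_series.tolist()))
        with open(paths["events"], "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["type", "start_s", "pause_s"])
            if self.report is not None:
                for e in self.report.events:
                    w.writerow([e.kind, f"{e.start_s:.4f}", f"{e.pause_s:.4f}"])
        with open(paths["summary"], "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        return paths


def detect(signal: AudioSignal, config: PipelineConfig | None = None) -> DetectionResult:
    """Run the full detection pipeline on one recording."""
    cfg = config or PipelineConfig()
    total_duration = signal.duration
    if signal.sample_rate > cfg.working_rate:
        signal = audio_io.downsample(signal, cfg.working_rate)
    raw = audio_io.normalize_amplitude(signal)
    signal = raw
    if cfg.apply_preprocess:
        signal = audio_io.normalize_amplitude(preprocess(raw, cfg.preprocess_config))
    scales = cfg.resolve_scales()
    tcw_wave = tcw(signal, scales)
    cmw_wave = cmw(tcw_wave, scales, normalized=cfg.normalized_cmw)
    activity = None
    if cfg.activity_half_s is not None and cfg.mode == "cmw_maxima":
        # short-window energy envelope of the raw signal: silence keeps its
        # full contrast here, unlike in the contrast-reduced TCW
        act_scales = ScaleParams(
            delta=cfg.activity_half_s, moment_l=cfg.activity_half_s / 3.0
        )
        # clip amplitude outliers (clicks, movement artifacts) so their
        # above-threshold footprint reflects their duration, not loudness
        ceil = float(np.quantile(np.abs(raw.samples), 0.98))
        clipped = AudioSignal(
            np.clip(raw.samples, -ceil, ceil) if ceil > 0 else raw.samples,
            raw.sample_rate,
            raw.start_time,
        )
        activity = tcw(clipped, act_scales)
    window_s = (
        cfg.suppression_window_s
        if cfg.suppression_window_s is not None
        else 1.6 * scales.delta
    )
    segmentation = segment_cycles(
        tcw_wave,
        cmw_wave,
        scales,
        mode=cfg.mode,
        w=cfg.w,
        min_separation=cfg.min_separation,
        window_s=window_s,
        activity=activity,
        act_ratio=cfg.act_ratio,
        long_quiet_s=cfg.long_quiet_s,
        snap_radius_s=cfg.snap_radius_s,
        total_duration=total_duration,
    )
    report: ApneaReport | None
    try:
        report = apnea_report(
            segmentation,
            rr_stable=cfg.rr_stable,
            hypo_min=cfg.hypo_min,
            include_hypopneas=cfg.include_hypopneas,
        )
    except ValueError as exc:  # e.g. silent recording, no RR to estimate
        warnings.warn(f"apnea analysis skipped: {exc}", stacklevel=2)
        report = None
    return DetectionResult(segmentation, report, tcw_wave, cmw_wave, cfg)
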