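import numpy as np
import pytest

from sleeprr import (
    CharacteristicWaveform,
    PipelineConfig,
    ScaleParams,
    SynthSpec,
    cmw_maxima,
    detect,
    generate_breathing,
    prominent_maxima,
    rr_per_minute,
    segment_cycles,
    tcw_minima,
)
from sleeprr.segmentation import local_extrema_indices


def _cw(values, fs=10, kind="cmw_normalized", delta=2.0):
    return CharacteristicWaveform(
        np.asarray(values, float), fs, kind, ScaleParams(delta, 0.1)
    )


class TestLocalExtrema:
    def test_triangular_bump_single_maximum(self):
        t, v = cmw_maxima(_cw([0, 1, 2, 3, 2, 1, 0]))
        assert t.size == 1
        assert t[0] == pytest.approx(3 / 10)

    def test_monotone_trace_has_no_maximum(self):
        t, _ = cmw_maxima(_cw(np.arange(10.0)))
        assert t.size == 0

    def test_plateau_yields_midpoint(self):
        idx = local_extrema_indices(np.array([0, 1, 5, 5, 5, 1, 0.0]), "max")
        np.testing.assert_array_equal(idx, [3])

    def test_matches_exhaustive_scan(self, rng):
        v = rng.normal(0, 1, 500)
        got = set(local_extrema_indices(v, "max"))
        expected = {
            i for i in range(1, 499) if v[i] > v[i - 1] and v[i] > v[i + 1]
        }
        assert got == expected

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            cmw_maxima(_cw([1.0, 2.0]))

    def test_v_shape_minimum(self):
        wave = _cw([3, 2, 1, 0, 1, 2, 3], kind="tcw")
        t, v = tcw_minima(wave)
        assert t.size == 1 and v[0] == 0.0

    def test_constant_trace_no_minima(self):
        t, _ = tcw_minima(_cw(np.full(20, 2.0), kind="tcw"))
        assert t.size == 0


class TestProminence:
    def test_close_pair_keeps_larger(self):
        sc = ScaleParams(2.0, 0.1)
        t, v = prominent_maxima([10.0, 10.3], [1.0, 0.4], sc)
        np.testing.assert_array_equal(t, [10.0])

    def test_distant_pair_both_survive(self):
        sc = ScaleParams(2.0, 0.1)
        t, _ = prominent_maxima([10.0, 15.0], [1.0, 0.4], sc)
        np.testing.assert_array_equal(t, [10.0, 15.0])

    def test_equal_values_earlier_survives(self):
        sc = ScaleParams(2.0, 0.1)
        t, _ = prominent_maxima([10.0, 10.3], [0.7, 0.7], sc)
        np.testing.assert_array_equal(t, [10.0])

    def test_chain_suppression_is_per_pair(self):
        # B killed by A; C killed by B even though B is itself dead
        sc = ScaleParams(2.0, 0.1)
        t, _ = prominent_maxima([0.0, 1.5, 3.0], [10.0, 8.0, 6.0], sc)
        np.testing.assert_array_equal(t, [0.0])

    def test_custom_window(self):
        sc = ScaleParams(2.0, 0.1)
        t, _ = prominent_maxima([0.0, 1.5, 3.0], [10.0, 8.0, 6.0], sc, window_s=2.0)
        np.testing.assert_array_equal(t, [0.0, 1.5, 3.0])

    def test_periodic_tcw_minima_count(self):
        # period-T sawtooth-like trace: about duration/T prominent minima
        fs, T, dur = 50, 4.0, 60.0
        t = np.arange(int(dur * fs)) / fs
        wave = CharacteristicWaveform(
            1.0 - np.cos(2 * np.pi * t / T), fs, "tcw", ScaleParams(T / 2, 0.1)
        )
        times, _ = tcw_minima(wave)
        assert abs(times.size - dur / T) <= 1


class TestSegmentCycles:
    def test_sixteen_cycle_recording(self):
        spec = SynthSpec(
            duration_s=66, cycle_period_s=4.0, period_jitter=0.0, seed=3
        )
        sig, truth = generate_breathing(spec)
        assert truth.cycle_boundaries.size == 16
        res = detect(sig, PipelineConfig(estimated_cycle_s=4.0))
        assert res.segmentation.n_cycles == 16

    def test_apnea_recording_has_one_long_interval(self):
        spec = SynthSpec(
            duration_s=50,
            cycle_period_s=4.0,
            period_jitter=0.0,
            seed=4,
            apnea_schedule=((16.0, 12.0),),
        )
        sig, truth = generate_breathing(spec)
        res = detect(sig, PipelineConfig(estimated_cycle_s=4.0))
        dd = res.segmentation.dd
        assert np.sum(dd > 10) == 1
        assert np.all(dd[dd <= 10] < 6)

    def test_tcw_minima_mode_rejects_unvalidated_candidate(self):
        # a TCW minimum with no CMW maximum within w/2 must be dropped
        fs = 10
        sc = ScaleParams(2.0, 0.1)
        tcw_vals = 1.0 + np.cos(2 * np.pi * np.arange(400) / (fs * 4.0))
        tcw_wave = CharacteristicWaveform(tcw_vals, fs, "tcw", sc)
        flat_cmw = CharacteristicWaveform(
            np.full(400, 0.0033), fs, "cmw_normalized", sc
        )
        with pytest.warns(UserWarning, match="no breath-cycle boundaries"):
            res = segment_cycles(tcw_wave, flat_cmw, sc, mode="tcw_minima")
        assert res.n_cycles == 0

    def test_determinism(self):
        spec = SynthSpec(duration_s=70, cycle_period_s=4.0, seed=11)
        sig, _ = generate_breathing(spec)
        cfg = PipelineConfig(estimated_cycle_s=4.0)
        a = detect(sig, cfg).segmentation.boundaries
        b = detect(sig, cfg).segmentation.boundaries
        np.testing.assert_array_equal(a, b)

    def test_click_robustness(self):
        # brief high-amplitude clicks between cycles leave the count alone
        spec = SynthSpec(duration_s=66, cycle_period_s=4.0, period_jitter=0.0, seed=5)
        sig, truth = generate_breathing(spec)
        cfg = PipelineConfig(estimated_cycle_s=4.0)
        base = detect(sig, cfg).segmentation.n_cycles
        clicked = sig.samples.copy()
        rng = np.random.default_rng(99)
        for tb in truth.cycle_boundaries[2:12:3]:
            i = int((tb + 0.2) * spec.sample_rate)  # inside the rest phase
            n = int(0.15 * spec.sample_rate)
            clicked[i : i + n] += 3.0 * rng.standard_normal(n)
        from sleeprr import AudioSignal

        noisy = detect(AudioSignal(clicked, spec.sample_rate), cfg)
        assert noisy.segmentation.n_cycles == base

    def test_dd_consistent_with_boundaries(self):
        spec = SynthSpec(duration_s=90, cycle_period_s=4.0, seed=6)
        sig, _ = generate_breathing(spec)
        seg = detect(sig, PipelineConfig(estimated_cycle_s=4.0)).segmentation
        assert np.all(np.diff(seg.boundaries) > 0)
        np.testing.assert_allclose(seg.dd, np.diff(seg.boundaries))
        assert seg.dd.size == seg.n_cycles - 1


class TestRrPerMinute:
    def test_uniform_minute(self):
        counts, partial = rr_per_minute(np.linspace(1, 59, 14), 60.0)
        np.testing.assert_array_equal(counts, [14])
        assert partial == 0

    def test_edge_boundary_goes_to_later_minute(self):
        counts, partial = rr_per_minute(np.array([60.0]), 120.0)
        np.testing.assert_array_equal(counts, [0, 1])

    def test_two_minutes(self):
        b = np.concatenate([np.linspace(1, 59, 14), np.linspace(61, 119, 14)])
        counts, _ = rr_per_minute(np.sort(b), 120.0)
        np.testing.assert_array_equal(counts, [14, 14])

    def test_partial_minute_reported_separately(self):
        counts, partial = rr_per_minute(np.array([10.0, 70.0, 80.0]), 90.0)
        np.testing.assert_array_equal(counts, [1])
        assert partial == 2

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rr_per_minute(np.array([70.0]), 60.0)


def test_rr_recovery_on_simulated_minutes():
    """Detected per-minute RR within +/-1 of truth for nearly all minutes."""
    ok = total = 0
    for i, T in enumerate((3.2, 4.0, 4.8)):
        spec = SynthSpec(duration_s=240, cycle_period_s=T, seed=200 + i)
        sig, truth = generate_breathing(spec)
        res = detect(sig, PipelineConfig(estimated_cycle_s=T))
        true_counts, _ = rr_per_minute(truth.cycle_boundaries, 240.0)
        got = res.segmentation.rr_series
        ok += int(np.sum(np.abs(got - true_counts) <= 1))
        total += true_counts.size
    assert ok / total >= 0.95
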