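import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sleeprr import (
    AudioSignal,
    EntropySignal,
    PreprocessConfig,
    amplitude_limit,
    contrast_cut,
    entropy_transform,
    preprocess,
)
from conftest import make_signal


class TestEntropyTransform:
    @pytest.mark.parametrize(
        "y, expected",
        [
            (0.0, 0.0),
            (1.0, 0.0),
            (-1.0, 0.0),
            (np.exp(-1.0), np.exp(-1.0)),
            (-np.exp(-1.0), -np.exp(-1.0)),
            (0.5, -0.5 * np.log(0.5)),
        ],
    )
    def test_pointwise_values(self, y, expected):
        out = entropy_transform(make_signal([y]))
        np.testing.assert_allclose(out.values, [expected], atol=1e-15)

    def test_sign_and_magnitude_convention(self, rng):
        y = rng.uniform(-1, 1, 1000)
        out = entropy_transform(make_signal(y))
        np.testing.assert_array_equal(np.sign(out.values), np.sign(y))
        nz = y != 0
        np.testing.assert_allclose(
            np.abs(out.values[nz]), np.abs(y[nz]) * np.abs(np.log(np.abs(y[nz])))
        )
        assert out.av == pytest.approx(np.mean(np.abs(out.values)))

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="normalize"):
            entropy_transform(make_signal([1.5]))


class TestContrastCut:
    def test_strong_branch(self):
        h = EntropySignal(np.array([0.5]), av=0.2, sample_rate=100)
        out = contrast_cut(h)
        np.testing.assert_allclose(out.values, [0.4 * 0.5 + 0.6 * 0.2])  # 0.32

    def test_strong_branch_negative_is_sign_symmetric(self):
        h = EntropySignal(np.array([-0.5]), av=0.2, sample_rate=100)
        out = contrast_cut(h)
        np.testing.assert_allclose(out.values, [-0.32])

    def test_weak_branch(self):
        h = EntropySignal(np.array([0.1]), av=0.2, sample_rate=100)
        out = contrast_cut(h)
        np.testing.assert_allclose(out.values, [0.15])

    def test_zero_maps_to_zero(self):
        h = EntropySignal(np.array([0.0]), av=0.2, sample_rate=100)
        assert contrast_cut(h).values[0] == 0.0

    def test_av_recomputed_on_output(self, rng):
        vals = rng.normal(0, 0.3, 512)
        h = EntropySignal(vals, av=float(np.mean(np.abs(vals))), sample_rate=100)
        out = contrast_cut(h)
        assert out.av == pytest.approx(np.mean(np.abs(out.values)))

    def test_block_processing_uses_local_level(self):
        # one loud block, one quiet: per-block av must differ from global
        vals = np.concatenate([np.full(100, 0.8), np.full(100, 0.01)])
        h = EntropySignal(vals, av=float(np.mean(np.abs(vals))), sample_rate=100)
        whole = contrast_cut(h, PreprocessConfig())
        blocked = contrast_cut(h, PreprocessConfig(block_s=1.0))
        # with a global level the quiet block is "weak" (boosted by c);
        # with per-block levels it is at its own level (cut branch)
        assert not np.allclose(whole.values[100:], blocked.values[100:])


class TestAmplitudeLimit:
    @pytest.mark.parametrize(
        "h, expected",
        [
            (0.0, 0.0),
            (1.0, 1.0),
            (-1.0, -1.0),
            (0.5, 0.5 * (0.15 + 0.85 * 0.5 ** 20)),  # ~0.075000405
        ],
    )
    def test_fixed_points_and_midrange(self, h, expected):
        sig = EntropySignal(np.array([h]), av=0.0, sample_rate=100)
        np.testing.assert_allclose(amplitude_limit(sig).samples, [expected], rtol=1e-12)

    def test_midrange_value_matches_hand_evaluation(self):
        sig = EntropySignal(np.array([0.5]), av=0.0, sample_rate=100)
        assert amplitude_limit(sig).samples[0] == pytest.approx(0.075000405, abs=1e-9)


class TestFullChain:
    def test_zero_signal_fixed(self):
        out = preprocess(make_signal(np.zeros(100)))
        assert np.all(out.samples == 0.0)

    def test_sign_pattern_preserved(self, rng):
        y = rng.uniform(-1, 1, 2000)
        out = preprocess(make_signal(y))
        np.testing.assert_array_equal(np.sign(out.samples), np.sign(y))

    def test_burst_contrast_shrinks(self, rng):
        # two disjoint noise bursts with 10:1 RMS ratio
        strong = 0.9 * rng.standard_normal(500)
        weak = 0.09 * rng.standard_normal(500)
        y = np.clip(np.concatenate([strong, np.zeros(200), weak]), -1, 1)
        out = preprocess(make_signal(y)).samples
        rms = lambda x: np.sqrt(np.mean(x * x))
        before = rms(y[:500]) / rms(y[700:])
        after = rms(out[:500]) / rms(out[700:])
        assert after < before

    def test_bounded_output(self, rng):
        y = rng.uniform(-1, 1, 5000)
        out = preprocess(make_signal(y)).samples
        assert np.max(np.abs(out)) <= 1.5


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
def test_every_stage_is_odd(x):
    """f(-x) == -f(x) through the whole chain (all three stages are odd)."""
    plus = preprocess(make_signal([x])).samples[0]
    minus = preprocess(make_signal([-x])).samples[0]
    assert minus == pytest.approx(-plus, abs=1e-15)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(a=1.5)
    with pytest.raises(ValueError):
        PreprocessConfig(c_enh=0.5)
    with pytest.raises(ValueError):
        PreprocessConfig(limit_factor=1.2)
    with pytest.raises(ValueError):
        PreprocessConfig(limit_power=1)
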