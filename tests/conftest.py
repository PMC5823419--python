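"""Shared fixtures and independent brute-force oracles.

The oracles evaluate the windowed-statistic definitions directly with
per-window slicing and explicit quadrature weights — no prefix sums — so
they stay independent of the O(n) implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from sleeprr import AudioSignal


def brute_tcw(y: np.ndarray, fs: int, delta: float) -> np.ndarray:
    """Direct per-window evaluation of the sliding-window variance."""
    y = np.asarray(y, dtype=np.float64)
    r = int(round(delta * fs))
    dt = 1.0 / fs
    w_len = (2 * r + 1) * dt
    out = np.empty(y.size - 2 * r)
    for i in range(r, y.size - r):
        win = y[i - r : i + r + 1]
        s1 = win.sum() * dt
        s2 = (win * win).sum() * dt
        out[i - r] = max(s2 - s1 * s1 / w_len, 0.0)
    return out


def simpson_weights(m: int) -> np.ndarray:
    w = np.full(2 * m + 1, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return w


def brute_cmw(
    c: np.ndarray, fs: int, moment_l: float, normalized: bool, eps: float = 1e-12
) -> np.ndarray:
    """Direct per-window Simpson evaluation of the local second moment."""
    c = np.asarray(c, dtype=np.float64)
    m = int(round(moment_l * fs))
    dt = 1.0 / fs
    w = simpson_weights(m) * (dt / 3.0)
    out = np.empty(c.size - 2 * m)
    const_limit = (m * dt) ** 2 / 3.0
    for i in range(m, c.size - m):
        win = c[i - m : i + m + 1]
        tau = (np.arange(i - m, i + m + 1) - i) * dt
        num = float(np.sum(w * tau * tau * win))
        if normalized:
            den = float(np.sum(w * win))
            out[i - m] = const_limit if abs(den) < eps else num / den
        else:
            out[i - m] = num
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_signal(samples, fs: int = 100, start: float = 0.0) -> AudioSignal:
    return AudioSignal(np.asarray(samples, dtype=np.float64), fs, start)
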