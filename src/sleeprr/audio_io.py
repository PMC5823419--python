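"""WAV reading/writing, resampling and amplitude normalization.

The detection pipeline works on an energy envelope over 0.1–3 s time
scales, so recordings made at 44.1 kHz are decimated to a working rate
(default 4 kHz) before any windowed statistic is computed.  All
downstream modules consume the :class:`AudioSignal` container defined
here; sample ``i`` corresponds to time ``start_time + i / sample_rate``
and every reported time is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = ["AudioSignal", "read_wav", "write_wav", "downsample", "normalize_amplitude"]

#: Default working sample rate (Hz) for envelope analysis.
DEFAULT_WORKING_RATE = 4000


@dataclass(frozen=True)
class AudioSignal:
    """Uniformly sampled mono amplitude sequence.

    Parameters
    ----------
    samples
        Dimensionless amplitudes, nominally in ``[-1, 1]``.
    sample_rate
        Sampling frequency in Hz (positive).
    start_time
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    sample_rate: int
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal holds mono audio (1-D sample array)")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, one entry per sample."""
        return self.start_time + np.arange(self.samples.size) / self.sample_rate


# integer PCM full-scale divisors accepted on read
_PCM_SCALE = {
    np.dtype(np.int16): 2 ** 15,
    np.dtype(np.int32): 2 ** 31,
}


def read_wav(path: str | Path) -> AudioSignal:
    """Read a RIFF/WAV file as a mono :class:`AudioSignal` scaled to [-1, 1].

    PCM16, PCM32 and float32/float64 encodings are accepted; unsigned 8-bit
    PCM is mapped through its midpoint.  Multichannel files are averaged
    down to mono (the acquisition device is a single microphone, so channel
    averaging is the least surprising reduction).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise ValueError(f"not a readable WAV file: {path}: {exc}") from exc
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:  # float32 / float64 WAV stores amplitudes directly
        samples = data.astype(np.float64)
    return AudioSignal(samples, int(rate))


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write an :class:`AudioSignal` as a float32 WAV file (lossless
    round-trip apart from float64→float32 quantization)."""
    wavfile.write(Path(path), signal.sample_rate, signal.samples.astype(np.float32))


def downsample(signal: AudioSignal, target_rate: int = DEFAULT_WORKING_RATE) -> AudioSignal:
    """Anti-alias filter and resample to ``target_rate``.

    Uses polyphase resampling (:func:`scipy.signal.resample_poly`), which
    preserves DC exactly away from the filter transient and keeps the
    duration within one output sample period.
    """
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate > signal.sample_rate:
        raise ValueError(
            f"target_rate {target_rate} exceeds source rate {signal.sample_rate}"
        )
    if target_rate == signal.sample_rate:
        return signal
    frac = Fraction(int(target_rate), int(signal.sample_rate))
    out = resample_poly(signal.samples, frac.numerator, frac.denominator)
    return AudioSignal(out, int(target_rate), signal.start_time)


def normalize_amplitude(signal: AudioSignal) -> AudioSignal:
    """Scale samples so the maximum absolute value is 1.

    An all-zero signal is returned unchanged; the operation is idempotent.
    """
    peak = np.max(np.abs(signal.samples)) if signal.samples.size else 0.0
    if peak == 0.0:
        return signal
    return replace(signal, samples=signal.samples / peak)
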