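"""Audio signal container, WAV I/O, resampling, envelope detection and
channel selection.

Doppler ultrasound audio is handled throughout as a 1-D float sequence with
nominal full scale +/-1 plus a sampling rate in Hz.  Baseline recordings from
clinical scanners arrive as stereo WAV files in which one channel carries
voice annotations and the other the Doppler signal; :func:`select_doppler_channel`
keeps the channel with the greater mean envelope energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d
from scipy.signal import hilbert, resample_poly

from .errors import AudioFormatError, DegenerateInputError

logger = logging.getLogger(__name__)

#: Default moving-average smoothing applied to the analytic-signal magnitude.
ENVELOPE_SMOOTH_MS = 20.0

#: Default working sample rate for generation (Hz).
DEFAULT_RATE = 8000


@dataclass(frozen=True, eq=False)
class AudioSignal:
    """A sampled audio signal.

    ``samples`` is 1-D for mono audio, or 2-D with shape
    ``(n_channels, n_samples)`` for multichannel recordings straight off disk.
    All amplitudes are dimensionless with nominal full scale +/-1.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim not in (1, 2):
            raise ValueError(f"samples must be 1-D or 2-D, got ndim={arr.ndim}")
        if not (self.rate > 0):
            raise ValueError(f"rate must be positive, got {self.rate}")
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("samples contain NaN or Inf")
        object.__setattr__(self, "samples", arr)

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.rate

    def channel(self, index: int) -> "AudioSignal":
        if self.samples.ndim == 1:
            if index != 0:
                raise IndexError("mono signal has only channel 0")
            return self
        return AudioSignal(self.samples[index], self.rate)


@dataclass(frozen=True, eq=False)
class Envelope:
    """Non-negative amplitude envelope aligned 1:1 with its source signal."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError("envelope must be 1-D")
        if arr.size and arr.min() < 0:
            raise ValueError("envelope values must be non-negative")
        object.__setattr__(self, "values", arr)


def read_wav(path: str | Path) -> AudioSignal:
    """Read a PCM or float WAV file, preserving all channels and native rate.

    Integer PCM samples are rescaled to [-1, 1].  Raises
    :class:`AudioFormatError` naming the path for anything unreadable.
    """
    path = Path(path)
    if not path.exists():
        raise AudioFormatError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on junk input
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"WAV file {path} contains no samples")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float32/float64 WAV already at full scale +/-1
        samples = data.astype(np.float64)
    if samples.ndim == 2:  # scipy gives (n_samples, n_channels)
        samples = samples.T
    return AudioSignal(samples, float(rate))


def write_wav(signal: AudioSignal, path: str | Path) -> None:
    """Write a signal as 16-bit PCM WAV at its own rate.

    Samples outside [-1, 1] are hard-clipped with a logged warning: track
    summation can exceed full scale.
    """
    path = Path(path)
    x = signal.samples
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    if peak > 1.0:
        logger.warning("clipping %d samples above full scale (peak %.3f) in %s",
                       int(np.sum(np.abs(x) > 1.0)), peak, path.name)
        x = np.clip(x, -1.0, 1.0)
    quantized = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    if quantized.ndim == 2:
        quantized = quantized.T
    try:
        wavfile.write(str(path), int(round(signal.rate)), quantized)
    except OSError as exc:
        raise AudioFormatError(f"cannot write WAV file {path}: {exc}") from exc


def resample(signal: AudioSignal, target_rate: float) -> AudioSignal:
    """Polyphase resampling to ``target_rate``, preserving duration within
    one output sample period."""
    if not (target_rate > 0):
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == signal.rate:
        return signal
    ratio = Fraction(target_rate).limit_denominator(10**6) / \
        Fraction(signal.rate).limit_denominator(10**6)
    out = resample_poly(signal.samples, ratio.numerator, ratio.denominator,
                        axis=-1)
    return AudioSignal(out, float(target_rate))


def envelope(signal: AudioSignal,
             smooth_ms: float | None = ENVELOPE_SMOOTH_MS) -> Envelope:
    """Amplitude envelope as the magnitude of the analytic (Hilbert) signal,
    smoothed by a short moving average.

    The moving average (default 20 ms) suppresses the carrier ripple that the
    raw analytic magnitude retains for narrow-band Doppler audio; pass
    ``smooth_ms=None`` for the raw magnitude.
    """
    if signal.n_samples == 0:
        raise DegenerateInputError("cannot take the envelope of an empty signal")
    if signal.samples.ndim != 1:
        raise ValueError("envelope expects a mono signal")
    mag = np.abs(hilbert(signal.samples))
    if smooth_ms:
        width = max(1, int(round(signal.rate * smooth_ms / 1000.0)))
        mag = uniform_filter1d(mag, size=width, mode="nearest")
    return Envelope(np.maximum(mag, 0.0), signal.rate)


def normalize(signal: AudioSignal) -> AudioSignal:
    """Scale so that the maximum absolute sample is exactly 1."""
    if signal.n_samples == 0:
        raise DegenerateInputError("cannot normalize an empty signal")
    peak = float(np.max(np.abs(signal.samples)))
    if peak == 0.0:
        raise DegenerateInputError("cannot normalize an all-zero signal")
    if peak == 1.0:
        return signal
    return AudioSignal(signal.samples / peak, signal.rate)


def select_doppler_channel(signal: AudioSignal) -> AudioSignal:
    """Keep the channel with the greatest mean envelope energy.

    Annotated baseline recordings carry voice markers on one stereo channel
    and the Doppler signal on the other; the Doppler channel has by far the
    larger mean envelope.  Mono input is returned unchanged with a logged
    note; ties keep channel 0.
    """
    if signal.n_channels == 1:
        logger.info("select_doppler_channel: mono input, returned unchanged")
        return signal if signal.samples.ndim == 1 else signal.channel(0)
    means = [float(np.mean(envelope(signal.channel(c)).values))
             for c in range(signal.n_channels)]
    best = int(np.argmax(means))  # argmax keeps the first index on ties
    return signal.channel(best)
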