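"""Stochastic audio augmentation for cardiac baselines and bubble snippets.

Four transforms are applied to each baseline crop — time-stretch (speed-up
factor 0.8-1.3), pitch-shift (+/-2 semitones), volume gain (+/-10 dB) and a
circular time-shift over the full signal length.  Bubble snippets get a wider
time-stretch (0.8-2.0), the same pitch-shift range, and a +/-15% amplitude
modulation at placement time.  All parameters are drawn uniformly from their
ranges, so a fixed seed reproduces the output bit for bit.

Time-stretch is a classic STFT phase vocoder (magnitude interpolation with
accumulated phase advance), so pitch content survives the duration change;
pitch-shift composes a stretch with a compensating resample.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import istft as _istft
from scipy.signal import resample_poly
from scipy.signal import stft as _stft
from fractions import Fraction

from .audio_core import AudioSignal
from .bubble_library import BubbleSegment

_N_FFT = 1024  # analysis window; shortened automatically for brief snippets


@dataclass(frozen=True)
class CardiacAugmentConfig:
    """Uniform draw ranges for the four baseline transforms."""

    speedup_range: tuple[float, float] = (0.8, 1.3)
    pitch_range: tuple[float, float] = (-2.0, 2.0)   # semitones
    gain_range: tuple[float, float] = (-10.0, 10.0)  # dB
    #: circular-shift draw range in samples; None spans the whole signal
    timeshift_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.speedup_range, self.pitch_range, self.gain_range):
            if lo > hi:
                raise ValueError("range low must not exceed high")
        if self.speedup_range[0] <= 0:
            raise ValueError("speed-up factors must be positive")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        """Draw the stretch/pitch/gain parameters uniformly (shift is drawn
        separately because its range depends on the stretched length)."""
        return {
            "factor": float(rng.uniform(*self.speedup_range)),
            "semitones": float(rng.uniform(*self.pitch_range)),
            "gain_db": float(rng.uniform(*self.gain_range)),
        }


@dataclass(frozen=True)
class BubbleAugmentConfig:
    """Uniform draw ranges for per-bubble transforms."""

    stretch_range: tuple[float, float] = (0.8, 2.0)
    pitch_range: tuple[float, float] = (-2.0, 2.0)  # semitones
    amp_mod: float = 0.15  # multiplicative modulation half-width

    def __post_init__(self) -> None:
        for lo, hi in (self.stretch_range, self.pitch_range):
            if lo > hi:
                raise ValueError("range low must not exceed high")
        if self.stretch_range[0] <= 0:
            raise ValueError("stretch factors must be positive")
        if not (0 <= self.amp_mod < 1):
            raise ValueError("amp_mod must be in [0, 1)")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        return {
            "factor": float(rng.uniform(*self.stretch_range)),
            "semitones": float(rng.uniform(*self.pitch_range)),
        }


def _fit_length(x: np.ndarray, n: int) -> np.ndarray:
    if len(x) >= n:
        return x[:n]
    return np.concatenate([x, np.zeros(n - len(x))])


def time_stretch(signal: AudioSignal, factor: float) -> AudioSignal:
    """Change duration by 1/factor while preserving pitch (phase vocoder).

    ``factor`` is a speed-up: 2.0 halves the duration, 0.8 lengthens it by
    25%.  Output length is exactly ``round(n / factor)`` samples.
    """
    if not (factor > 0):
        raise ValueError(f"stretch factor must be positive, got {factor}")
    x = signal.samples
    n = x.size
    if factor == 1.0 or n == 0:
        return signal
    n_out = max(1, int(round(n / factor)))
    if n < 32:  # too short for spectral processing; plain interpolation
        t_out = np.linspace(0.0, n - 1, n_out)
        return AudioSignal(np.interp(t_out, np.arange(n), x), signal.rate)
    n_fft = min(_N_FFT, 2 ** int(np.floor(np.log2(n))))
    hop = n_fft // 4
    _, _, Z = _stft(x, window="hann", nperseg=n_fft, noverlap=n_fft - hop,
                    boundary="zeros", padded=True)
    n_bins, n_frames = Z.shape
    steps = np.arange(0.0, n_frames, factor)
    # expected per-hop phase advance of each bin center
    omega = np.linspace(0.0, np.pi * hop, n_bins)
    Z = np.concatenate([Z, np.zeros((n_bins, 1), dtype=Z.dtype)], axis=1)
    mags = np.abs(Z)
    phases = np.angle(Z)
    out = np.empty((n_bins, len(steps)), dtype=Z.dtype)
    phase_acc = phases[:, 0].copy()
    for i, step in enumerate(steps):
        idx = int(step)
        frac = step - idx
        mag = (1.0 - frac) * mags[:, idx] + frac * mags[:, idx + 1]
        out[:, i] = mag * np.exp(1j * phase_acc)
        dphi = phases[:, idx + 1] - phases[:, idx] - omega
        dphi -= 2.0 * np.pi * np.round(dphi / (2.0 * np.pi))
        phase_acc += omega + dphi
    _, y = _istft(out, window="hann", nperseg=n_fft, noverlap=n_fft - hop,
                  input_onesided=True, boundary=True)
    return AudioSignal(_fit_length(np.asarray(y), n_out), signal.rate)


def pitch_shift(signal: AudioSignal, semitones: float) -> AudioSignal:
    """Scale all frequencies by 2^(semitones/12) at unchanged duration."""
    if abs(semitones) > 12:
        raise ValueError("pitch shift limited to +/-12 semitones")
    if semitones == 0 or signal.n_samples == 0:
        return signal
    ratio = 2.0 ** (semitones / 12.0)
    stretched = time_stretch(signal, 1.0 / ratio)  # longer/shorter, same pitch
    frac = Fraction(1.0 / ratio).limit_denominator(1000)
    y = resample_poly(stretched.samples, frac.numerator, frac.denominator)
    return AudioSignal(_fit_length(y, signal.n_samples), signal.rate)


def apply_gain(signal: AudioSignal, gain_db: float) -> AudioSignal:
    """Multiply samples by 10^(gain_db/20)."""
    if gain_db == 0:
        return signal
    return AudioSignal(signal.samples * 10.0 ** (gain_db / 20.0), signal.rate)


def time_shift(signal: AudioSignal, offset: int) -> AudioSignal:
    """Circular rotation by ``offset`` samples (no silence padding)."""
    if signal.n_samples == 0 or offset % signal.n_samples == 0:
        return signal
    return AudioSignal(np.roll(signal.samples, offset), signal.rate)


def augment_cardiac(signal: AudioSignal, config: CardiacAugmentConfig,
                    rng: np.random.Generator) -> AudioSignal:
    """Apply stretch -> pitch -> gain -> circular shift with uniform draws."""
    if signal.n_samples == 0:
        raise ValueError("cannot augment an empty signal")
    params = config.draw(rng)
    out = time_stretch(signal, params["factor"])
    out = pitch_shift(out, params["semitones"])
    out = apply_gain(out, params["gain_db"])
    if config.timeshift_range is None:
        offset = int(rng.integers(0, out.n_samples))
    else:
        lo, hi = config.timeshift_range
        offset = int(rng.integers(lo, hi + 1))
    return time_shift(out, offset)


def augment_bubble(segment: BubbleSegment, config: BubbleAugmentConfig,
                   rng: np.random.Generator) -> BubbleSegment:
    """Stretch and pitch-shift one bubble snippet; duration metadata follows."""
    params = config.draw(rng)
    audio = pitch_shift(time_stretch(segment.audio, params["factor"]),
                        params["semitones"])
    return replace(segment, audio=audio,
                   duration=audio.n_samples / audio.rate)


def modulate_amplitude(segment: BubbleSegment, rng: np.random.Generator,
                       half_width: float = 0.15) -> BubbleSegment:
    """Multiply by a factor drawn uniformly from [1-half_width, 1+half_width]."""
    factor = float(rng.uniform(1.0 - half_width, 1.0 + half_width))
    audio = AudioSignal(segment.audio.samples * factor, segment.audio.rate)
    return replace(segment, audio=audio)
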