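"""Programmatic synthesis of cardiac-like baselines and bubble-like chirps.

Real precordial and subclavian Doppler baselines are human recordings that
cannot ship with the package; these fixtures reproduce the *statistical
structure* the pipeline relies on — a periodic two-burst (S1/S2-like)
amplitude envelope over band-limited noise for the cardiac signal, and short
decaying tone bursts for single bubbles — without claiming acoustic fidelity.
Every fixture is deterministic in its seed and its ground truth (beat times,
injected event times and widths) is known exactly by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_core import DEFAULT_RATE, AudioSignal, write_wav
from .bubble_library import BubbleLibrary, BubbleSegment, build_library

#: S2 burst sits this far into the cycle, as a fraction of the period.
_S2_PHASE = 0.33
#: S2 amplitude relative to S1.
_S2_LEVEL = 0.55
#: Envelope floor relative to S1: precordial bursts tower over the trough,
#: subclavian bursts ride on continuous venous flow noise.
_FLOOR = {"precordial": 0.08, "subclavian": 0.60}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic cardiac baseline."""

    style: Literal["precordial", "subclavian"] = "precordial"
    heart_rate_bpm: float = 72.0
    duration: float = 30.0
    snr_db: float = 30.0
    rate: float = DEFAULT_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.style not in _FLOOR:
            raise ValueError(f"unknown style {self.style!r}")
        if not (40.0 <= self.heart_rate_bpm <= 180.0):
            raise ValueError("heart rate must be 40-180 bpm, "
                             f"got {self.heart_rate_bpm}")
        if self.duration < 2.0:
            raise ValueError(f"duration must be >= 2 s, got {self.duration}")

    @property
    def period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    def beat_times(self) -> np.ndarray:
        """Exact S1 burst centers (seconds)."""
        t0 = 0.5 * self.period_s
        return np.arange(t0, self.duration, self.period_s)


def _bandlimited_noise(n: int, rate: float, rng: np.random.Generator,
                       low: float = 200.0, high: float = 2000.0) -> np.ndarray:
    high = min(high, 0.45 * rate)
    sos = butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


def synth_cardiac_baseline(spec: FixtureSpec,
                           rng: np.random.Generator | None = None,
                           ) -> AudioSignal:
    """Synthesize one cardiac-like Doppler baseline.

    Band-limited noise (200-2000 Hz) is amplitude-modulated by a periodic
    envelope carrying an S1-like and a weaker S2-like Gaussian burst per
    cycle over a style-dependent floor, then buried under white noise at the
    spec's SNR.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    env = np.full(n, _FLOOR[spec.style])
    sigma_s1 = 0.030  # seconds
    sigma_s2 = 0.025
    for beat in spec.beat_times():
        env += np.exp(-0.5 * ((t - beat) / sigma_s1) ** 2)
        env += _S2_LEVEL * np.exp(
            -0.5 * ((t - beat - _S2_PHASE * spec.period_s) / sigma_s2) ** 2)
    carrier = _bandlimited_noise(n, spec.rate, rng)
    signal = env * carrier
    noise_rms = np.std(signal) * 10.0 ** (-spec.snr_db / 20.0)
    signal = signal + noise_rms * rng.standard_normal(n)
    peak = np.max(np.abs(signal))
    return AudioSignal(0.9 * signal / peak, spec.rate)


def _chirp(fw20_duration: float, center_freq: float, rate: float,
           phase: float = 0.0) -> np.ndarray:
    """Decaying tone burst whose envelope FW20%M equals ``fw20_duration``.

    A short linear attack is followed by an exponential decay tuned so the
    envelope crosses 20% of its peak at ``fw20_duration``; a mild downward
    frequency glide mimics the Doppler shift of a bubble leaving the beam.
    """
    total = 1.4 * fw20_duration
    n = max(8, int(round(total * rate)))
    t = np.arange(n) / rate
    attack = 0.1 * fw20_duration
    tau = (fw20_duration - attack) / np.log(5.0)  # env(fw20) = 0.2
    env = np.where(t < attack, t / attack, np.exp(-(t - attack) / tau))
    freq = center_freq * (1.0 - 0.15 * t / total)  # mild glide
    return env * np.sin(2.0 * np.pi * np.cumsum(freq) / rate + phase)


def synth_bubble_chirp(duration: float, center_freq: float = 2000.0,
                       rng: np.random.Generator | None = None,
                       rate: float = DEFAULT_RATE) -> BubbleSegment:
    """One bubble-like chirp whose envelope FW20%M is ``duration`` seconds."""
    if not (0.005 <= duration <= 0.3):
        raise ValueError(f"chirp duration must be 0.005-0.3 s, got {duration}")
    phase = float(rng.uniform(0, 2 * np.pi)) if rng is not None else 0.0
    samples = _chirp(duration, center_freq, rate, phase)
    audio = AudioSignal(samples, rate)
    return BubbleSegment(audio, audio.duration, source_id="synth_chirp")


def default_bubble_library(rng: np.random.Generator,
                           n: int = 20,
                           rate: float = DEFAULT_RATE) -> BubbleLibrary:
    """A pool of chirps spanning realistic single-bubble widths and pitches."""
    segments = [
        synth_bubble_chirp(float(rng.uniform(0.03, 0.25)),
                           float(rng.uniform(800.0, 3000.0)), rng, rate)
        for _ in range(n)
    ]
    return build_library(segments)


def make_known_answer_recording(rate: float = DEFAULT_RATE,
                                fw20_durations: tuple[float, ...] = (0.1, 0.3, 0.6),
                                gap: float = 1.5,
                                ) -> tuple[AudioSignal, list[dict]]:
    """A silent track with injected chirps of known FW20%M widths.

    Events wider than the 0.5 s segmentation filter are included on purpose
    so the duration filter has something to reject.  Returns the recording
    and a truth list of ``{"time_s", "fw20_s"}`` per event.
    """
    total = gap * (len(fw20_durations) + 1)
    samples = np.zeros(int(round(total * rate)))
    truth = []
    for k, width in enumerate(fw20_durations):
        start = int(round((gap * (k + 1) - width / 2) * rate))
        burst = _chirp(width, 1500.0, rate)
        samples[start:start + len(burst)] += burst
        truth.append({"time_s": start / rate, "fw20_s": width})
    return AudioSignal(samples, rate), truth


def make_fixture_set(seed: int, out_dir: str | Path,
                     rate: float = DEFAULT_RATE) -> dict:
    """Write a deterministic directory of fixture WAVs plus truth JSON.

    Contents: three cardiac baselines (two precordial heart rates, one
    subclavian), a bubble recording with randomly spaced chirps at recorded
    times, and the known-answer filter recording with FW20%M widths
    {0.1, 0.3, 0.6} s.  Returns the truth dictionary (also written to
    ``truth.json``).
    """
    out_dir = Path(out_dir)
    (out_dir / "baselines").mkdir(parents=True, exist_ok=True)
    (out_dir / "bubbles").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth: dict = {"baselines": {}, "bubbles": {}}

    specs = [
        FixtureSpec("precordial", 72.0, rate=rate, seed=seed),
        FixtureSpec("precordial", 60.0, rate=rate, seed=seed + 1),
        FixtureSpec("subclavian", 72.0, rate=rate, seed=seed + 2),
    ]
    for spec in specs:
        name = f"{spec.style}_{int(spec.heart_rate_bpm)}bpm.wav"
        write_wav(synth_cardiac_baseline(spec), out_dir / "baselines" / name)
        truth["baselines"][name] = {
            "style": spec.style,
            "heart_rate_bpm": spec.heart_rate_bpm,
            "beat_times_s": spec.beat_times().tolist(),
        }

    # randomly spaced, well-separated chirp train with recorded event times
    n_events = 20
    events = []
    samples = np.zeros(int(round(rate * (n_events + 1) * 0.8)))
    position = 0.6
    for _ in range(n_events):
        width = float(rng.uniform(0.03, 0.25))
        freq = float(rng.uniform(800.0, 3000.0))
        start = int(round(position * rate))
        burst = float(rng.uniform(0.4, 1.0)) * _chirp(width, freq, rate)
        samples[start:start + len(burst)] += burst
        events.append({"time_s": start / rate, "fw20_s": width})
        position += 0.8
    write_wav(AudioSignal(samples, rate), out_dir / "bubbles" / "bubbles.wav")
    truth["bubbles"]["bubbles.wav"] = events

    known, known_truth = make_known_answer_recording(rate)
    write_wav(known, out_dir / "bubbles" / "filter_fixture.wav")
    truth["bubbles"]["filter_fixture.wav"] = known_truth

    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
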