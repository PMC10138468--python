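"""Cardiac-cycle detection and bubble-placement windows.

The heart period is estimated from the autocorrelation of the normalized
amplitude envelope, searched over the physiological band 40-180 bpm.  Cycle
peaks are then local envelope maxima at least 0.7 periods apart and at least
30% of the envelope maximum high.  A cardiac cycle is the span between two
consecutive peaks; only these interior cycles receive bubbles.

Two placement-window modes exist: *full* windows admit a bubble anywhere
peak-to-peak, while *partial* windows (precordial data only) restrict
placement to the samples where the cycle-local envelope sits strictly below
50% of that cycle's maximum, i.e. the quiet gaps between heart sounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .audio_core import Envelope
from .errors import CycleDetectionError

#: Physiological heart-rate search band (bpm) for the autocorrelation lag.
MIN_BPM = 40.0
MAX_BPM = 180.0

#: Peak-detection defaults: minimum height as a fraction of the envelope
#: maximum, minimum separation as a fraction of the estimated period.
PEAK_HEIGHT_FRACTION = 0.3
PEAK_DISTANCE_FRACTION = 0.7

#: Partial windows keep samples strictly below this fraction of the
#: cycle-local envelope maximum.
PARTIAL_THRESHOLD = 0.5

WindowMode = Literal["full", "partial"]


@dataclass(frozen=True, eq=False)
class CycleWindows:
    """Detected cycle peaks plus admissible placement intervals per cycle.

    ``windows[i]`` lists half-open ``(start, stop)`` sample intervals inside
    the i-th interior cycle (between ``peak_indices[i]`` and
    ``peak_indices[i+1]``).  In partial mode a cycle with no sample below
    threshold carries an empty list and is excluded from placement.
    """

    peak_indices: np.ndarray
    period_s: float
    windows: tuple[tuple[tuple[int, int], ...], ...]
    mode: WindowMode
    rate: float

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peak_indices, dtype=np.int64)
        if np.any(np.diff(peaks) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "peak_indices", peaks)
        for i, cycle in enumerate(self.windows):
            lo, hi = peaks[i], peaks[i + 1]
            for start, stop in cycle:
                if not (lo <= start < stop <= hi):
                    raise ValueError(
                        f"window [{start},{stop}) escapes cycle [{lo},{hi})")

    @property
    def n_cycles(self) -> int:
        return len(self.windows)


def estimate_heart_period(env: Envelope) -> float:
    """Heart period (s) from the dominant autocorrelation lag in 40-180 bpm.

    Needs at least 2 s of audio so the longest admissible period fits the
    lag range.  Raises :class:`CycleDetectionError` when no autocorrelation
    peak falls inside the band.
    """
    n = len(env.values)
    if n / env.rate < 2.0:
        raise CycleDetectionError("need at least 2 s of audio to estimate "
                                  "the heart period")
    x = env.values - env.values.mean()
    if not np.any(x):
        raise CycleDetectionError("flat envelope: no periodicity to estimate")
    # FFT autocorrelation, positive lags only
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    lag_min = int(np.ceil(env.rate * 60.0 / MAX_BPM))
    lag_max = int(np.floor(env.rate * 60.0 / MIN_BPM))
    lag_max = min(lag_max, n - 1)
    if lag_min >= lag_max:
        raise CycleDetectionError("signal too short for the heart-rate band")
    band = acf[lag_min:lag_max + 1]
    peaks, _ = find_peaks(band)
    if len(peaks) == 0 or band.max() <= 0:
        raise CycleDetectionError("no autocorrelation peak in 40-180 bpm")
    best = peaks[np.argmax(band[peaks])]
    return float((lag_min + best) / env.rate)


def detect_cycle_peaks(env: Envelope, period_s: float,
                       height_fraction: float = PEAK_HEIGHT_FRACTION,
                       distance_fraction: float = PEAK_DISTANCE_FRACTION,
                       ) -> np.ndarray:
    """Locate one envelope peak per heartbeat.

    Local maxima of the envelope with height >= ``height_fraction`` of the
    envelope maximum and separation >= ``distance_fraction`` x period.
    Raises :class:`CycleDetectionError` with fewer than 2 peaks (no interior
    cycle exists).
    """
    values = env.values
    peak = values.max()
    if peak <= 0:
        raise CycleDetectionError("flat envelope: no cycle peaks")
    distance = max(1, int(round(distance_fraction * period_s * env.rate)))
    peaks, _ = find_peaks(values, height=height_fraction * peak,
                          distance=distance)
    if len(peaks) < 2:
        raise CycleDetectionError(
            f"found {len(peaks)} cycle peak(s); need at least 2")
    return peaks.astype(np.int64)


def build_windows(peaks: np.ndarray, env: Envelope,
                  mode: WindowMode = "full") -> CycleWindows:
    """Build per-cycle placement windows between consecutive peaks.

    Full mode yields one peak-to-peak interval per cycle.  Partial mode keeps
    the maximal runs of samples where the cycle-local envelope is strictly
    below 50% of that cycle's maximum (boundary samples at exactly 50% are
    excluded).
    """
    peaks = np.asarray(peaks, dtype=np.int64)
    if len(peaks) < 2:
        raise CycleDetectionError("need at least 2 peaks to define a cycle")
    if mode not in ("full", "partial"):
        raise ValueError(f"unknown window mode {mode!r}")
    period_s = float(np.median(np.diff(peaks)) / env.rate)
    cycles: list[tuple[tuple[int, int], ...]] = []
    for lo, hi in zip(peaks[:-1], peaks[1:]):
        if mode == "full":
            cycles.append(((int(lo), int(hi)),))
            continue
        segment = env.values[lo:hi]
        admissible = segment < PARTIAL_THRESHOLD * segment.max()
        # maximal runs of admissible samples
        edges = np.flatnonzero(np.diff(np.concatenate(
            ([False], admissible, [False])).astype(np.int8)))
        runs = tuple((int(lo + edges[k]), int(lo + edges[k + 1]))
                     for k in range(0, len(edges), 2))
        cycles.append(runs)
    return CycleWindows(peaks, period_s, tuple(cycles), mode, env.rate)
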