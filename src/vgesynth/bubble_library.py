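"""Segmentation of single-bubble events from laboratory Doppler recordings
and the bubble pool sampled during generation.

A gas bubble passing through the ultrasound beam produces a short "chirp"
transient.  Each event is cut out of the recording at the full width of its
envelope peak at 20% of the peak maximum (FW20%M); anything wider than 0.5 s
is discarded as a non-single-bubble artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .audio_core import AudioSignal, envelope, read_wav
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

#: Segments whose FW20%M extent exceeds this duration are dropped (seconds).
MAX_SEGMENT_DURATION = 0.5

#: Fraction of the peak height at which segment boundaries are taken.
FW_FRACTION = 0.2

#: Default peak-detection parameters for bubble recordings.  The source
#: recordings contain audibly separable events, so a coarse global height
#: threshold and a 50 ms refractory distance suffice; both are configurable.
DEFAULT_MIN_PEAK_HEIGHT = 0.2
DEFAULT_MIN_PEAK_SEPARATION = 0.05


@dataclass(frozen=True, eq=False)
class BubbleSegment:
    """One segmented single-bubble snippet."""

    audio: AudioSignal
    duration: float
    source_id: str = ""
    peak_index: int = 0
    #: start of the segment within its source recording (samples)
    start_index: int = 0

    def __post_init__(self) -> None:
        if self.audio.n_samples == 0:
            raise ValueError("bubble segment audio must be non-empty")


@dataclass(frozen=True, eq=False)
class BubbleLibrary:
    """Pool of bubble snippets sampled (with replacement) during generation."""

    segments: tuple[BubbleSegment, ...]
    average_bubble_length: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise DegenerateInputError("bubble library must be non-empty")
        object.__setattr__(self, "segments", tuple(self.segments))
        mean = float(np.mean([s.duration for s in self.segments]))
        object.__setattr__(self, "average_bubble_length", mean)

    def __len__(self) -> int:
        return len(self.segments)


def segment_bubbles(recording: AudioSignal,
                    min_peak_height: float = DEFAULT_MIN_PEAK_HEIGHT,
                    min_peak_separation: float = DEFAULT_MIN_PEAK_SEPARATION,
                    source_id: str = "") -> list[BubbleSegment]:
    """Cut single-bubble events out of a recording at their FW20%M extents.

    Peak detection runs on the envelope; each retained peak yields the
    contiguous region around it where the envelope stays at or above 20% of
    that peak's height.  The search is bounded by the envelope minima toward
    neighboring peaks so adjacent bubbles never merge.  Segments longer than
    0.5 s are removed.  A silent recording yields an empty list.
    """
    if recording.n_samples == 0:
        raise DegenerateInputError("cannot segment an empty recording")
    env = envelope(recording).values
    global_max = float(env.max())
    if global_max == 0.0:
        return []
    distance = max(1, int(round(min_peak_separation * recording.rate)))
    peaks, _ = find_peaks(env, height=min_peak_height * global_max,
                          distance=distance)
    segments: list[BubbleSegment] = []
    for i, peak in enumerate(peaks):
        # bound the width search at the envelope minimum toward each neighbor
        lo = 0 if i == 0 else peaks[i - 1] + int(np.argmin(env[peaks[i - 1]:peak]))
        hi = (len(env) - 1 if i == len(peaks) - 1
              else peak + int(np.argmin(env[peak:peaks[i + 1]])))
        threshold = FW_FRACTION * env[peak]
        start = peak
        while start > lo and env[start - 1] >= threshold:
            start -= 1
        end = peak
        while end < hi and env[end + 1] >= threshold:
            end += 1
        duration = (end - start + 1) / recording.rate
        if duration > MAX_SEGMENT_DURATION:
            logger.debug("dropping %.3f s segment at %d (> %.1f s)",
                         duration, peak, MAX_SEGMENT_DURATION)
            continue
        audio = AudioSignal(recording.samples[start:end + 1], recording.rate)
        segments.append(BubbleSegment(audio, duration, source_id,
                                      peak_index=int(peak),
                                      start_index=int(start)))
    return segments


def build_library(segments: list[BubbleSegment]) -> BubbleLibrary:
    """Assemble segments into a sampling pool; the mean segment duration
    feeds the rolling/continuous bubble-count cap."""
    if not segments:
        raise DegenerateInputError("cannot build a library from zero segments")
    return BubbleLibrary(tuple(segments))


def sample_bubble(library: BubbleLibrary,
                  rng: np.random.Generator) -> BubbleSegment:
    """Uniform draw with replacement from the pool."""
    return library.segments[int(rng.integers(len(library)))]


def segment_directory(directory: str | Path,
                      min_peak_height: float = DEFAULT_MIN_PEAK_HEIGHT,
                      min_peak_separation: float = DEFAULT_MIN_PEAK_SEPARATION,
                      ) -> tuple[list[BubbleSegment], pd.DataFrame]:
    """Segment every WAV file in a directory.

    Returns the segments plus a manifest table with one row per retained
    segment (source_id, start_s, end_s, duration_s).  Stereo recordings keep
    only the Doppler channel.
    """
    from .audio_core import select_doppler_channel

    directory = Path(directory)
    segments: list[BubbleSegment] = []
    rows = []
    for path in sorted(directory.glob("*.wav")):
        recording = select_doppler_channel(read_wav(path))
        found = segment_bubbles(recording, min_peak_height,
                                min_peak_separation, source_id=path.stem)
        for seg in found:
            start_s = seg.start_index / recording.rate
            rows.append({"source_id": seg.source_id, "start_s": start_s,
                         "end_s": start_s + seg.duration,
                         "duration_s": seg.duration})
        segments.extend(found)
        logger.info("%s: %d segments", path.name, len(found))
    manifest = pd.DataFrame(rows, columns=["source_id", "start_s", "end_s",
                                           "duration_s"])
    return segments, manifest
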