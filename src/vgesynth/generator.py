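"""Synthesis of one graded recording: crop, augment, detect cycles, place
bubbles, mix, crop, and emit the triplet with exact ground truth.

Each synthetic recording is built from a baseline crop 50% longer than the
requested clip, augmented, and analyzed for cardiac cycles.  A Kisman-Masurel
code then drives placement: the second digit fixes how many cycles receive
bubbles, the first digit how many bubbles each selected cycle gets, and the
third digit the relative bubble amplitude.  The bubble-only track is summed
with the cardiac-only track, and all three are center-cropped to the clip
length.  The ground truth records every placement exactly, including any
that end up in the discarded crop buffer (their times can fall outside
[0, clip_length]).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import resample as _fourier_resample

from . import augmentation, grading
from .audio_core import DEFAULT_RATE, AudioSignal, Envelope, envelope, \
    normalize, resample, write_wav
from .augmentation import BubbleAugmentConfig, CardiacAugmentConfig
from .bubble_library import BubbleLibrary, sample_bubble
from .cardiac_cycles import CycleWindows, build_windows, detect_cycle_peaks, \
    estimate_heart_period
from .errors import ConfigError, CycleDetectionError, DegenerateInputError
from .grading import KMGrade, PGamma, compute_p_gamma, km_to_spencer, \
    list_valid_km, sample_amplitude, sample_bubble_count, sample_cycle_count

logger = logging.getLogger(__name__)

#: case -> (measurement site, grading scale, placement-window mode)
CASE_TABLE: dict[int, tuple[str, str, str]] = {
    1: ("precordial", "spencer", "full"),
    2: ("subclavian", "spencer", "full"),
    3: ("precordial", "km", "full"),
    4: ("subclavian", "km", "full"),
    5: ("precordial", "spencer", "partial"),
    6: ("precordial", "km", "partial"),
}

#: times placed bubbles are re-drawn before falling back to compression
MAX_PLACEMENT_RETRIES = 10
#: times a fresh baseline crop is tried after a cycle-detection failure
MAX_CROP_RETRIES = 5


@dataclass(frozen=True)
class GenerationConfig:
    """Everything needed to generate one case's recordings."""

    case: int = 1
    clip_length: float = 10.0
    sample_rate: float = DEFAULT_RATE
    noise_sigma: float = 0.001  # Gaussian noise floor std, full-scale units
    noise_full_track: bool = False  # noise over whole track vs selected cycles
    seed: int = 0
    cardiac_aug: CardiacAugmentConfig = field(default_factory=CardiacAugmentConfig)
    bubble_aug: BubbleAugmentConfig = field(default_factory=BubbleAugmentConfig)

    def __post_init__(self) -> None:
        if self.case not in CASE_TABLE:
            raise ConfigError(f"case must be 1-6, got {self.case}")
        if not (self.clip_length > 0):
            raise ConfigError("clip_length must be positive")
        if not (self.sample_rate > 0):
            raise ConfigError("sample_rate must be positive")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be non-negative")

    @property
    def style(self) -> str:
        return CASE_TABLE[self.case][0]

    @property
    def scale(self) -> str:
        return CASE_TABLE[self.case][1]

    @property
    def window_mode(self) -> str:
        return CASE_TABLE[self.case][2]

    @property
    def class_labels(self) -> list[str]:
        if self.scale == "spencer":
            return [f"spencer{g}" for g in range(5)]
        return [f"km{code}" for code in map(str, list_valid_km())]


@dataclass(frozen=True)
class PlacedBubble:
    """Ground truth for one placed bubble (times relative to the final crop)."""

    cycle_index: int
    start_s: float
    duration_s: float
    amplitude_scale: float
    source_id: str


@dataclass(frozen=True)
class GroundTruth:
    """Exact record of every bubble placement in one recording."""

    km_code: str
    spencer_grade: int
    period_s: float
    peak_times_s: tuple[float, ...]
    n_interior_cycles: int
    selected_cycles: tuple[int, ...]
    bubbles: tuple[PlacedBubble, ...]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruth":
        bubbles = tuple(PlacedBubble(**b) for b in data["bubbles"])
        return cls(km_code=data["km_code"],
                   spencer_grade=data["spencer_grade"],
                   period_s=data["period_s"],
                   peak_times_s=tuple(data["peak_times_s"]),
                   n_interior_cycles=data["n_interior_cycles"],
                   selected_cycles=tuple(data["selected_cycles"]),
                   bubbles=bubbles)

    def cycles_with_bubbles(self) -> set[int]:
        return {b.cycle_index for b in self.bubbles}

    def bubbles_per_cycle(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for b in self.bubbles:
            counts[b.cycle_index] = counts.get(b.cycle_index, 0) + 1
        return counts


@dataclass(frozen=True, eq=False)
class SyntheticRecording:
    """Cardiac-only, bubble-only and combined tracks plus ground truth."""

    cardiac: AudioSignal
    bubbles: AudioSignal
    combined: AudioSignal
    truth: GroundTruth

    def __post_init__(self) -> None:
        n = self.cardiac.n_samples
        if self.bubbles.n_samples != n or self.combined.n_samples != n:
            raise ValueError("tracks must have equal lengths")


def crop_with_buffer(baseline: AudioSignal, clip_length: float,
                     rng: np.random.Generator) -> AudioSignal:
    """Random contiguous crop of 1.5 x clip_length from the baseline.

    The 50% buffer absorbs the later time-stretch and center crop.
    """
    n_req = int(round(1.5 * clip_length * baseline.rate))
    if baseline.n_samples < n_req:
        raise DegenerateInputError(
            f"baseline is {baseline.duration:.2f} s; need at least "
            f"{1.5 * clip_length:.2f} s (1.5 x clip length)")
    offset = int(rng.integers(0, baseline.n_samples - n_req + 1))
    return AudioSignal(baseline.samples[offset:offset + n_req], baseline.rate)


def _fit_bubble(seg_samples: np.ndarray, intervals, rng) -> int | None:
    """Uniform start index over every placement where the bubble fits wholly
    inside one admissible interval, or None if it fits nowhere."""
    length = len(seg_samples)
    slots = [(start, stop - start - length + 1)
             for start, stop in intervals if stop - start >= length]
    total = sum(count for _, count in slots)
    if total == 0:
        return None
    draw = int(rng.integers(total))
    for start, count in slots:
        if draw < count:
            return start + draw
        draw -= count
    raise AssertionError("unreachable")


def build_bubble_track(windows: CycleWindows, grade: KMGrade,
                       library: BubbleLibrary, p_gamma: PGamma,
                       config: GenerationConfig, rng: np.random.Generator,
                       n_samples: int | None = None,
                       ) -> tuple[AudioSignal, list[PlacedBubble], list[int]]:
    """Place graded bubbles into an initially silent track.

    Per selected cycle, each bubble is sampled from the library, augmented,
    normalized, scaled by the km3 amplitude, modulated by +/-15%, and added
    at a uniform start position such that it fits wholly inside one
    admissible window interval.  A bubble that fits nowhere is re-drawn up to
    10 times and finally time-compressed into the cycle's largest interval.
    A zero-mean Gaussian noise floor is added over each selected cycle's
    extent.  Returns the track plus the placement records and the selected
    cycle indices (times in the track's own coordinates).
    """
    if not grade.is_valid:
        raise ConfigError(f"KM code [{grade}] is not in the conversion chart")
    rate = config.sample_rate
    if n_samples is None:
        n_samples = int(windows.peak_indices[-1]) + 1
    track = np.zeros(n_samples)
    placed: list[PlacedBubble] = []

    total = windows.n_cycles
    placeable = [i for i in range(total) if windows.windows[i]]
    n_select = sample_cycle_count(grade.km2, total, rng)
    if n_select > len(placeable):
        logger.debug("only %d of %d cycles admit placement", len(placeable),
                     total)
        n_select = len(placeable)
    if n_select == 0:
        return AudioSignal(track, rate), placed, []
    selected = sorted(int(i) for i in
                      rng.choice(placeable, size=n_select, replace=False))

    for cycle in selected:
        intervals = windows.windows[cycle]
        n_bubbles = sample_bubble_count(grade.km1, p_gamma, rng)
        for _ in range(n_bubbles):
            start = None
            for attempt in range(MAX_PLACEMENT_RETRIES):
                seg = sample_bubble(library, rng)
                if seg.audio.rate != rate:
                    seg_audio = resample(seg.audio, rate)
                else:
                    seg_audio = seg.audio
                seg = augmentation.augment_bubble(
                    type(seg)(seg_audio, seg_audio.duration, seg.source_id),
                    config.bubble_aug, rng)
                # normalize -> scale by km3 amplitude -> modulate +/-15%
                amp = sample_amplitude(grade.km3, rng)
                scaled = AudioSignal(normalize(seg.audio).samples * amp, rate)
                seg = augmentation.modulate_amplitude(
                    type(seg)(scaled, scaled.duration, seg.source_id),
                    rng, config.bubble_aug.amp_mod)
                samples = seg.audio.samples
                start = _fit_bubble(samples, intervals, rng)
                if start is not None:
                    break
            if start is None:
                # compress into the largest interval of this cycle
                lo, hi = max(intervals, key=lambda iv: iv[1] - iv[0])
                target = hi - lo
                samples = _fourier_resample(samples, target)
                base_peak = np.max(np.abs(samples))
                if base_peak > 0:
                    samples = samples / base_peak * amp
                start = lo
                logger.debug("bubble compressed to %d samples in cycle %d",
                             target, cycle)
            track[start:start + len(samples)] += samples
            placed.append(PlacedBubble(cycle_index=cycle,
                                       start_s=start / rate,
                                       duration_s=len(samples) / rate,
                                       amplitude_scale=amp,
                                       source_id=seg.source_id))
        lo = int(windows.peak_indices[cycle])
        hi = int(windows.peak_indices[cycle + 1])
        if config.noise_sigma > 0 and not config.noise_full_track:
            track[lo:hi] += rng.normal(0.0, config.noise_sigma, hi - lo)
    if config.noise_sigma > 0 and config.noise_full_track:
        track += rng.normal(0.0, config.noise_sigma, n_samples)
    return AudioSignal(track, rate), placed, selected


def center_crop_start(n: int, n_clip: int) -> int:
    # odd remainders leave the extra discarded sample at the head
    return (n - n_clip + 1) // 2


def analyze_baseline(config: GenerationConfig, baseline: AudioSignal,
                     rng: np.random.Generator,
                     ) -> tuple[AudioSignal, Envelope, float, CycleWindows]:
    """Crop, augment and analyze a baseline: the deterministic front half of
    the generation pipeline.

    Returns the augmented cardiac track, its normalized envelope, the
    estimated heart period and the placement windows.  Cycle-detection
    failure triggers a fresh random crop, up to 5 times.
    """
    if baseline.samples.ndim != 1:
        raise ConfigError("baseline must be mono; use select_doppler_channel")
    if baseline.rate != config.sample_rate:
        baseline = resample(baseline, config.sample_rate)

    last_error: Exception | None = None
    for attempt in range(MAX_CROP_RETRIES):
        crop = crop_with_buffer(baseline, config.clip_length, rng)
        cardiac = augmentation.augment_cardiac(crop, config.cardiac_aug, rng)
        env = envelope(cardiac)
        env_norm = Envelope(env.values / env.values.max(), env.rate) \
            if env.values.max() > 0 else env
        try:
            period = estimate_heart_period(env_norm)
            peaks = detect_cycle_peaks(env_norm, period)
            windows = build_windows(peaks, env_norm, config.window_mode)
        except CycleDetectionError as exc:
            last_error = exc
            logger.debug("cycle detection failed (attempt %d): %s",
                         attempt + 1, exc)
            continue
        return cardiac, env_norm, period, windows
    raise CycleDetectionError(
        f"cycle detection failed after {MAX_CROP_RETRIES} crops: "
        f"{last_error}")


def generate_recording(config: GenerationConfig, baseline: AudioSignal,
                       library: BubbleLibrary,
                       grade_or_spencer: KMGrade | int,
                       rng: np.random.Generator) -> SyntheticRecording:
    """Run the full pipeline for one recording.

    ``grade_or_spencer`` is either a KM code or a Spencer grade 0-4; Spencer
    input draws a KM code uniformly from that grade's chart row.
    """
    cardiac, env_norm, period, windows = analyze_baseline(config, baseline,
                                                          rng)
    if isinstance(grade_or_spencer, KMGrade):
        grade = grade_or_spencer
    else:
        grade = grading.spencer_to_km(int(grade_or_spencer), rng)
    p_gamma = compute_p_gamma(period, library.average_bubble_length)
    bubble_track, placed, selected = build_bubble_track(
        windows, grade, library, p_gamma, config, rng,
        n_samples=cardiac.n_samples)
    combined = AudioSignal(cardiac.samples + bubble_track.samples,
                           config.sample_rate)

    n_clip = int(round(config.clip_length * config.sample_rate))
    start = center_crop_start(cardiac.n_samples, n_clip)
    shift_s = start / config.sample_rate

    def _crop(sig: AudioSignal) -> AudioSignal:
        return AudioSignal(sig.samples[start:start + n_clip], sig.rate)

    truth = GroundTruth(
        km_code=str(grade),
        spencer_grade=km_to_spencer(grade),
        period_s=period,
        peak_times_s=tuple(float(p) / config.sample_rate - shift_s
                           for p in windows.peak_indices),
        n_interior_cycles=windows.n_cycles,
        selected_cycles=tuple(selected),
        bubbles=tuple(
            PlacedBubble(b.cycle_index, b.start_s - shift_s, b.duration_s,
                         b.amplitude_scale, b.source_id)
            for b in placed),
    )
    return SyntheticRecording(_crop(cardiac), _crop(bubble_track),
                              _crop(combined), truth)


def _class_grade(label: str) -> KMGrade | int:
    if label.startswith("spencer"):
        return int(label[len("spencer"):])
    return KMGrade.from_string(label[len("km"):])


def _grade_subdir(label: str) -> str:
    return label[len("spencer"):] if label.startswith("spencer") \
        else label[len("km"):]


def generate_dataset(config: GenerationConfig, n_per_class: int,
                     out_dir: str | Path, baselines: list[AudioSignal],
                     library: BubbleLibrary) -> pd.DataFrame:
    """Generate ``n_per_class`` triplets per class of the config's case.

    Layout: ``case<N>/{combined,cardiac,bubble}/<grade>/<name>.wav`` with the
    same basename across the three track directories, plus a ground-truth
    JSON sidecar next to each combined file.  File naming is
    ``case<N>_<classLabel>_<index>.wav`` with zero-based, zero-padded
    sequential indices.  Returns the manifest.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    if not baselines:
        raise ConfigError("at least one baseline is required")
    out_dir = Path(out_dir)
    case_dir = out_dir / f"case{config.case}"
    rows = []
    for class_idx, label in enumerate(config.class_labels):
        grade_dir = _grade_subdir(label)
        for track in ("combined", "cardiac", "bubble"):
            (case_dir / track / grade_dir).mkdir(parents=True, exist_ok=True)
        for i in range(n_per_class):
            rng = np.random.default_rng(
                [config.seed, config.case, class_idx, i])
            baseline = baselines[int(rng.integers(len(baselines)))]
            rec = generate_recording(config, baseline, library,
                                     _class_grade(label), rng)
            name = f"case{config.case}_{label}_{i:04d}.wav"
            paths = {}
            for track, sig in (("combined", rec.combined),
                               ("cardiac", rec.cardiac),
                               ("bubble", rec.bubbles)):
                path = case_dir / track / grade_dir / name
                write_wav(sig, path)
                paths[track] = str(path.relative_to(out_dir))
            truth_path = case_dir / "combined" / grade_dir / \
                name.replace(".wav", ".json")
            with open(truth_path, "w") as fh:
                json.dump(rec.truth.to_dict(), fh)
            rows.append({"case": config.case, "scale": config.scale,
                         "class_label": label, "filename": name,
                         "combined": paths["combined"],
                         "cardiac": paths["cardiac"],
                         "bubble": paths["bubble"],
                         "truth": str(truth_path.relative_to(out_dir)),
                         "seed": config.seed, "index": i})
        logger.info("case %d class %s: %d triplets", config.case, label,
                    n_per_class)
    return pd.DataFrame(rows)
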