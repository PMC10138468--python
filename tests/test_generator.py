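"""End-to-end recording generation: cropping, graded placement, mixing,
ground truth."""

import json

import numpy as np
import pytest

from vgesynth.audio_core import AudioSignal, envelope, read_wav
from vgesynth.cardiac_cycles import (build_windows, detect_cycle_peaks,
                                     estimate_heart_period)
from vgesynth.errors import ConfigError, DegenerateInputError
from vgesynth.generator import (GenerationConfig, GroundTruth, PlacedBubble,
                                analyze_baseline, build_bubble_track,
                                center_crop_start, crop_with_buffer,
                                generate_dataset, generate_recording)
from vgesynth.grading import KMGrade, compute_p_gamma

RATE = 8000


def _windows(baseline, mode="full"):
    env = envelope(baseline)
    period = estimate_heart_period(env)
    peaks = detect_cycle_peaks(env, period)
    return build_windows(peaks, env, mode), env, period


class TestCropWithBuffer:
    def test_crop_is_1p5_times_clip(self, rng):
        baseline = AudioSignal(np.random.default_rng(0).standard_normal(
            60 * RATE), RATE)
        crop = crop_with_buffer(baseline, 10.0, rng)
        assert crop.duration == pytest.approx(15.0)

    def test_exact_length_forces_zero_offset(self, rng):
        baseline = AudioSignal(np.arange(15 * RATE, dtype=float), RATE)
        crop = crop_with_buffer(baseline, 10.0, rng)
        assert crop.samples[0] == 0.0

    def test_too_short_baseline_names_required_duration(self, rng):
        baseline = AudioSignal(np.zeros(12 * RATE), RATE)
        with pytest.raises(DegenerateInputError, match="15"):
            crop_with_buffer(baseline, 10.0, rng)


class TestBubbleTrack:
    def test_grade_000_yields_silence(self, precordial_baseline,
                                      bubble_library, rng):
        windows, env, period = _windows(precordial_baseline)
        config = GenerationConfig(case=3)
        p_gamma = compute_p_gamma(period,
                                  bubble_library.average_bubble_length)
        track, placed, selected = build_bubble_track(
            windows, KMGrade(0, 0, 0), bubble_library, p_gamma, config, rng)
        assert np.all(track.samples == 0.0)
        assert placed == [] and selected == []

    def test_grade_222_selects_10_to_50_percent_with_3_to_8_bubbles(
            self, precordial_baseline, bubble_library, rng):
        windows, env, period = _windows(precordial_baseline)
        config = GenerationConfig(case=3)
        p_gamma = compute_p_gamma(period,
                                  bubble_library.average_bubble_length)
        track, placed, selected = build_bubble_track(
            windows, KMGrade(2, 2, 2), bubble_library, p_gamma, config, rng)
        total = windows.n_cycles
        assert max(1, round(0.10 * total)) <= len(selected)
        assert len(selected) <= round(0.50 * total)
        counts = {}
        for b in placed:
            counts[b.cycle_index] = counts.get(b.cycle_index, 0) + 1
        assert set(counts) == set(selected)
        assert all(3 <= c <= 8 for c in counts.values())

    def test_partial_mode_placement_is_exhaustively_below_threshold(
            self, precordial_baseline, bubble_library, rng):
        windows, env, period = _windows(precordial_baseline, "partial")
        config = GenerationConfig(case=6)
        p_gamma = compute_p_gamma(period,
                                  bubble_library.average_bubble_length)
        track, placed, _ = build_bubble_track(
            windows, KMGrade(2, 4, 3), bubble_library, p_gamma, config, rng)
        assert placed
        for bubble in placed:
            start = int(round(bubble.start_s * RATE))
            stop = start + int(round(bubble.duration_s * RATE))
            assert any(a <= start and stop <= b
                       for a, b in windows.windows[bubble.cycle_index])
            lo = windows.peak_indices[bubble.cycle_index]
            hi = windows.peak_indices[bubble.cycle_index + 1]
            cycle_max = env.values[lo:hi].max()
            assert np.all(env.values[start:stop] < 0.5 * cycle_max)

    def test_amplitudes_recorded_in_km3_interval(self, precordial_baseline,
                                                 bubble_library, rng):
        windows, env, period = _windows(precordial_baseline)
        config = GenerationConfig(case=3)
        p_gamma = compute_p_gamma(period,
                                  bubble_library.average_bubble_length)
        _, placed, _ = build_bubble_track(
            windows, KMGrade(1, 1, 3), bubble_library, p_gamma, config, rng)
        assert placed
        assert all(0.450 <= b.amplitude_scale <= 0.775 for b in placed)

    def test_invalid_code_rejected(self, precordial_baseline, bubble_library,
                                   rng):
        windows, env, period = _windows(precordial_baseline)
        config = GenerationConfig(case=3)
        p_gamma = compute_p_gamma(period,
                                  bubble_library.average_bubble_length)
        with pytest.raises(ConfigError):
            build_bubble_track(windows, KMGrade(1, 3, 4), bubble_library,
                               p_gamma, config, rng)


class TestGenerateRecording:
    def test_fixed_seed_reproduces_everything(self, precordial_baseline,
                                              bubble_library):
        config = GenerationConfig(case=3, seed=0)
        recs = [generate_recording(config, precordial_baseline,
                                   bubble_library, KMGrade(2, 2, 2),
                                   np.random.default_rng(77))
                for _ in range(2)]
        for track in ("cardiac", "bubbles", "combined"):
            np.testing.assert_array_equal(
                getattr(recs[0], track).samples,
                getattr(recs[1], track).samples)
        assert recs[0].truth == recs[1].truth

    def test_mixing_identity(self, precordial_baseline, bubble_library, rng):
        config = GenerationConfig(case=1)
        rec = generate_recording(config, precordial_baseline, bubble_library,
                                 2, rng)
        residual = rec.combined.samples - rec.cardiac.samples - \
            rec.bubbles.samples
        assert np.max(np.abs(residual)) < 1e-12

    def test_km2_four_fills_every_interior_cycle(self, precordial_baseline,
                                                 bubble_library, rng):
        config = GenerationConfig(case=3)
        rec = generate_recording(config, precordial_baseline, bubble_library,
                                 KMGrade(2, 4, 2), rng)
        truth = rec.truth
        assert truth.cycles_with_bubbles() == set(range(truth.n_interior_cycles))

    def test_spencer_input_draws_km_from_chart_row(self, precordial_baseline,
                                                   bubble_library, rng):
        config = GenerationConfig(case=1)
        rec = generate_recording(config, precordial_baseline, bubble_library,
                                 3, rng)
        assert rec.truth.spencer_grade == 3
        assert rec.truth.km_code in {"232", "233", "242", "243",
                                     "332", "333", "342", "343"}

    def test_output_duration_is_clip_length(self, precordial_baseline,
                                            bubble_library, rng):
        config = GenerationConfig(case=1, clip_length=6.0)
        rec = generate_recording(config, precordial_baseline, bubble_library,
                                 1, rng)
        assert rec.combined.n_samples == 6 * RATE

    def test_partial_containment_survives_center_crop(
            self, precordial_baseline, bubble_library):
        """Replaying the analysis stage with the same seed reproduces the
        windows exactly; every bubble must land below the 50% envelope
        threshold of its cycle."""
        config = GenerationConfig(case=6, seed=0)
        rec = generate_recording(config, precordial_baseline, bubble_library,
                                 KMGrade(2, 3, 3), np.random.default_rng(5))
        cardiac, env, period, windows = analyze_baseline(
            config, precordial_baseline, np.random.default_rng(5))
        n_clip = int(round(config.clip_length * config.sample_rate))
        shift = center_crop_start(cardiac.n_samples, n_clip)
        for bubble in rec.truth.bubbles:
            start = int(round(bubble.start_s * RATE)) + shift
            stop = start + int(round(bubble.duration_s * RATE))
            lo = windows.peak_indices[bubble.cycle_index]
            hi = windows.peak_indices[bubble.cycle_index + 1]
            cycle_max = env.values[lo:hi].max()
            assert np.all(env.values[start:stop] < 0.5 * cycle_max)

    def test_ground_truth_round_trips_through_json(self, precordial_baseline,
                                                   bubble_library, rng):
        config = GenerationConfig(case=3)
        rec = generate_recording(config, precordial_baseline, bubble_library,
                                 KMGrade(1, 1, 1), rng)
        back = GroundTruth.from_dict(
            json.loads(json.dumps(rec.truth.to_dict())))
        assert back == rec.truth


@pytest.fixture(scope="module")
def dataset(tmp_path_factory, precordial_baseline, bubble_library):
    out = tmp_path_factory.mktemp("dataset")
    config = GenerationConfig(case=1, clip_length=6.0, seed=42)
    manifest = generate_dataset(config, 1, out, [precordial_baseline],
                                bubble_library)
    return out, manifest


class TestGenerateDataset:

    def test_spencer_counts(self, dataset):
        out, manifest = dataset
        assert len(manifest) == 5
        assert len(list(out.rglob("*.wav"))) == 15
        assert len(list(out.rglob("*.json"))) == 5

    def test_layout_and_naming(self, dataset):
        out, manifest = dataset
        row = manifest.iloc[2]
        assert row["combined"] == "case1/combined/2/case1_spencer2_0000.wav"
        assert (out / row["cardiac"]).exists()
        assert (out / row["bubble"]).exists()

    def test_triplet_shares_basename_across_tracks(self, dataset):
        _, manifest = dataset
        for _, row in manifest.iterrows():
            names = {row[t].split("/")[-1]
                     for t in ("combined", "cardiac", "bubble")}
            assert len(names) == 1

    def test_all_durations_equal_clip_length(self, dataset):
        out, _ = dataset
        for path in out.rglob("*.wav"):
            sig = read_wav(path)
            assert sig.n_samples == 6 * RATE

    def test_truth_sidecar_matches_grade_dir(self, dataset):
        out, manifest = dataset
        truth = GroundTruth.from_dict(
            json.loads((out / manifest.iloc[4]["truth"]).read_text()))
        assert truth.spencer_grade == 4
        assert truth.km_code == "444"
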