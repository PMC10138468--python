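# Methods

This note documents the models, numerical choices and known limitations of
`vgesynth`. It is the package's own account of what is simulated and why;
all quantitative claims here are re-computed by the test suite or by
`scripts/acceptance.py`.

## Signal model and preprocessing

All audio is mono float64 at a working rate of 8 kHz by default (clinical
Doppler audio is typically recorded at 44.1 or 48 kHz and carries no useful
content above ~3 kHz for this purpose; 8 kHz keeps memory and FFT costs
low). Resampling is polyphase (`scipy.signal.resample_poly`) with the exact
rational rate ratio, preserving duration to within one output sample.

The amplitude envelope is the magnitude of the analytic (Hilbert) signal
smoothed by a 20 ms moving average. Rectification + low-pass would satisfy
the same contract; the analytic magnitude was chosen because it is exact for
narrow-band carriers and exactly homogeneous (env(c·x) = c·env(x)), which
the tests assert. Annotated stereo baselines keep the channel with the
larger mean envelope (annotation channels carry sparse voice markers and
lose by an order of magnitude); ties keep channel 0.

WAV output is 16-bit PCM. Samples beyond ±1 — possible after summation — are
hard-clipped with a logged warning. Quantization uses a scale of 32768 with
the positive rail clipped to 32767, so a write/read round trip is accurate
to one LSB (2⁻¹⁵).

## Bubble segmentation

Single-bubble events are cut from laboratory recordings at the full width of
their envelope peak at 20% of the peak maximum (FW20%M). Peak detection uses
a height floor of 0.2 × the global envelope maximum and a 50 ms minimum
separation — the source recordings contain deliberately separable events, so
these defaults are coarse and both are exposed in the API and CLI. The
width search is bounded at the envelope minimum toward each neighboring
peak, so adjacent events cannot merge; segments wider than 0.5 s are
discarded as non-single-bubble artifacts. The pool's mean segment duration
feeds P_γ below.

## Cardiac cycle detection

The heart period is the lag of the largest autocorrelation peak of the
mean-removed normalized envelope, searched over 40–180 bpm (0.333–1.5 s) —
wide enough for rest through post-exercise human rates while excluding the
S1→S2 intra-beat lag at typical heart rates. Cycle peaks are then local
envelope maxima at least 0.7 periods apart and at least 30% of the envelope
maximum high; both fractions are module constants with function-argument
overrides. A cardiac cycle is the span between consecutive detected peaks:
the partial beats before the first and after the last peak are never used
for placement. Fewer than two peaks, or no autocorrelation peak in band, is
a detection error; the generator then retries with a fresh random baseline
crop (up to 5 times) because a crop can land on an atypical stretch.

Placement windows are either *full* (the whole peak-to-peak interval) or
*partial*: the maximal runs where the cycle-local envelope is strictly below
50% of that cycle's maximum. Boundary samples at exactly 50% are excluded
(strict inequality). A cycle whose envelope never dips below threshold
carries an empty window and is skipped.

## Augmentation

Baseline crops get four transforms in a fixed order — time-stretch (speed-up
factor 0.8–1.3), pitch-shift (±2 semitones), gain (±10 dB), circular
time-shift over the whole length — with every parameter drawn uniformly from
its closed range. The fixed order and uniform draws make a seeded run
bit-reproducible. Circular rotation (rather than zero-padded shifting) was
chosen for the time-shift because it preserves energy and duration. Bubble
snippets get a wider stretch (0.8–2.0), the same pitch range, and a ±15%
multiplicative amplitude modulation applied after grade scaling.

Time-stretch is an STFT phase vocoder: Hann window of 1024 samples (shrunk
to the largest power of two that fits for very short snippets; plain linear
interpolation below 32 samples, where spectral processing is meaningless),
hop of a quarter window, linear magnitude interpolation between analysis
frames and accumulated phase advance. Output length is forced to
round(n/factor). Pitch-shift composes a stretch by 1/2^(s/12) with a
compensating polyphase resample back to the original length.

## The quantified KM model

P_γ = cardiac period / mean library bubble duration, computed per recording
from the *estimated* period (so it reflects the augmented signal, not the
fixture's nominal rate). Interval endpoints are treated as closed, and
"round" is round-half-up:

* km1 (bubbles per selected cycle): 0; 1–2; 3–8; 9–max(9, round(P_γ));
  max(1, round(P_γ))–2·round(P_γ). The grade-3 interval collapses to {9}
  when P_γ < 9, reading 9 as the floor of a "rolling" sound and P_γ as a
  maximum.
* km2 (fraction of cycles): 0; 1–10%; 10–50%; 50–99%; 100%. The drawn
  fraction times the interior-cycle count is rounded half-up, clamped to at
  least 1 cycle for digits 1–3, and for digit 3 additionally capped at
  total−1 when more than one cycle exists (99% never means "all").
* km3 (relative amplitude): 0; then the closed bands 0.100–0.250,
  0.250–0.450, 0.450–0.775, 0.775–0.999.

Only the 22 codes of the KM↔Spencer chart are generated; Spencer-scale
requests draw uniformly from the requested grade's chart row. Cycle subsets
are drawn uniformly without replacement from the cycles that admit
placement.

## Placement and mixing

Each bubble must fit wholly inside one admissible interval of its cycle; the
start index is uniform over all feasible positions across that cycle's
intervals, so bubbles may overlap one another (bubble "showers" do overlap)
but never spill across window boundaries. A bubble that fits nowhere is
re-drawn up to 10 times, then time-compressed (Fourier resampling) into the
cycle's largest interval — a logged fallback that in practice only triggers
for partial windows combined with long stretch draws. Zero-mean Gaussian
noise (σ = 0.001 full scale by default) is added over each selected cycle's
extent of the bubble track, emulating a low-amplitude sensor noise floor;
a config switch spreads it over the whole track instead. The cardiac-only
track carries no added noise.

The combined track is the exact sample-wise sum of the cardiac and bubble
tracks; all three are center-cropped to the requested clip length (an odd
remainder discards the extra sample at the head). Ground truth keeps every
placement made before the crop, with times re-expressed relative to the
crop — placements in the discarded buffer appear with negative or
beyond-clip start times rather than being silently dropped, so grade
statistics computed from the truth always reflect the placement model.

## Fixtures

The fixture generator aims at *structural* equivalence with clinical
recordings, not acoustic fidelity: a periodic two-burst (S1/S2-like)
Gaussian envelope (S2 at 33% of the cycle, 55% of S1's height) modulating
200–2000 Hz band-limited noise, over an envelope floor of 0.08 (precordial:
bursts tower over the trough) or 0.60 (subclavian: bursts ride on continuous
flow noise), plus white noise at 30 dB SNR. Bubble fixtures are decaying
tone bursts (5–300 ms FW20%M, mild downward frequency glide). Beat times and
injected event times are known exactly by construction. Consequently,
passing tests demonstrate that the pipeline honors its contracts on signals
with the assumed statistical structure; they do not demonstrate robustness
to motion artifacts, probe repositioning, arrhythmia, or device-specific
coloration, none of which the fixtures contain.

## Problem sizes and determinism

The statistical test and acceptance runs use 6 s clips from 20–30 s
fixture baselines at 8 kHz: long enough for ~7–10 interior cycles per
recording, which exercises every km2 band, while keeping the default suite
fast. Grading fidelity is checked over 50 recordings per each of the 22
codes; bubble-count extremes over 200 recordings per first digit. All
randomness flows through `numpy.random.Generator` objects seeded from
explicit integer lists, and per-file generator seeds are derived as
(seed, case, class, index), so any (config, seed) pair reproduces output
files byte for byte.

## Known limitations

* No motion artifacts, flex-protocol cycles, or probe-handling noise.
* Grade realism inherits the quantified table; human raters vary, and the
  table's parameters are deliberately user-editable rather than asserted as
  the unique reading of the ordinal scale.
* The phase vocoder shares the usual transient smearing of
  magnitude-interpolating vocoders; for sub-second bubble chirps this is
  audible only as mild softening.
* Subclavian fixtures are a stylized stand-in; real subclavian recordings
  differ in spectral shape more than in envelope structure.
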