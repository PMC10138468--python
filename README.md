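# vgesynth

Procedural generation of synthetic post-dive Doppler ultrasound audio with
exact venous-gas-emboli (VGE) ground truth.

## Why

After decompression (diving, altitude exposure, EVA), inert-gas bubbles in
venous blood are audible in Doppler ultrasound as short "chirps" riding on
the cardiac flow signal. Clinical practice grades the bubble load on ordinal
scales — Spencer (0–4) or the three-digit Kisman-Masurel (KM) code — by ear.
Developing automated graders and signal-separation methods is hard because
real post-dive recordings are scarce, skewed toward low grades, and carry no
ground truth: nobody knows exactly how many bubbles are in a recording or
where they are.

`vgesynth` sidesteps this by *constructing* recordings. It mixes augmented
baseline cardiac Doppler audio with isolated single-bubble signals placed
according to a quantified KM model, and emits, for every recording, the
combined audio **plus** the isolated cardiac-only and bubble-only tracks and
a manifest of every placed bubble (cycle, onset, duration, amplitude). The
result is unlimited labelled data for training and for benchmarking
separation algorithms against exact ground truth.

## The grading model

Each KM digit is 0–4 and is quantified as:

| KM | bubbles per cardiac cycle | % of cycles with bubbles | relative amplitude |
|----|---------------------------|--------------------------|--------------------|
| 0  | 0                         | 0%                       | 0.000              |
| 1  | 1–2                       | 1–10%                    | 0.100–0.250        |
| 2  | 3–8                       | 10–50%                   | 0.250–0.450        |
| 3  | 9–P<sub>γ</sub>           | 50–99%                   | 0.450–0.775        |
| 4  | P<sub>γ</sub>–2·P<sub>γ</sub> | 100%                 | 0.775–0.999        |

where P<sub>γ</sub> = cardiac period / mean bubble duration is the number of
average-length bubbles that tile one cardiac cycle — the cap for a "rolling"
(grade 3) or "continuous" (grade 4) bubble sound. Only the 22 KM codes that
appear in the KM↔Spencer conversion chart are generated; the chart partitions
them into Spencer grades as {0: 1 code, 1: 6, 2: 6, 3: 8, 4: 1}.

Per recording the pipeline: crops a baseline 50% longer than the requested
clip at a random offset → augments it (time-stretch 0.8–1.3, pitch ±2
semitones, gain ±10 dB, circular time-shift) → detects cardiac cycles from
the autocorrelation of the normalized envelope → places bubbles (each
time-stretched 0.8–2.0, pitch-shifted ±2 semitones, normalized, scaled by
the KM amplitude, modulated ±15%) into full peak-to-peak windows or, for the
"partial" cases, only where the envelope is below 50% of the cycle maximum →
sums the tracks and center-crops everything to the clip length.

Six dataset cases are supported: precordial/subclavian site ×
Spencer/KM scale × full/partial windows (partial is precordial-only, since
subclavian cardiac sounds do not mask bubbles).

Real baseline recordings are not required: `vgesynth.fixtures` synthesizes
cardiac-like baselines (band-limited noise under a periodic S1/S2-like burst
envelope) and bubble-like decaying chirps with known event times.

## Worked example

```python
import numpy as np
import vgesynth as v
from vgesynth.fixtures import FixtureSpec, synth_cardiac_baseline, default_bubble_library

rng = np.random.default_rng(0)
baseline = synth_cardiac_baseline(FixtureSpec("precordial", heart_rate_bpm=72.0, seed=1))
library = default_bubble_library(rng)
config = v.GenerationConfig(case=3, seed=0)   # precordial, KM scale, full windows
rec = v.generate_recording(config, baseline, library, v.KMGrade(2, 2, 2), rng)
```

This prints (via the truth object and the tracks):

```
KM code        : 222  (Spencer 2)
heart period   : 0.926 s
interior cycles: 17
selected cycles: (3, 10, 12, 14)
placed bubbles : 24
first bubble   : cycle 3, start 0.002 s, duration 0.123 s, amplitude 0.338
max |combined - (cardiac + bubbles)| = 1.1e-16
clip: 10.0 s at 8000 Hz
```

Reading it: the augmented baseline carried 17 interior cardiac cycles; the
KM second digit (2 → 10–50% of cycles) selected 4 of them; each selected
cycle received 3–8 bubbles (first digit 2) for 24 in total, each scaled into
the 0.250–0.450 amplitude band (third digit 2). The combined track is the
exact sample-wise sum of the cardiac-only and bubble-only tracks.

From the shell, the same machinery generates whole datasets:

```sh
vgesynth generate --case 1 --fixtures --n-per-class 10 --seed 1 --out data/
vgesynth generate --case 1 --case 2 --case 5 --n-per-class 1000 --dry-run --out plan/
vgesynth segment --bubble-dir my_bubble_wavs/ --out segments.csv
```

Output layout is `case<N>/{combined,cardiac,bubble}/<grade>/` with the same
basename across the three track directories and a ground-truth JSON sidecar
per recording.

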