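"""Quantified Kisman-Masurel grading model and Spencer conversion.

The Kisman-Masurel (KM) code grades venous gas emboli load with three digits,
each 0-4: bubbles per cardiac cycle (km1), percentage of cardiac cycles with
detectable bubbles (km2), and relative bubble amplitude (km3).  This module
holds the quantified version of that scale used for procedural generation:

===  ====================  ==================  ==================
km   bubbles/cycle         % cycles            relative amplitude
===  ====================  ==================  ==================
0    0                     0%                  0.000
1    1-2                   1-10%               0.100-0.250
2    3-8                   10-50%              0.250-0.450
3    9-P_gamma             50-99%              0.450-0.775
4    P_gamma-2*P_gamma     100%                0.775-0.999
===  ====================  ==================  ==================

P_gamma = cardiac period / average bubble duration caps the counts regarded
as a "rolling" (grade 3) or "continuous" (grade 4) bubble sound: it is the
number of average-length bubbles that tile one cardiac cycle end to end.

Only 22 of the 125 possible codes appear in the KM-to-Spencer conversion
chart; generation samples exclusively from those.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidGradeError

#: km2 digit -> closed fraction-of-cycles range.
CYCLE_FRACTION_RANGES: dict[int, tuple[float, float]] = {
    0: (0.0, 0.0),
    1: (0.01, 0.10),
    2: (0.10, 0.50),
    3: (0.50, 0.99),
    4: (1.0, 1.0),
}

#: km3 digit -> closed relative-amplitude range.
AMPLITUDE_RANGES: dict[int, tuple[float, float]] = {
    0: (0.0, 0.0),
    1: (0.100, 0.250),
    2: (0.250, 0.450),
    3: (0.450, 0.775),
    4: (0.775, 0.999),
}

#: Spencer grade -> the KM codes that convert to it.
SPENCER_TO_KM_CHART: dict[int, tuple[str, ...]] = {
    0: ("000",),
    1: ("111", "112", "113", "211", "212", "213"),
    2: ("121", "122", "123", "221", "222", "223"),
    3: ("232", "233", "242", "243", "332", "333", "342", "343"),
    4: ("444",),
}

_KM_TO_SPENCER: dict[str, int] = {
    code: spencer
    for spencer, codes in SPENCER_TO_KM_CHART.items()
    for code in codes
}


@dataclass(frozen=True, order=True)
class KMGrade:
    """A three-digit Kisman-Masurel code."""

    km1: int  # bubbles per cycle digit
    km2: int  # percentage of cycles digit
    km3: int  # amplitude digit

    def __post_init__(self) -> None:
        for digit in (self.km1, self.km2, self.km3):
            if digit not in range(5):
                raise InvalidGradeError(f"KM digits must be 0-4, got {self}")

    @classmethod
    def from_string(cls, code: str) -> "KMGrade":
        code = code.strip("[]")
        if len(code) != 3 or not code.isdigit():
            raise InvalidGradeError(f"not a 3-digit KM code: {code!r}")
        return cls(int(code[0]), int(code[1]), int(code[2]))

    def __str__(self) -> str:
        return f"{self.km1}{self.km2}{self.km3}"

    @property
    def is_valid(self) -> bool:
        """True when the code appears in the conversion chart."""
        return str(self) in _KM_TO_SPENCER


@dataclass(frozen=True)
class PGamma:
    """Cardiac period divided by average bubble duration (dimensionless)."""

    value: float

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValueError(f"P_gamma must be positive, got {self.value}")


def compute_p_gamma(cardiac_period: float,
                    average_bubble_length: float) -> PGamma:
    """Exact ratio of cardiac period to mean bubble duration (both seconds)."""
    if not (cardiac_period > 0):
        raise ValueError(f"cardiac period must be positive, got {cardiac_period}")
    if not (average_bubble_length > 0):
        raise ValueError("average bubble length must be positive, "
                         f"got {average_bubble_length}")
    return PGamma(cardiac_period / average_bubble_length)


def bubbles_per_cycle_range(km1: int, p_gamma: PGamma) -> tuple[int, int]:
    """Closed integer interval of bubbles per selected cycle for a km1 digit.

    Grade 3 spans 9 up to round(P_gamma) (collapsing to {9} when P_gamma < 9,
    since 9 is the floor of a "rolling" sound); grade 4 spans round(P_gamma)
    to 2*round(P_gamma), with at least 1 bubble.
    """
    rounded = int(np.floor(p_gamma.value + 0.5))  # round half up
    if km1 == 0:
        return (0, 0)
    if km1 == 1:
        return (1, 2)
    if km1 == 2:
        return (3, 8)
    if km1 == 3:
        return (9, max(9, rounded))
    if km1 == 4:
        return (max(1, rounded), max(1, 2 * rounded))
    raise InvalidGradeError(f"km1 digit out of range: {km1}")


def km_to_spencer(grade: KMGrade) -> int:
    """Convert a KM code to its Spencer grade via the conversion chart."""
    spencer = _KM_TO_SPENCER.get(str(grade))
    if spencer is None:
        raise InvalidGradeError(
            f"KM code [{grade}] is not in the conversion chart")
    return spencer


def spencer_to_km(spencer: int, rng: np.random.Generator) -> KMGrade:
    """Uniform draw of a KM code from the given Spencer grade's chart row."""
    if spencer not in SPENCER_TO_KM_CHART:
        raise ValueError(f"Spencer grade must be 0-4, got {spencer}")
    codes = SPENCER_TO_KM_CHART[spencer]
    return KMGrade.from_string(codes[int(rng.integers(len(codes)))])


def list_valid_km() -> list[KMGrade]:
    """All chart-valid KM codes, deduplicated and sorted lexicographically."""
    codes = sorted({code for row in SPENCER_TO_KM_CHART.values()
                    for code in row})
    return [KMGrade.from_string(code) for code in codes]


def sample_cycle_count(km2: int, total_cycles: int,
                       rng: np.random.Generator) -> int:
    """Number of cardiac cycles to receive bubbles for a km2 digit.

    A fraction is drawn uniformly from the km2 range and multiplied by the
    total cycle count, rounding half up.  Digits 1-3 are clamped to at least
    one cycle; digit 3 (50-99%) additionally never selects every cycle when
    more than one exists; digit 4 selects all cycles; digit 0 selects none.
    """
    if total_cycles < 1:
        raise ValueError(f"total_cycles must be >= 1, got {total_cycles}")
    if km2 not in CYCLE_FRACTION_RANGES:
        raise InvalidGradeError(f"km2 digit out of range: {km2}")
    if km2 == 0:
        return 0
    if km2 == 4:
        return total_cycles
    fraction = float(rng.uniform(*CYCLE_FRACTION_RANGES[km2]))
    count = int(np.floor(fraction * total_cycles + 0.5))
    count = min(max(count, 1), total_cycles)
    if km2 == 3 and total_cycles >= 2:
        count = min(count, total_cycles - 1)
    return count


def sample_bubble_count(km1: int, p_gamma: PGamma,
                        rng: np.random.Generator) -> int:
    """Uniform integer draw of bubbles for one cycle from the km1 interval."""
    lo, hi = bubbles_per_cycle_range(km1, p_gamma)
    return int(rng.integers(lo, hi + 1))


def sample_amplitude(km3: int, rng: np.random.Generator) -> float:
    """Uniform draw of the relative bubble amplitude from the km3 range."""
    if km3 not in AMPLITUDE_RANGES:
        raise InvalidGradeError(f"km3 digit out of range: {km3}")
    if km3 == 0:
        return 0.0
    return float(rng.uniform(*AMPLITUDE_RANGES[km3]))
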