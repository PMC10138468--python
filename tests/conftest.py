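import numpy as np
import pytest

from vgesynth.fixtures import (FixtureSpec, default_bubble_library,
                               synth_cardiac_baseline)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def precordial_baseline():
    """30 s precordial-style baseline at 72 bpm, 8 kHz."""
    return synth_cardiac_baseline(FixtureSpec("precordial", 72.0, seed=11))


@pytest.fixture(scope="session")
def subclavian_baseline():
    return synth_cardiac_baseline(FixtureSpec("subclavian", 72.0, seed=12))


@pytest.fixture(scope="session")
def bubble_library():
    """20-chirp pool spanning 0.03-0.25 s widths."""
    return default_bubble_library(np.random.default_rng(5))
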