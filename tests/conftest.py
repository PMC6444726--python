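import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def condition_sets():
    """One generated condition set per culture condition (session-shared:
    generation and detection on full movies is the expensive part)."""
    from astrocal import synth

    out = {}
    for cond in ("A_alone", "NA_same", "N_A_adjacent"):
        movies, truth = synth.generate_condition_set(cond, seed=1)
        out[cond] = (movies, truth)
    return out


@pytest.fixture(scope="session")
def condition_detections(condition_sets):
    """Detected events for the green (astrocyte) channel of each condition."""
    from astrocal import detection

    out = {}
    for cond, (movies, truth) in condition_sets.items():
        movie = movies["green"]
        baseline = detection.estimate_baseline(movie)
        events = detection.detect_events(movie, baseline)
        out[cond] = (movie, truth, events)
    return out
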