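import numpy as np
import pytest

from fluidresp import BeatSeries


@pytest.fixture
def regular_beats():
    """60 beats at 1 Hz over 10 respiratory cycles (6 beats per cycle)."""
    t = np.arange(60, dtype=float)
    rng = np.random.default_rng(7)
    pp = 50.0 + 5.0 * rng.random(60)
    sv = 65.0 + 6.0 * rng.random(60)
    marks = np.arange(0.0, 66.0, 6.0)  # 11 marks -> 10 windows
    return BeatSeries(beat_time=t, pulse_pressure=pp, stroke_volume=sv, cycle_marks=marks)


@pytest.fixture
def separated_scores():
    """Perfectly separated responder/non-responder scores."""
    scores = np.r_[np.full(8, 10.0), np.zeros(10)]
    labels = np.r_[np.ones(8, dtype=bool), np.zeros(10, dtype=bool)]
    return scores, labels
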