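import numpy as np
import pytest

from aoiscan import DwellSequence, default_world_model
from aoiscan.preprocessing import Dwell


@pytest.fixture(scope="session")
def model():
    return default_world_model()


def make_sequence(labels, durations=None, source_id="test"):
    """Build a DwellSequence with unit (or given) durations, back to back."""
    if durations is None:
        durations = [1.0] * len(labels)
    onsets = np.concatenate(([0.0], np.cumsum(durations)[:-1]))
    return DwellSequence(
        dwells=tuple(
            Dwell(aoi=int(a), onset=float(t), duration=float(d))
            for a, t, d in zip(labels, onsets, durations)
        ),
        source_id=source_id,
    )


@pytest.fixture
def seq_factory():
    return make_sequence
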