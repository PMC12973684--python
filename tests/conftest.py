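import numpy as np
import pytest

from thermobreath.events import NRI, PRDI, LabeledEvent
from thermobreath.signal import BreathEvent


def make_labeled(pos_depths, neg_depths):
    """Labeled events from two depth lists (PRDI positives first)."""
    events = []
    i = 0
    for d in pos_depths:
        events.append(LabeledEvent(event=BreathEvent(i, float(i), float(d)), label=PRDI))
        i += 1
    for d in neg_depths:
        events.append(LabeledEvent(event=BreathEvent(i, float(i), float(d)), label=NRI))
        i += 1
    return events


@pytest.fixture
def labeled_factory():
    return make_labeled


@pytest.fixture
def default_recording():
    """One default-config synthetic recording (2 min, seeded)."""
    from thermobreath.simulate import SimulationConfig, simulate_recording

    return simulate_recording(SimulationConfig(duration_s=120.0, seed=42))
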