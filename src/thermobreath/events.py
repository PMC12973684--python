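"""Ground-truth labeling of breath events and threshold classification.

Each annotated regurgitation opens a 3-second half-open window
``[t, t + 3)``; every breath minimum inside the union of windows is a
post-regurgitation deep inhalation (PRDI), every other minimum a
non-rumination inhalation (NRI).  Prediction is a single depth threshold:
an event is called PRDI when its minimum is at least as deep (as negative)
as the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import RegurgitationAnnotation, ValidationError
from .signal import BreathEvent

__all__ = ["PRDI", "NRI", "PRDIWindow", "LabeledEvent", "build_windows", "label_events", "classify"]

PRDI = "PRDI"
NRI = "NRI"


@dataclass(frozen=True)
class PRDIWindow:
    """Half-open post-regurgitation window [start_s, end_s)."""

    start_s: float
    end_s: float
    source_regurg_s: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError("window end must exceed its start")


@dataclass(frozen=True)
class LabeledEvent:
    """A breath event with its ground-truth label and optional prediction."""

    event: BreathEvent
    label: str
    recording_id: str = "recording"
    predicted: str | None = None

    @property
    def depth_z(self) -> float:
        return self.event.depth_z

    @property
    def time_s(self) -> float:
        return self.event.time_s


def build_windows(
    annotation: RegurgitationAnnotation, window_len_s: float = 3.0
) -> list[PRDIWindow]:
    """One half-open window [t, t + window_len_s) per regurgitation."""
    if window_len_s <= 0:
        raise ValidationError("window_len_s must be > 0")
    return [
        PRDIWindow(start_s=float(t), end_s=float(t) + window_len_s, source_regurg_s=float(t))
        for t in annotation.regurg_times_s
    ]


def _in_union(time_s: float, windows: Sequence[PRDIWindow]) -> bool:
    return any(w.start_s <= time_s < w.end_s for w in windows)


def label_events(
    events: Sequence[BreathEvent],
    windows: Sequence[PRDIWindow],
    recording_id: str = "recording",
) -> list[LabeledEvent]:
    """Label each event PRDI iff its time falls in the union of windows.

    Overlapping windows count once; membership is order-independent.
    """
    return [
        LabeledEvent(
            event=ev,
            label=PRDI if _in_union(ev.time_s, windows) else NRI,
            recording_id=recording_id,
        )
        for ev in events
    ]


def classify(events: Sequence[LabeledEvent], threshold_z: float) -> list[LabeledEvent]:
    """Predict PRDI for every event at least as deep as the threshold.

    Depth is a z-value of the smoothed signal's minimum: more negative means
    a deeper inhalation, so ``depth_z <= threshold_z`` is a positive call.
    Ties at the threshold count as positive, matching the ROC convention
    used in evaluation.  Ground-truth labels are untouched.
    """
    out = []
    for ev in events:
        if not np.isfinite(ev.depth_z):
            raise ValidationError("event depths must be finite")
        out.append(replace(ev, predicted=PRDI if ev.depth_z <= threshold_z else NRI))
    return out
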