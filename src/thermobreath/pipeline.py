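"""End-to-end helpers wiring simulation, signal chain, labeling and fitting.

Events are pooled across recordings *after* per-recording standardization,
so depths are comparable between animals and sessions despite different
absolute nostril temperatures.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np

from .events import LabeledEvent, build_windows, label_events
from .io import RegurgitationAnnotation, TemperatureSeries
from .model import PRDIThresholdModel, PRDIThresholdResults
from .signal import BreathEvent, FilterSpec, detect_breath_minima, extract_breathing_signal
from .simulate import SimulationConfig, simulate_recording

__all__ = [
    "events_from_series",
    "label_recording",
    "simulate_study",
    "fit_pooled",
]


def events_from_series(
    series: TemperatureSeries,
    filter_spec: FilterSpec = FilterSpec(),
    smoothing_window: int = 9,
    min_separation_s: float = 0.6,
    min_prominence_z: float = 0.2,
    max_gap_s: float = 1.0,
) -> list[BreathEvent]:
    """Run the full breathing chain on one recording and detect minima."""
    sig = extract_breathing_signal(
        series, filter_spec=filter_spec, smoothing_window=smoothing_window, max_gap_s=max_gap_s
    )
    return detect_breath_minima(
        sig, min_separation_s=min_separation_s, min_prominence_z=min_prominence_z
    )


def label_recording(
    series: TemperatureSeries,
    annotation: RegurgitationAnnotation,
    window_len_s: float = 3.0,
    **chain_kwargs,
) -> list[LabeledEvent]:
    """Detect breath events in one recording and label them PRDI/NRI."""
    events = events_from_series(series, **chain_kwargs)
    windows = build_windows(annotation, window_len_s=window_len_s)
    return label_events(events, windows, recording_id=series.recording_id)


def simulate_study(
    n_recordings: int,
    base_config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    window_len_s: float = 3.0,
    **chain_kwargs,
) -> list[LabeledEvent]:
    """Simulate ``n_recordings`` recordings and pool their labeled events.

    Per-recording seeds are derived from ``seed``; ground-truth
    regurgitation times from the simulator serve as the annotations.
    """
    children = np.random.SeedSequence(seed).generate_state(n_recordings) % (2**31)
    pooled: list[LabeledEvent] = []
    for s in children:
        rec = simulate_recording(replace(base_config, seed=int(s)))
        ann = RegurgitationAnnotation(
            recording_id=rec.series.recording_id, regurg_times_s=rec.regurg_times_s
        )
        pooled.extend(
            label_recording(rec.series, ann, window_len_s=window_len_s, **chain_kwargs)
        )
    return pooled


def fit_pooled(events: Sequence[LabeledEvent]) -> PRDIThresholdResults:
    """Fit the depth-threshold model on pooled labeled events."""
    return PRDIThresholdModel(events).fit()
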