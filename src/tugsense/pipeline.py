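"""End-to-end convenience layer: train the hierarchy, detect events, score.

These functions wire the modules together the way the command-line interface
(and most callers) use them: labeled recordings -> trained hierarchy ->
per-sample labels -> smoothed segments -> matched TUG events.
"""

from __future__ import annotations

import numpy as np

from .defaults import RunConfig
from .grammar import TugEvent, match_tug
from .model import (
    HierarchicalModel,
    build_training_set,
    classify_stream,
    segment_labels,
    train_classifier,
)
from .recording import ImuRecording

__all__ = ["train_hierarchy", "detect_events", "match_events_to_truth"]


def train_hierarchy(
    recordings,
    config: RunConfig | None = None,
    seed: int = 0,
    oversample_transitions: bool = False,
) -> HierarchicalModel:
    """Train all four classifiers on labeled recordings."""
    config = config or RunConfig()
    classifiers = {}
    for level, cc in config.classifiers.items():
        X, y, _ = build_training_set(recordings, cc, oversample_transitions)
        classifiers[level] = train_classifier(X, y, cc, seed=seed)
    return HierarchicalModel(classifiers)


def detect_events(
    rec: ImuRecording,
    model: HierarchicalModel,
    config: RunConfig | None = None,
) -> list[TugEvent]:
    """Classify a recording and match TUG executions in the label stream."""
    config = config or RunConfig()
    track = classify_stream(rec, model)
    segments = segment_labels(
        track,
        rec.sample_rate,
        min_duration_s=config.min_segment_s,
        t0=float(rec.timestamps[0]) if len(rec) else 0.0,
    )
    return match_tug(
        segments,
        model_set=config.model_set,
        max_duration_s=config.max_tug_duration_s,
        boundary_min_s=config.boundary_min_s,
    )


def match_events_to_truth(
    events: list[TugEvent], truth_events: list[dict], tolerance_s: float = 2.0
):
    """Pair detected events with manifest ground truth by start-time proximity.

    Returns (pairs, misses): ``pairs`` is a list of (truth, detected) whose
    starts agree within ``tolerance_s``; ``misses`` the unmatched truths.
    """
    pairs, misses = [], []
    used = set()
    for truth in truth_events:
        best, best_d = None, tolerance_s
        for i, ev in enumerate(events):
            if i in used:
                continue
            d = abs(ev.start_s - truth["start_s"])
            if d <= best_d:
                best, best_d = i, d
        if best is None:
            misses.append(truth)
        else:
            used.add(best)
            pairs.append((truth, events[best]))
    return pairs, misses
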