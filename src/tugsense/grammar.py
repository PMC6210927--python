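"""Rule-based TUG sequence recognition over an activity-segment stream.

A valid Timed Up and Go execution is an ordered run of phase tokens —
sit-to-stand (↑), walk (W), turn (T), stand-to-sit (↓) — bounded by sitting or
standing.  Nine templates are accepted by default; beyond the canonical
↑WTWT↓ they tolerate doubled activities (merged beforehand) and short
implausible fragments such as a spurious ↑↓ pair, which real classifier
output produces at transition boundaries.  Each match yields per-phase and
total durations; matches at or above a duration ceiling (default 30 s) are
discarded as outside the test's plausible range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import LabelSegment

__all__ = [
    "PHASE_LABELS",
    "TugTemplate",
    "TugModelSet",
    "TugEvent",
    "DEFAULT_MODEL_SET",
    "parse_template",
    "canonicalize_segments",
    "match_tug",
    "phase_durations",
    "cumulative_accuracy",
    "events_to_frame",
]

PHASE_LABELS = ("sit_to_stand", "walk", "turn", "stand_to_sit")

_TOKEN_TO_LABEL = {
    "↑": "sit_to_stand",
    "^": "sit_to_stand",
    "W": "walk",
    "T": "turn",
    "↓": "stand_to_sit",
    "v": "stand_to_sit",
}
_LABEL_TO_TOKEN = {
    "sit_to_stand": "↑",
    "walk": "W",
    "turn": "T",
    "stand_to_sit": "↓",
}


def parse_template(notation: str) -> tuple[str, ...]:
    """Parse arrow/letter notation (``"↑WTWT↓"``; ASCII ``^``/``v`` accepted)."""
    labels = []
    for ch in notation:
        if ch in " \t":
            continue
        if ch not in _TOKEN_TO_LABEL:
            raise ValueError(f"unknown phase token {ch!r} in {notation!r}")
        labels.append(_TOKEN_TO_LABEL[ch])
    if not labels:
        raise ValueError("empty template")
    return tuple(labels)


@dataclass(frozen=True)
class TugTemplate:
    """One accepted phase sequence; must start with ↑ and end with ↓."""

    template_id: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.labels[0] != "sit_to_stand" or self.labels[-1] != "stand_to_sit":
            raise ValueError("template must start with sit_to_stand and end with stand_to_sit")
        bad = set(self.labels) - set(PHASE_LABELS)
        if bad:
            raise ValueError(f"non-phase labels in template: {sorted(bad)}")

    @classmethod
    def from_notation(cls, template_id: int, notation: str) -> "TugTemplate":
        return cls(template_id, parse_template(notation))

    @property
    def notation(self) -> str:
        return "".join(_LABEL_TO_TOKEN[lab] for lab in self.labels)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class TugModelSet:
    """The accepted templates, optionally with per-template recognition
    accuracies (percent) carried along for reporting."""

    templates: tuple[TugTemplate, ...]
    accuracies: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.accuracies is not None and len(self.accuracies) != len(self.templates):
            raise ValueError("need one accuracy per template")

    @property
    def cumulative_accuracy(self) -> float:
        if self.accuracies is None:
            return 0.0
        return cumulative_accuracy(self.accuracies)

    def without(self, template_id: int) -> "TugModelSet":
        keep = [i for i, t in enumerate(self.templates) if t.template_id != template_id]
        return TugModelSet(
            tuple(self.templates[i] for i in keep),
            None if self.accuracies is None else tuple(self.accuracies[i] for i in keep),
        )


#: The nine accepted sequence templates with their recognition accuracies
#: (percent of test executions recognized by each, summing to 96.55).
DEFAULT_MODEL_SET = TugModelSet(
    templates=tuple(
        TugTemplate.from_notation(i + 1, s)
        for i, s in enumerate(
            [
                "↑WTWT↓",
                "↑↓WTWT↓",
                "↑↓TWT↓",
                "↑↓T↓",
                "↑↓WT↓",
                "↑TWT↓",
                "↑↓WTWTW↓",
                "↑WTWTW↓",
                "↑WT↓",
            ]
        )
    ),
    accuracies=(15.37, 52.15, 12.35, 5.67, 4.34, 2.34, 1.67, 1.33, 1.33),
)


@dataclass(frozen=True)
class TugEvent:
    """One matched TUG execution.

    ``phases`` are the matched segments in template order; the total duration
    runs from the start of the first matched segment to the end of the last
    (the test is timed until the subject is seated again).
    """

    template_id: int
    phases: tuple[LabelSegment, ...]
    total_duration_s: float

    @property
    def start_s(self) -> float:
        return self.phases[0].start_s

    @property
    def end_s(self) -> float:
        return self.phases[-1].end_s


def canonicalize_segments(segments) -> list[LabelSegment]:
    """Merge consecutive same-label segments into one (time union).

    Doubled activities such as turn-turn are a frequent, legitimate artifact
    of window classification and count as a single phase.  Any gap between the
    merged segments is absorbed.  Confidences are duration-weighted averages.
    """
    out: list[LabelSegment] = []
    for seg in segments:
        if out and seg.label == out[-1].label:
            prev = out[-1]
            w1, w2 = prev.duration_s, seg.duration_s
            conf = (prev.mean_confidence * w1 + seg.mean_confidence * w2) / (w1 + w2)
            out[-1] = replace(
                prev,
                start_s=min(prev.start_s, seg.start_s),
                end_s=max(prev.end_s, seg.end_s),
                mean_confidence=conf,
            )
        else:
            out.append(replace(seg))
    return out


def _episodes(segments, boundary_min_s: float):
    """Split the canonicalized stream into candidate episodes.

    Sit/stand (and unknown) segments delimit episodes: a run of phase tokens
    between two such boundaries is one candidate.  Non-phase segments shorter
    than ``boundary_min_s`` are skipped rather than terminating the episode,
    tolerating brief misclassification blips inside an execution.
    """
    episodes: list[list[LabelSegment]] = []
    current: list[LabelSegment] = []
    for seg in segments:
        if seg.label in PHASE_LABELS:
            current.append(seg)
        elif seg.duration_s >= boundary_min_s:
            if current:
                episodes.append(current)
            current = []
        # short non-phase blip: skip
    if current:
        episodes.append(current)
    return episodes


def match_tug(
    segments,
    model_set: TugModelSet = DEFAULT_MODEL_SET,
    max_duration_s: float = 30.0,
    boundary_min_s: float = 1.0,
) -> list[TugEvent]:
    """Find all non-overlapping TUG executions in a canonicalized segment stream.

    Within each candidate episode the phase-token sequence is scanned left to
    right; at each position the templates are tried longest first (then by
    template id) and the first exact contiguous match is emitted, provided its
    span is below ``max_duration_s``.  Matched segments are consumed, so events
    never overlap.  An empty list — never an error — means no valid execution.
    """
    segments = canonicalize_segments(segments)
    order = sorted(model_set.templates, key=lambda t: (-len(t), t.template_id))
    events: list[TugEvent] = []
    for episode in _episodes(segments, boundary_min_s):
        labels = [seg.label for seg in episode]
        pos = 0
        while pos < len(labels):
            matched = None
            for tpl in order:
                k = len(tpl)
                if labels[pos : pos + k] == list(tpl.labels):
                    span = episode[pos + k - 1].end_s - episode[pos].start_s
                    if span < max_duration_s:
                        matched = (tpl, k, span)
                        break
            if matched is None:
                pos += 1
            else:
                tpl, k, span = matched
                events.append(
                    TugEvent(tpl.template_id, tuple(episode[pos : pos + k]), span)
                )
                pos += k
    return events


def phase_durations(event: TugEvent) -> dict[str, float]:
    """Named per-phase durations of a matched event.

    Walks and turns are numbered in order of occurrence (``walk_1``,
    ``turn_1``, ...); the single rise is ``sit_to_stand``; the final descent is
    ``stand_to_sit`` and any earlier descent (the tolerated spurious ↑↓ pair)
    is ``stand_to_sit_spurious``.  Phases a template does not contain are
    absent from the mapping, not zero.
    """
    out: dict[str, float] = {}
    walk = turn = 0
    last_down = max(
        i for i, seg in enumerate(event.phases) if seg.label == "stand_to_sit"
    )
    for i, seg in enumerate(event.phases):
        if seg.label == "walk":
            walk += 1
            out[f"walk_{walk}"] = seg.duration_s
        elif seg.label == "turn":
            turn += 1
            out[f"turn_{turn}"] = seg.duration_s
        elif seg.label == "sit_to_stand":
            out["sit_to_stand"] = seg.duration_s
        elif i == last_down:
            out["stand_to_sit"] = seg.duration_s
        else:
            out["stand_to_sit_spurious"] = seg.duration_s
    return out


def cumulative_accuracy(per_template_accuracies) -> float:
    """Cumulative recognition accuracy: the plain sum of the per-template
    recognition accuracies, in percent.  Empty input sums to 0."""
    return float(np.sum(np.asarray(list(per_template_accuracies), dtype=float)))


_EXPORT_PHASES = (
    "sit_to_stand",
    "walk_1",
    "turn_1",
    "walk_2",
    "turn_2",
    "walk_3",
    "stand_to_sit",
    "stand_to_sit_spurious",
)


def events_to_frame(events, subject_id: str = "") -> pd.DataFrame:
    """Tabulate events for delimited-text export (one row per event)."""
    rows = []
    for ev in events:
        row = {
            "subject": subject_id,
            "template_id": ev.template_id,
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "total_duration_s": ev.total_duration_s,
        }
        durs = phase_durations(ev)
        for name in _EXPORT_PHASES:
            row[name] = durs.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["subject", "template_id", "start_s", "end_s", "total_duration_s", *_EXPORT_PHASES],
    )
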