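"""Seeded generator of labeled synthetic hip-IMU recordings.

The generator produces the morphology a belt-worn lower-back sensor shows
during a Timed Up and Go execution: near-constant gravity-dominated channels
while sitting or standing (with a pitch offset separating the two postures),
periodic vertical step peaks while walking, a sustained mediolateral gyroscope
plateau during turns, and a biphasic anterior-posterior acceleration pulse
with a monotone pitch ramp during sit-to-stand / stand-to-sit transitions
(opposite signs for the two directions).  Signals are stylized primitives,
not biomechanics: they exercise the pipeline's contracts — windowing,
classification, segmentation, sequence matching, timing — with exactly known
ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .recording import G_MS2, ImuRecording

__all__ = [
    "SignalParams",
    "ActivityScript",
    "Corpus",
    "generate",
    "generate_corpus",
    "standard_tug_script",
    "chair_change_script",
    "ACTIVITIES",
]

ACTIVITIES = ("sit", "stand", "walk", "turn", "sit_to_stand", "stand_to_sit")


@dataclass(frozen=True)
class SignalParams:
    """Amplitude/timing parameters of the signal primitives.

    Defaults are scaled to a ~12 s test execution: a 2 Hz step cadence
    (about 3 steps per 3 m walk at older adults' gait speed), step peaks of
    3 m/s^2 on the vertical axis, 120 deg/s turn plateaus, a 20 deg trunk
    pitch while seated, and Gaussian channel noise of 0.2 m/s^2 / 2 deg/s.
    """

    cadence_hz: float = 2.0
    step_peak_ms2: float = 3.0
    turn_rate_dps: float = 120.0
    sit_pitch_deg: float = 20.0
    transition_peak_ms2: float = 2.5
    noise_sd_acc: float = 0.2
    noise_sd_gyro: float = 2.0


@dataclass(frozen=True)
class ActivityScript:
    """An ordered (activity, duration) program plus signal parameters and seed.

    The seed fully determines the generated recording.
    """

    steps: tuple[tuple[str, float], ...]
    params: SignalParams = field(default_factory=SignalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple((str(a), float(d)) for a, d in self.steps))
        for activity, duration in self.steps:
            if activity not in ACTIVITIES:
                raise ValueError(f"unknown activity {activity!r}; known: {ACTIVITIES}")
            if duration <= 0:
                raise ValueError(f"non-positive duration for {activity!r}")

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.steps)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5 + 1e-9))


def _plateau(n: int, ramp: int) -> np.ndarray:
    """Unit plateau with raised-cosine edges of ``ramp`` samples."""
    env = np.ones(n)
    r = min(ramp, n // 2)
    if r > 0:
        edge = 0.5 * (1 - np.cos(np.linspace(0, np.pi, r)))
        env[:r] = edge
        env[n - r :] = edge[::-1]
    return env


def generate(script: ActivityScript, sample_rate: float = 100.0) -> ImuRecording:
    """Render an activity script into a labeled IMU recording.

    Gravity is distributed between the vertical and anterior-posterior axes
    according to the current trunk pitch (``sit_pitch_deg`` while seated, 0
    upright); transitions ramp the pitch with a raised cosine, so the
    mediolateral gyroscope carries the signed pitch rate (negative rising,
    positive sitting down).  The label track matches the script exactly.
    """
    p = script.params
    rng = np.random.default_rng(script.seed)
    counts = [_round_half_up(d * sample_rate) for _, d in script.steps]
    n = int(np.sum(counts))
    acc = np.zeros((n, 3))  # V, ML, AP
    gyro = np.zeros((n, 3))
    labels = np.empty(n, dtype=object)

    pitch = np.zeros(n)  # degrees
    pos = 0
    for (activity, _dur), k in zip(script.steps, counts):
        sl = slice(pos, pos + k)
        tau = np.arange(k) / sample_rate
        labels[sl] = activity
        if activity == "sit":
            pitch[sl] = p.sit_pitch_deg
        elif activity in ("stand", "walk", "turn"):
            pitch[sl] = 0.0
        elif activity == "sit_to_stand":
            ramp = 0.5 * (1 + np.cos(np.pi * np.arange(k) / max(k - 1, 1)))
            pitch[sl] = p.sit_pitch_deg * ramp  # sit_pitch -> 0
        else:  # stand_to_sit
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / max(k - 1, 1)))
            pitch[sl] = p.sit_pitch_deg * ramp  # 0 -> sit_pitch

        if activity == "walk":
            s = np.sin(2 * np.pi * p.cadence_hz * tau)
            bump = p.step_peak_ms2 * np.where(s > 0, s * s, 0.0)
            acc[sl, 0] += bump
            acc[sl, 2] += 0.3 * p.step_peak_ms2 * np.sin(2 * np.pi * p.cadence_hz * tau)
            gyro[sl, 0] += 10.0 * np.sin(np.pi * p.cadence_hz * tau)
        elif activity == "turn":
            gyro[sl, 1] += p.turn_rate_dps * _plateau(k, _round_half_up(0.2 * sample_rate))
            acc[sl, 1] += 0.4 * np.sin(2 * np.pi * 1.0 * tau)
        elif activity in ("sit_to_stand", "stand_to_sit"):
            sign = 1.0 if activity == "sit_to_stand" else -1.0
            T = k / sample_rate
            acc[sl, 2] += sign * p.transition_peak_ms2 * np.sin(2 * np.pi * tau / T)
            acc[sl, 0] += 0.5 * p.transition_peak_ms2 * np.sin(np.pi * tau / T)
        pos += k

    rad = np.radians(pitch)
    acc[:, 0] += G_MS2 * np.cos(rad)
    acc[:, 2] += G_MS2 * np.sin(rad)
    # signed pitch rate on the mediolateral gyro axis
    if n > 1:
        gyro[:, 1] += np.gradient(pitch) * sample_rate

    if p.noise_sd_acc > 0:
        acc += rng.normal(0.0, p.noise_sd_acc, acc.shape)
    if p.noise_sd_gyro > 0:
        gyro += rng.normal(0.0, p.noise_sd_gyro, gyro.shape)

    t = np.arange(n) / sample_rate
    return ImuRecording(t, acc, gyro, sample_rate, labels=labels)


# ---------------------------------------------------------------------------
# scripted episodes and corpora
# ---------------------------------------------------------------------------


def standard_tug_script(
    rng: np.random.Generator | None = None,
    walk_s: float = 3.0,
    transition_s: float = 1.5,
    turn_s: float = 1.5,
    lead_sit_s: float = 2.5,
    tail_sit_s: float = 2.5,
) -> tuple[tuple[str, float], ...]:
    """Steps of a standard test: sit, rise, 3 m out, turn, 3 m back, turn,
    sit down, sit — about 12 s of execution with the defaults.  Passing a
    generator jitters the durations subject-realistically."""
    if rng is not None:
        walk_s = float(np.clip(rng.normal(walk_s, 0.4), 2.0, 5.0))
        transition_s = float(np.clip(rng.normal(transition_s, 0.15), 1.0, 2.5))
        turn_s = float(np.clip(rng.normal(turn_s, 0.15), 1.0, 2.5))
        lead_sit_s = float(rng.uniform(2.0, 3.5))
        tail_sit_s = float(rng.uniform(2.0, 3.5))
    return (
        ("sit", lead_sit_s),
        ("sit_to_stand", transition_s),
        ("walk", walk_s),
        ("turn", turn_s),
        ("walk", walk_s),
        ("turn", turn_s),
        ("stand_to_sit", transition_s),
        ("sit", tail_sit_s),
    )


def chair_change_script(
    rng: np.random.Generator | None = None,
    distance_m: float = 3.55,
    speed_ms: float = 1.0,
    transition_s: float = 1.5,
    turn_s: float = 1.5,
) -> tuple[tuple[str, float], ...]:
    """A naturalistic chair-to-chair sequence: rise, one walk (3-4.1 m), one
    turn, sit down — the semi-unsupervised variant of the test."""
    if rng is not None:
        distance_m = float(rng.uniform(3.0, 4.1))
        speed_ms = float(np.clip(rng.normal(speed_ms, 0.15), 0.6, 1.5))
        transition_s = float(np.clip(rng.normal(transition_s, 0.15), 1.0, 2.5))
    return (
        ("sit", 2.5),
        ("sit_to_stand", transition_s),
        ("walk", distance_m / speed_ms),
        ("turn", turn_s),
        ("stand_to_sit", transition_s),
        ("sit", 2.5),
    )


_DISTRACTOR = (
    ("sit", 3.0),
    ("stand", 2.5),
    ("walk", 5.0),
    ("turn", 1.5),
    ("walk", 5.0),
    ("stand", 2.0),
    ("sit", 3.0),
)


@dataclass
class Corpus:
    """A set of generated recordings with their ground truth manifest.

    ``manifest[i]`` holds the i-th recording's subject id, scripted segments
    and embedded events (type ``"tug"`` or ``"chair_change"`` with start/end/
    duration in seconds).
    """

    recordings: list[ImuRecording]
    manifest: list[dict]

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=1)


def _script_truth(steps) -> tuple[list[dict], list[dict]]:
    """Segment list and embedded events implied by a script."""
    segments, events = [], []
    t = 0.0
    for activity, dur in steps:
        segments.append({"label": activity, "start_s": t, "end_s": t + dur})
        t += dur
    phase = [s for s in segments if s["label"] not in ("sit", "stand")]
    # an embedded execution runs from each rise to the next sit-down
    i = 0
    while i < len(phase):
        if phase[i]["label"] == "sit_to_stand":
            j = i
            while j < len(phase) and phase[j]["label"] != "stand_to_sit":
                j += 1
            if j < len(phase):
                n_walk = sum(1 for s in phase[i : j + 1] if s["label"] == "walk")
                events.append(
                    {
                        "type": "tug" if n_walk >= 2 else "chair_change",
                        "start_s": phase[i]["start_s"],
                        "end_s": phase[j]["end_s"],
                        "duration_s": phase[j]["end_s"] - phase[i]["start_s"],
                    }
                )
                i = j + 1
                continue
        i += 1
    return segments, events


def generate_corpus(
    n_subjects: int,
    tug_fraction: float = 1.0,
    distractor_activities: bool = True,
    seed: int = 0,
    chair_change_fraction: float = 0.0,
    params: SignalParams = SignalParams(),
    sample_rate: float = 100.0,
) -> Corpus:
    """Generate one labeled recording per synthetic subject.

    A fraction ``tug_fraction`` of subjects perform a standard test episode;
    ``chair_change_fraction`` adds naturalistic chair-to-chair episodes; with
    ``distractor_activities`` every recording also contains a walk/stand
    sequence that must not be mistaken for a test.  Per-subject amplitude
    jitter (cadence, turn rate, seated pitch) emulates inter-individual
    variation.  Fully determined by ``seed``.
    """
    rng = np.random.default_rng(seed)
    recordings, manifest = [], []
    for i in range(n_subjects):
        srng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        subject = f"S{i:03d}"
        subj_params = replace(
            params,
            cadence_hz=float(np.clip(srng.normal(params.cadence_hz, 0.15), 1.4, 2.6)),
            turn_rate_dps=float(np.clip(srng.normal(params.turn_rate_dps, 15.0), 80.0, 180.0)),
            sit_pitch_deg=float(np.clip(srng.normal(params.sit_pitch_deg, 2.0), 14.0, 28.0)),
            step_peak_ms2=float(np.clip(srng.normal(params.step_peak_ms2, 0.3), 2.0, 4.5)),
        )
        steps: list[tuple[str, float]] = []
        if srng.random() < tug_fraction:
            steps.extend(standard_tug_script(srng))
        if srng.random() < chair_change_fraction:
            steps.extend(chair_change_script(srng))
        if distractor_activities or not steps:
            steps.extend(_DISTRACTOR)
        script = ActivityScript(
            tuple(steps), params=subj_params, seed=int(srng.integers(0, 2**31 - 1))
        )
        rec = generate(script, sample_rate)
        rec.subject_id = subject
        segments, events = _script_truth(script.steps)
        recordings.append(rec)
        manifest.append(
            {
                "subject_id": subject,
                "duration_s": rec.duration_s,
                "segments": segments,
                "events": events,
            }
        )
    return Corpus(recordings, manifest)
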