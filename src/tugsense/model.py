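"""Two-level hierarchical activity classification for belt-worn IMU streams.

A *state* classifier first labels each window as static / dynamic / transition;
three specialist classifiers then resolve the fine activity within each state
(static: sit vs stand, dynamic: walk vs turn, transition: sit-to-stand vs
stand-to-sit).  Every classifier runs on its own filter and window grid; the
four asynchronous window tracks are fused to a per-sample label stream by
nearest-window-center assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostClassifier, HistGradientBoostingClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix, FeatureSpec, WindowSpec, extract_features
from .metrics import MetricsReport, compute_metrics, per_class_counts
from .recording import FilterSpec, ImuRecording, apply_filter

__all__ = [
    "LEVELS",
    "LEVEL_ALPHABET",
    "STATE_OF",
    "UNKNOWN",
    "ClassifierConfig",
    "LabelSegment",
    "TrainedClassifier",
    "HierarchicalModel",
    "train_classifier",
    "build_training_set",
    "classify_stream",
    "segment_labels",
    "segments_to_track",
    "cross_validate",
    "save_model",
    "load_model",
]

UNKNOWN = "unknown"
LEVELS = ("state", "static", "dynamic", "transition")
LEVEL_ALPHABET = {
    "state": ("static", "dynamic", "transition"),
    "static": ("sit", "stand"),
    "dynamic": ("walk", "turn"),
    "transition": ("sit_to_stand", "stand_to_sit"),
}
#: which state each fine activity belongs to
STATE_OF = {
    "sit": "static",
    "stand": "static",
    "walk": "dynamic",
    "turn": "dynamic",
    "sit_to_stand": "transition",
    "stand_to_sit": "transition",
}
METHODS = ("boosted_decision_trees", "boosted_decision_stump", "multilayer_perceptron")


@dataclass(frozen=True)
class ClassifierConfig:
    """Full configuration of one classifier in the hierarchy.

    ``hyperparams`` carries method-specific settings: for boosting ``rounds``
    (default 200) and ``depth`` (default 3; stumps are fixed at 1), for the
    multilayer perceptron ``hidden_layers`` x ``hidden_nodes`` (read as that
    many equally sized layers) plus ``max_iter``.
    """

    level: str
    method: str
    window: WindowSpec
    filter: FilterSpec
    features: tuple[FeatureSpec, ...]
    hyperparams: dict = field(default_factory=dict)
    autocorr_lag_s: float = 0.5

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        object.__setattr__(self, "features", tuple(self.features))

    @property
    def alphabet(self) -> tuple[str, ...]:
        return LEVEL_ALPHABET[self.level]


@dataclass
class LabelSegment:
    """A contiguous run of one activity label in seconds."""

    label: str
    start_s: float
    end_s: float
    mean_confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("segment must have end_s > start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _make_estimator(config: ClassifierConfig, seed: int):
    hp = config.hyperparams
    if config.method == "boosted_decision_trees":
        return HistGradientBoostingClassifier(
            max_iter=int(hp.get("rounds", 200)),
            max_depth=int(hp.get("depth", 3)),
            learning_rate=float(hp.get("learning_rate", 0.1)),
            random_state=seed,
        )
    if config.method == "boosted_decision_stump":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
            n_estimators=int(hp.get("rounds", 200)),
            learning_rate=float(hp.get("learning_rate", 1.0)),
            random_state=seed,
        )
    layers = (int(hp.get("hidden_nodes", 10)),) * int(hp.get("hidden_layers", 1))
    # perceptrons need standardized inputs; the scaler is fit on training data
    # only and travels with the model
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=layers,
                    max_iter=int(hp.get("max_iter", 400)),
                    random_state=seed,
                ),
            ),
        ]
    )


@dataclass
class TrainedClassifier:
    """A fitted estimator bound to its configuration and feature schema."""

    config: ClassifierConfig
    estimator: object
    feature_names: tuple[str, ...]

    def predict(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(values), dtype=object)


def train_classifier(
    features: FeatureMatrix | np.ndarray,
    labels,
    config: ClassifierConfig,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit one classifier on per-window feature vectors.

    Labels must come from the level's alphabet and at least two classes must
    be present; a single-class input raises an error naming the missing ones.
    Training is deterministic for a fixed seed.
    """
    if isinstance(features, FeatureMatrix):
        X, names = features.values, features.columns
    else:
        X = np.asarray(features, dtype=float)
        names = tuple(f"f{i}" for i in range(X.shape[1]))
    y = np.asarray(labels, dtype=object)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have equal length")
    present = set(y)
    bad = present - set(config.alphabet)
    if bad:
        raise ValueError(f"labels {sorted(bad)} not in level {config.level!r} alphabet")
    if len(present) < 2:
        missing = sorted(set(config.alphabet) - present)
        raise ValueError(
            f"training needs >= 2 classes; got {sorted(present)}, missing {missing}"
        )
    est = _make_estimator(config, seed)
    est.fit(X, y.astype(str))
    return TrainedClassifier(config, est, names)


# ---------------------------------------------------------------------------
# training-set extraction from labeled recordings
# ---------------------------------------------------------------------------


def _window_truth_labels(rec: ImuRecording, fm: FeatureMatrix) -> np.ndarray:
    """Ground-truth label of each window: the label at the window's center sample."""
    if rec.labels is None:
        raise ValueError("recording has no label track")
    centers = np.clip(
        np.round((fm.center_times - rec.timestamps[0]) * rec.sample_rate).astype(int),
        0,
        len(rec) - 1,
    )
    return rec.labels[centers]


def build_training_set(
    recordings,
    config: ClassifierConfig,
    oversample_transitions: bool = False,
):
    """Window features + labels + subject groups for one classifier level.

    For the state level, fine ground-truth labels are mapped to their states.
    For a specialist level only windows whose true state matches that level are
    kept.  ``oversample_transitions`` duplicates transition windows (the rarest
    class) in the extracted set, mirroring deliberate enrichment of
    underrepresented activities.
    """
    Xs, ys, gs = [], [], []
    for rec in recordings:
        filtered = apply_filter(rec, config.filter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fm = extract_features(filtered, config.window, config.features, config.autocorr_lag_s)
        if fm.values.shape[0] == 0:
            continue
        fine = _window_truth_labels(rec, fm)
        known = np.array([lab in STATE_OF for lab in fine])
        fine = fine[known]
        vals = fm.values[known]
        states = np.array([STATE_OF[lab] for lab in fine], dtype=object)
        if config.level == "state":
            keep = np.ones(len(fine), dtype=bool)
            labels = states
        else:
            keep = states == config.level
            labels = fine
        vals, labels = vals[keep], labels[keep]
        if oversample_transitions:
            is_tr = np.array(
                [lab == "transition" or STATE_OF.get(lab) == "transition" for lab in labels]
            )
            if np.any(is_tr):
                vals = np.vstack([vals, vals[is_tr]])
                labels = np.concatenate([labels, labels[is_tr]])
        Xs.append(vals)
        ys.append(labels)
        gs.extend([rec.subject_id] * len(labels))
    if not Xs:
        return np.empty((0, 0)), np.empty(0, dtype=object), np.empty(0, dtype=object)
    return np.vstack(Xs), np.concatenate(ys), np.asarray(gs, dtype=object)


# ---------------------------------------------------------------------------
# the hierarchy and stream classification
# ---------------------------------------------------------------------------


@dataclass
class HierarchicalModel:
    """The four trained classifiers keyed by level."""

    classifiers: dict[str, TrainedClassifier]

    def __post_init__(self) -> None:
        missing = set(LEVELS) - set(self.classifiers)
        if missing:
            raise ValueError(f"missing classifiers for levels {sorted(missing)}")

    def classify(self, rec: ImuRecording) -> np.ndarray:
        return classify_stream(rec, self)


def _window_track(rec: ImuRecording, clf: TrainedClassifier):
    """Per-sample label track from one classifier's own grid.

    Each sample takes the label of the window whose center is nearest (ties go
    to the earlier window).  Samples outside the span covered by windows are
    left unknown.
    """
    n = len(rec)
    track = np.full(n, UNKNOWN, dtype=object)
    filtered = apply_filter(rec, clf.config.filter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fm = extract_features(
            filtered, clf.config.window, clf.config.features, clf.config.autocorr_lag_s
        )
    if fm.values.shape[0] == 0:
        return track
    preds = clf.predict(fm.values)
    win = clf.config.window.size_samples(rec.sample_rate)
    centers = fm.start_indices + (win - 1) / 2.0
    samples = np.arange(n)
    pos = np.searchsorted(centers, samples)
    left = np.clip(pos - 1, 0, len(centers) - 1)
    right = np.clip(pos, 0, len(centers) - 1)
    # ties (equidistant) go to the earlier (left) window
    take_left = np.abs(samples - centers[left]) <= np.abs(centers[right] - samples)
    nearest = np.where(take_left, left, right)
    covered = (samples >= fm.start_indices[0]) & (samples < fm.start_indices[-1] + win)
    track[covered] = preds[nearest[covered]]
    return track


def classify_stream(rec: ImuRecording, model: HierarchicalModel) -> np.ndarray:
    """Per-sample fine activity labels for a recording.

    The state classifier picks each sample's state; the matching specialist
    supplies the fine label.  Samples covered by no window of the relevant
    grids are labeled ``"unknown"``.  A recording shorter than the largest
    window yields an all-unknown track with a warning.
    """
    n = len(rec)
    state_track = _window_track(rec, model.classifiers["state"])
    fine = np.full(n, UNKNOWN, dtype=object)
    for level in ("static", "dynamic", "transition"):
        mask = state_track == level
        if not np.any(mask):
            continue
        sub_track = _window_track(rec, model.classifiers[level])
        fine[mask] = sub_track[mask]
    if not np.any(fine != UNKNOWN) and n > 0:
        warnings.warn("no sample could be classified (recording too short?)", stacklevel=2)
    return fine


# ---------------------------------------------------------------------------
# label-track segmentation
# ---------------------------------------------------------------------------


def segment_labels(
    track,
    sample_rate: float,
    min_duration_s: float = 0.0,
    t0: float = 0.0,
) -> list[LabelSegment]:
    """Run-length encode a per-sample label track into segments.

    Runs shorter than ``min_duration_s`` are absorbed into their longer
    neighbor (repeatedly, shortest first) and adjacent equal labels are then
    re-merged, so the output alternates labels.  Segment times are half-open:
    a run of k samples spans k / sample_rate seconds starting at ``t0``.
    """
    track = np.asarray(track, dtype=object)
    n = track.shape[0]
    if n == 0:
        return []
    # runs as [label, start_idx, end_idx) triples
    change = np.nonzero(track[1:] != track[:-1])[0] + 1
    bounds = np.concatenate([[0], change, [n]])
    runs = [
        [track[bounds[i]], int(bounds[i]), int(bounds[i + 1])]
        for i in range(len(bounds) - 1)
    ]

    min_len = min_duration_s * sample_rate

    def merge_equal(rs):
        out = [rs[0]]
        for r in rs[1:]:
            if r[0] == out[-1][0]:
                out[-1][2] = r[2]
            else:
                out.append(r)
        return out

    runs = merge_equal(runs)
    while len(runs) > 1:
        lengths = [r[2] - r[1] for r in runs]
        short = [i for i, ln in enumerate(lengths) if ln < min_len]
        if not short:
            break
        i = min(short, key=lambda k: (lengths[k], k))
        if i == 0:
            runs[1][1] = runs[0][1]
            del runs[0]
        elif i == len(runs) - 1:
            runs[-2][2] = runs[-1][2]
            del runs[-1]
        else:
            left_len, right_len = lengths[i - 1], lengths[i + 1]
            if left_len >= right_len:
                runs[i - 1][2] = runs[i][2]
            else:
                runs[i + 1][1] = runs[i][1]
            del runs[i]
        runs = merge_equal(runs)

    return [
        LabelSegment(r[0], t0 + r[1] / sample_rate, t0 + r[2] / sample_rate)
        for r in runs
    ]


def segments_to_track(
    segments, sample_rate: float, t0: float | None = None
) -> np.ndarray:
    """Render alternating segments back to a per-sample label track."""
    if not segments:
        return np.empty(0, dtype=object)
    if t0 is None:
        t0 = segments[0].start_s
    n = int(round((segments[-1].end_s - t0) * sample_rate))
    track = np.full(n, UNKNOWN, dtype=object)
    for seg in segments:
        i0 = int(round((seg.start_s - t0) * sample_rate))
        i1 = int(round((seg.end_s - t0) * sample_rate))
        track[i0:i1] = seg.label
    return track


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def cross_validate(
    recordings,
    configs: dict[str, ClassifierConfig],
    n_folds: int = 5,
    seed: int = 0,
    oversample_transitions: bool = False,
) -> dict[str, dict[str, MetricsReport]]:
    """Five-fold cross-validation of every classifier level, subject-grouped.

    Subjects are shuffled and split into ``n_folds`` near-equal folds (sizes
    differ by at most one); each fold serves once as validation while the
    rest train.  Because adjacent windows overlap heavily, the split is at the
    subject level so no subject contributes to both sides.  Per-class
    confusion counts are pooled over folds and the metrics derived from the
    pooled counts.
    """
    recordings = list(recordings)
    subjects = sorted({rec.subject_id for rec in recordings})
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    folds = [set(f) for f in np.array_split(np.asarray(subjects, dtype=object), n_folds)]

    data = {
        level: build_training_set(recordings, cfg, oversample_transitions)
        for level, cfg in configs.items()
    }
    pooled: dict[str, dict[str, dict[str, int]]] = {
        level: {c: {"tp": 0, "fp": 0, "fn": 0, "tn": 0} for c in configs[level].alphabet}
        for level in configs
    }
    for fold in folds:
        for level, cfg in configs.items():
            X, y, groups = data[level]
            val = np.array([g in fold for g in groups])
            if not np.any(val) or not np.any(~val):
                continue
            try:
                clf = train_classifier(X[~val], y[~val], cfg, seed=seed)
            except ValueError:
                continue  # a fold may lose a class entirely on tiny corpora
            preds = clf.predict(X[val])
            counts = per_class_counts(y[val], preds, classes=cfg.alphabet)
            for c, cc in counts.items():
                for k in ("tp", "fp", "fn", "tn"):
                    pooled[level][c][k] += cc[k]
    return {
        level: {c: compute_metrics(**cc) for c, cc in per_level.items()}
        for level, per_level in pooled.items()
    }


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_BUNDLE_VERSION = 1


def save_model(model: HierarchicalModel, path) -> None:
    """Serialize the four classifiers + configs + feature schemas to one file."""
    joblib.dump({"version": _BUNDLE_VERSION, "classifiers": model.classifiers}, path)


def load_model(path) -> HierarchicalModel:
    bundle = joblib.load(path)
    if bundle.get("version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported model bundle version {bundle.get('version')!r}")
    return HierarchicalModel(bundle["classifiers"])
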