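"""Sliding-window segmentation and the per-window signal features.

Each classifier in the hierarchy works on its own window grid (window size and
step width in seconds) and its own named feature set.  The ten features are
the classic accelerometry set: mean, standard deviation, root mean square,
signal energy, signal magnitude area (SMA), signal vector magnitude (SVM),
autocorrelation, inter-channel Pearson correlation, trunk pitch, and spectral
entropy.  Scalar reference implementations are exposed one operation per
feature; :func:`extract_features` computes them vectorized over all windows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .recording import CHANNELS, ImuRecording

__all__ = [
    "WindowSpec",
    "FeatureSpec",
    "Windows",
    "FeatureMatrix",
    "make_windows",
    "extract_features",
    "feature_mean",
    "feature_sd",
    "feature_rms",
    "feature_signal_energy",
    "feature_sma",
    "feature_svm",
    "feature_autocorrelation",
    "feature_correlation",
    "feature_pitch",
    "feature_spectral_entropy",
]

FEATURE_NAMES = (
    "mean",
    "sd",
    "rms",
    "signal_energy",
    "sma",
    "svm",
    "autocorrelation",
    "correlation",
    "pitch",
    "spectral_entropy",
)

CHANNEL_SETS = {
    "acc": CHANNELS[:3],
    "gyro": CHANNELS[3:],
    "acc+gyro": CHANNELS,
}


def _round_half_up(x: float) -> int:
    # small epsilon so values that are exactly .5 in decimal (e.g. 1.405 s at
    # 100 Hz -> 140.5 samples) round up despite binary float representation
    return int(math.floor(x + 0.5 + 1e-9))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in seconds."""

    size_s: float
    step_s: float

    def __post_init__(self) -> None:
        if not (0 < self.step_s <= self.size_s):
            raise ValueError("require 0 < step_s <= size_s")

    def size_samples(self, sample_rate: float) -> int:
        return _round_half_up(self.size_s * sample_rate)

    def hop_samples(self, sample_rate: float) -> int:
        return max(1, _round_half_up(self.step_s * sample_rate))


@dataclass(frozen=True)
class FeatureSpec:
    """One named feature applied to a channel set (``acc``, ``gyro``, ``acc+gyro``).

    Per-channel features emit one column per channel in the set; ``correlation``
    emits one column per unordered channel pair; ``sma``/``svm`` emit one column
    per sensor triple in the set; ``pitch`` is a single column computed from the
    acceleration triple regardless of the tag.
    """

    feature: str
    channels: str = "acc"

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature!r}; known: {FEATURE_NAMES}")
        if self.channels not in CHANNEL_SETS:
            raise ValueError(f"unknown channel set {self.channels!r}")


@dataclass
class Windows:
    """Window decomposition of a recording: blocks plus their time anchors."""

    start_indices: np.ndarray  # (n_win,)
    center_times: np.ndarray  # (n_win,) seconds, fractional-sample centers
    blocks: np.ndarray  # (n_win, win_samples, 6) in CHANNELS order
    win_samples: int
    hop_samples: int

    def __len__(self) -> int:
        return int(self.start_indices.shape[0])


def make_windows(rec: ImuRecording, spec: WindowSpec) -> Windows:
    """Cut a recording into overlapping windows on the spec's grid.

    Window length is ``round(size_s * sample_rate)`` (half-up) and the hop is
    at least one sample.  A trailing partial window is dropped.  A recording
    shorter than one window yields an empty decomposition with a warning.
    """
    win = spec.size_samples(rec.sample_rate)
    hop = spec.hop_samples(rec.sample_rate)
    x = rec.channels
    n = x.shape[0]
    if n < win:
        warnings.warn(
            f"recording of {n} samples is shorter than one {win}-sample window",
            stacklevel=2,
        )
        return Windows(
            np.empty(0, dtype=int), np.empty(0), np.empty((0, win, 6)), win, hop
        )
    blocks = sliding_window_view(x, win, axis=0)[::hop]  # (n_win, 6, win)
    blocks = np.swapaxes(blocks, 1, 2)
    starts = np.arange(blocks.shape[0]) * hop
    t0 = rec.timestamps[0] if n else 0.0
    centers = t0 + (starts + (win - 1) / 2.0) / rec.sample_rate
    return Windows(starts, centers, blocks, win, hop)


# ---------------------------------------------------------------------------
# scalar feature definitions (normative single-window forms)
# ---------------------------------------------------------------------------


def _require_nonempty(block: np.ndarray) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    if block.size == 0:
        raise ValueError("feature of an empty block is undefined")
    return block


def feature_mean(block) -> float:
    """Arithmetic mean of one channel."""
    return float(np.mean(_require_nonempty(block)))


def feature_sd(block) -> float:
    """Population (ddof=0) standard deviation of one channel."""
    return float(np.std(_require_nonempty(block)))


def feature_rms(block) -> float:
    """Root mean square of one channel."""
    x = _require_nonempty(block)
    return float(np.sqrt(np.mean(x * x)))


def feature_signal_energy(block) -> float:
    """Sum of squared samples of one channel."""
    x = _require_nonempty(block)
    return float(np.sum(x * x))


def feature_sma(triple) -> float:
    """Signal magnitude area of a 3-channel block: mean over samples of
    |v| + |ml| + |ap|."""
    x = _require_nonempty(triple)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("sma expects an (n, 3) block")
    return float(np.mean(np.sum(np.abs(x), axis=1)))


def feature_svm(triple) -> float:
    """Signal vector magnitude: mean per-sample Euclidean norm of a 3-channel block."""
    x = _require_nonempty(triple)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("svm expects an (n, 3) block")
    return float(np.mean(np.linalg.norm(x, axis=1)))


def feature_autocorrelation(block, lag: int) -> float:
    """Normalized autocorrelation coefficient at ``lag`` samples.

    Mean-removed, normalized by the population variance, with the lagged
    product averaged over the ``n - lag`` available terms so a period-``p``
    signal scores ~1 at ``lag = p``.  Zero-variance blocks (and lags that
    leave no overlap) return 0; lag 0 returns 1.
    """
    x = _require_nonempty(block)
    n = x.shape[0]
    var = float(np.var(x))
    if var == 0.0 or lag >= n or lag < 0:
        return 1.0 if (lag == 0 and var > 0.0) else 0.0
    if lag == 0:
        return 1.0
    mu = float(np.mean(x))
    num = float(np.mean((x[: n - lag] - mu) * (x[lag:] - mu)))
    return num / var


def feature_correlation(block_a, block_b) -> float:
    """Pearson correlation between two channels of the same window; 0 when
    either channel has zero variance."""
    a = _require_nonempty(block_a)
    b = _require_nonempty(block_b)
    if a.shape != b.shape:
        raise ValueError("correlation requires equally sized blocks")
    sa, sb = float(np.std(a)), float(np.std(b))
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def feature_pitch(acc_triple) -> float:
    """Forward-tilt angle (degrees) of the window's gravity estimate:
    ``atan2(mean AP, hypot(mean V, mean ML))``.  0 deg upright, 90 deg when
    gravity lies fully on the anterior-posterior axis."""
    x = _require_nonempty(acc_triple)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("pitch expects an (n, 3) acceleration block")
    v, ml, ap = np.mean(x, axis=0)
    return float(np.degrees(np.arctan2(ap, np.hypot(v, ml))))


def feature_spectral_entropy(block) -> float:
    """Shannon entropy of the window's normalized power spectrum in [0, 1].

    The DC bin is excluded, the remaining power is normalized to a probability
    mass function, and the entropy is divided by log(number of bins).  Low for
    periodic signals, high for broadband noise; constant blocks are defined
    as 0.
    """
    x = _require_nonempty(block)
    p = np.abs(np.fft.rfft(x)) ** 2
    p = p[1:]  # drop DC
    total = float(np.sum(p))
    if total <= 0.0 or p.size < 2:
        return 0.0
    pmf = p / total
    nz = pmf[pmf > 0]
    h = -float(np.sum(nz * np.log(nz)))
    return h / math.log(p.size)


# ---------------------------------------------------------------------------
# vectorized extraction
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Per-window feature vectors with a fixed, named column order."""

    values: np.ndarray  # (n_win, n_feat)
    columns: tuple[str, ...]
    start_indices: np.ndarray
    center_times: np.ndarray


def _vec_autocorrelation(blocks: np.ndarray, lag: int) -> np.ndarray:
    n = blocks.shape[1]
    var = np.var(blocks, axis=1)
    out = np.zeros(blocks.shape[0])
    if lag == 0:
        out[var > 0] = 1.0
        return out
    if lag >= n or lag < 0:
        return out
    mu = np.mean(blocks, axis=1, keepdims=True)
    c = blocks - mu
    num = np.mean(c[:, : n - lag] * c[:, lag:], axis=1)
    good = var > 0
    out[good] = num[good] / var[good]
    return out


def _vec_spectral_entropy(blocks: np.ndarray) -> np.ndarray:
    p = np.abs(np.fft.rfft(blocks, axis=1)) ** 2
    p = p[:, 1:]
    total = np.sum(p, axis=1, keepdims=True)
    out = np.zeros(blocks.shape[0])
    good = total[:, 0] > 0
    if p.shape[1] < 2 or not np.any(good):
        return out
    pmf = np.zeros_like(p)
    pmf[good] = p[good] / total[good]
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(pmf > 0, np.log(pmf), 0.0)
    h = -np.sum(pmf * logp, axis=1)
    out[good] = h[good] / math.log(p.shape[1])
    return out


def _channel_index(name: str) -> int:
    return CHANNELS.index(name)


def feature_columns(spec: FeatureSpec) -> tuple[str, ...]:
    """Column names a single FeatureSpec expands to, in emission order."""
    chans = CHANNEL_SETS[spec.channels]
    if spec.feature in ("mean", "sd", "rms", "signal_energy", "autocorrelation", "spectral_entropy"):
        return tuple(f"{spec.feature}_{c}" for c in chans)
    if spec.feature == "correlation":
        return tuple(
            f"correlation_{a}_{b}"
            for i, a in enumerate(chans)
            for b in chans[i + 1 :]
        )
    if spec.feature in ("sma", "svm"):
        triples = []
        if set(CHANNELS[:3]) <= set(chans):
            triples.append("acc")
        if set(CHANNELS[3:]) <= set(chans):
            triples.append("gyro")
        return tuple(f"{spec.feature}_{t}" for t in triples)
    if spec.feature == "pitch":
        return ("pitch",)
    raise ValueError(spec.feature)


def extract_features(
    rec: ImuRecording,
    window: WindowSpec,
    feature_set: tuple[FeatureSpec, ...],
    autocorr_lag_s: float = 0.5,
) -> FeatureMatrix:
    """Compute the configured feature set on the recording's window grid.

    The recording is expected to have been filtered already with the
    classifier's own filter.  Column order is fixed by the feature-set order,
    so train-time and apply-time matrices always line up.
    """
    wins = make_windows(rec, window)
    lag = _round_half_up(autocorr_lag_s * rec.sample_rate)
    blocks = wins.blocks  # (n_win, w, 6)
    cols: list[str] = []
    mats: list[np.ndarray] = []

    for spec in feature_set:
        chans = CHANNEL_SETS[spec.channels]
        idx = [_channel_index(c) for c in chans]
        names = feature_columns(spec)
        cols.extend(names)
        if len(wins) == 0:
            mats.append(np.empty((0, len(names))))
            continue
        f = spec.feature
        if f == "mean":
            out = np.mean(blocks[:, :, idx], axis=1)
        elif f == "sd":
            out = np.std(blocks[:, :, idx], axis=1)
        elif f == "rms":
            out = np.sqrt(np.mean(blocks[:, :, idx] ** 2, axis=1))
        elif f == "signal_energy":
            out = np.sum(blocks[:, :, idx] ** 2, axis=1)
        elif f == "autocorrelation":
            out = np.column_stack(
                [_vec_autocorrelation(blocks[:, :, j], lag) for j in idx]
            )
        elif f == "spectral_entropy":
            out = np.column_stack([_vec_spectral_entropy(blocks[:, :, j]) for j in idx])
        elif f == "correlation":
            sub = blocks[:, :, idx]
            c = sub - np.mean(sub, axis=1, keepdims=True)
            sd = np.std(sub, axis=1)
            pairs = []
            for i in range(len(idx)):
                for j in range(i + 1, len(idx)):
                    num = np.mean(c[:, :, i] * c[:, :, j], axis=1)
                    den = sd[:, i] * sd[:, j]
                    r = np.zeros_like(num)
                    good = den > 0
                    r[good] = num[good] / den[good]
                    pairs.append(r)
            out = np.column_stack(pairs)
        elif f in ("sma", "svm"):
            outs = []
            for name in names:
                tr = CHANNELS[:3] if name.endswith("_acc") else CHANNELS[3:]
                sub = blocks[:, :, [_channel_index(c) for c in tr]]
                if f == "sma":
                    outs.append(np.mean(np.sum(np.abs(sub), axis=2), axis=1))
                else:
                    outs.append(np.mean(np.linalg.norm(sub, axis=2), axis=1))
            out = np.column_stack(outs)
        elif f == "pitch":
            sub = blocks[:, :, [0, 1, 2]]
            m = np.mean(sub, axis=1)  # (n_win, 3) -> v, ml, ap
            out = np.degrees(np.arctan2(m[:, 2], np.hypot(m[:, 0], m[:, 1])))[:, None]
        else:  # pragma: no cover - guarded by FeatureSpec validation
            raise ValueError(f)
        if out.ndim == 1:
            out = out[:, None]
        mats.append(out)

    values = (
        np.hstack(mats) if mats else np.empty((len(wins), 0))
    )
    return FeatureMatrix(values, tuple(cols), wins.start_indices, wins.center_times)
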