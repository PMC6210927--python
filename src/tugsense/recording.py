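"""Single-sensor IMU recordings: data model, delimited-text I/O, noise filters.

The sensor is a belt-worn unit at the lower back (L3-L5) sampling a triaxial
accelerometer and gyroscope at a nominal 100 Hz.  Axis order is fixed
throughout the package as (vertical V, mediolateral ML, anterior-posterior AP),
with acceleration gravity-inclusive in m/s^2 and angular rate in deg/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt

__all__ = [
    "AXES",
    "CHANNELS",
    "G_MS2",
    "FilterSpec",
    "ImuRecording",
    "read_recording",
    "write_recording",
    "apply_filter",
]

AXES = ("v", "ml", "ap")
#: canonical channel order used everywhere: 3 acceleration, then 3 gyro axes
CHANNELS = ("acc_v", "acc_ml", "acc_ap", "gyro_v", "gyro_ml", "gyro_ap")
G_MS2 = 9.81

DEFAULT_COLUMNS = {
    "time": "time",
    "acc_v": "acc_v",
    "acc_ml": "acc_ml",
    "acc_ap": "acc_ap",
    "gyro_v": "gyro_v",
    "gyro_ml": "gyro_ml",
    "gyro_ap": "gyro_ap",
    "label": "label",
}


class FormatError(ValueError):
    """Raised when an input file does not match the declared column layout."""


@dataclass(frozen=True)
class FilterSpec:
    """Noise-reduction filter applied to all six channels before windowing.

    kind
        ``"none"`` (identity), ``"lowpass"`` (4th-order zero-phase Butterworth,
        ``cutoff_hz``) or ``"gaussian"`` (Gaussian smoothing, ``sigma_s``
        standard deviation in seconds).
    """

    kind: str = "none"
    cutoff_hz: float | None = None
    sigma_s: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "lowpass", "gaussian"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "lowpass" and (self.cutoff_hz is None or self.cutoff_hz <= 0):
            raise ValueError("lowpass filter requires cutoff_hz > 0")
        if self.kind == "gaussian" and (self.sigma_s is None or self.sigma_s <= 0):
            raise ValueError("gaussian filter requires sigma_s > 0")

    def validate(self, sample_rate: float) -> None:
        if self.kind == "lowpass" and self.cutoff_hz >= sample_rate / 2:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz is not below the Nyquist "
                f"frequency {sample_rate / 2} Hz"
            )


@dataclass
class ImuRecording:
    """A time-stamped 3-axis accelerometer + 3-axis gyroscope stream.

    ``acc`` and ``gyro`` are ``(n, 3)`` arrays in (V, ML, AP) axis order;
    acceleration includes gravity.  ``labels`` is an optional per-sample
    activity label track (used as ground truth for training/evaluation).
    """

    timestamps: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    sample_rate: float
    labels: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.acc.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"acc {self.acc.shape} and gyro {self.gyro.shape} must both be "
                f"({n}, 3) to match the timestamps"
            )
        if n > 1:
            bad = np.nonzero(np.diff(self.timestamps) <= 0)[0]
            if bad.size:
                raise ValueError(
                    f"timestamps must be strictly increasing; first violation "
                    f"at row {int(bad[0]) + 1}"
                )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape[0] != n:
                raise ValueError("labels must have one entry per sample")

    def __len__(self) -> int:
        return int(self.timestamps.shape[0])

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def channels(self) -> np.ndarray:
        """All six channels as one ``(n, 6)`` array in :data:`CHANNELS` order."""
        return np.hstack([self.acc, self.gyro])

    def with_channels(self, channels: np.ndarray) -> "ImuRecording":
        """Copy of the recording with channel values replaced (same grid)."""
        channels = np.asarray(channels, dtype=float)
        return replace(self, acc=channels[:, :3].copy(), gyro=channels[:, 3:].copy())


def read_recording(
    path,
    column_map: dict | None = None,
    sample_rate: float | None = None,
    acc_units: str = "m/s2",
    subject_id: str = "",
    delimiter: str | None = None,
    jitter_tolerance: float = 0.1,
) -> ImuRecording:
    """Read a delimited-text recording (one header line, one row per sample).

    ``column_map`` maps the canonical names (``time``, ``acc_v`` ... ``gyro_ap``,
    optional ``label``) to the file's column headers; omitted keys default to
    the canonical names themselves.  ``acc_units`` may be ``"m/s2"`` or ``"g"``
    (converted by 9.81).  If timestamp jitter exceeds ``jitter_tolerance`` of
    the sample period, the stream is resampled onto a uniform grid by linear
    interpolation.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=delimiter)

    needed = ["time", "acc_v", "acc_ml", "acc_ap", "gyro_v", "gyro_ml", "gyro_ap"]
    missing = [cols[k] for k in needed if cols[k] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")

    data = {}
    for key in needed:
        raw = df[cols[key]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise FormatError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column "
                f"{cols[key]!r} at data row {row}"
            )
        if vals.isna().any():
            row = int(np.nonzero(vals.isna().to_numpy())[0][0])
            raise FormatError(f"{path}: empty cell in column {cols[key]!r} at data row {row}")
        data[key] = vals.to_numpy(dtype=float)

    t = data["time"]
    if t.size > 1:
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise FormatError(
                f"{path}: timestamps not strictly increasing at data row {int(bad[0]) + 1}"
            )

    scale = G_MS2 if acc_units == "g" else 1.0
    if acc_units not in ("m/s2", "g"):
        raise ValueError(f"unknown acc_units {acc_units!r}")
    acc = np.column_stack([data["acc_v"], data["acc_ml"], data["acc_ap"]]) * scale
    gyro = np.column_stack([data["gyro_v"], data["gyro_ml"], data["gyro_ap"]])

    labels = None
    if cols.get("label") in df.columns:
        labels = df[cols["label"]].astype(str).to_numpy(dtype=object)

    if sample_rate is None:
        if t.size < 2:
            raise ValueError("cannot infer sample rate from fewer than 2 samples")
        sample_rate = 1.0 / float(np.median(np.diff(t)))

    # resample onto a uniform grid when the file's own timestamps are too jittery
    if t.size > 1:
        period = 1.0 / sample_rate
        jitter = np.abs(np.diff(t) - period)
        if np.max(jitter) > jitter_tolerance * period:
            n_new = int(np.floor((t[-1] - t[0]) / period)) + 1
            t_new = t[0] + np.arange(n_new) * period
            acc = np.column_stack([np.interp(t_new, t, acc[:, j]) for j in range(3)])
            gyro = np.column_stack([np.interp(t_new, t, gyro[:, j]) for j in range(3)])
            if labels is not None:
                idx = np.clip(np.searchsorted(t, t_new), 0, t.size - 1)
                left = np.clip(idx - 1, 0, t.size - 1)
                take_left = np.abs(t[left] - t_new) <= np.abs(t[idx] - t_new)
                labels = labels[np.where(take_left, left, idx)]
            t = t_new

    return ImuRecording(t, acc, gyro, float(sample_rate), labels=labels, subject_id=subject_id)


def write_recording(rec: ImuRecording, path, delimiter: str | None = None) -> None:
    """Write a recording in the same delimited-text layout ``read_recording`` reads."""
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = {"time": rec.timestamps}
    for j, name in enumerate(CHANNELS[:3]):
        frame[name] = rec.acc[:, j]
    for j, name in enumerate(CHANNELS[3:]):
        frame[name] = rec.gyro[:, j]
    if rec.labels is not None:
        frame["label"] = rec.labels
    pd.DataFrame(frame).to_csv(path, sep=delimiter, index=False, float_format="%.9f")


def apply_filter(rec: ImuRecording, spec: FilterSpec) -> ImuRecording:
    """Apply a noise filter to all six channels; timestamps are untouched.

    Low-pass filtering is a 4th-order Butterworth run forward-backward
    (zero phase) with reflect padding, so event timings stay aligned with the
    label track.  Gaussian smoothing uses reflected edges as well.
    ``kind="none"`` returns an identical copy.
    """
    spec.validate(rec.sample_rate)
    x = rec.channels
    if spec.kind == "none" or len(rec) == 0:
        return rec.with_channels(x)
    if spec.kind == "lowpass":
        b, a = butter(4, spec.cutoff_hz, btype="low", fs=rec.sample_rate)
        padlen = min(len(rec) - 1, int(round(rec.sample_rate)))
        y = filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)
    else:  # gaussian
        sigma = spec.sigma_s * rec.sample_rate
        y = gaussian_filter1d(x, sigma=sigma, axis=0, mode="reflect")
    return rec.with_channels(y)
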