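"""Core time-series containers, trial I/O and per-second resampling.

Every downstream stage consumes the types defined here: :class:`TimeSeries`
(uniformly sampled multichannel signal), :class:`TrialMeta` (participant and
treadmill metadata) and :class:`PerSecondSeries` (the 1-Hz grid on which
features and reference power are aligned).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TimeSeries",
    "TrialMeta",
    "PerSecondSeries",
    "FormatError",
    "SamplingError",
    "CleaningError",
    "read_timeseries",
    "write_timeseries",
    "read_trial",
    "clean_outliers",
    "hampel_flags",
    "resample_per_second",
]


class FormatError(ValueError):
    """A file or container does not match the expected layout."""


class SamplingError(ValueError):
    """Timestamps are inconsistent with the declared sampling rate."""


class CleaningError(ValueError):
    """Outlier cleaning cannot produce a valid signal."""


@dataclass
class TimeSeries:
    """Uniformly sampled multichannel signal.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz, > 0.
    channels : sequence of str
        Ordered channel labels, one per column of ``values``.
    values : ndarray, shape (n_samples, n_channels)
        Sample values in SI units per channel.
    t0 : float
        Start time in seconds (sample ``i`` is at ``t0 + i / fs``).
    """

    fs: float
    channels: Sequence[str]
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.channels = list(self.channels)
        if self.fs <= 0:
            raise SamplingError(f"sampling rate must be positive, got {self.fs}")
        if self.values.shape[1] != len(self.channels):
            raise FormatError(
                f"{self.values.shape[1]} columns but {len(self.channels)} channel labels"
            )
        if self.values.shape[0] < 1:
            raise FormatError("time series needs at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("time series contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        """Signal span in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise FormatError(f"channel {name!r} not present (have {self.channels})")
        return self.values[:, idx]

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.channels)


_CONDITIONS = ("level", "uphill", "downhill")


def condition_from_grade(grade: float) -> str:
    """Slope condition implied by the signed treadmill grade (%)."""
    if grade > 0:
        return "uphill"
    if grade < 0:
        return "downhill"
    return "level"


@dataclass
class TrialMeta:
    """Trial metadata: participant anthropometrics and treadmill condition.

    ``speed`` is the belt speed v0y in m/s; ``grade`` is the signed treadmill
    grade in percent (tangent * 100).
    """

    participant_id: str
    mass: float  # kg
    height: float  # cm
    age: float  # years
    leg_length: float  # cm
    speed: float  # m/s
    grade: float  # % (signed)
    condition: str = field(default="")

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.speed <= 0:
            raise ValueError(f"treadmill speed must be positive, got {self.speed}")
        implied = condition_from_grade(self.grade)
        if not self.condition:
            self.condition = implied
        elif self.condition != implied:
            raise ValueError(
                f"condition {self.condition!r} inconsistent with grade {self.grade}"
            )
        if self.condition not in _CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def theta(self) -> float:
        """Magnitude of the slope angle in radians (grade is a tangent)."""
        return math.atan(abs(self.grade) / 100.0)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "TrialMeta":
        required = ["participant_id", "mass", "height", "age", "leg_length", "speed", "grade"]
        missing = [k for k in required if k not in data]
        if missing:
            raise FormatError(f"trial metadata missing fields: {missing}")
        return cls(
            participant_id=str(data["participant_id"]),
            mass=float(data["mass"]),
            height=float(data["height"]),
            age=float(data["age"]),
            leg_length=float(data["leg_length"]),
            speed=float(data["speed"]),
            grade=float(data["grade"]),
            condition=str(data.get("condition", "")),
        )

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "mass": self.mass,
            "height": self.height,
            "age": self.age,
            "leg_length": self.leg_length,
            "speed": self.speed,
            "grade": self.grade,
            "condition": self.condition,
        }


@dataclass
class PerSecondSeries:
    """Values on a 1-Hz grid: one value per whole second of trial time."""

    seconds: np.ndarray  # integer second indices, strictly increasing
    values: np.ndarray

    def __post_init__(self) -> None:
        self.seconds = np.asarray(self.seconds, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.seconds.shape[0] != self.values.shape[0]:
            raise FormatError("seconds and values length mismatch")
        if self.seconds.size > 1 and not np.all(np.diff(self.seconds) > 0):
            raise FormatError("second indices must be strictly increasing")

    def __len__(self) -> int:
        return self.seconds.size

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.seconds)


# ---------------------------------------------------------------------------
# File I/O


def read_timeseries(path, fs: float, t0: float = 0.0,
                    required_channels: Sequence[str] | None = None) -> TimeSeries:
    """Read a one-header-row CSV (one column per channel) into a TimeSeries."""
    df = pd.read_csv(path, float_precision="round_trip")
    if required_channels is not None:
        missing = [c for c in required_channels if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing channel(s) {missing}")
        df = df[list(required_channels)]
    if df.isna().any().any():
        raise FormatError(f"{path}: contains missing values")
    return TimeSeries(fs=fs, channels=list(df.columns), values=df.to_numpy(float), t0=t0)


def write_timeseries(ts: TimeSeries, path) -> None:
    ts.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_meta(path) -> TrialMeta:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return TrialMeta.from_mapping(data)


def read_trial(paths: Mapping[str, object], meta: Mapping | TrialMeta | None = None,
               fs_force: float = 1000.0, fs_imu: float = 512.0):
    """Read one trial's force-plate and left/right IMU CSVs plus metadata.

    ``paths`` maps keys ``force_plate``, ``imu_left``, ``imu_right`` and
    optionally ``meta`` to file paths. Returns
    ``(force_plate, imu_left, imu_right, meta)``.
    """
    if meta is None:
        if "meta" not in paths:
            raise FormatError("no metadata given: pass `meta` or a 'meta' path")
        meta = read_meta(paths["meta"])
    elif not isinstance(meta, TrialMeta):
        meta = TrialMeta.from_mapping(meta)
    imu_channels = ["ax", "ay", "az", "gx", "gy", "gz"]
    fp = read_timeseries(paths["force_plate"], fs=fs_force, required_channels=["Fy", "Fz"])
    left = read_timeseries(paths["imu_left"], fs=fs_imu, required_channels=imu_channels)
    right = read_timeseries(paths["imu_right"], fs=fs_imu, required_channels=imu_channels)
    return fp, left, right, meta


# ---------------------------------------------------------------------------
# Outlier cleaning


def hampel_flags(x: np.ndarray, window: int = 11, n_mad: float = 3.0) -> np.ndarray:
    """Flag samples deviating > ``n_mad`` scaled MADs from the rolling median.

    The classic Hampel identifier: within a centred window the median and the
    median absolute deviation (scaled by 1.4826 for Gaussian consistency) are
    computed; a sample further than ``n_mad`` scaled MADs from the window
    median is flagged.
    """
    s = pd.Series(np.asarray(x, dtype=float))
    med = s.rolling(window, center=True, min_periods=1).median()
    mad = (s - med).abs().rolling(window, center=True, min_periods=1).median()
    sigma = 1.4826 * mad
    # guard: an exactly-constant window has sigma 0; any deviation flags
    diff = (s - med).abs()
    return (diff > n_mad * sigma).to_numpy()


def _interpolate_flagged(x: np.ndarray, flags: np.ndarray) -> np.ndarray:
    good = ~flags
    if not good.any():
        raise CleaningError("all samples flagged as outliers")
    idx = np.arange(x.size)
    out = x.copy()
    # np.interp holds endpoint values constant outside the good range,
    # which matches nearest-value extrapolation at the edges
    out[flags] = np.interp(idx[flags], idx[good], x[good])
    return out


def clean_outliers(ts: TimeSeries, window: int = 11, n_mad: float = 3.0,
                   flags: np.ndarray | None = None) -> TimeSeries:
    """Replace outlier samples by linear interpolation between good neighbours.

    Outliers are flagged per channel with a Hampel filter unless explicit
    ``flags`` (n_samples,) or (n_samples, n_channels) are supplied.
    """
    if ts.n_samples < 3:
        raise CleaningError("need at least 3 samples to clean outliers")
    vals = ts.values
    if flags is not None:
        flags = np.asarray(flags, dtype=bool)
        if flags.ndim == 1:
            flags = np.broadcast_to(flags[:, None], vals.shape)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        fl = flags[:, j] if flags is not None else hampel_flags(vals[:, j], window, n_mad)
        out[:, j] = _interpolate_flagged(vals[:, j], fl)
    return ts.with_values(out)


# ---------------------------------------------------------------------------
# Per-second resampling


def resample_per_second(times: Sequence[float], values: Sequence[float],
                        start_second: int = 0,
                        end_second: int | None = None) -> PerSecondSeries:
    """Aggregate per-step values onto a 1-Hz grid.

    Each step (timestamped at its cycle midpoint) is bucketed into the whole
    second containing it; multiple steps in a second are averaged; seconds
    with no steps carry the previous second's value forward (the first
    seconds, if empty, take the first available value).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        return PerSecondSeries(np.empty(0, dtype=int), np.empty(0))
    if times.size != values.size:
        raise FormatError("times and values length mismatch")
    if end_second is None:
        end_second = int(np.floor(times.max()))
    seconds = np.arange(start_second, end_second + 1)
    buckets = np.floor(times).astype(int)
    sums = np.zeros(seconds.size)
    counts = np.zeros(seconds.size)
    for b, v in zip(buckets, values):
        k = b - start_second
        if 0 <= k < seconds.size:
            sums[k] += v
            counts[k] += 1
    out = np.full(seconds.size, np.nan)
    has = counts > 0
    out[has] = sums[has] / counts[has]
    filled = pd.Series(out).ffill().bfill().to_numpy()
    return PerSecondSeries(seconds, filled)
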