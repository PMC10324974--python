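"""Per-stride feature construction, condition noise, balancing and splitting.

The feature set X = {Xg, Xs, Xa, Xc} combines, per stride:

* Xg — 8 gait parameters (tc, tf, ts, strd, kvert, fzmax, dz, fsa),
* Xs — 132 statistical features: 11 statistics x 3 signals (foot
  acceleration ``a``, angular velocity ``w``, drift-corrected foot velocity
  ``v``) x 4 channels (x, y, z and the Euclidean norm ``n``),
* Xa — 4 anthropometric features (height, age, mass, leg length),
* Xc — 2 running-condition features: treadmill speed and grade, each
  corrupted by uniform white noise emulating field estimation error
  (full-noise halfwidths 0.16 m/s and 4.86 % grade).

146 features in total.  Rows are aligned on a 1-Hz grid; class imbalance
across (speed x slope) conditions is corrected on the development set by
exponent-interpolated random oversampling, and train/test splits are always
by participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import TrialMeta
from .imu_processing import SpringMassParams, TemporalParams

__all__ = [
    "NoiseSpec",
    "FeatureTable",
    "STAT_NAMES",
    "GAIT_FEATURES",
    "ANTHROPOMETRIC_FEATURES",
    "CONDITION_FEATURES",
    "SPEED_CLASSES_KMH",
    "gait_features",
    "statistical_features",
    "anthropometric_features",
    "condition_features",
    "ros_balance",
    "apply_ros",
    "split_by_participant",
    "speed_class",
    "ar_coefficients",
]

GAIT_FEATURES = ["tc", "tf", "ts", "strd", "kvert", "fzmax", "dz", "fsa"]
ANTHROPOMETRIC_FEATURES = ["height", "age", "mass", "leg_length"]
CONDITION_FEATURES = ["speed_hat", "grade_hat"]
STAT_NAMES = ["mu", "sigma", "med", "iqr", "max", "rms", "kurt", "skew",
              "arm1", "arm2", "arm3"]
_SIGNALS = ["a", "w", "v"]
_CHANNELS = ["x", "y", "z", "n"]

#: protocol treadmill speeds used as oversampling classes
SPEED_CLASSES_KMH = (8.0, 10.0, 12.0, 14.0)

#: full-noise (100 %) halfwidths for the condition features
SPEED_NOISE_HALFWIDTH = 0.16  # m/s
GRADE_NOISE_HALFWIDTH = 4.86  # % grade


class IncompleteStrideError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseSpec:
    """Condition-feature noise level: 100, 50 or 0 % of the field error."""

    level: float = 100.0

    def __post_init__(self):
        if self.level not in (0.0, 50.0, 100.0):
            raise ValueError(f"noise level must be 0, 50 or 100, got {self.level}")

    @property
    def speed_halfwidth(self) -> float:
        return SPEED_NOISE_HALFWIDTH * self.level / 100.0

    @property
    def grade_halfwidth(self) -> float:
        return GRADE_NOISE_HALFWIDTH * self.level / 100.0


@dataclass
class FeatureTable:
    """Per-second feature matrix with response and class labels.

    ``frame`` holds one row per second with the feature columns, the
    response column ``P`` (reference peak power, W) and the label columns
    ``participant_id``, ``speed``, ``grade``, ``condition``, ``speed_class``.
    """

    frame: pd.DataFrame
    feature_columns: list = field(default_factory=list)
    response_column: str = "P"

    def __post_init__(self):
        missing = [c for c in self.feature_columns + [self.response_column]
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if len(set(self.feature_columns)) != len(self.feature_columns):
            raise ValueError("duplicate feature column names")
        if self.frame[self.feature_columns + [self.response_column]].isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    @property
    def P(self) -> pd.Series:
        return self.frame[self.response_column]

    def subset(self, mask) -> "FeatureTable":
        return FeatureTable(self.frame.loc[mask].reset_index(drop=True),
                            list(self.feature_columns), self.response_column)


def speed_class(speed_ms: float) -> float:
    """Nearest protocol treadmill speed (km/h) used as the ROS class."""
    kmh = speed_ms * 3.6
    return min(SPEED_CLASSES_KMH, key=lambda s: abs(s - kmh))


# ---------------------------------------------------------------------------
# Per-stride feature extractors


def gait_features(tp: TemporalParams, smp: SpringMassParams, fsa: float) -> dict:
    """Xg: spatiotemporal and spring-mass parameters of one stride."""
    if fsa is None or not np.isfinite(fsa):
        raise IncompleteStrideError("stride lacks a foot-strike angle")
    return {"tc": tp.tc, "tf": tp.tf, "ts": tp.ts, "strd": tp.strd,
            "kvert": smp.kvert, "fzmax": smp.fzmax, "dz": smp.dz, "fsa": fsa}


def ar_coefficients(x: np.ndarray, order: int = 3) -> np.ndarray:
    """Autoregressive coefficients by the Yule-Walker equations.

    Returns the ``order`` lag coefficients (leading 1 excluded). A constant
    signal has no autocovariance structure; zeros are returned.
    """
    x = np.asarray(x, dtype=float)
    if x.size < order + 1:
        raise IncompleteStrideError(f"need > {order} samples for an AR({order}) fit")
    xc = x - x.mean()
    denom = xc @ xc
    if denom <= 0:
        return np.zeros(order)
    r = np.array([xc[: x.size - k] @ xc[k:] for k in range(order + 1)]) / x.size
    Rm = np.array([[r[abs(i - j)] for j in range(order)] for i in range(order)])
    try:
        return np.linalg.solve(Rm, r[1:])
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(Rm, r[1:], rcond=None)[0]


def _channel_stats(x: np.ndarray, prefix: str) -> dict:
    n = x.size
    mu = x.mean()
    sd = x.std(ddof=0)
    q75, q25 = np.percentile(x, [75, 25])
    rms = float(np.sqrt(np.mean(x ** 2)))
    if sd > 0:
        z = (x - mu) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))  # non-excess: normal -> 3
    else:
        skew, kurt = 0.0, 3.0  # undefined moments of a constant signal
    a1, a2, a3 = ar_coefficients(x)
    return {f"mu_{prefix}": float(mu), f"sigma_{prefix}": float(sd),
            f"med_{prefix}": float(np.median(x)), f"iqr_{prefix}": float(q75 - q25),
            f"max_{prefix}": float(x.max()), f"rms_{prefix}": rms,
            f"kurt_{prefix}": kurt, f"skew_{prefix}": skew,
            f"arm1_{prefix}": float(a1), f"arm2_{prefix}": float(a2),
            f"arm3_{prefix}": float(a3)}


def statistical_features(af: np.ndarray, omega_f: np.ndarray, vf: np.ndarray) -> dict:
    """Xs: 11 statistics per channel of a, w, v plus their Euclidean norms.

    Each input is the (n_samples, 3) slice of one stride; 132 named values.
    """
    out = {}
    for sig, arr in zip(_SIGNALS, (af, omega_f, vf)):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise IncompleteStrideError(f"signal {sig} must be (n, 3)")
        if arr.shape[0] < 8:
            raise IncompleteStrideError("stride too short for stable statistics")
        for k, ch in enumerate(_CHANNELS):
            x = np.linalg.norm(arr, axis=1) if ch == "n" else arr[:, k]
            out.update(_channel_stats(x, f"{sig}{ch}"))
    return out


def anthropometric_features(meta: TrialMeta) -> dict:
    """Xa: participant height (cm), age (y), mass (kg), leg length (cm)."""
    return {"height": meta.height, "age": meta.age, "mass": meta.mass,
            "leg_length": meta.leg_length}


def condition_features(meta: TrialMeta, noise: NoiseSpec,
                       rng: np.random.Generator) -> dict:
    """Xc: treadmill speed and grade with uniform field-estimation noise."""
    ws, wg = noise.speed_halfwidth, noise.grade_halfwidth
    speed_hat = meta.speed + (rng.uniform(-ws, ws) if ws > 0 else 0.0)
    grade_hat = meta.grade + (rng.uniform(-wg, wg) if wg > 0 else 0.0)
    return {"speed_hat": speed_hat, "grade_hat": grade_hat}


def all_feature_names() -> list:
    names = list(GAIT_FEATURES)
    for sig in _SIGNALS:
        for ch in _CHANNELS:
            names += [f"{s}_{sig}{ch}" for s in STAT_NAMES]
    return names + ANTHROPOMETRIC_FEATURES + list(CONDITION_FEATURES)


# ---------------------------------------------------------------------------
# Balancing and splitting


def ros_balance(class_sizes: dict, alpha: float = 0.8) -> dict:
    """Exponent-interpolated random-oversampling target sizes.

    ``n'_i = round(n_i (n_max / n_i)^alpha)``: alpha=0 keeps the sizes,
    alpha=1 fully equalizes to the largest class.
    """
    if not class_sizes:
        raise ValueError("empty class map")
    n_max = max(class_sizes.values())
    return {k: int(np.round(n * (n_max / n) ** alpha))
            for k, n in class_sizes.items()}


def apply_ros(table: FeatureTable, alpha: float = 0.8,
              seed: int | np.random.Generator = 0) -> FeatureTable:
    """Duplicate rows of under-represented (speed x slope) classes.

    Rows to add are drawn uniformly at random with replacement from the
    class's own rows; no row is ever removed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = table.frame
    labels = list(zip(df["speed_class"], df["condition"]))
    sizes = pd.Series(labels).value_counts().to_dict()
    targets = ros_balance(sizes, alpha)
    extra_idx = []
    lab_arr = pd.Series(labels, index=df.index)
    for cls, target in targets.items():
        members = lab_arr.index[lab_arr == cls]
        deficit = target - len(members)
        if deficit > 0:
            extra_idx.extend(rng.choice(members, size=deficit, replace=True))
    out = pd.concat([df, df.loc[extra_idx]], ignore_index=True)
    return FeatureTable(out, list(table.feature_columns), table.response_column)


def split_by_participant(table: FeatureTable, test_fraction: float = 1 / 3,
                         seed: int = 0) -> tuple[FeatureTable, FeatureTable]:
    """Participant-wise development/test split.

    Every row of a participant lands in exactly one subset, removing the
    optimistic bias of training and testing on the same subject.
    """
    ids = sorted(table.frame["participant_id"].unique())
    if len(ids) < 3:
        raise ValueError(f"need at least 3 participants, got {len(ids)}")
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(test_fraction * len(ids))))
    test_ids = set(rng.choice(ids, size=n_test, replace=False))
    mask = table.frame["participant_id"].isin(test_ids)
    return table.subset(~mask), table.subset(mask)
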