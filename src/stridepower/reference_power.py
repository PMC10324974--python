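"""Force-plate reference for peak horizontal running power.

The reference treats the runner as a point mass. The antero-posterior ground
reaction force Fy accelerates the centre of mass along the running direction;
on a slope of angle theta the gravity component m*g*sin(theta) opposes
(uphill) or aids (downhill, where the running direction — and with it the
sign of Fy, ay, vy — is reversed) the motion:

    level/uphill:  ay = (Fy - m g sin(theta)) / m
    downhill:      ay = (Fy + m g sin(theta)) / m

Integrating ay from stance onset (initial CoM velocity = belt speed v0y)
gives vy, and Py = vy * Fy is the horizontal "power" — one directional
component of a 3-D quantity. The per-step reference P is the concentric
(positive) peak of Py for level and uphill running and the eccentric
(negative) peak for downhill running.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .signal_io import PerSecondSeries, TimeSeries, TrialMeta, resample_per_second

__all__ = [
    "G",
    "StanceInterval",
    "StepPower",
    "filter_forces",
    "detect_stances",
    "com_acceleration",
    "step_power",
    "trial_reference_power",
    "grade_to_angle",
]

#: standard gravity, m/s^2
G = 9.81


class SignalLengthError(ValueError):
    """Signal too short for the requested filter or integration."""


@dataclass(frozen=True)
class StanceInterval:
    """One stance phase: [ic_index, tc_index) with its mid-stance sample."""

    ic_index: int
    tc_index: int
    midstance_index: int

    def __post_init__(self):
        if not (self.ic_index < self.midstance_index < self.tc_index):
            raise ValueError(
                f"stance events out of order: ic={self.ic_index}, "
                f"mid={self.midstance_index}, tc={self.tc_index}"
            )

    @property
    def n_samples(self) -> int:
        return self.tc_index - self.ic_index


@dataclass
class StepPower:
    """Per-step reference power with the underlying CoM traces."""

    step_time: float  # s, cycle midpoint on the trial time base
    peak_power: float  # W; >=0 level/uphill, <=0 downhill
    ay_trace: np.ndarray
    vy_trace: np.ndarray
    py_trace: np.ndarray
    contact_time: float  # s
    condition: str


def grade_to_angle(grade: float) -> float:
    """Signed slope angle (rad) from treadmill grade (%); grade is a tangent."""
    return math.atan(grade / 100.0)


def filter_forces(fp: TimeSeries, cutoff_hz: float = 25.0, order: int = 3) -> TimeSeries:
    """Zero-phase low-pass Butterworth filter for force-plate channels.

    Forward-backward filtering (``filtfilt``) doubles the effective order's
    attenuation while cancelling phase lag.
    """
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fp.fs, output="sos")
    padlen = 3 * (2 * order + 1)
    if fp.n_samples <= padlen:
        raise SignalLengthError(
            f"signal of {fp.n_samples} samples shorter than filter warm-up ({padlen})"
        )
    filtered = sps.sosfiltfilt(sos, fp.values, axis=0)
    return fp.with_values(filtered)


def detect_stances(fz: np.ndarray, contact_threshold: float = 20.0,
                   min_samples: int = 40,
                   midstance_threshold: float = 300.0) -> list[StanceInterval]:
    """Detect stance phases on the vertical force channel.

    Maximal runs with ``fz > contact_threshold`` (20 N) lasting at least
    ``min_samples`` (40 at 1 kHz) are stances; within each, the mid-stance is
    the peak of the region above ``midstance_threshold`` (300 N). Stances
    never exceeding 300 N are discarded.
    """
    fz = np.asarray(fz, dtype=float)
    above = fz > contact_threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(fz.size)
    stances = []
    for ic, tc in zip(starts, ends):
        if tc - ic < min_samples:
            continue
        seg = fz[ic:tc]
        if seg.max() <= midstance_threshold:
            continue
        # earliest maximal sample within the >300 N region
        mid = ic + int(np.argmax(seg))
        if not ic < mid < tc:  # peak at a boundary: degenerate profile
            continue
        stances.append(StanceInterval(ic, tc, mid))
    return stances


def com_acceleration(fy: np.ndarray, mass: float, theta: float,
                     condition: str, g: float = G) -> np.ndarray:
    """Antero-posterior CoM acceleration from the propulsive GRF.

    ``theta`` is the magnitude of the slope angle (rad). For downhill trials
    the running direction is reversed, flipping the sign of the gravity term.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    if theta < 0:
        raise ValueError("theta is a magnitude; pass condition='downhill' for slopes down")
    fy = np.asarray(fy, dtype=float)
    grav = g * math.sin(theta)
    if condition == "downhill":
        return (fy + mass * grav) / mass
    return (fy - mass * grav) / mass


def step_power(fp_cycle: TimeSeries, meta: TrialMeta,
               stance: StanceInterval | None = None,
               step_time: float | None = None, g: float = G) -> StepPower:
    """Per-step peak horizontal power over one segmented gait cycle.

    The cycle starts at stance onset; vy integrates ay (trapezoidal rule)
    from the belt speed v0y at stance onset. The peak is the maximum of
    Py = vy*Fy for level/uphill and the minimum for downhill.
    """
    if fp_cycle.n_samples < 2:
        raise SignalLengthError("cycle must span at least 2 samples to integrate")
    fy = fp_cycle.channel("Fy")
    ay = com_acceleration(fy, meta.mass, meta.theta, meta.condition, g=g)
    t = np.arange(fy.size) / fp_cycle.fs
    vy = meta.speed + cumulative_trapezoid(ay, t, initial=0.0)
    py = vy * fy
    if meta.condition == "downhill":
        peak = float(py.min())
    else:
        peak = float(py.max())
    tc = stance.n_samples / fp_cycle.fs if stance is not None else fy.size / fp_cycle.fs
    if step_time is None:
        step_time = fp_cycle.t0 + 0.5 * fp_cycle.duration
    return StepPower(step_time=step_time, peak_power=peak, ay_trace=ay,
                     vy_trace=vy, py_trace=py, contact_time=tc,
                     condition=meta.condition)


def trial_reference_power(fp: TimeSeries, meta: TrialMeta,
                          prefiltered: bool = False,
                          end_second: int | None = None,
                          g: float = G) -> tuple[PerSecondSeries, list[StepPower]]:
    """Per-second reference power for one trial.

    Filters the force-plate signals, detects stances, computes each step's
    peak power over the stance-onset-to-next-stance-onset cycle and resamples
    the per-step peaks to the 1-Hz grid.
    """
    filtered = fp if prefiltered else filter_forces(fp)
    stances = detect_stances(filtered.channel("Fz"))
    if not stances:
        warnings.warn("no stances detected; empty reference power series")
        return PerSecondSeries(np.empty(0, dtype=int), np.empty(0)), []
    steps = []
    onsets = [s.ic_index for s in stances] + [filtered.n_samples]
    for k, stance in enumerate(stances):
        lo, hi = stance.ic_index, onsets[k + 1]
        cycle = TimeSeries(fs=filtered.fs, channels=filtered.channels,
                           values=filtered.values[lo:hi], t0=filtered.t0 + lo / filtered.fs)
        mid_t = filtered.t0 + 0.5 * (stance.ic_index + stance.tc_index) / filtered.fs
        steps.append(step_power(cycle, meta, stance=stance, step_time=mid_t, g=g))
    series = resample_per_second([s.step_time for s in steps],
                                 [s.peak_power for s in steps],
                                 end_second=end_second)
    return series, steps
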