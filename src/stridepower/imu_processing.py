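"""Foot-worn IMU processing: calibration, gait segmentation, derived parameters.

The chain mirrors a standard foot-IMU running pipeline:

1. low-pass filter the raw 6-axis signals,
2. functionally calibrate the sensor frame to a foot-functional frame
   (Z up along gravity, Y antero-posterior, X the sagittal pitch axis),
3. segment mid-swing-to-mid-swing gait cycles from the pitch angular
   velocity and detect initial/terminal contact inside each cycle,
4. derive temporal parameters (tc, tf, ts, strd), spring-mass parameters
   (kvert, fzmax, dz), the foot strike angle (fsa) and the drift-corrected
   stride velocity of the foot (vf).

Orientation is obtained by strapdown integration of the angular velocity,
re-anchored at every mid-stance where the foot is flat and (nearly) static,
so gyroscope drift cannot accumulate across strides. Velocity integration
uses the zero-velocity assumption during stance: the trapezoidally
integrated acceleration is de-drifted linearly so that the foot velocity is
exactly zero at consecutive mid-stance anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .signal_io import FormatError, TimeSeries

__all__ = [
    "GaitCycle",
    "TemporalParams",
    "SpringMassParams",
    "CalibrationError",
    "SegmentationError",
    "EventOrderError",
    "lowpass_imu",
    "functional_calibration",
    "apply_calibration",
    "segment_cycles",
    "temporal_params",
    "stride_flight_times",
    "spring_mass",
    "foot_orientation_and_fsa",
    "foot_velocity",
]

ACCEL_CHANNELS = ["ax", "ay", "az"]
GYRO_CHANNELS = ["gx", "gy", "gz"]
G = 9.81


class CalibrationError(ValueError):
    pass


class SegmentationError(ValueError):
    pass


class EventOrderError(ValueError):
    pass


@dataclass(frozen=True)
class GaitCycle:
    """One mid-swing-to-mid-swing gait cycle with its stance events (samples)."""

    midswing_start: int
    ic: int
    tc_event: int
    midswing_end: int

    def __post_init__(self):
        if not (self.midswing_start < self.ic < self.tc_event < self.midswing_end):
            raise EventOrderError(
                f"cycle events out of order: ms={self.midswing_start}, ic={self.ic}, "
                f"tc={self.tc_event}, ms_end={self.midswing_end}"
            )

    @property
    def midstance(self) -> int:
        return (self.ic + self.tc_event) // 2


@dataclass(frozen=True)
class TemporalParams:
    """Per-stride temporal gait parameters, seconds."""

    tc: float  # ground contact time
    tf: float  # flight time
    ts: float  # swing time
    strd: float  # stride duration

    def __post_init__(self):
        if min(self.tc, self.tf, self.ts, self.strd) <= 0:
            raise ValueError(f"temporal parameters must be positive: {self}")


@dataclass(frozen=True)
class SpringMassParams:
    """Spring-mass model parameters: stiffness kN/m, peak force N, CoM drop m."""

    kvert: float
    fzmax: float
    dz: float


def lowpass_imu(raw: TimeSeries, cutoff_hz: float = 50.0, order: int = 4) -> TimeSeries:
    """Per-channel zero-phase 4th-order low-pass Butterworth at 50 Hz."""
    if len(raw.channels) != 6:
        raise FormatError(
            f"IMU series must have 6 channels (3 accel + 3 gyro), got {raw.channels}"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=raw.fs, output="sos")
    return raw.with_values(sps.sosfiltfilt(sos, raw.values, axis=0))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise CalibrationError("zero-length axis vector")
    return v / n


def _forward_swing_is_positive(pitch_rate: np.ndarray, fs: float) -> bool:
    """Decide the pitch-axis sign from the regularity of the peak train.

    With the correct sign, the dominant positive peaks are the mid-swing
    forward rotations — one per stride, evenly spaced and broad (the swing
    lasts hundreds of ms). With the flipped sign they are initial/terminal
    contact transients: either an alternating short/long train (contact
    time vs swing time, never equal in running) or, if one transient
    dominates, a regular train of narrow impulsive peaks. Regularity of
    the inter-peak intervals decides first; near-ties fall back to the
    median peak width.
    """
    height = 0.3 * np.max(np.abs(pitch_rate))
    min_dist = max(1, int(round(0.2 * fs)))

    def train(sig):
        peaks, props = sps.find_peaks(sig, height=height, distance=min_dist,
                                      width=1)
        if peaks.size < 3:
            return np.inf, 0.0
        gaps = np.diff(peaks)
        return gaps.std() / gaps.mean(), float(np.median(props["widths"]))

    cv_pos, w_pos = train(pitch_rate)
    cv_neg, w_neg = train(-pitch_rate)
    if np.isinf(cv_pos) and np.isinf(cv_neg):
        raise CalibrationError("no periodic pitch-rate peaks in the initial steps")
    if cv_pos < cv_neg - 0.15:
        return True
    if cv_neg < cv_pos - 0.15:
        return False
    return w_pos >= w_neg


def functional_calibration(filtered: TimeSeries, static_window: float = 5.0,
                           run_window: float = 10.0,
                           static_motion_tol: float = 0.1) -> np.ndarray:
    """Estimate the rotation mapping the sensor frame to the functional frame.

    The static standing period defines the vertical: the mean specific force
    points up (functional +Z). The initial running steps define the sagittal
    pitch axis (functional +X) as the dominant principal axis of the
    angular-velocity variance, orthogonalized against Z; its sign is chosen
    so that the dominant pitch-rate extremum (the mid-swing forward swing)
    is positive. Functional +Y (antero-posterior) completes the right-handed
    triad, Y = Z x X.

    Returns a 3x3 rotation matrix ``R`` with ``v_functional = R @ v_sensor``.
    """
    fs = filtered.fs
    n_static = int(round(static_window * fs))
    if filtered.n_samples <= n_static:
        raise CalibrationError("recording shorter than the static calibration window")
    acc = filtered.values[:, [filtered.channels.index(c) for c in ACCEL_CHANNELS]]
    gyr = filtered.values[:, [filtered.channels.index(c) for c in GYRO_CHANNELS]]

    static_acc = acc[:n_static]
    if np.linalg.norm(static_acc, axis=1).std() > static_motion_tol:
        raise CalibrationError(
            "motion detected during the static calibration window "
            f"(accel norm std > {static_motion_tol} m/s^2)"
        )
    z = _unit(static_acc.mean(axis=0))  # specific force at rest points up

    n_run = min(filtered.n_samples, n_static + int(round(run_window * fs)))
    run_gyr = gyr[n_static:n_run]
    if run_gyr.shape[0] < 10:
        raise CalibrationError("no running data after the static window")
    centred = run_gyr - run_gyr.mean(axis=0)
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    x = vecs[:, -1]  # dominant angular-velocity axis
    x = x - (x @ z) * z
    x = _unit(x)
    pitch_rate = run_gyr @ x
    if not _forward_swing_is_positive(pitch_rate, fs):
        x = -x
    y = np.cross(z, x)
    R = np.vstack([x, y, z])
    # orthonormal by construction; guard against numerical slip
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
        raise CalibrationError("calibration produced a non-rotation matrix")
    return R


def apply_calibration(ts: TimeSeries, R: np.ndarray) -> TimeSeries:
    """Rotate accelerometer and gyroscope channels into the functional frame."""
    acc_idx = [ts.channels.index(c) for c in ACCEL_CHANNELS]
    gyr_idx = [ts.channels.index(c) for c in GYRO_CHANNELS]
    out = ts.values.copy()
    out[:, acc_idx] = ts.values[:, acc_idx] @ R.T
    out[:, gyr_idx] = ts.values[:, gyr_idx] @ R.T
    return ts.with_values(out)


def segment_cycles(calibrated: TimeSeries, midswing_height: float = 2.0,
                   midswing_separation: float = 0.4,
                   skip_seconds: float = 0.0) -> list[GaitCycle]:
    """Segment mid-swing-to-mid-swing cycles from the pitch angular velocity.

    Mid-swings are pitch-rate maxima above ``midswing_height`` (rad/s) at
    least ``midswing_separation`` s apart; IC is the pitch-rate minimum in
    the first half of each cycle, TC the minimum in the second half.
    """
    fs = calibrated.fs
    pitch_rate = calibrated.channel("gx")
    start = int(round(skip_seconds * fs))
    peaks, _ = sps.find_peaks(pitch_rate[start:], height=midswing_height,
                              distance=max(1, int(round(midswing_separation * fs))))
    peaks = peaks + start
    if peaks.size < 2:
        raise SegmentationError(
            f"found {peaks.size} mid-swing(s); need at least 2 to form a cycle"
        )
    cycles = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        half = (a + b) // 2
        ic = a + int(np.argmin(pitch_rate[a:half]))
        tc = half + int(np.argmin(pitch_rate[half:b]))
        cycles.append(GaitCycle(int(a), int(ic), int(tc), int(b)))
    return cycles


def temporal_params(cycle: GaitCycle, fs: float,
                    next_contact_sample: int | None = None) -> TemporalParams:
    """Temporal parameters for one cycle.

    ``next_contact_sample`` is the first initial contact of *either* foot
    after this cycle's terminal contact (merged left/right event streams);
    the flight time is the gap from toe-off to that contact. Without the
    contralateral stream the same-foot gap (2 flights + 1 contralateral
    contact) is halved after removing the contact time — a documented
    symmetric-gait fallback.
    """
    tc = (cycle.tc_event - cycle.ic) / fs
    strd = (cycle.midswing_end - cycle.midswing_start) / fs
    ts = strd - tc
    if next_contact_sample is not None:
        if next_contact_sample <= cycle.tc_event:
            raise EventOrderError("next contact precedes terminal contact")
        tf = (next_contact_sample - cycle.tc_event) / fs
    else:
        gap = strd - tc  # same-foot TC -> next IC gap = 2*tf + tc (symmetric)
        tf = (gap - tc) / 2.0
    return TemporalParams(tc=tc, tf=tf, ts=ts, strd=strd)


def stride_flight_times(cycles_this: list[GaitCycle],
                        cycles_other: list[GaitCycle], fs: float) -> list[float | None]:
    """Flight time per cycle of ``cycles_this`` using both feet's contacts."""
    other_ics = sorted(c.ic for c in cycles_other)
    out: list[float | None] = []
    for c in cycles_this:
        nxt = next((ic for ic in other_ics if ic > c.tc_event), None)
        if nxt is None or (nxt - c.tc_event) / fs > 0.5:
            out.append(None)  # no plausible contralateral contact
        else:
            out.append((nxt - c.tc_event) / fs)
    return out


def spring_mass(tp: TemporalParams, mass: float, g: float = G) -> SpringMassParams:
    """Spring-mass running model from contact and flight times.

    The vertical GRF is modelled as a half-sine over the contact; force
    balance over the step gives the peak force, and double integration the
    CoM excursion:

        fzmax = m g (pi/2) (tf/tc + 1)
        dz    = fzmax tc^2 / (m pi^2) - g tc^2 / 8
        kvert = fzmax / dz
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    tc, tf = tp.tc, tp.tf
    fzmax = mass * g * (math.pi / 2.0) * (tf / tc + 1.0)
    dz = fzmax * tc ** 2 / (mass * math.pi ** 2) - g * tc ** 2 / 8.0
    if dz <= 0:
        raise ValueError(f"non-physiological contact/flight times: dz={dz:.4g} <= 0")
    kvert = fzmax / dz / 1000.0  # kN/m
    return SpringMassParams(kvert=kvert, fzmax=fzmax, dz=dz)


# ---------------------------------------------------------------------------
# Strapdown orientation and zero-velocity-anchored foot velocity


def _integrate_quaternions(gyr: np.ndarray, dt: float) -> np.ndarray:
    """Cumulative body-rate quaternion integration (midpoint rule).

    Returns scalar-last quaternions, shape (n, 4), with q[0] = identity;
    q[k] maps body-frame vectors at sample k into the frame of sample 0.
    """
    n = gyr.shape[0]
    out = np.empty((n, 4))
    out[0] = (0.0, 0.0, 0.0, 1.0)
    qx, qy, qz, qw = 0.0, 0.0, 0.0, 1.0
    gx, gy, gz = gyr[:, 0], gyr[:, 1], gyr[:, 2]
    half_dt = 0.5 * dt
    for k in range(1, n):
        # rotation vector over [k-1, k] from the midpoint angular rate
        rx = (gx[k - 1] + gx[k]) * half_dt * 0.5
        ry = (gy[k - 1] + gy[k]) * half_dt * 0.5
        rz = (gz[k - 1] + gz[k]) * half_dt * 0.5
        ang2 = rx * rx + ry * ry + rz * rz
        ang = math.sqrt(ang2)
        if ang > 1e-12:
            s = math.sin(ang) / ang
            dw = math.cos(ang)
            dx, dy, dz_ = rx * s, ry * s, rz * s
        else:
            dw, dx, dy, dz_ = 1.0, rx, ry, rz
        # q <- q * dq (body-frame increment)
        nqw = qw * dw - qx * dx - qy * dy - qz * dz_
        nqx = qw * dx + qx * dw + qy * dz_ - qz * dy
        nqy = qw * dy - qx * dz_ + qy * dw + qz * dx
        nqz = qw * dz_ + qx * dy - qy * dx + qz * dw
        norm = math.sqrt(nqw * nqw + nqx * nqx + nqy * nqy + nqz * nqz)
        qw, qx, qy, qz = nqw / norm, nqx / norm, nqy / norm, nqz / norm
        out[k] = (qx, qy, qz, qw)
    return out


def _pitch_deg(q: np.ndarray) -> float:
    """Sagittal pitch (deg) of the foot long axis (+Y) for one quaternion."""
    a = Rotation.from_quat(q).apply([0.0, 1.0, 0.0])
    return math.degrees(math.atan2(a[2], a[1]))


def _anchor_indices(cycles: list[GaitCycle]) -> list[int]:
    return [c.midstance for c in cycles]


def foot_orientation_and_fsa(calibrated: TimeSeries, cycles: list[GaitCycle],
                             gravity_window: float = 0.05) -> np.ndarray:
    """Foot strike angle (deg, dorsiflexion positive) per cycle.

    Orientation is integrated from the mid-stance of the *preceding* cycle
    (foot flat: the anchor defines the zero-pitch reference) up to the sample
    immediately before this cycle's initial contact. The first cycle has no
    preceding stance anchor and reports NaN.
    """
    gyr = calibrated.values[:, [calibrated.channels.index(c) for c in GYRO_CHANNELS]]
    dt = 1.0 / calibrated.fs
    fsa = np.full(len(cycles), np.nan)
    for k in range(1, len(cycles)):
        anchor = cycles[k - 1].midstance
        stop = cycles[k].ic  # fsa read at the sample immediately before IC
        if stop <= anchor:
            continue
        quats = _integrate_quaternions(gyr[anchor:stop], dt)
        fsa[k] = _pitch_deg(quats[-1])
    return fsa


def foot_velocity(calibrated: TimeSeries, cycles: list[GaitCycle],
                  gravity_window: float = 0.05) -> tuple[TimeSeries, np.ndarray]:
    """Drift-corrected foot velocity in the functional frame.

    Between consecutive mid-stance anchors the specific force is rotated to
    the anchor frame via strapdown orientation, the gravity measured at the
    anchor is removed, and the trapezoidal integral is linearly de-drifted
    so the velocity is exactly zero at both anchors; the result is rotated
    back into the (body) functional frame.

    Returns ``(vf, valid)`` where ``vf`` has channels vx/vy/vz and ``valid``
    flags samples lying between the first and last stance anchors.
    """
    if not cycles:
        raise SegmentationError("no gait cycles: cannot anchor drift correction")
    fs = calibrated.fs
    dt = 1.0 / fs
    acc = calibrated.values[:, [calibrated.channels.index(c) for c in ACCEL_CHANNELS]]
    gyr = calibrated.values[:, [calibrated.channels.index(c) for c in GYRO_CHANNELS]]
    n = calibrated.n_samples
    vel = np.zeros((n, 3))
    valid = np.zeros(n, dtype=bool)
    half_win = max(1, int(round(gravity_window * fs / 2)))
    anchors = _anchor_indices(cycles)
    for a0, a1 in zip(anchors[:-1], anchors[1:]):
        quats = _integrate_quaternions(gyr[a0:a1 + 1], dt)
        rots = Rotation.from_quat(quats)
        f_anchor = acc[max(0, a0 - half_win):a0 + half_win + 1].mean(axis=0)
        a_lin = rots.apply(acc[a0:a1 + 1]) - f_anchor  # anchor frame, gravity removed
        v = cumulative_trapezoid(a_lin, dx=dt, initial=0.0, axis=0)
        t_rel = np.linspace(0.0, 1.0, a1 - a0 + 1)
        v -= np.outer(t_rel, v[-1])  # linear de-drift: zero at both anchors
        vel[a0:a1 + 1] = rots.apply(v, inverse=True)
        valid[a0:a1 + 1] = True
    vf = TimeSeries(fs=fs, channels=["vx", "vy", "vz"], values=vel, t0=calibrated.t0)
    return vf, valid
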