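"""Synthetic treadmill-running trials with analytically known ground truth.

The generator emulates the measurement setup the pipeline expects: an
instrumented treadmill (antero-posterior and vertical GRF at 1 kHz) and one
6-axis IMU per foot at 512 Hz, for speeds 8-14 km/h and grades -20 % to
+20 %.

Force model
-----------
Per stance of duration ``tc`` the vertical force is a half-sine with the
spring-mass peak ``fzmax = m g (pi/2)(tf/tc + 1)``; the antero-posterior
force is an antisymmetric sine (braking lobe then propulsive lobe) whose
net impulse balances the gravity component along the slope at constant
belt speed.  Both follow from constant-speed force balance, so the per-step
peak horizontal power has a closed form the pipeline can be checked against.

Kinematic model
---------------
Each foot rests during stance (zero velocity — the assumption the pipeline's
drift correction relies on) and swings forward along a quintic
position profile covering one stride length, with a smooth vertical lift.
Foot pitch is built from three angular-rate pulses per stride: a sharp
landing pulse at initial contact (dorsiflexed by the foot-strike angle fsa,
then flat), a push-off pulse at terminal contact (to plantarflexion) and a
broad forward-swing pulse peaking at mid-swing.  Signals are emitted in a
sensor frame rotated from the foot-functional frame by a configurable
mounting rotation so functional calibration is exercised nontrivially.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.special import ndtr

from .signal_io import TimeSeries, TrialMeta, condition_from_grade

__all__ = [
    "SyntheticTrialConfig",
    "GroundTruth",
    "SyntheticTrial",
    "generate_grf",
    "generate_imu",
    "generate_trial",
    "generate_cohort",
    "closed_form_peak_power",
    "PROTOCOL_SPEEDS_KMH",
    "PROTOCOL_GRADES",
]

G = 9.81
#: treadmill protocol: speeds (km/h) and signed grades (%) — note +15 has no
#: downhill counterpart
PROTOCOL_SPEEDS_KMH = (8.0, 10.0, 12.0, 14.0)
PROTOCOL_GRADES = (0.0, 5.0, -5.0, 10.0, -10.0, 15.0, 20.0, -20.0)


class ConfigError(ValueError):
    pass


def _default_cadence(speed: float) -> float:
    """Steps/min rising gently with speed (~163 at 8 km/h, ~173 at 14 km/h)."""
    return 150.0 + 6.0 * speed


def _default_duty_factor(speed: float) -> float:
    """Contact time as a fraction of stride duration, decreasing with speed."""
    return float(np.clip(0.45 - 0.04 * speed, 0.22, 0.42))


@dataclass
class SyntheticTrialConfig:
    """Parameters of one generated trial. Units: SI unless stated."""

    speed: float  # m/s
    grade: float  # % (signed)
    mass: float = 69.0  # kg
    height: float = 174.0  # cm
    age: float = 35.0  # years
    leg_length: float = 90.0  # cm
    participant_id: str = "synthetic"
    cadence: float | None = None  # steps/min
    duty_factor: float | None = None  # tc / strd
    fsa_deg: float = 10.0  # foot strike angle at initial contact
    pushoff_deg: float = 20.0  # plantarflexion at toe-off
    swing_height: float = 0.12  # m, peak foot lift
    #: in-band MEMS noise of a shoe-mounted IMU at rest (quiet stance)
    noise_sd_accel: float = 0.05  # m/s^2
    noise_sd_gyro: float = 0.005  # rad/s
    #: stride-to-stride variability: relative SD of per-step force
    #: amplitudes and of the per-stride pitch-profile angles
    step_variability: float = 0.03
    duration: float = 30.0  # s of running
    static_duration: float = 5.0  # s of quiet standing before the run
    run_lead_in: float = 0.25  # s on the force-plate clock before the first IC
    mount_rotvec: tuple = (0.15, -0.25, 0.6)  # sensor mounting rotation, rad
    seed: int = 0
    fs_force: float = 1000.0
    fs_imu: float = 512.0

    def __post_init__(self):
        if self.cadence is None:
            self.cadence = _default_cadence(self.speed)
        if self.duty_factor is None:
            self.duty_factor = _default_duty_factor(self.speed)
        if not 0.0 < self.duty_factor < 0.5:
            raise ConfigError(
                f"duty factor must be in (0, 0.5) for running, got {self.duty_factor}"
            )
        if not 1.5 <= self.speed <= 6.0:
            raise ConfigError(f"speed {self.speed} m/s outside plausible running range")
        if abs(self.grade) > 25.0:
            raise ConfigError(f"grade {self.grade}% outside the supported range")

    # --- derived timing ---
    @property
    def stride_duration(self) -> float:
        return 2.0 * 60.0 / self.cadence

    @property
    def step_period(self) -> float:
        return self.stride_duration / 2.0

    @property
    def contact_time(self) -> float:
        return self.duty_factor * self.stride_duration

    @property
    def flight_time(self) -> float:
        return self.step_period - self.contact_time

    @property
    def theta_signed(self) -> float:
        return math.atan(self.grade / 100.0)

    def meta(self) -> TrialMeta:
        return TrialMeta(
            participant_id=self.participant_id, mass=self.mass, height=self.height,
            age=self.age, leg_length=self.leg_length, speed=self.speed,
            grade=self.grade,
        )


@dataclass
class GroundTruth:
    """Analytic truth for one trial, on the force-plate clock (seconds)."""

    step_ic_times: np.ndarray  # all steps, both feet, sorted
    step_tc_times: np.ndarray
    peak_power: float  # W, nominal (steady-state) per-step value
    contact_time: float
    flight_time: float
    swing_time: float
    stride_duration: float
    fzmax: float
    dz: float
    kvert: float  # kN/m
    fsa_deg: float
    foot_ic_times: dict = field(default_factory=dict)  # per-foot IC times
    foot_tc_times: dict = field(default_factory=dict)
    #: per-step peak power including stride-to-stride variability
    step_peak_powers: np.ndarray | None = None


@dataclass
class SyntheticTrial:
    config: SyntheticTrialConfig
    meta: TrialMeta
    force_plate: TimeSeries
    imu_left: TimeSeries
    imu_right: TimeSeries
    truth: GroundTruth
    #: force-plate t=0 occurs at this time on the IMU clock
    imu_run_offset: float = 0.0


# ---------------------------------------------------------------------------
# Force model


def _force_amplitudes(cfg: SyntheticTrialConfig):
    """Braking/propulsive sine-lobe amplitudes satisfying impulse balance.

    Net antero-posterior impulse per step must equal the gravity impulse
    along the slope: (A_p - A_b) tc / pi = m g sin(theta) (tc + tf).
    """
    m = cfg.mass
    base = m * G * (0.20 + 0.045 * cfg.speed)
    net_mean = m * G * math.sin(cfg.theta_signed)  # required stride-mean Fy
    delta = math.pi * net_mean * cfg.step_period / cfg.contact_time
    if abs(delta) > 6.0 * base:
        raise ConfigError(
            "impulse balance infeasible: grade/duty-factor combination requires "
            f"a propulsive-braking asymmetry {delta:.0f} N beyond the force model"
        )
    return base - delta / 2.0, base + delta / 2.0  # A_b, A_p


def _fzmax(cfg: SyntheticTrialConfig) -> float:
    return cfg.mass * G * (math.pi / 2.0) * (cfg.flight_time / cfg.contact_time + 1.0)


def _fy_stance(u: np.ndarray, cfg: SyntheticTrialConfig) -> np.ndarray:
    """Antero-posterior force at time ``u`` within the stance, u in [0, tc]."""
    a_b, a_p = _force_amplitudes(cfg)
    w = 2.0 * math.pi / cfg.contact_time
    amp = np.where(u < cfg.contact_time / 2.0, a_b, a_p)
    return -amp * np.sin(w * u)


def closed_form_peak_power(cfg: SyntheticTrialConfig, n_grid: int = 20001,
                           scale: float = 1.0) -> float:
    """Analytic per-step peak horizontal power of the generated gait.

    vy(t) has a closed form (integral of sine lobes); the extremum of
    Py = vy * Fy is located on a dense grid of the analytic expressions.
    ``scale`` multiplies both force lobes (stride-to-stride variability).
    """
    tc = cfg.contact_time
    a_b, a_p = _force_amplitudes(cfg)
    a_b, a_p = a_b * scale, a_p * scale
    w = 2.0 * math.pi / tc
    m = cfg.mass
    gsin = G * math.sin(cfg.theta_signed)
    u = np.linspace(0.0, tc, n_grid)
    fy = _fy_stance(u, cfg) * scale
    # vy = v0y + int (Fy/m - g sin theta); lobe integrals are analytic
    int1 = -(a_b / (m * w)) * (1.0 - np.cos(w * np.minimum(u, tc / 2.0)))
    # second (propulsive) lobe: int of -a_p sin(w u') from tc/2 to u
    int2 = (a_p / (m * w)) * (np.cos(w * u) - math.cos(w * tc / 2.0))
    int2 = np.where(u > tc / 2.0, int2, 0.0)
    vy = cfg.speed + int1 + int2 - gsin * u
    py = vy * fy
    if condition_from_grade(cfg.grade) == "downhill":
        return float(py.min())
    return float(py.max())


def _step_schedule(cfg: SyntheticTrialConfig):
    """IC times of every step on the force-plate clock, alternating feet.

    The first contact is pushed past one swing duration so the preceding
    (virtual) toe-off stays on the running side of the clock and cannot
    contaminate the static calibration window.
    """
    swing = cfg.stride_duration - cfg.contact_time
    t = max(cfg.run_lead_in, swing + 0.05)
    ics = []
    while t + cfg.contact_time < cfg.duration:
        ics.append(t)
        t += cfg.step_period
    if len(ics) < 2:
        raise ConfigError("duration too short for at least two steps")
    return np.asarray(ics)


def generate_grf(cfg: SyntheticTrialConfig, rng: np.random.Generator | None = None) -> tuple[TimeSeries, GroundTruth]:
    """Force-plate recording (Fy, Fz at 1 kHz) and the trial's ground truth."""
    rng = rng or np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs_force))
    t = np.arange(n) / cfg.fs_force
    fy = np.zeros(n)
    fz = np.zeros(n)
    ics = _step_schedule(cfg)
    fzmax = _fzmax(cfg)
    tc = cfg.contact_time
    # stride-to-stride force-amplitude variability, one factor per step
    scales = (1.0 + rng.normal(0.0, cfg.step_variability, ics.size)
              if cfg.step_variability > 0 else np.ones(ics.size))
    scales = np.clip(scales, 0.85, 1.15)
    for ic, sc in zip(ics, scales):
        i0 = int(round(ic * cfg.fs_force))
        i1 = min(int(round((ic + tc) * cfg.fs_force)), n)
        u = t[i0:i1] - ic
        fz[i0:i1] = sc * fzmax * np.sin(np.pi * u / tc)
        fy[i0:i1] = sc * _fy_stance(u, cfg)
    if cfg.noise_sd_accel > 0:
        # force-plate noise scaled from the accel noise figure via body mass
        fy = fy + rng.normal(0.0, cfg.noise_sd_accel * cfg.mass, n)
        fz = fz + rng.normal(0.0, cfg.noise_sd_accel * cfg.mass, n)
    ts = TimeSeries(fs=cfg.fs_force, channels=["Fy", "Fz"], values=np.column_stack([fy, fz]))
    tf = cfg.flight_time
    strd = cfg.stride_duration
    dz = fzmax * tc ** 2 / (cfg.mass * math.pi ** 2) - G * tc ** 2 / 8.0
    nominal_peak = closed_form_peak_power(cfg)
    step_peaks = np.array([
        nominal_peak if sc == 1.0 else closed_form_peak_power(cfg, n_grid=2001, scale=sc)
        for sc in scales])
    truth = GroundTruth(
        step_ic_times=ics,
        step_tc_times=ics + tc,
        peak_power=nominal_peak,
        step_peak_powers=step_peaks,
        contact_time=tc,
        flight_time=tf,
        swing_time=strd - tc,
        stride_duration=strd,
        fzmax=fzmax,
        dz=dz,
        kvert=fzmax / dz / 1000.0,
        fsa_deg=cfg.fsa_deg,
        foot_ic_times={"left": ics[0::2], "right": ics[1::2]},
        foot_tc_times={"left": ics[0::2] + tc, "right": ics[1::2] + tc},
    )
    return ts, truth


# ---------------------------------------------------------------------------
# Kinematic model


def _biexp_pulse(t, onset, tau, sharp=20.0):
    """One-sided angular-rate pulse with unit area: fast attack, slow decay.

    Shape (e^(-s/tau) - e^(-sharp s/tau)) normalised to unit area; its
    extremum sits ~0.16 tau after onset so a detector keyed to the rate
    extremum lands within a few ms of the true event.
    """
    s = np.clip(t - onset, 0.0, None)
    area = tau * (1.0 - 1.0 / sharp)
    rate = (np.exp(-s / tau) - np.exp(-sharp * s / tau)) / area
    rate[t < onset] = 0.0
    angle = (tau * (1.0 - np.exp(-s / tau)) - (tau / sharp) * (1.0 - np.exp(-sharp * s / tau))) / area
    angle[t < onset] = 0.0
    return rate, angle


def _gauss_pulse(t, centre, sigma):
    """Symmetric unit-area angular-rate pulse (forward-swing rotation)."""
    s = (t - centre) / sigma
    rate = np.exp(-0.5 * s ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    angle = ndtr(s)
    return rate, angle


def _quintic(u):
    """Smoothstep with zero velocity and acceleration at both ends."""
    p = 10 * u ** 3 - 15 * u ** 4 + 6 * u ** 5
    v = 30 * u ** 2 - 60 * u ** 3 + 30 * u ** 4
    a = 60 * u - 180 * u ** 2 + 120 * u ** 3
    return p, v, a


def _foot_profiles(t: np.ndarray, ic_times: np.ndarray, cfg: SyntheticTrialConfig,
                   rng: np.random.Generator | None = None):
    """Pitch rate/angle and sensor-point position/acceleration for one foot.

    ``t`` and ``ic_times`` share the force-plate clock. The foot rests until
    its first (virtual) toe-off, then alternates stance and swing. With
    ``cfg.step_variability > 0`` the landing/push-off angles and foot lift
    vary slightly from stride to stride.
    """
    tc = cfg.contact_time
    strd = cfg.stride_duration
    swing = strd - tc
    L = cfg.speed * strd  # stride length
    fsa = math.radians(cfg.fsa_deg)
    poff = math.radians(cfg.pushoff_deg)

    # one virtual cycle before the first IC so the first landing is complete
    all_ics = np.concatenate([[ic_times[0] - strd], ic_times])
    n_cyc = all_ics.size
    sv = cfg.step_variability
    if sv > 0 and rng is not None:
        jit = lambda: np.clip(1.0 + rng.normal(0.0, sv, n_cyc + 1), 0.85, 1.15)
    else:
        jit = lambda: np.ones(n_cyc + 1)
    fsa_j, poff_j, lift_j = fsa * jit(), poff * jit(), cfg.swing_height * jit()

    rate = np.zeros_like(t)
    angle = np.zeros_like(t)
    # Each contact event is a sharp transient (the pitch-rate extremum an
    # event detector locks onto, carrying ~30% of the rotation) followed by
    # a broader rotation completing it: heel-strike slap then foot lowering
    # at IC, push-off transient then plantarflexing roll-off at TC.
    tau_trans, sharp_trans = 0.008, 10.0
    q_ic, q_tc = 0.30, 0.35
    sigma_ms = 0.035
    for j, ic in enumerate(all_ics):
        toe_off = ic + tc
        midswing = toe_off + swing / 2.0
        for amount, onset, frac, centre_off, sigma in (
            (fsa_j[j], ic, q_ic, 0.18 * tc, 0.07 * tc),
            (poff_j[j], toe_off, q_tc, 0.030, 0.015),
        ):
            r, a = _biexp_pulse(t, onset, tau_trans, sharp_trans)
            rate -= frac * amount * r
            angle -= frac * amount * a
            r, a = _gauss_pulse(t, onset + centre_off, sigma)
            rate -= (1.0 - frac) * amount * r
            angle -= (1.0 - frac) * amount * a
        # swing rotation closes the cycle: undo this push-off, arrive at the
        # next landing's foot-strike angle
        r, a = _gauss_pulse(t, midswing, sigma_ms)
        rate += (fsa_j[j + 1] + poff_j[j]) * r
        angle += (fsa_j[j + 1] + poff_j[j]) * a

    # translation: rest during stance, quintic advance + sin^3 lift in swing
    y = np.zeros_like(t)
    z = np.zeros_like(t)
    ay = np.zeros_like(t)
    az = np.zeros_like(t)
    for j, ic in enumerate(all_ics):
        toe_off = ic + tc
        next_ic = ic + strd
        y_start = (j - 1) * L  # stance j holds this position
        in_stance = (t >= ic) & (t < toe_off)
        y[in_stance] = y_start
        in_swing = (t >= toe_off) & (t < next_ic)
        u = (t[in_swing] - toe_off) / swing
        p, v, a = _quintic(u)
        y[in_swing] = y_start + L * p
        ay[in_swing] = L * a / swing ** 2
        s, c = np.sin(np.pi * u), np.cos(np.pi * u)
        z[in_swing] = lift_j[j] * s ** 3
        az[in_swing] = lift_j[j] * (np.pi ** 2) * (6.0 * s * c ** 2 - 3.0 * s ** 3) / swing ** 2
    before = t < all_ics[0]
    y[before] = (0 - 1) * L  # resting at the pre-run stance position
    return rate, angle, y, z, ay, az


def generate_imu(cfg: SyntheticTrialConfig, truth: GroundTruth,
                 rng: np.random.Generator | None = None) -> tuple[TimeSeries, TimeSeries]:
    """Left/right 6-axis IMU recordings at 512 Hz (static phase then run).

    The IMU clock starts ``static_duration`` s before the force-plate clock.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n = int(round((cfg.static_duration + cfg.duration) * cfg.fs_imu))
    t_imu = np.arange(n) / cfg.fs_imu
    t_run = t_imu - cfg.static_duration  # force-plate clock
    alpha = cfg.theta_signed
    g_vec = G * np.array([0.0, -math.sin(alpha), -math.cos(alpha)])
    mount = Rotation.from_rotvec(cfg.mount_rotvec)

    out = []
    for foot in ("left", "right"):
        ics = truth.foot_ic_times[foot]
        rate, angle, y, z, ay, az = _foot_profiles(t_run, ics, cfg, rng)
        still = t_run < ics[0] - cfg.stride_duration + cfg.contact_time
        # linear acceleration in the surface frame
        acc_surf = np.column_stack([np.zeros_like(ay), ay, az])
        acc_surf[still] = 0.0
        rate[still] = 0.0
        # functional frame: rotate (acc - g) by pitch about +X
        cphi, sphi = np.cos(angle), np.sin(angle)
        f_surf = acc_surf - g_vec
        fx = f_surf[:, 0]
        fy = cphi * f_surf[:, 1] + sphi * f_surf[:, 2]
        fz = -sphi * f_surf[:, 1] + cphi * f_surf[:, 2]
        f_func = np.column_stack([fx, fy, fz])
        omega_func = np.column_stack([rate, np.zeros_like(rate), np.zeros_like(rate)])
        # sensor frame: v_func = R_cal v_sensor  =>  v_sensor = v_func @ R_cal
        acc_sensor = f_func @ mount.as_matrix()
        gyr_sensor = omega_func @ mount.as_matrix()
        if cfg.noise_sd_accel > 0:
            acc_sensor = acc_sensor + rng.normal(0.0, cfg.noise_sd_accel, acc_sensor.shape)
        if cfg.noise_sd_gyro > 0:
            gyr_sensor = gyr_sensor + rng.normal(0.0, cfg.noise_sd_gyro, gyr_sensor.shape)
        out.append(TimeSeries(
            fs=cfg.fs_imu, channels=["ax", "ay", "az", "gx", "gy", "gz"],
            values=np.column_stack([acc_sensor, gyr_sensor]),
        ))
    return out[0], out[1]


def generate_trial(cfg: SyntheticTrialConfig) -> SyntheticTrial:
    """One full synthetic trial: GRF + both IMUs + metadata + ground truth."""
    rng = np.random.default_rng(cfg.seed)
    grf, truth = generate_grf(cfg, rng)
    left, right = generate_imu(cfg, truth, rng)
    return SyntheticTrial(config=cfg, meta=cfg.meta(), force_plate=grf,
                          imu_left=left, imu_right=right, truth=truth,
                          imu_run_offset=cfg.static_duration)


# ---------------------------------------------------------------------------
# Cohort generation


def _dropout_probability(speed_kmh: float, grade: float, scale: float) -> float:
    """Participation loss rises with intensity (speed, |grade|, uphill extra)."""
    intensity = (0.5 * (speed_kmh - 8.0) / 6.0
                 + 0.4 * abs(grade) / 20.0
                 + (0.25 * grade / 20.0 if grade > 0 else 0.0))
    return min(0.9, scale * intensity)


def generate_cohort(n_participants: int, seed: int = 0,
                    speeds_kmh=PROTOCOL_SPEEDS_KMH, grades=PROTOCOL_GRADES,
                    dropout_scale: float = 1.0, duration: float = 30.0,
                    noise_sd_accel: float = 0.05, noise_sd_gyro: float = 0.005
                    ) -> list[SyntheticTrialConfig]:
    """Trial configurations for a cohort with an imbalanced condition grid.

    Anthropometrics are drawn from the study population (age 35 +- 11 y,
    height 174 +- 10 cm, mass 69 +- 12 kg, truncated at +-2.5 SD); intense
    conditions (fast, steep, uphill) are dropped with increasing probability
    to emulate reduced participation. Gait timing follows the speed-dependent
    defaults; within-trial stride-to-stride variability and sensor noise
    make repeated seconds distinct.
    """
    if n_participants < 3:
        raise ConfigError("need at least 3 participants")
    rng = np.random.default_rng(seed)

    def _trunc_normal(mean, sd, lim=2.5):
        while True:
            x = rng.normal(mean, sd)
            if abs(x - mean) <= lim * sd:
                return x

    configs = []
    for p in range(n_participants):
        age = _trunc_normal(35.0, 11.0)
        height = _trunc_normal(174.0, 10.0)
        mass = _trunc_normal(69.0, 12.0)
        leg = 0.51 * height + rng.normal(0.0, 2.0)
        pid = f"P{p:02d}"
        for v_kmh in speeds_kmh:
            for grade in grades:
                if rng.random() < _dropout_probability(v_kmh, grade, dropout_scale):
                    continue
                configs.append(SyntheticTrialConfig(
                    speed=v_kmh / 3.6, grade=grade, mass=mass, height=height,
                    age=age, leg_length=leg, participant_id=pid,
                    duration=duration, noise_sd_accel=noise_sd_accel,
                    noise_sd_gyro=noise_sd_gyro,
                    seed=int(rng.integers(0, 2 ** 31 - 1)),
                ))
    return configs
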