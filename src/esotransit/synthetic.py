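"""Synthetic swallow-sensor generator with exact ground truth.

Emulates the recordings of a tethered ingestible esophageal device sampled
at 50 Hz: two axial pressure channels (rear/proximal and front/distal,
cmH₂O) plus a 9-axis inertial/magnetic unit.  Each scenario produces a
physically consistent trajectory — oral hold, reorientation at esophageal
entry, descent to the stomach, a terminal bend at the esophagogastric
junction — together with the pressure signature of the swallow (oral
negative pulse, propagating peristaltic contractions with the rear channel
leading and dominating, positive gastric baseline shift, maneuver steps).

The trajectory is analytic (minimum-jerk position segments, smooth pitch
transitions), so velocity and acceleration are exact derivatives and every
event time is known.  Sensors are synthesized from the analytic state:
the accelerometer reads specific force in the sensor frame, the gyroscope
the body angular rate, the magnetometer a fixed earth field rotated into
the sensor frame; seeded Gaussian noise and optional biases are added last,
so identical (scenario, seed) pairs give byte-identical logs.

Postures
--------
seated    : fast transit; two-segment minimum-jerk descent whose fast
            segment peaks at ``peak_velocity_cm_s``.
supine    : prolonged transit as slow advances separated by quasistatic
            holds (≥ 60% of the transit is spent holding).
stationary: fixed mid-esophageal pose with a programmed swallow pressure
            complex (baseline pre-rise, rear/front peaks, after-contraction).
gastric_maneuver: fixed intragastric pose with stepwise baseline shifts
            (leg raise, deep inspiration) programmed via ``maneuvers``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .orientation import GRAVITY_EARTH
from .quaternion import quat_conjugate, quat_multiply, rotate_vector
from .sensor_io import LogMetadata, SensorLog

__all__ = [
    "NoiseSpec",
    "SwallowScenario",
    "GroundTruth",
    "PRESETS",
    "build_scenario",
    "simulate_trajectory",
    "synthesize_sensors",
    "generate_swallow",
    "MAG_EARTH_UT",
    "ORAL_HOLD_S",
    "ENTRY_DELAY_S",
]

# ---------------------------------------------------------------------------
# timeline and field constants

ORAL_HOLD_S = 2.0          # stationary oral hold before initiation
ENTRY_DELAY_S = 0.4        # oral initiation -> esophageal entry
ENTRY_ROT_S = 0.6          # duration of the entry reorientation
BEND_LEAD_S = 0.5          # terminal bend starts this long before gastric entry
BEND_DUR_S = 1.5           # duration of the terminal bend
BEND_ANGLE_DEG = 35.0      # pitch change at the esophagogastric junction
SEATED_DESCENT_PITCH_DEG = 75.0
SUPINE_ORAL_PITCH_DEG = 20.0
STATIONARY_PITCH_DEG = 60.0
GASTRIC_PITCH_DEG = 40.0
WOBBLE_AMP_RAD = 0.08      # gentle attitude wobble while the device moves
WOBBLE_FREQ_HZ = 0.6
WOBBLE_RAMP_S = 0.3
N_SUPINE_ADVANCES = 5
FAST_PATH_FRACTION = 0.8   # share of the path covered by the fast seated segment;
                           # the remainder advances at ~3.5 cm/s, the speed of a
                           # peristaltic wavefront
SEATED_CREEP_MIN = 2.0     # cm/s; slower implied creep becomes stop-and-go
SEATED_SLOW_PEAK = 3.5     # cm/s peak of the stop-and-go advances
CONTRACTION_DELAY_S = 1.2  # esophageal entry -> rear contraction peak
ORAL_PULSE_SIGMA_S = 0.15
REAR_PULSE_SIGMA_S = 0.35
FRONT_PULSE_SIGMA_S = 0.15
LAG_S_PER_CM = 0.1         # peristaltic lag: front trails rear by 1 s per 10 cm
GASTRIC_SHIFT_CMH2O = 8.0  # positive baseline shift after gastric entry
GASTRIC_BASELINE_CMH2O = 10.0   # resting intragastric baseline (maneuver preset)
ESOPH_BASELINE_CMH2O = 2.0      # resting mid-esophageal baseline (stationary)
STATIONARY_SWALLOW_S = 10.0     # programmed swallow time in stationary logs
PRE_RISE_CMH2O = 6.0            # bolus-induced pre-contraction baseline rise
AFTER_CONTRACTION_LAG_S = 2.0   # front peak -> after-contraction trough
MANEUVER_RAMP_S = 1.0
POST_GASTRIC_S = 15.0      # stationary gastric tail appended by the duration rule

MAG_EARTH_UT = np.array([0.0, 22.0, -42.0])  # earth field, ENU (north+down)

_PRESET_NAMES = (
    "seated_reference",
    "supine_reference",
    "stationary_banana",
    "gastric_maneuver",
)


# ---------------------------------------------------------------------------
# scenario types


@dataclass
class NoiseSpec:
    """Additive sensor-noise model (white Gaussian) plus constant biases."""

    accel_sigma: float = 0.05    # m/s^2
    gyro_sigma: float = 0.005    # rad/s
    mag_sigma: float = 0.5       # uT
    pressure_sigma: float = 1.0  # cmH2O
    accel_bias: tuple = (0.0, 0.0, 0.0)
    gyro_bias: tuple = (0.0, 0.0, 0.0)

    def validate(self) -> None:
        for name in ("accel_sigma", "gyro_sigma", "mag_sigma", "pressure_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"NoiseSpec.{name} must be >= 0")
        for name in ("accel_bias", "gyro_bias"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"NoiseSpec.{name} must be a 3-vector")

    @classmethod
    def from_dict(cls, d) -> "NoiseSpec":
        if isinstance(d, NoiseSpec):
            return d
        return cls(**d)


@dataclass
class SwallowScenario:
    posture: str = "seated"
    transit_duration_s: float = 6.0
    path_length_cm: float = 35.0
    oral_peak_cmH2O: float = -141.0
    rear_contraction_peak_cmH2O: float = 195.0
    front_contraction_peak_cmH2O: float = 99.0
    front_dip_cmH2O: float = 5.0        # front-channel dip at the rear peak
    after_contraction_cmH2O: float = 0.0
    peak_velocity_cm_s: float = 30.0
    cardiac_amplitude_m_s2: float = 0.05
    cardiac_freq_hz: float = 1.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    maneuvers: list = field(default_factory=list)  # (label, start_s, end_s, delta_cmH2O)
    sample_rate_hz: float = 50.0
    duration_s: float = 23.0
    seed: int = 0
    yaw_deg: float = 0.0
    device_length_cm: float = 4.2
    subject_label: str = "synthetic"

    def validate(self) -> None:
        if self.posture not in ("seated", "supine", "stationary", "gastric_maneuver"):
            raise ValueError(f"posture: unknown value {self.posture!r}")
        if not self.transit_duration_s > 0:
            raise ValueError("transit_duration_s must be > 0")
        if not self.path_length_cm > 0:
            raise ValueError("path_length_cm must be > 0")
        if not self.oral_peak_cmH2O < 0:
            raise ValueError("oral_peak_cmH2O must be negative")
        if self.peak_velocity_cm_s < 0:
            raise ValueError("peak_velocity_cm_s must be >= 0")
        if self.cardiac_amplitude_m_s2 < 0:
            raise ValueError("cardiac_amplitude_m_s2 must be >= 0")
        if not self.cardiac_freq_hz > 0:
            raise ValueError("cardiac_freq_hz must be > 0")
        if not self.sample_rate_hz > 2.0 * self.cardiac_freq_hz:
            raise ValueError("sample_rate_hz must exceed twice cardiac_freq_hz")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if self.posture in ("seated", "supine"):
            if self.duration_s < self.transit_duration_s + ORAL_HOLD_S:
                raise ValueError(
                    "duration_s must cover the oral hold plus transit_duration_s"
                )
        for m in self.maneuvers:
            if len(m) != 4:
                raise ValueError("maneuvers entries must be (label, start_s, end_s, delta)")
            if not (0 <= m[1] < m[2] <= self.duration_s):
                raise ValueError(f"maneuver {m[0]!r} interval outside the record")
        self.noise.validate()

    def hash(self) -> str:
        payload = dict(self.__dict__)
        payload["noise"] = self.noise.__dict__
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Analytic state and event schedule behind a synthesized log."""

    times: np.ndarray                 # (n,) s
    true_position: np.ndarray         # (n, 3) cm, earth frame
    true_quaternion: np.ndarray       # (n, 4) sensor->earth
    true_velocity: np.ndarray         # (n, 3) cm/s, earth frame
    true_linear_accel: np.ndarray     # (n, 3) m/s^2, earth frame (gravity-free)
    true_angular_rate: np.ndarray     # (n, 3) rad/s, sensor frame
    event_times: dict                 # oral_initiation / esophageal_entry /
                                      # rear_contraction / les_passage / gastric_entry
    true_path_length_cm: float
    true_transit_s: Optional[float]
    hold_segments: list = field(default_factory=list)  # interior quasistatic holds (s, e)


# ---------------------------------------------------------------------------
# presets


def _load_presets() -> dict:
    presets = {}
    for name in _PRESET_NAMES:
        with resources.files(__package__).joinpath(f"presets/{name}.json").open() as fh:
            presets[name] = json.load(fh)
    return presets


PRESETS = _load_presets()


def build_scenario(preset: str, overrides: Optional[dict] = None) -> SwallowScenario:
    """Instantiate a named preset, optionally overriding individual fields.

    Overriding ``transit_duration_s`` without ``duration_s`` stretches the
    record to keep the oral hold and a stationary gastric tail.
    """
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; valid presets: {', '.join(_PRESET_NAMES)}"
        )
    cfg = dict(PRESETS[preset])
    overrides = dict(overrides or {})
    valid_fields = set(SwallowScenario.__dataclass_fields__)
    for key in overrides:
        if key not in valid_fields:
            raise ValueError(f"unknown scenario field {key!r}")
    if "transit_duration_s" in overrides and "duration_s" not in overrides:
        overrides["duration_s"] = (
            float(overrides["transit_duration_s"]) + ORAL_HOLD_S + POST_GASTRIC_S
        )
    cfg.update(overrides)
    cfg["noise"] = NoiseSpec.from_dict(cfg.get("noise", {}))
    cfg["maneuvers"] = [tuple(m) for m in cfg.get("maneuvers", [])]
    scenario = SwallowScenario(**cfg)
    scenario.validate()
    return scenario


# ---------------------------------------------------------------------------
# smooth primitives (all analytic, with derivatives)


def _mj_shape(tau: np.ndarray):
    """Minimum-jerk rest-to-rest unit shape and its derivative on tau∈[0,1]."""
    tau = np.clip(tau, 0.0, 1.0)
    s = tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)
    ds = 30.0 * tau**2 * (1.0 - tau) ** 2
    return s, ds


def _min_jerk_segment(t: np.ndarray, t0: float, T: float, L: float):
    """Position/velocity/acceleration of a minimum-jerk move of length L."""
    tau = np.clip((t - t0) / T, 0.0, 1.0)
    s = L * tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)
    v = (L / T) * 30.0 * tau**2 * (1.0 - tau) ** 2
    a = (L / T**2) * 60.0 * tau * (1.0 - 3.0 * tau + 2.0 * tau**2)
    return s, v, a


def _window_env(t: np.ndarray, a: float, b: float, ramp: float):
    """C¹ envelope: 0 → 1 over [a, a+ramp], 1 → 0 over [b−ramp, b]."""
    up, dup = _mj_shape((t - a) / ramp)
    dn, ddn = _mj_shape((t - (b - ramp)) / ramp)
    env = up - dn
    denv = (dup - ddn) / ramp
    return env, denv


# ---------------------------------------------------------------------------
# trajectory


def _motion_segments(sc: SwallowScenario):
    """Return (segments, holds): minimum-jerk (t0, T, L) moves and hold spans.

    Seated uses a fast segment covering FAST_PATH_FRACTION of the path with
    peak speed equal to ``peak_velocity_cm_s`` followed by a slow segment
    filling the rest of the transit window (the device keeps creeping, so
    the transit interior never goes quasistatic).  When the transit is long
    enough that the remainder would imply a sub-peristaltic creep (peak
    below SEATED_CREEP_MIN), the remainder becomes stop-and-go: slow
    advances at SEATED_SLOW_PEAK separated by quasistatic holds, the way a
    retained bolus actually progresses.  Supine advances in
    N_SUPINE_ADVANCES slow minimum-jerk steps separated by equal holds.
    """
    t_entry = ORAL_HOLD_S + ENTRY_DELAY_S
    D = sc.transit_duration_s - ENTRY_DELAY_S
    L = sc.path_length_cm
    v = sc.peak_velocity_cm_s
    if sc.posture == "seated":
        v_single = 1.875 * L / D
        if v < v_single * (1.0 - 1e-9):
            raise ValueError(
                "transit_duration_s incompatible with peak_velocity_cm_s and "
                f"path_length_cm: a rest-to-rest profile needs peak velocity "
                f">= {v_single:.2f} cm/s"
            )
        if v <= v_single * (1.0 + 1e-6):
            return [(t_entry, D, L)], []
        L1 = FAST_PATH_FRACTION * L
        T1 = 1.875 * L1 / v
        rem_L, rem_T = L - L1, D - T1
        segments = [(t_entry, T1, L1)]
        if 1.875 * rem_L / rem_T >= SEATED_CREEP_MIN:
            segments.append((t_entry + T1, rem_T, rem_L))
            return segments, []
        n = 3
        T_seg = 1.875 * (rem_L / n) / SEATED_SLOW_PEAK
        hold = (rem_T - n * T_seg) / n
        holds = []
        for k in range(n):
            start = t_entry + T1 + (k + 1) * hold + k * T_seg
            holds.append((start - hold, start))
            segments.append((start, T_seg, rem_L / n))
        return segments, holds
    if sc.posture == "supine":
        n = N_SUPINE_ADVANCES
        T_seg = 1.875 * (L / n) / v
        if n * T_seg > 0.4 * D:
            v_min = 1.875 * L / (0.4 * D)
            raise ValueError(
                "transit_duration_s incompatible with peak_velocity_cm_s and "
                f"path_length_cm: supine advances with >=60% hold time need "
                f"peak velocity >= {v_min:.2f} cm/s"
            )
        hold = (D - n * T_seg) / n
        segments = []
        holds = []
        for k in range(n):
            start = t_entry + (k + 1) * hold + k * T_seg
            holds.append((start - hold, start))
            segments.append((start, T_seg, L / n))
        return segments, holds
    return [], []


def _pitch_schedule(sc: SwallowScenario, t_gastric: float):
    """(base_deg, transitions): pitch transitions as (t0, T, delta_deg)."""
    t_entry = ORAL_HOLD_S + ENTRY_DELAY_S
    bend0 = t_gastric - BEND_LEAD_S
    if sc.posture == "seated":
        return 0.0, [
            (t_entry, ENTRY_ROT_S, SEATED_DESCENT_PITCH_DEG),
            (bend0, BEND_DUR_S, -BEND_ANGLE_DEG),
        ]
    if sc.posture == "supine":
        return SUPINE_ORAL_PITCH_DEG, [
            (t_entry, ENTRY_ROT_S, -SUPINE_ORAL_PITCH_DEG),
            (bend0, BEND_DUR_S, BEND_ANGLE_DEG),
        ]
    base = STATIONARY_PITCH_DEG if sc.posture == "stationary" else GASTRIC_PITCH_DEG
    return base, []


def _path_direction(sc: SwallowScenario) -> np.ndarray:
    if sc.posture == "seated":  # near-vertical descent, slight anterior lean
        ang = np.radians(8.0)
        return np.array([np.sin(ang), 0.0, -np.cos(ang)])
    ang = np.radians(6.0)       # supine: near-horizontal advance
    return np.array([np.cos(ang), 0.0, -np.sin(ang)])


def simulate_trajectory(scenario: SwallowScenario) -> GroundTruth:
    """Analytic device trajectory and event schedule for a scenario."""
    sc = scenario
    sc.validate()
    fs = sc.sample_rate_hz
    n = int(round(sc.duration_s * fs))
    t = np.arange(n) / fs

    transiting = sc.posture in ("seated", "supine")
    t_oral = ORAL_HOLD_S
    t_entry = t_oral + ENTRY_DELAY_S
    t_gastric = t_oral + sc.transit_duration_s if transiting else None

    # --- position along the path (cm) ---
    s = np.zeros(n)
    v = np.zeros(n)
    a = np.zeros(n)
    segments, holds = _motion_segments(sc) if transiting else ([], [])
    for t0, T, L in segments:
        si, vi, ai = _min_jerk_segment(t, t0, T, L)
        s += si
        v += vi
        a += ai
    direction = _path_direction(sc)
    position = np.outer(s, direction)                    # cm
    velocity = np.outer(v, direction)                    # cm/s
    linear_accel = np.outer(a, direction) / 100.0        # m/s^2

    # --- pitch angle (deg) and rate ---
    base_deg, transitions = _pitch_schedule(sc, t_gastric if transiting else 0.0)
    theta = np.full(n, np.radians(base_deg))
    theta_dot = np.zeros(n)
    for t0, T, delta in transitions:
        shape, dshape = _mj_shape((t - t0) / T)
        theta += np.radians(delta) * shape
        theta_dot += np.radians(delta) * dshape / T

    # wobble while moving: keeps the slow-descent interior out of the
    # quasistatic detector, as a tumbling device would; holds stay quiet
    if transiting:
        wobble_windows = [(t0, t0 + T) for t0, T, _ in segments]
        w = 2.0 * np.pi * WOBBLE_FREQ_HZ
        for wa, wb in wobble_windows:
            env, denv = _window_env(t, wa, wb, WOBBLE_RAMP_S)
            osc = np.sin(w * (t - wa))
            dosc = w * np.cos(w * (t - wa))
            theta += WOBBLE_AMP_RAD * osc * env
            theta_dot += WOBBLE_AMP_RAD * (dosc * env + osc * denv)

    # --- quaternions: fixed yaw ∘ time-varying pitch about body y ---
    half = 0.5 * theta
    q_pitch = np.stack(
        [np.cos(half), np.zeros(n), np.sin(half), np.zeros(n)], axis=-1
    )
    psi = np.radians(sc.yaw_deg)
    q_yaw = np.array([np.cos(psi / 2), 0.0, 0.0, np.sin(psi / 2)])
    quats = quat_multiply(np.broadcast_to(q_yaw, (n, 4)), q_pitch)
    angular_rate = np.zeros((n, 3))
    angular_rate[:, 1] = theta_dot
    if abs(psi) > 0:
        position = rotate_vector(np.broadcast_to(q_yaw, (n, 4)), position)
        velocity = rotate_vector(np.broadcast_to(q_yaw, (n, 4)), velocity)
        linear_accel = rotate_vector(np.broadcast_to(q_yaw, (n, 4)), linear_accel)

    events = {}
    transit_s = None
    path_len = 0.0
    if transiting:
        events = {
            "oral_initiation": t_oral,
            "esophageal_entry": t_entry,
            "rear_contraction": t_entry + CONTRACTION_DELAY_S,
            "les_passage": t_gastric,
            "gastric_entry": t_gastric,
        }
        transit_s = sc.transit_duration_s
        path_len = float(np.sum(np.linalg.norm(np.diff(position, axis=0), axis=1)))
    elif sc.posture == "stationary":
        events = {"swallow": STATIONARY_SWALLOW_S}

    return GroundTruth(
        times=t,
        true_position=position,
        true_quaternion=quats,
        true_velocity=velocity,
        true_linear_accel=linear_accel,
        true_angular_rate=angular_rate,
        event_times=events,
        true_path_length_cm=path_len,
        true_transit_s=transit_s,
        hold_segments=holds,
    )


# ---------------------------------------------------------------------------
# sensors


def _gauss(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _pressure_traces(sc: SwallowScenario, gt: GroundTruth):
    """Noise-free rear/front pressure channels (cmH₂O)."""
    t = gt.times
    rear = np.zeros_like(t)
    front = np.zeros_like(t)
    lag = LAG_S_PER_CM * sc.device_length_cm

    if sc.posture in ("seated", "supine"):
        t_oral = gt.event_times["oral_initiation"]
        t_c1 = gt.event_times["rear_contraction"]
        t_gastric = gt.event_times["gastric_entry"]
        rear += sc.oral_peak_cmH2O * _gauss(t, t_oral, ORAL_PULSE_SIGMA_S)
        front += 0.6 * sc.oral_peak_cmH2O * _gauss(t, t_oral, ORAL_PULSE_SIGMA_S)
        rear += sc.rear_contraction_peak_cmH2O * _gauss(t, t_c1, REAR_PULSE_SIGMA_S)
        front += -sc.front_dip_cmH2O * _gauss(t, t_c1, FRONT_PULSE_SIGMA_S)
        front += sc.front_contraction_peak_cmH2O * _gauss(t, t_c1 + lag, FRONT_PULSE_SIGMA_S)
        # passage through the lower esophageal sphincter: second, smaller peak
        rear += 0.6 * sc.rear_contraction_peak_cmH2O * _gauss(t, t_gastric, REAR_PULSE_SIGMA_S)
        front += 0.6 * sc.front_contraction_peak_cmH2O * _gauss(
            t, t_gastric + lag, FRONT_PULSE_SIGMA_S
        )
        shift, _ = _mj_shape((t - t_gastric) / 2.0)
        rear += GASTRIC_SHIFT_CMH2O * shift
        front += GASTRIC_SHIFT_CMH2O * shift
    elif sc.posture == "stationary":
        t_sw = gt.event_times["swallow"]
        rear += ESOPH_BASELINE_CMH2O
        front += ESOPH_BASELINE_CMH2O
        env, _ = _window_env(t, t_sw - 3.0, t_sw + 1.0, 2.0)
        rear += PRE_RISE_CMH2O * env
        front += 0.5 * PRE_RISE_CMH2O * env
        rear += sc.rear_contraction_peak_cmH2O * _gauss(t, t_sw, 0.3)
        front += sc.front_contraction_peak_cmH2O * _gauss(t, t_sw + lag, 0.2)
        if sc.after_contraction_cmH2O != 0.0:
            t_after = t_sw + lag + AFTER_CONTRACTION_LAG_S
            rear += sc.after_contraction_cmH2O * _gauss(t, t_after, 0.4)
            front += 0.5 * sc.after_contraction_cmH2O * _gauss(t, t_after, 0.4)
    else:  # gastric_maneuver
        rear += GASTRIC_BASELINE_CMH2O
        front += GASTRIC_BASELINE_CMH2O

    for label, start, end, delta in sc.maneuvers:
        env, _ = _window_env(t, start, end, MANEUVER_RAMP_S)
        rear += delta * env
        front += delta * env
    return rear, front


def synthesize_sensors(gt: GroundTruth, scenario: SwallowScenario) -> SensorLog:
    """Render a :class:`SensorLog` from analytic ground truth plus noise."""
    sc = scenario
    t = gt.times
    n = len(t)
    if abs((t[1] - t[0]) - 1.0 / sc.sample_rate_hz) > 1e-9:
        raise ValueError("ground truth not sampled at scenario.sample_rate_hz")
    rng = np.random.default_rng(sc.seed)
    q = gt.true_quaternion
    q_conj = quat_conjugate(q)

    # specific force: linear acceleration minus gravity, in the sensor frame
    f_earth = gt.true_linear_accel - GRAVITY_EARTH
    accel = rotate_vector(q_conj, f_earth)

    # cardiac modulation along the sensor-frame gravity direction so the
    # acceleration magnitude fluctuates at cardiac_freq_hz (ballistic motion)
    if sc.cardiac_amplitude_m_s2 > 0 and sc.posture != "gastric_maneuver":
        if sc.posture in ("seated", "supine"):
            win = (gt.event_times["esophageal_entry"], gt.event_times["gastric_entry"])
        else:
            win = (float(t[0]), float(t[-1]) + 1.0 / sc.sample_rate_hz)
        env, _ = _window_env(t, win[0], win[1], 0.5)
        g_dir = rotate_vector(q_conj, np.array([0.0, 0.0, -1.0]))
        osc = sc.cardiac_amplitude_m_s2 * np.sin(2.0 * np.pi * sc.cardiac_freq_hz * t)
        accel = accel + (osc * env)[:, None] * g_dir

    noise = sc.noise
    accel = accel + np.asarray(noise.accel_bias) + rng.normal(0.0, noise.accel_sigma, (n, 3))
    gyro = (
        gt.true_angular_rate
        + np.asarray(noise.gyro_bias)
        + rng.normal(0.0, noise.gyro_sigma, (n, 3))
    )
    mag = rotate_vector(q_conj, MAG_EARTH_UT) + rng.normal(0.0, noise.mag_sigma, (n, 3))

    rear, front = _pressure_traces(sc, gt)
    rear = rear + rng.normal(0.0, noise.pressure_sigma, n)
    front = front + rng.normal(0.0, noise.pressure_sigma, n)

    metadata = LogMetadata(
        sample_rate_hz=sc.sample_rate_hz,
        posture=sc.posture,
        device_length_cm=sc.device_length_cm,
        subject_label=sc.subject_label,
        scenario_hash=sc.hash(),
    )
    log = SensorLog(
        metadata=metadata,
        times=t.copy(),
        p_rear=rear,
        p_front=front,
        accel=accel,
        gyro=gyro,
        mag=mag,
    )
    log.validate()
    return log


def generate_swallow(scenario: SwallowScenario):
    """Convenience composition: trajectory + sensors → (SensorLog, GroundTruth)."""
    gt = simulate_trajectory(scenario)
    log = synthesize_sensors(gt, scenario)
    return log, gt


# Per-swallow transit durations for a five-swallow session, chosen so the
# session median and type-7 quartiles reproduce the reference per-posture
# statistics exactly (seated: median 6 s, IQR 6–23; supine: median 233 s,
# IQR 142–317).  Individual raw swallows are not available; these fixtures
# parameterize multi-swallow sessions, they are not measured data.
SEATED_SESSION_TRANSITS_S = (6.0, 6.0, 6.0, 23.0, 23.0)
SUPINE_SESSION_TRANSITS_S = (142.0, 142.0, 233.0, 317.0, 317.0)


def session_scenarios(preset: str, base_seed: int = 1):
    """Five per-swallow scenarios emulating one posture session.

    Swallow k uses seed ``base_seed + k`` and the k-th fixture transit
    duration; record length stretches automatically to keep the oral hold
    and gastric tail.
    """
    transits = {
        "seated_reference": SEATED_SESSION_TRANSITS_S,
        "supine_reference": SUPINE_SESSION_TRANSITS_S,
    }[preset]
    return [
        build_scenario(preset, {"seed": base_seed + k, "transit_duration_s": transits[k]})
        for k in range(len(transits))
    ]
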