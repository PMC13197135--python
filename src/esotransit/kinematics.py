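"""Gravity compensation, smoothing, and ZUPT-anchored double integration.

The chain mirrors the standard inertial dead-reckoning recipe for slow
physiological motion:

1. rotate each accelerometer sample into the earth frame with the estimated
   quaternion and add gravity (the accelerometer measures specific force, so
   linear acceleration = R(q)·a_sensor + g with g = (0, 0, −9.81) m/s²);
2. Savitzky–Golay smooth the linear acceleration (default 0.2 s window,
   cubic), which suppresses wideband sensor noise while preserving the
   ≈0.5–1 s peristaltic acceleration transients;
3. detect quasistatic segments (low windowed gyro variance AND low windowed
   linear-acceleration magnitude) to serve as zero-velocity references;
4. integrate acceleration to velocity (trapezoidal), remove the
   piecewise-linear drift that would leave nonzero velocity at the segment
   midpoints, and clamp velocity to zero across each quasistatic segment;
5. integrate velocity to displacement and accumulate arc length on the
   smoothed displacement.

A Monte-Carlo perturbation of the linear acceleration (noise σ estimated
from the quasistatic segments themselves) gives the distance-uncertainty
half-width reported alongside the path length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .orientation import GRAVITY_EARTH, OrientationTrack
from .quaternion import rotate_vector
from .sensor_io import SensorLog

__all__ = [
    "SmoothingParams",
    "ZuptParams",
    "KinematicsResult",
    "compensate_gravity",
    "smooth",
    "detect_quasistatic",
    "integrate_velocity",
    "integrate_displacement",
    "estimate_distance_uncertainty",
    "compute_kinematics",
]


@dataclass
class SmoothingParams:
    """Savitzky–Golay smoothing configuration.

    ``lambda_raw`` is the smoothing constant as conventionally quoted for
    this pipeline; it is read as the window length in seconds (0.2 s → an
    11-point window at 50 Hz) with a cubic local polynomial.
    """

    lambda_raw: float = 0.2
    window_s: Optional[float] = None
    polyorder: int = 3

    @property
    def effective_window_s(self) -> float:
        return self.window_s if self.window_s is not None else self.lambda_raw

    def window_samples(self, sample_rate_hz: float) -> int:
        w = int(round(self.effective_window_s * sample_rate_hz))
        if w % 2 == 0:
            w += 1
        if w < self.polyorder + 2:
            raise ValueError(
                f"smoothing window ({w} samples) must be an odd integer "
                f">= polyorder + 2 ({self.polyorder + 2})"
            )
        return w


@dataclass
class ZuptParams:
    """Quasistatic (zero-velocity) detector thresholds."""

    window_s: float = 0.5
    gyro_var_thresh: float = 1e-4   # (rad/s)^2, per-axis windowed variance
    accel_mag_thresh: float = 0.2   # m/s^2, windowed mean |linear accel|
    min_segment_s: float = 1.0

    def validate(self) -> None:
        for name in ("window_s", "gyro_var_thresh", "accel_mag_thresh", "min_segment_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ZuptParams.{name} must be > 0")


@dataclass
class KinematicsResult:
    times: np.ndarray
    linear_accel_earth: np.ndarray   # (n, 3) m/s^2
    velocity_earth: np.ndarray       # (n, 3) cm/s
    displacement_earth: np.ndarray   # (n, 3) cm
    path_length_cm: float
    net_displacement_cm: float
    zupt_segments: List[Tuple[float, float]]
    distance_uncertainty_cm: Optional[float]
    peak_speed_cm_s: float
    warnings: list = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "lin_ax_m_s2": self.linear_accel_earth[:, 0],
                "lin_ay_m_s2": self.linear_accel_earth[:, 1],
                "lin_az_m_s2": self.linear_accel_earth[:, 2],
                "vx_cm_s": self.velocity_earth[:, 0],
                "vy_cm_s": self.velocity_earth[:, 1],
                "vz_cm_s": self.velocity_earth[:, 2],
                "dx_cm": self.displacement_earth[:, 0],
                "dy_cm": self.displacement_earth[:, 1],
                "dz_cm": self.displacement_earth[:, 2],
            }
        )


def compensate_gravity(log: SensorLog, track: OrientationTrack) -> np.ndarray:
    """Earth-frame linear acceleration (m/s²): rotate and cancel gravity."""
    if len(track.quaternions) != log.n_samples:
        raise ValueError("orientation track length does not match log")
    f_earth = rotate_vector(track.quaternions, log.accel)
    return f_earth + GRAVITY_EARTH


def smooth(signal: np.ndarray, params: SmoothingParams, sample_rate_hz: float) -> np.ndarray:
    """Savitzky–Golay smoothing along axis 0; edges use truncated-window fits."""
    signal = np.asarray(signal, dtype=float)
    w = params.window_samples(sample_rate_hz)
    if signal.shape[0] < w:
        raise ValueError(f"signal ({signal.shape[0]} samples) shorter than window ({w})")
    return savgol_filter(signal, w, params.polyorder, axis=0, mode="interp")


def _segments_from_mask(mask: np.ndarray, times: np.ndarray, min_len_s: float):
    """Maximal True runs of ``mask`` as (start_s, end_s), short runs dropped."""
    idx = np.nonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))[0]
    segments = []
    for s, e in zip(idx[::2], idx[1::2]):
        t0, t1 = float(times[s]), float(times[e - 1])
        if t1 - t0 >= min_len_s:
            segments.append((t0, t1))
    return segments


def detect_quasistatic(
    linear_accel: np.ndarray,
    gyro: np.ndarray,
    times: np.ndarray,
    params: Optional[ZuptParams] = None,
) -> List[Tuple[float, float]]:
    """Quasistatic segments: low rotation AND low linear acceleration.

    A sample is quasistatic when, over a centred ``window_s`` window, every
    gyro axis has variance below ``gyro_var_thresh`` and the mean
    linear-acceleration magnitude is below ``accel_mag_thresh``.  Maximal
    runs shorter than ``min_segment_s`` are dropped.  Returns non-
    overlapping, sorted (start_s, end_s) pairs; may be empty.
    """
    params = params or ZuptParams()
    params.validate()
    fs = 1.0 / float(np.median(np.diff(times)))
    w = max(3, int(round(params.window_s * fs)))

    gyro = np.asarray(gyro, dtype=float)
    mean = uniform_filter1d(gyro, w, axis=0, mode="nearest")
    mean_sq = uniform_filter1d(gyro**2, w, axis=0, mode="nearest")
    gyro_var = np.clip(mean_sq - mean**2, 0.0, None)

    amag = np.linalg.norm(np.asarray(linear_accel, dtype=float), axis=1)
    amag_mean = uniform_filter1d(amag, w, mode="nearest")

    mask = np.all(gyro_var < params.gyro_var_thresh, axis=1) & (
        amag_mean < params.accel_mag_thresh
    )
    return _segments_from_mask(mask, times, params.min_segment_s)


def _segment_mask(times: np.ndarray, segments) -> np.ndarray:
    mask = np.zeros(len(times), dtype=bool)
    for s, e in segments:
        mask |= (times >= s) & (times <= e)
    return mask


def _anchor_indices(times: np.ndarray, segments) -> np.ndarray:
    """Zero-velocity anchor samples: midpoint and both edges of each segment.

    Velocity is zero throughout a quasistatic segment, so anchoring at the
    edges as well as the midpoint keeps the unaided drift interval as short
    as the data allow.
    """
    idx = set()
    for s, e in segments:
        for t_anchor in (s, 0.5 * (s + e), e):
            idx.add(int(np.argmin(np.abs(times - t_anchor))))
    return np.array(sorted(idx), dtype=int)


def integrate_velocity(
    linear_accel: np.ndarray,
    zupt_segments,
    times: np.ndarray,
    warnings_out: Optional[list] = None,
) -> np.ndarray:
    """Trapezoidal velocity with zero-velocity anchoring.

    The raw integral is corrected so velocity vanishes at the midpoint of
    every quasistatic segment: between consecutive anchors the linear-in-
    time ramp through the anchor errors is subtracted (piecewise detrend);
    before the first and after the last anchor the constant anchor error is
    subtracted.  Velocity is then clamped to zero across the full extent of
    each quasistatic segment.  With no segments the uncorrected integral is
    returned and a warning is recorded.
    """
    a = np.atleast_2d(np.asarray(linear_accel, dtype=float).T).T
    v = cumulative_trapezoid(a, times, axis=0, initial=0.0)
    if len(zupt_segments) == 0:
        if warnings_out is not None:
            warnings_out.append(
                "no quasistatic segment found: velocity integrated without "
                "zero-velocity correction and may drift"
            )
        return v if linear_accel.ndim > 1 else v[:, 0]
    anchors = _anchor_indices(times, zupt_segments)
    # piecewise-linear drift through the anchor errors, constant beyond the ends
    drift = np.empty_like(v)
    for k in range(v.shape[1]):
        drift[:, k] = np.interp(times, times[anchors], v[anchors, k])
    v = v - drift
    v[_segment_mask(times, zupt_segments)] = 0.0
    return v if linear_accel.ndim > 1 else v[:, 0]


def integrate_displacement(
    velocity: np.ndarray,
    times: np.ndarray,
    smoothing: Optional[SmoothingParams] = None,
) -> Tuple[np.ndarray, float]:
    """Trapezoidal displacement and arc length (units follow the input).

    Arc length is accumulated on a Savitzky–Golay-smoothed copy of the
    displacement so sample-to-sample noise does not inflate it; the raw
    displacement is returned.
    """
    v = np.atleast_2d(np.asarray(velocity, dtype=float).T).T
    d = cumulative_trapezoid(v, times, axis=0, initial=0.0)
    d_for_path = d
    if smoothing is not None:
        fs = 1.0 / float(np.median(np.diff(times)))
        if d.shape[0] >= smoothing.window_samples(fs):
            d_for_path = smooth(d, smoothing, fs)
    path = float(np.sum(np.linalg.norm(np.diff(d_for_path, axis=0), axis=1)))
    return (d if velocity.ndim > 1 else d[:, 0]), path


def estimate_distance_uncertainty(
    log: SensorLog,
    track: OrientationTrack,
    zupt_segments,
    K: int = 20,
    seed: int = 0,
    smoothing: Optional[SmoothingParams] = None,
) -> float:
    """Monte-Carlo distance-uncertainty half-width (cm).

    Noise σ is estimated per axis from the linear acceleration inside the
    quasistatic segments (where the true value is zero); K noise-perturbed
    copies of the linear acceleration are re-integrated and the half-width
    of the central 95% spread of the resulting path lengths is returned.
    """
    if K < 10:
        raise ValueError("K must be >= 10")
    if len(zupt_segments) == 0:
        raise ValueError("cannot estimate noise sigma without a quasistatic segment")
    smoothing = smoothing or SmoothingParams()
    fs = log.metadata.sample_rate_hz
    a_raw = compensate_gravity(log, track)
    mask = _segment_mask(log.times, zupt_segments)
    resid = a_raw[mask] - a_raw[mask].mean(axis=0)
    sigma = resid.std(axis=0)
    rng = np.random.default_rng(seed)
    paths = np.empty(K)
    for k in range(K):
        a_pert = a_raw + rng.normal(0.0, 1.0, a_raw.shape) * sigma
        a_s = smooth(a_pert, smoothing, fs)
        v = integrate_velocity(a_s, zupt_segments, log.times) * 100.0  # cm/s
        _, paths[k] = integrate_displacement(v, log.times, smoothing)
    lo, hi = np.percentile(paths, [2.5, 97.5])
    return float(0.5 * (hi - lo))


def compute_kinematics(
    log: SensorLog,
    track: OrientationTrack,
    smoothing: Optional[SmoothingParams] = None,
    zupt: Optional[ZuptParams] = None,
    uncertainty_K: Optional[int] = 20,
    uncertainty_seed: int = 0,
) -> KinematicsResult:
    """Full chain: gravity compensation → smoothing → ZUPT → double integration."""
    smoothing = smoothing or SmoothingParams()
    zupt = zupt or ZuptParams()
    warnings_out: list = []
    fs = log.metadata.sample_rate_hz

    a_lin = compensate_gravity(log, track)
    a_s = smooth(a_lin, smoothing, fs)
    segments = detect_quasistatic(a_s, log.gyro, log.times, zupt)
    v = integrate_velocity(a_s, segments, log.times, warnings_out) * 100.0  # cm/s
    d, path = integrate_displacement(v, log.times, smoothing)

    uncertainty = None
    if uncertainty_K is not None and segments:
        uncertainty = estimate_distance_uncertainty(
            log, track, segments, K=uncertainty_K, seed=uncertainty_seed, smoothing=smoothing
        )
    return KinematicsResult(
        times=log.times,
        linear_accel_earth=a_s,
        velocity_earth=v,
        displacement_earth=d,
        path_length_cm=path,
        net_displacement_cm=float(np.linalg.norm(d[-1] - d[0])),
        zupt_segments=segments,
        distance_uncertainty_cm=uncertainty,
        peak_speed_cm_s=float(np.max(np.linalg.norm(v, axis=1))),
        warnings=warnings_out,
    )
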