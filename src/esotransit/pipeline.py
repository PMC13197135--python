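"""End-to-end per-recording analysis: log in, report dict out.

``analyze_log`` is a pure function of (log, config): orientation
estimation, kinematics, and event detection are run as appropriate for the
recorded posture, and the results are collected into the stable report
schema used by the CLI and the session aggregator:

    {events: [{type, time_s, amplitude_cmH2O, channel}], transit_s,
     max_rear_cmH2O, max_front_cmH2O, max_delta_cmH2O, path_length_cm,
     distance_uncertainty_cm, peak_velocity_cm_s, cardiac_freq_hz,
     maneuvers: [{label, delta_cmH2O}], ...}
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from . import events as ev
from .kinematics import SmoothingParams, ZuptParams, compute_kinematics
from .orientation import FilterParams, estimate_orientation
from .sensor_io import SensorLog

__all__ = ["AnalysisConfig", "analyze_log"]


class AnalysisConfig:
    """Tunables for a full-log analysis (all defaults are sensible)."""

    def __init__(
        self,
        filter_params: Optional[FilterParams] = None,
        smoothing: Optional[SmoothingParams] = None,
        zupt: Optional[ZuptParams] = None,
        maneuver_intervals: Optional[list] = None,
        uncertainty_K: Optional[int] = 20,
        uncertainty_seed: int = 0,
        cardiac_band_hz: tuple = (0.5, 3.0),
    ):
        self.filter_params = filter_params or FilterParams()
        self.smoothing = smoothing or SmoothingParams()
        self.zupt = zupt or ZuptParams()
        self.maneuver_intervals = maneuver_intervals or []
        self.uncertainty_K = uncertainty_K
        self.uncertainty_seed = uncertainty_seed
        self.cardiac_band_hz = tuple(cardiac_band_hz)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kw = {}
        if "beta" in d:
            kw["filter_params"] = FilterParams(beta=float(d["beta"]))
        if "smoothing_window_s" in d:
            kw["smoothing"] = SmoothingParams(window_s=float(d["smoothing_window_s"]))
        if "maneuver_intervals" in d:
            kw["maneuver_intervals"] = [tuple(m) for m in d["maneuver_intervals"]]
        for key in ("uncertainty_K", "uncertainty_seed", "cardiac_band_hz"):
            if key in d:
                kw[key] = d[key]
        return cls(**kw)


def _base_report(log: SensorLog) -> dict:
    rear_max, front_max, delta_max = ev.max_pressures(log.p_rear, log.p_front)
    return {
        "posture": log.metadata.posture,
        "subject_label": log.metadata.subject_label,
        "events": [],
        "transit_s": None,
        "oral_peak_cmH2O": None,
        "max_rear_cmH2O": rear_max,
        "max_front_cmH2O": front_max,
        "max_delta_cmH2O": delta_max,
        "path_length_cm": None,
        "net_displacement_cm": None,
        "distance_uncertainty_cm": None,
        "peak_velocity_cm_s": None,
        "cardiac_freq_hz": None,
        "maneuvers": [],
        "warnings": [],
    }


def _event_dict(e: ev.PressureEvent) -> dict:
    return {
        "type": e.type,
        "time_s": e.time_s,
        "amplitude_cmH2O": e.amplitude_cmH2O,
        "channel": e.channel,
    }


def analyze_log(log: SensorLog, config: Optional[AnalysisConfig] = None) -> dict:
    """Analyze one recording into the per-swallow report dict."""
    config = config or AnalysisConfig()
    report = _base_report(log)
    posture = log.metadata.posture

    if posture in ("seated", "supine"):
        _analyze_transit(log, config, report)
    elif posture == "stationary":
        _analyze_stationary(log, config, report)
    if config.maneuver_intervals:
        responses = ev.analyze_maneuver(log, config.maneuver_intervals)
        report["maneuvers"] = [
            {"label": r.label, "delta_cmH2O": r.delta_cmH2O} for r in responses
        ]
    return report


def _analyze_transit(log: SensorLog, config: AnalysisConfig, report: dict) -> None:
    track = estimate_orientation(log, config.filter_params)
    kin = compute_kinematics(
        log,
        track,
        smoothing=config.smoothing,
        zupt=config.zupt,
        uncertainty_K=config.uncertainty_K,
        uncertainty_seed=config.uncertainty_seed,
    )
    report["path_length_cm"] = kin.path_length_cm
    report["net_displacement_cm"] = kin.net_displacement_cm
    report["distance_uncertainty_cm"] = kin.distance_uncertainty_cm
    report["peak_velocity_cm_s"] = kin.peak_speed_cm_s
    report["warnings"].extend(kin.warnings)

    oral = ev.detect_oral_initiation(log.p_rear, log.times)
    if oral is None:
        report["warnings"].append("no oral initiation event detected")
        return
    report["events"].append(_event_dict(oral))
    report["oral_peak_cmH2O"] = oral.amplitude_cmH2O

    peaks = ev.detect_peristaltic_peaks(log.p_rear, log.times)
    report["events"].extend(_event_dict(p) for p in peaks)

    gastric = ev.detect_gastric_entry(log.p_rear, track, log.times, oral)
    if not gastric.found:
        report["warnings"].append("transit incomplete: no gastric entry detected")
        return
    transit = ev.compute_transit(oral, gastric.time_s, gastric.mode)
    report["transit_s"] = transit.transit_s
    report["gastric_entry_mode"] = gastric.mode
    report["events"].append(
        {
            "type": "les_passage",
            "time_s": gastric.time_s,
            "amplitude_cmH2O": float(
                log.p_rear[int(np.argmin(np.abs(log.times - gastric.time_s)))]
            ),
            "channel": "rear",
        }
    )

    seg = (log.times >= oral.time_s) & (log.times <= gastric.time_s)
    if np.count_nonzero(seg) > 4 * log.metadata.sample_rate_hz:
        report["cardiac_freq_hz"] = ev.dominant_modulation_frequency(
            log.accel[seg], log.times[seg], config.cardiac_band_hz
        )


def _analyze_stationary(log: SensorLog, config: AnalysisConfig, report: dict) -> None:
    res = ev.analyze_stationary_swallow(log)
    if not res.found:
        report["warnings"].append("no swallow detected")
        return
    report["baseline_rise_cmH2O"] = res.baseline_rise_cmH2O
    report["events"].append(_event_dict(res.rear_peak))
    report["stationary_rear_peak_cmH2O"] = res.rear_peak.amplitude_cmH2O
    if res.front_peak is not None:
        report["events"].append(_event_dict(res.front_peak))
    report["events"].extend(_event_dict(e) for e in res.after_contractions)
    if log.duration_s >= 4.0:
        report["cardiac_freq_hz"] = ev.dominant_modulation_frequency(
            log.accel, log.times, config.cardiac_band_hz
        )
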