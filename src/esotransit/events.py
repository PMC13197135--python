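"""Pressure and orientation event detection.

Detects the landmarks of a swallow as seen by the device: the short
negative oral-initiation pressure pulse, positive peristaltic contraction
peaks (rear channel leading), passage through the lower esophageal
sphincter / gastric entry (last rear peak followed by a sustained positive
gastric baseline and, when available, the terminal pitch bend at the angle
of His), maneuver-induced baseline steps, stationary mid-esophageal swallow
features, and the ~1 Hz cardiac modulation of the acceleration magnitude
during thoracic transit.

Transit time is defined as oral-initiation onset → gastric-entry peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import detrend, find_peaks, peak_prominences, periodogram, savgol_filter

from .orientation import OrientationTrack
from .sensor_io import SensorLog

__all__ = [
    "PressureEvent",
    "TransitResult",
    "ManeuverResponse",
    "GastricEntryResult",
    "StationarySwallowResult",
    "detect_oral_initiation",
    "detect_peristaltic_peaks",
    "detect_gastric_entry",
    "compute_transit",
    "max_pressures",
    "analyze_stationary_swallow",
    "analyze_maneuver",
    "dominant_modulation_frequency",
]

ORAL_THRESHOLD_CMH2O = -50.0
ORAL_MIN_DURATION_S = 0.06
PEAK_PROMINENCE_CMH2O = 20.0
PEAK_SEPARATION_S = 1.0
GASTRIC_BASELINE_RISE_CMH2O = 5.0
GASTRIC_PITCH_CHANGE_DEG = 30.0


@dataclass
class PressureEvent:
    type: str        # oral_initiation | peristaltic_peak | les_passage |
                     # after_contraction | maneuver_step
    time_s: float
    amplitude_cmH2O: float
    channel: str     # rear | front | delta

    def __post_init__(self):
        if self.type == "oral_initiation" and not self.amplitude_cmH2O < 0:
            raise ValueError("oral_initiation amplitude must be negative")
        if self.type == "peristaltic_peak" and not self.amplitude_cmH2O > 0:
            raise ValueError("peristaltic_peak amplitude must be positive")


@dataclass
class TransitResult:
    oral_initiation_s: float
    gastric_entry_s: float
    transit_s: float
    mode: str = "pressure+orientation"


@dataclass
class ManeuverResponse:
    label: str
    baseline_before_cmH2O: float
    baseline_during_cmH2O: float

    @property
    def delta_cmH2O(self) -> float:
        return self.baseline_during_cmH2O - self.baseline_before_cmH2O


@dataclass
class GastricEntryResult:
    time_s: Optional[float]
    mode: str  # "pressure+orientation" | "pressure-only" | "transit-incomplete"

    @property
    def found(self) -> bool:
        return self.time_s is not None


@dataclass
class StationarySwallowResult:
    found: bool
    baseline_rise_cmH2O: Optional[float] = None
    rear_peak: Optional[PressureEvent] = None
    front_peak: Optional[PressureEvent] = None
    after_contractions: List[PressureEvent] = field(default_factory=list)


def detect_oral_initiation(
    p_rear: np.ndarray,
    times: np.ndarray,
    threshold_cmH2O: float = ORAL_THRESHOLD_CMH2O,
    min_duration_s: float = ORAL_MIN_DURATION_S,
) -> Optional[PressureEvent]:
    """First sustained sub-threshold negative pressure run, or None.

    The event time is the onset (first sample) of the first run that stays
    below ``threshold_cmH2O`` for at least ``min_duration_s``; its amplitude
    is the minimum pressure within that run.
    """
    p = np.asarray(p_rear, dtype=float)
    below = p < threshold_cmH2O
    idx = np.nonzero(np.diff(np.concatenate([[0], below.astype(int), [0]])))[0]
    dt = float(np.median(np.diff(times)))
    for s, e in zip(idx[::2], idx[1::2]):
        if (e - s) * dt >= min_duration_s:
            seg = slice(s, e)
            return PressureEvent(
                type="oral_initiation",
                time_s=float(times[s]),
                amplitude_cmH2O=float(np.min(p[seg])),
                channel="rear",
            )
    return None


def detect_peristaltic_peaks(
    p: np.ndarray,
    times: np.ndarray,
    min_prominence_cmH2O: float = PEAK_PROMINENCE_CMH2O,
    min_separation_s: float = PEAK_SEPARATION_S,
    channel: str = "rear",
) -> List[PressureEvent]:
    """Prominent positive local maxima with a minimum temporal separation.

    Contract: strict local maxima are filtered by prominence, then a greedy
    pass in order of decreasing amplitude (ties broken by earliest time)
    enforces ``min_separation_s``.  Events are returned in time order.
    """
    p = np.asarray(p, dtype=float)
    cand, _ = find_peaks(p)
    if cand.size == 0:
        return []
    prom = peak_prominences(p, cand)[0]
    cand = cand[prom >= min_prominence_cmH2O]
    order = sorted(cand, key=lambda i: (-p[i], times[i]))
    kept: List[int] = []
    for i in order:
        if all(abs(times[i] - times[j]) >= min_separation_s for j in kept):
            kept.append(i)
    kept.sort()
    return [
        PressureEvent(
            type="peristaltic_peak",
            time_s=float(times[i]),
            amplitude_cmH2O=float(p[i]),
            channel=channel,
        )
        for i in kept
        if p[i] > 0
    ]


def detect_gastric_entry(
    p_rear: np.ndarray,
    track: Optional[OrientationTrack],
    times: np.ndarray,
    oral_event: PressureEvent,
    baseline_rise_cmH2O: float = GASTRIC_BASELINE_RISE_CMH2O,
    pitch_change_deg: float = GASTRIC_PITCH_CHANGE_DEG,
    min_prominence_cmH2O: float = PEAK_PROMINENCE_CMH2O,
    min_separation_s: float = PEAK_SEPARATION_S,
) -> GastricEntryResult:
    """Gastric entry: last rear peak with a sustained gastric baseline rise.

    A candidate peak at t qualifies when (a) the median rear pressure over
    the following ~10 s exceeds the pre-swallow baseline by at least
    ``baseline_rise_cmH2O`` (stomach shows a positive resting baseline) and
    (b) the device pitch changes by ≥ ``pitch_change_deg`` within ±5 s of t
    (terminal bend at the angle of His).  The latest peak meeting both wins;
    if none does, the latest meeting (a) alone is returned flagged
    "pressure-only"; otherwise the transit is incomplete.
    """
    if oral_event is None:
        raise ValueError("gastric entry detection requires a detected oral event")
    p = np.asarray(p_rear, dtype=float)
    pre_mask = times <= oral_event.time_s - 0.5
    if not np.any(pre_mask):
        pre_mask = times <= oral_event.time_s
    pre_baseline = float(np.median(p[pre_mask]))

    peaks = [
        ev
        for ev in detect_peristaltic_peaks(
            p, times, min_prominence_cmH2O, min_separation_s
        )
        if ev.time_s > oral_event.time_s
    ]
    pitch = track.euler_deg[:, 1] if track is not None else None

    def baseline_ok(t_pk: float) -> bool:
        m = (times >= t_pk + 0.5) & (times <= t_pk + 10.5)
        if not np.any(m):
            return False
        return float(np.median(p[m])) - pre_baseline >= baseline_rise_cmH2O

    def pitch_ok(t_pk: float) -> bool:
        if pitch is None:
            return False
        m = (times >= t_pk - 5.0) & (times <= t_pk + 5.0)
        return float(np.ptp(pitch[m])) >= pitch_change_deg if np.any(m) else False

    for ev in reversed(peaks):
        if baseline_ok(ev.time_s) and pitch_ok(ev.time_s):
            return GastricEntryResult(time_s=ev.time_s, mode="pressure+orientation")
    for ev in reversed(peaks):
        if baseline_ok(ev.time_s):
            return GastricEntryResult(time_s=ev.time_s, mode="pressure-only")
    return GastricEntryResult(time_s=None, mode="transit-incomplete")


def compute_transit(
    oral_event: PressureEvent, gastric_entry_s: float, mode: str = "pressure+orientation"
) -> TransitResult:
    """Oral-initiation onset → gastric entry, seconds."""
    if gastric_entry_s < oral_event.time_s:
        raise ValueError("gastric entry precedes oral initiation: inconsistent detection")
    return TransitResult(
        oral_initiation_s=oral_event.time_s,
        gastric_entry_s=float(gastric_entry_s),
        transit_s=float(gastric_entry_s) - oral_event.time_s,
        mode=mode,
    )


def max_pressures(p_rear: np.ndarray, p_front: np.ndarray) -> Tuple[float, float, float]:
    """(max rear, max front, max samplewise rear−front) in cmH₂O.

    The differential maximum is taken over the samplewise difference, which
    can exceed max(rear) − max(front) when the channels peak at different
    times (and even max(rear), when the front channel dips negative).
    """
    p_rear = np.asarray(p_rear, dtype=float)
    p_front = np.asarray(p_front, dtype=float)
    if p_rear.shape != p_front.shape:
        raise ValueError("pressure channels must be aligned")
    return (
        float(np.max(p_rear)),
        float(np.max(p_front)),
        float(np.max(p_rear - p_front)),
    )


def analyze_stationary_swallow(
    log: SensorLog,
    min_prominence_cmH2O: float = PEAK_PROMINENCE_CMH2O,
    min_separation_s: float = PEAK_SEPARATION_S,
) -> StationarySwallowResult:
    """Features of a stationary mid-esophageal swallow.

    Amplitudes are reported relative to the pre-swallow baseline (median of
    the first 5 s).  The baseline rise is the median of the 2 s window
    preceding the rear peak minus that baseline; after-contractions are
    negative deflections below the baseline within 5 s after the front peak.
    """
    t = log.times
    baseline = float(np.median(log.p_rear[t <= t[0] + 5.0]))
    rear_peaks = detect_peristaltic_peaks(
        log.p_rear - baseline, t, min_prominence_cmH2O, min_separation_s, channel="rear"
    )
    if not rear_peaks:
        return StationarySwallowResult(found=False)
    rear = max(rear_peaks, key=lambda ev: ev.amplitude_cmH2O)

    pre = (t >= rear.time_s - 2.0) & (t < rear.time_s)
    rise = float(np.median(log.p_rear[pre])) - baseline if np.any(pre) else None

    fbase = float(np.median(log.p_front[t <= t[0] + 5.0]))
    front_peaks = [
        ev
        for ev in detect_peristaltic_peaks(
            log.p_front - fbase, t, 0.5 * min_prominence_cmH2O, min_separation_s, "front"
        )
        if ev.time_s >= rear.time_s
    ]
    front = max(front_peaks, key=lambda ev: ev.amplitude_cmH2O) if front_peaks else None

    after: List[PressureEvent] = []
    if front is not None:
        m = (t > front.time_s) & (t <= front.time_s + 5.0)
        # smooth lightly so the trough amplitude is not the noisiest sample
        fs = 1.0 / float(np.median(np.diff(t)))
        w = max(5, int(round(0.2 * fs)) | 1)
        p_s = savgol_filter(log.p_rear, w, 3) if len(t) > w else log.p_rear
        seg = baseline - p_s[m]  # positive where trace dips below baseline
        idx, _ = find_peaks(seg, height=5.0, prominence=5.0)
        tm = t[m]
        after = [
            PressureEvent(
                type="after_contraction",
                time_s=float(tm[i]),
                amplitude_cmH2O=float(-seg[i]),
                channel="rear",
            )
            for i in idx
        ]
    return StationarySwallowResult(
        found=True,
        baseline_rise_cmH2O=rise,
        rear_peak=rear,
        front_peak=front,
        after_contractions=after,
    )


def analyze_maneuver(
    log: SensorLog, intervals: Sequence[Sequence]
) -> List[ManeuverResponse]:
    """Baseline shift per labeled maneuver interval.

    ``intervals`` holds (label, start_s, end_s[, ...]) entries; the shift is
    the median rear pressure during the interval minus the median over the
    10 s preceding it.
    """
    t = log.times
    out = []
    for entry in intervals:
        label, start, end = entry[0], float(entry[1]), float(entry[2])
        if start < t[0] or end > t[-1] or start >= end:
            raise ValueError(f"maneuver interval {label!r} outside the log")
        before = (t >= start - 10.0) & (t < start)
        during = (t >= start) & (t <= end)
        if not np.any(before):
            raise ValueError(f"no pre-interval baseline for maneuver {label!r}")
        out.append(
            ManeuverResponse(
                label=label,
                baseline_before_cmH2O=float(np.median(log.p_rear[before])),
                baseline_during_cmH2O=float(np.median(log.p_rear[during])),
            )
        )
    return out


def dominant_modulation_frequency(
    accel: np.ndarray,
    times: np.ndarray,
    band_hz: Tuple[float, float] = (0.5, 3.0),
) -> Optional[float]:
    """Frequency of the strongest acceleration-magnitude modulation in band.

    A slow baseline (Savitzky–Golay, 1.5 s window, quadratic) is subtracted
    from the magnitude to reject motion transients — the swallow's own
    propulsive acceleration pulse is seconds wide and would otherwise leak
    across the band — and the residual is run through a Hann-windowed
    periodogram; the largest in-band peak is refined by quadratic
    interpolation.  Returns None when no peak rises above 3× the median
    in-band spectral floor (or the segment is essentially constant).
    """
    accel = np.asarray(accel, dtype=float)
    mag = np.linalg.norm(accel, axis=1) if accel.ndim == 2 else accel
    if times[-1] - times[0] < 4.0:
        raise ValueError("segment must span at least 4 s")
    fs_est = 1.0 / float(np.median(np.diff(times)))
    w = int(round(1.5 * fs_est))
    w += 1 - w % 2
    if w >= 5 and w < len(mag):
        x = mag - savgol_filter(mag, w, 2)
    else:
        x = detrend(mag, type="linear")
    if float(np.std(x)) < 1e-9:
        return None
    fs = 1.0 / float(np.median(np.diff(times)))
    freqs, power = periodogram(x, fs=fs, window="hann")
    m = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(m):
        return None
    band_idx = np.nonzero(m)[0]
    floor = float(np.median(power[band_idx]))
    k = band_idx[int(np.argmax(power[band_idx]))]
    if power[k] < 3.0 * floor or power[k] <= 0:
        return None
    if 0 < k < len(freqs) - 1:
        y0, y1, y2 = power[k - 1], power[k], power[k + 1]
        denom = y0 - 2.0 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = freqs[1] - freqs[0]
    return float(freqs[k] + delta * df)
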