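"""Session-level aggregation: medians with interquartile ranges.

Per-swallow reports are pooled into a session summary (median, Q1, Q3 per
metric) and postures are compared by ratios of medians.  Quartiles use
linear interpolation of order statistics (the common "type 7" convention).
No hypothesis testing is performed; summaries are descriptive only, and a
single level of aggregation is supported (summaries of summaries are not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = ["SwallowSummary", "median_iqr", "summarize_session", "compare_postures", "METRIC_UNITS"]

METRIC_UNITS = {
    "transit_s": "s",
    "oral_peak_cmH2O": "cmH2O",
    "max_rear_cmH2O": "cmH2O",
    "max_front_cmH2O": "cmH2O",
    "max_delta_cmH2O": "cmH2O",
    "path_length_cm": "cm",
    "peak_velocity_cm_s": "cm/s",
    "cardiac_freq_hz": "Hz",
}


@dataclass
class SwallowSummary:
    posture: str
    n_swallows: int
    metrics: Dict[str, dict] = field(default_factory=dict)
    # metrics[name] = {"median","q1","q3","units","n"}

    def to_dict(self) -> dict:
        return {"posture": self.posture, "n_swallows": self.n_swallows, "metrics": self.metrics}


def median_iqr(values: Sequence[float]) -> Tuple[float, float, float]:
    """(median, Q1, Q3) by linear interpolation of order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("median_iqr requires finite values")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0], method="linear")
    return float(med), float(q1), float(q3)


def summarize_session(
    per_swallow_reports: Sequence[dict], posture: Optional[str] = None
) -> SwallowSummary:
    """Median/IQR per metric over a session's per-swallow reports.

    Reports must share a posture (an explicit ``posture`` argument overrides
    the check only if consistent).  A metric missing or null in some reports
    is summarized over the reports that do carry it, with that count
    annotated; metrics absent everywhere are omitted.
    """
    reports = list(per_swallow_reports)
    if not reports:
        raise ValueError("summarize_session requires at least one report")
    postures = {r.get("posture") for r in reports if r.get("posture") is not None}
    if posture is not None:
        postures.add(posture)
    if len(postures) > 1:
        raise ValueError(f"mixed postures in session: {sorted(postures)}")
    posture = postures.pop() if postures else "unknown"

    summary = SwallowSummary(posture=posture, n_swallows=len(reports))
    for name, units in METRIC_UNITS.items():
        vals = [r[name] for r in reports if r.get(name) is not None]
        if not vals:
            continue
        med, q1, q3 = median_iqr(vals)
        summary.metrics[name] = {
            "median": med,
            "q1": q1,
            "q3": q3,
            "units": units,
            "n": len(vals),
        }
    return summary


def compare_postures(seated: SwallowSummary, supine: SwallowSummary) -> Dict[str, Optional[float]]:
    """supine/seated ratio of medians per shared metric.

    A zero seated median yields None (an explicit undefined marker) rather
    than an infinity; metrics missing from either summary are skipped.
    """
    ratios: Dict[str, Optional[float]] = {}
    for name in seated.metrics:
        if name not in supine.metrics:
            continue
        denom = seated.metrics[name]["median"]
        num = supine.metrics[name]["median"]
        ratios[name] = None if denom == 0 else num / denom
    return ratios
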