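"""Sensor-log container and on-disk format.

A recording is a CSV file with the fixed header

    time_s,p_rear_cmH2O,p_front_cmH2O,ax_m_s2,ay_m_s2,az_m_s2,
    gx_rad_s,gy_rad_s,gz_rad_s,mx_uT,my_uT,mz_uT

plus a sibling ``<name>.meta.json`` holding :class:`LogMetadata`.  Floats are
written at 9 significant digits (RFC 4180 CSV, '.' decimal, UTF-8); the
format is inspectable with any spreadsheet tool.  Time is absolute seconds
from record start (0-based) and sample indexing is 0-based throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["LogMetadata", "SensorLog", "ParseError", "read_log", "write_log", "CSV_COLUMNS"]

CSV_COLUMNS = [
    "time_s",
    "p_rear_cmH2O",
    "p_front_cmH2O",
    "ax_m_s2",
    "ay_m_s2",
    "az_m_s2",
    "gx_rad_s",
    "gy_rad_s",
    "gz_rad_s",
    "mx_uT",
    "my_uT",
    "mz_uT",
]

VALID_POSTURES = ("seated", "supine", "stationary", "gastric_maneuver")
VALID_DEVICE_LENGTHS_CM = (4.2, 5.0)


class ParseError(ValueError):
    """Structured log-parsing failure; ``row`` is the offending 0-based row."""

    def __init__(self, message: str, row: Optional[int] = None):
        super().__init__(message if row is None else f"{message} (row {row})")
        self.row = row


@dataclass
class LogMetadata:
    sample_rate_hz: float = 50.0
    posture: str = "seated"
    device_length_cm: Optional[float] = 4.2
    subject_label: str = ""
    scenario_hash: Optional[str] = None

    def validate(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be > 0")
        if self.posture not in VALID_POSTURES:
            raise ValueError(f"posture must be one of {VALID_POSTURES}, got {self.posture!r}")
        if self.device_length_cm is not None and not any(
            abs(self.device_length_cm - v) < 1e-9 for v in VALID_DEVICE_LENGTHS_CM
        ):
            raise ValueError(
                f"device_length_cm must be one of {VALID_DEVICE_LENGTHS_CM} when set"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LogMetadata":
        return cls(**{k: d[k] for k in d if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass
class SensorLog:
    """Uniformly sampled multichannel record.

    Channels: two axial pressures (cmH₂O), 3-axis accelerometer (m/s²,
    specific force in the sensor frame), 3-axis gyroscope (rad/s), 3-axis
    magnetometer (µT).
    """

    metadata: LogMetadata
    times: np.ndarray  # (n,) s
    p_rear: np.ndarray  # (n,) cmH2O
    p_front: np.ndarray  # (n,) cmH2O
    accel: np.ndarray  # (n, 3) m/s^2
    gyro: np.ndarray  # (n, 3) rad/s
    mag: np.ndarray  # (n, 3) uT
    warnings: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def validate(self) -> None:
        n = self.n_samples
        if n < 2:
            raise ParseError("log must contain at least 2 samples")
        for name in ("p_rear", "p_front"):
            if len(getattr(self, name)) != n:
                raise ParseError(f"channel {name} length mismatch")
        for name in ("accel", "gyro", "mag"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ParseError(f"channel {name} must have shape (n, 3)")
        dt = np.diff(self.times)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ParseError("time_s not strictly increasing", row=int(bad[0]) + 1)
        nominal = 1.0 / self.metadata.sample_rate_hz
        if abs(float(np.median(dt)) - nominal) >= 1e-9:
            raise ParseError(
                f"median sample interval {np.median(dt):.6g} s disagrees with "
                f"metadata rate {self.metadata.sample_rate_hz} Hz"
            )
        self.metadata.validate()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "p_rear_cmH2O": self.p_rear,
                "p_front_cmH2O": self.p_front,
                "ax_m_s2": self.accel[:, 0],
                "ay_m_s2": self.accel[:, 1],
                "az_m_s2": self.accel[:, 2],
                "gx_rad_s": self.gyro[:, 0],
                "gy_rad_s": self.gyro[:, 1],
                "gz_rad_s": self.gyro[:, 2],
                "mx_uT": self.mag[:, 0],
                "my_uT": self.mag[:, 1],
                "mz_uT": self.mag[:, 2],
            }
        )


def _meta_path(path: Path) -> Path:
    path = Path(path)
    return path.with_suffix(".meta.json") if path.suffix == ".csv" else Path(str(path) + ".meta.json")


def write_log(log: SensorLog, path) -> tuple[Path, Path]:
    """Write CSV + JSON sidecar; returns (csv_path, meta_path)."""
    log.validate()
    path = Path(path)
    df = log.to_dataframe()
    df.to_csv(path, index=False, float_format="%.9g")
    mpath = _meta_path(path)
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(log.metadata.to_dict(), fh, indent=1)
        fh.write("\n")
    return path, mpath


def read_log(path) -> SensorLog:
    """Read and validate a CSV log and its ``.meta.json`` sidecar."""
    path = Path(path)
    mpath = _meta_path(path)
    if not path.exists():
        raise ParseError(f"log file not found: {path}")
    if not mpath.exists():
        raise ParseError(f"metadata sidecar not found: {mpath}")
    with open(mpath, encoding="utf-8") as fh:
        metadata = LogMetadata.from_dict(json.load(fh))
    df = pd.read_csv(path)
    if list(df.columns) != CSV_COLUMNS:
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        raise ParseError(
            f"bad CSV header: missing columns {missing}" if missing else
            f"bad CSV header: expected {CSV_COLUMNS}, got {list(df.columns)}"
        )
    if df.isna().any().any():
        row = int(df.index[df.isna().any(axis=1)][0])
        raise ParseError("NaN value in log", row=row)
    log = SensorLog(
        metadata=metadata,
        times=df["time_s"].to_numpy(float),
        p_rear=df["p_rear_cmH2O"].to_numpy(float),
        p_front=df["p_front_cmH2O"].to_numpy(float),
        accel=df[["ax_m_s2", "ay_m_s2", "az_m_s2"]].to_numpy(float),
        gyro=df[["gx_rad_s", "gy_rad_s", "gz_rad_s"]].to_numpy(float),
        mag=df[["mx_uT", "my_uT", "mz_uT"]].to_numpy(float),
    )
    log.validate()
    return log
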