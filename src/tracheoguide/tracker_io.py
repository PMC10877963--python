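"""The dual-sensor tracker-log dialect: read, write, validate, replay.

The electromagnetic tracker streams position (X, Y, Z, mm) and
orientation (roll, pitch, yaw, degrees) for up to four sensors at a
nominal 255 Hz.  The vendor's wire format is proprietary, so this
package defines its own plain-text dialect:

* CSV with header ``timestamp,sensor_id,x,y,z,roll,pitch,yaw,quality``
* JSONL with one object per line using the same keys

Timestamps are seconds from log start (float).  Numeric fields are
written with 6 decimal places, UTF-8, '.' decimal separator; ``quality``
is an optional [0, 1] figure of merit and is left blank (CSV) or omitted
(JSONL) when absent.  Parsing is strict by default (malformed lines and
non-monotone timestamps are errors naming the line); lenient mode
reports, repairs by skipping/sorting, and continues.
"""

from __future__ import annotations

import csv
import json
import math
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

from .errors import OrderingError, SchemaError
from .geometry import Frame, TRANSMITTER_FRAME

__all__ = [
    "SENSOR_NEEDLE",
    "SENSOR_TARGET",
    "NOMINAL_RATE_HZ",
    "TrackerRecord",
    "TrackerLog",
    "read_log",
    "write_log",
    "replay",
    "validate_log",
]

SENSOR_NEEDLE = "NEEDLE"
SENSOR_TARGET = "TARGET"
_VALID_SENSORS = (SENSOR_NEEDLE, SENSOR_TARGET)

#: Nominal sample rate of the tracking hardware.
NOMINAL_RATE_HZ = 255.0

_COLUMNS = ["timestamp", "sensor_id", "x", "y", "z", "roll", "pitch", "yaw", "quality"]
_FLOAT_FIELDS = ("timestamp", "x", "y", "z", "roll", "pitch", "yaw")


@dataclass(frozen=True)
class TrackerRecord:
    """One sensor sample: time, identity, position (mm), orientation (deg)."""

    timestamp: float
    sensor_id: str
    x: float
    y: float
    z: float
    roll: float
    pitch: float
    yaw: float
    quality: Optional[float] = None

    def __post_init__(self):
        if self.sensor_id not in _VALID_SENSORS:
            raise ValueError(
                f"sensor_id must be one of {_VALID_SENSORS}, got {self.sensor_id!r}"
            )
        for name in _FLOAT_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite {name}: {v!r}")
        if self.quality is not None and not (0.0 <= self.quality <= 1.0):
            raise ValueError(f"quality must lie in [0, 1], got {self.quality}")

    def to_json_obj(self) -> dict:
        obj = {
            "timestamp": round(self.timestamp, 6),
            "sensor_id": self.sensor_id,
            "x": round(self.x, 6),
            "y": round(self.y, 6),
            "z": round(self.z, 6),
            "roll": round(self.roll, 6),
            "pitch": round(self.pitch, 6),
            "yaw": round(self.yaw, 6),
        }
        if self.quality is not None:
            obj["quality"] = round(self.quality, 6)
        return obj


@dataclass
class TrackerLog:
    """A time-ordered dual-sensor record stream with frame metadata."""

    records: list[TrackerRecord] = field(default_factory=list)
    nominal_rate_hz: float = NOMINAL_RATE_HZ
    frame: Frame = TRANSMITTER_FRAME
    provenance: str = ""

    def __post_init__(self):
        issues = validate_log(self)
        if issues:
            raise OrderingError("; ".join(issues))

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrackerLog):
            return NotImplemented
        return (
            self.records == other.records
            and self.nominal_rate_hz == other.nominal_rate_hz
            and self.frame == other.frame
        )


def validate_log(log: TrackerLog) -> list[str]:
    """Return a list of invariant violations (empty when valid):
    per-sensor non-decreasing timestamps, at most 4 distinct sensor ids."""
    issues: list[str] = []
    last: dict[str, float] = {}
    for i, rec in enumerate(log.records):
        prev = last.get(rec.sensor_id)
        if prev is not None and rec.timestamp < prev:
            issues.append(
                f"record {i}: sensor {rec.sensor_id} timestamp {rec.timestamp} "
                f"precedes {prev}"
            )
        last[rec.sensor_id] = rec.timestamp
    if len(last) > 4:
        issues.append(f"{len(last)} distinct sensor ids (tracker supports 4)")
    return issues


def _infer_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        return dialect
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson", ".json"):
        return "jsonl"
    return "csv"


def _parse_record(raw: dict, lineno: int) -> TrackerRecord:
    try:
        quality = raw.get("quality")
        if quality in (None, ""):
            quality = None
        else:
            quality = float(quality)
        return TrackerRecord(
            timestamp=float(raw["timestamp"]),
            sensor_id=str(raw["sensor_id"]),
            x=float(raw["x"]),
            y=float(raw["y"]),
            z=float(raw["z"]),
            roll=float(raw["roll"]),
            pitch=float(raw["pitch"]),
            yaw=float(raw["yaw"]),
            quality=quality,
        )
    except KeyError as exc:
        raise SchemaError(f"line {lineno}: missing column {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"line {lineno}: {exc}") from exc


def read_log(
    path,
    dialect: Optional[str] = None,
    strict: bool = True,
    nominal_rate_hz: float = NOMINAL_RATE_HZ,
    frame: Frame = TRANSMITTER_FRAME,
) -> TrackerLog:
    """Read a tracker log from CSV or JSONL (inferred from the extension
    unless given).

    In strict mode (default) any malformed line or per-sensor timestamp
    regression raises :class:`SchemaError` / :class:`OrderingError` naming
    the line; in lenient mode malformed lines are skipped and out-of-order
    records sorted, with warnings.
    """
    import warnings

    path = Path(path)
    fmt = _infer_dialect(path, dialect)
    records: list[TrackerRecord] = []
    problems: list[str] = []

    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file (no header)")
            missing = [c for c in _COLUMNS[:-1] if c not in reader.fieldnames]
            if missing:
                raise SchemaError(f"{path}: header missing columns {missing}")
            for lineno, raw in enumerate(reader, start=2):
                try:
                    records.append(_parse_record(raw, lineno))
                except SchemaError as exc:
                    if strict:
                        raise SchemaError(f"{path}: {exc}") from exc
                    problems.append(str(exc))
    elif fmt == "jsonl":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    err = SchemaError(f"{path}: line {lineno}: invalid JSON ({exc})")
                    if strict:
                        raise err from exc
                    problems.append(str(err))
                    continue
                try:
                    records.append(_parse_record(obj, lineno))
                except SchemaError as exc:
                    if strict:
                        raise SchemaError(f"{path}: {exc}") from exc
                    problems.append(str(exc))
    else:
        raise ValueError(f"unknown dialect {fmt!r} (expected 'csv' or 'jsonl')")

    # Ordering check: strict -> error; lenient -> stable sort by timestamp.
    tentative = TrackerLog.__new__(TrackerLog)
    tentative.records = records
    tentative.nominal_rate_hz = nominal_rate_hz
    tentative.frame = frame
    tentative.provenance = str(path)
    issues = validate_log(tentative)
    if issues:
        if strict:
            raise OrderingError(f"{path}: " + "; ".join(issues))
        problems.extend(issues)
        records = sorted(records, key=lambda r: r.timestamp)

    if problems:
        warnings.warn(
            f"read_log({path}): {len(problems)} issue(s) repaired in lenient "
            f"mode: {problems[:3]}...",
            stacklevel=2,
        )
    return TrackerLog(
        records=records,
        nominal_rate_hz=nominal_rate_hz,
        frame=frame,
        provenance=str(path),
    )


def write_log(log: TrackerLog, path, dialect: Optional[str] = None) -> Path:
    """Write a tracker log to CSV or JSONL with 6-decimal numeric
    formatting, such that ``read_log(write_log(x)) == x`` for logs whose
    values carry at most 6 decimals."""
    path = Path(path)
    fmt = _infer_dialect(path, dialect)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_COLUMNS)
            for rec in log.records:
                writer.writerow(
                    [f"{getattr(rec, c):.6f}" for c in _FLOAT_FIELDS[:1]]
                    + [rec.sensor_id]
                    + [f"{getattr(rec, c):.6f}" for c in _FLOAT_FIELDS[1:]]
                    + ["" if rec.quality is None else f"{rec.quality:.6f}"]
                )
    elif fmt == "jsonl":
        with open(path, "w") as fh:
            for rec in log.records:
                fh.write(json.dumps(rec.to_json_obj()) + "\n")
    else:
        raise ValueError(f"unknown dialect {fmt!r} (expected 'csv' or 'jsonl')")
    return path


def replay(
    log: TrackerLog, speed_factor: Union[float, str] = "unlimited"
) -> Iterator[TrackerRecord]:
    """Yield the log's records in timestamp order, optionally paced.

    ``speed_factor`` is a multiple of real time (1.0 reproduces the
    recorded cadence by sleeping between records) or the string
    ``"unlimited"`` to emit as fast as possible.  Never reorders or drops
    validated records.
    """
    paced = speed_factor != "unlimited"
    if paced and not (isinstance(speed_factor, (int, float)) and speed_factor > 0):
        raise ValueError(f"speed_factor must be > 0 or 'unlimited', got {speed_factor}")
    ordered = sorted(log.records, key=lambda r: r.timestamp)
    prev_t: Optional[float] = None
    for rec in ordered:
        if paced and prev_t is not None and rec.timestamp > prev_t:
            _time.sleep((rec.timestamp - prev_t) / float(speed_factor))
        prev_t = rec.timestamp
        yield rec
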