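"""Session record serialization: 1 Hz angle records plus all feedback events.

The document follows an OpenMHealth-inspired envelope — a ``header``
carrying the schema id/version, subject and stage identity, the config
snapshot and the calibration reference, and a ``body`` with the data
series. Timestamps inside the body are seconds since stage start; each
event also carries a derived ISO-8601 wall-clock timestamp computed from
the header's ``start_time`` (informational; regenerated on write and not
part of round-trip identity).

Validation is structural and names the offending field in its diagnostic;
the same contract is described by the JSON Schema document shipped as
``posturekit/data/session-log.schema.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Any

from .engine import EventKind, FeedbackEvent, PostureConfig, PostureState
from .imu import CalibrationReference

SCHEMA_ID = "posturekit:session-log"
SCHEMA_VERSION = "1.0"

STAGE_LABELS = ("feedback_on", "feedback_off")

DEFAULT_START_TIME = "2000-01-01T00:00:00+00:00"


class SchemaError(ValueError):
    """A document violates the session-log contract; names the field."""

    def __init__(self, field_path: str, message: str):
        self.field = field_path
        super().__init__(f"{field_path}: {message}")


@dataclass(frozen=True)
class AngleRecord:
    """One per-second deviation record with the posture state at that time."""

    t: float
    frontal_deg: float
    lateral_deg: float
    posture: PostureState


@dataclass
class SessionHeader:
    subject_id: str
    stage: str
    config: PostureConfig
    calibration: CalibrationReference | None = None
    start_time: str = DEFAULT_START_TIME
    schema_id: str = SCHEMA_ID
    schema_version: str = SCHEMA_VERSION


@dataclass
class SessionLog:
    """Complete record of one monitored stage."""

    header: SessionHeader
    angle_records: list[AngleRecord] = field(default_factory=list)
    events: list[FeedbackEvent] = field(default_factory=list)

    def validate(self) -> None:
        """Raise :class:`SchemaError` on the first invariant violation."""
        if self.header.stage not in STAGE_LABELS:
            raise SchemaError("header.stage", f"must be one of {STAGE_LABELS}, "
                                              f"got {self.header.stage!r}")
        if self.header.schema_id != SCHEMA_ID:
            raise SchemaError("header.schema_id", f"expected {SCHEMA_ID!r}")
        if self.header.schema_version != SCHEMA_VERSION:
            raise SchemaError("header.schema_version",
                              f"unknown schema version {self.header.schema_version!r}; "
                              f"this reader supports {SCHEMA_VERSION!r}")
        for name, seq in (("angle_records", self.angle_records), ("events", self.events)):
            prev = None
            for i, item in enumerate(seq):
                if prev is not None and item.t < prev:
                    raise SchemaError(f"body.{name}[{i}].t",
                                      f"timestamps must be non-decreasing "
                                      f"({item.t} after {prev})")
                prev = item.t


def _event_to_dict(ev: FeedbackEvent, start: datetime) -> dict[str, Any]:
    return {
        "t": ev.t,
        "timestamp": (start + timedelta(seconds=ev.t)).isoformat(),
        "kind": ev.kind.value,
        "payload": ev.payload,
    }


def to_document(log: SessionLog) -> dict[str, Any]:
    """Serialize to a plain dict (stable key order); validates first."""
    log.validate()
    h = log.header
    start = datetime.fromisoformat(h.start_time)
    if start.tzinfo is None:
        start = start.replace(tzinfo=timezone.utc)
    calib = None
    if h.calibration is not None:
        calib = {"r0": list(h.calibration.r0), "created_at": h.calibration.created_at}
    return {
        "header": {
            "schema_id": h.schema_id,
            "schema_version": h.schema_version,
            "subject_id": h.subject_id,
            "stage": h.stage,
            "start_time": h.start_time,
            "config": h.config.to_dict(),
            "calibration": calib,
        },
        "body": {
            "angle_records": [
                {"t": r.t, "frontal_deg": r.frontal_deg, "lateral_deg": r.lateral_deg,
                 "posture": r.posture.value}
                for r in log.angle_records
            ],
            "events": [_event_to_dict(ev, start) for ev in log.events],
        },
    }


def write_log(log: SessionLog, destination: str | Path | None = None) -> str:
    """Serialize a session log to JSON; optionally write it to a file."""
    text = json.dumps(to_document(log), indent=2, ensure_ascii=False)
    if destination is not None:
        Path(destination).write_text(text + "\n", "utf-8")
    return text


def _require(d: dict[str, Any], key: str, path: str, types: type | tuple = dict) -> Any:
    if not isinstance(d, dict):
        raise SchemaError(path, f"expected an object, got {type(d).__name__}")
    if key not in d:
        raise SchemaError(f"{path}.{key}" if path else key, "missing required field")
    value = d[key]
    if types is not None and not isinstance(value, types):
        want = types.__name__ if isinstance(types, type) else \
            "/".join(t.__name__ for t in types)
        raise SchemaError(f"{path}.{key}" if path else key,
                          f"expected {want}, got {type(value).__name__}")
    return value


def from_document(doc: dict[str, Any]) -> SessionLog:
    """Parse and validate a session-log document dict."""
    header = _require(doc, "header", "")
    body = _require(doc, "body", "")

    version = _require(header, "schema_version", "header", str)
    if version != SCHEMA_VERSION:
        raise SchemaError("header.schema_version",
                          f"unknown schema version {version!r}; "
                          f"this reader supports {SCHEMA_VERSION!r}")
    schema_id = _require(header, "schema_id", "header", str)
    subject_id = _require(header, "subject_id", "header", str)
    stage = _require(header, "stage", "header", str)
    start_time = _require(header, "start_time", "header", str)
    cfg_dict = _require(header, "config", "header", dict)
    try:
        config = PostureConfig.from_dict(cfg_dict)
    except (TypeError, ValueError) as exc:
        raise SchemaError("header.config", str(exc)) from exc
    calib_raw = header.get("calibration")
    calibration = None
    if calib_raw is not None:
        r0 = _require(calib_raw, "r0", "header.calibration", list)
        if len(r0) != 3:
            raise SchemaError("header.calibration.r0", "must have 3 components")
        try:
            calibration = CalibrationReference(
                r0=tuple(float(c) for c in r0),
                created_at=float(calib_raw.get("created_at", 0.0)),
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError("header.calibration", str(exc)) from exc

    records = []
    raw_records = _require(body, "angle_records", "body", list)
    for i, r in enumerate(raw_records):
        path = f"body.angle_records[{i}]"
        posture_raw = _require(r, "posture", path, str)
        try:
            posture = PostureState(posture_raw)
        except ValueError:
            raise SchemaError(f"{path}.posture",
                              f"unknown posture state {posture_raw!r}") from None
        records.append(AngleRecord(
            t=float(_require(r, "t", path, (int, float))),
            frontal_deg=float(_require(r, "frontal_deg", path, (int, float))),
            lateral_deg=float(_require(r, "lateral_deg", path, (int, float))),
            posture=posture,
        ))

    events = []
    raw_events = _require(body, "events", "body", list)
    for i, e in enumerate(raw_events):
        path = f"body.events[{i}]"
        kind_raw = _require(e, "kind", path, str)
        try:
            kind = EventKind(kind_raw)
        except ValueError:
            raise SchemaError(f"{path}.kind",
                              f"unknown event kind {kind_raw!r}") from None
        payload = e.get("payload")
        if payload is not None and not isinstance(payload, dict):
            raise SchemaError(f"{path}.payload", "must be an object or null")
        events.append(FeedbackEvent(
            t=float(_require(e, "t", path, (int, float))), kind=kind, payload=payload,
        ))

    log = SessionLog(
        header=SessionHeader(
            subject_id=subject_id, stage=stage, config=config,
            calibration=calibration, start_time=start_time,
            schema_id=schema_id, schema_version=version,
        ),
        angle_records=records,
        events=events,
    )
    log.validate()
    return log


def read_log(source: str | Path | dict[str, Any]) -> SessionLog:
    """Parse a session log from a dict, a JSON string, or a file path."""
    if isinstance(source, dict):
        return from_document(source)
    text: str
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text("utf-8")
    else:
        text = str(source)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemaError("(document)", f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("(document)", "top level must be an object")
    return from_document(doc)
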