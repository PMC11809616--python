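"""Headless monitoring loop: stream in, session log out.

Mirrors the clinical workflow: the wearer holds their best-at-the-time
posture during an initial calibration window, monitoring then starts
(screen green) and the engine runs over the rest of the stream. Angle
records are decimated to 1 Hz regardless of the input sample rate.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import FeedbackEngine, PostureConfig
from .imu import (
    DEFAULT_ALPHA,
    AccelSample,
    CalibrationError,
    CalibrationReference,
    deviation_angles_arrays,
    gravity_filter_arrays,
    stream_arrays,
    validate_stream,
)
from .sessionlog import DEFAULT_START_TIME, AngleRecord, SessionHeader, SessionLog

DEFAULT_CALIBRATION_WINDOW_S = 1.0


def read_stream(path: str | Path) -> list[AccelSample]:
    """Read an accelerometer stream file.

    CSV with header ``t,ax,ay,az`` (seconds, m/s^2), or JSON-lines with
    the same keys (chosen by sniffing the first non-blank character).
    """
    path = Path(path)
    text = path.read_text("utf-8")
    first = text.lstrip()[:1]
    if first == "{":
        rows = [json.loads(line) for line in text.splitlines() if line.strip()]
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    missing = {"t", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise ValueError(f"stream file {path} is missing columns: {sorted(missing)}")
    return [
        AccelSample(t=float(r.t), ax=float(r.ax), ay=float(r.ay), az=float(r.az))
        for r in df.itertuples()
    ]


def write_stream(samples: Sequence[AccelSample], path: str | Path) -> None:
    """Write samples as a ``t,ax,ay,az`` CSV."""
    df = pd.DataFrame(
        {"t": [s.t for s in samples], "ax": [s.ax for s in samples],
         "ay": [s.ay for s in samples], "az": [s.az for s in samples]}
    )
    df.to_csv(path, index=False)


def calibrate_from_stream(
    samples: Sequence[AccelSample],
    window_s: float = DEFAULT_CALIBRATION_WINDOW_S,
    alpha: float = DEFAULT_ALPHA,
) -> CalibrationReference:
    """Calibration reference from the first ``window_s`` seconds of a stream."""
    samples = validate_stream(samples)
    if not samples:
        raise CalibrationError("cannot calibrate: empty stream")
    t, a, valid = stream_arrays(samples)
    gx, gy, gz, have = gravity_filter_arrays(a, valid, alpha)
    mask = (t <= t[0] + window_s) & have
    if not mask.any():
        raise CalibrationError("cannot calibrate: no valid gravity estimate in window")
    mean = np.array([gx[mask].mean(), gy[mask].mean(), gz[mask].mean()])
    norm = float(np.linalg.norm(mean))
    if norm == 0.0:
        raise CalibrationError("cannot calibrate: mean gravity vector is zero")
    return CalibrationReference(
        r0=tuple(float(c) for c in mean / norm), created_at=float(t[mask][-1])
    )


def run_session(
    samples: Sequence[AccelSample],
    cfg: PostureConfig,
    *,
    calibration_window_s: float = DEFAULT_CALIBRATION_WINDOW_S,
    subject_id: str = "S00",
    stage: str = "feedback_on",
    start_time: str = DEFAULT_START_TIME,
    alpha: float = DEFAULT_ALPHA,
) -> SessionLog:
    """Calibrate from the first window, run the engine, return the full log.

    The engine always runs — a silent-recording stage simply has all
    feedback channels disabled in ``cfg`` — so the log registers every
    movement either way.
    """
    samples = validate_stream(samples)
    if not samples:
        raise ValueError("empty stream: nothing to monitor")
    t, a, valid = stream_arrays(samples)
    gx, gy, gz, have = gravity_filter_arrays(a, valid, alpha)

    mask = (t <= t[0] + calibration_window_s) & have
    if not mask.any():
        raise CalibrationError("cannot calibrate: no valid gravity estimate in window")
    mean = np.array([gx[mask].mean(), gy[mask].mean(), gz[mask].mean()])
    norm = float(np.linalg.norm(mean))
    if norm == 0.0:
        raise CalibrationError("cannot calibrate: mean gravity vector is zero")
    ref = CalibrationReference(
        r0=tuple(float(c) for c in mean / norm), created_at=float(t[mask][-1])
    )

    engine = FeedbackEngine(cfg)
    engine.calibrated(ref.created_at)

    frontal, lateral = deviation_angles_arrays(gx, gy, gz, ref)
    start_idx = int(np.searchsorted(t, t[0] + calibration_window_s, side="right"))
    if start_idx >= len(samples):
        start_idx = len(samples) - 1
    engine.control("play", float(t[start_idx]))

    records: list[AngleRecord] = []
    next_rec = float(t[start_idx])
    step = engine.step_angles
    for i in range(start_idx, len(samples)):
        if not have[i]:
            continue
        ti = float(t[i])
        step(float(frontal[i]), float(lateral[i]), ti)
        if ti >= next_rec:
            records.append(AngleRecord(
                t=ti, frontal_deg=float(frontal[i]), lateral_deg=float(lateral[i]),
                posture=engine.state.posture,
            ))
            next_rec = math.floor(ti) + 1.0
    engine.control("pause", float(t[-1]))

    log = SessionLog(
        header=SessionHeader(
            subject_id=subject_id, stage=stage, config=cfg,
            calibration=ref, start_time=start_time,
        ),
        angle_records=records,
        events=engine.events,
    )
    log.validate()
    return log
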