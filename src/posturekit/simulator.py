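"""Synthetic trunk-movement generator with rotation-matrix ground truth.

Stands in for both a wearer and an optical motion-capture reference:
trunk orientation trajectories are built from movement primitives
(flexion, extension, left/right side bending, left/right axial rotation,
hold), each ramping smoothly from upright to its peak amplitude and back
("began upright, executed the movement, returned"). The device-frame
accelerometer signal is the rotated gravity vector plus Gaussian noise.

Angle conventions match :mod:`posturekit.imu`: ground-truth pitch
(forward +) and roll (right +) are the per-plane projected tilt angles of
the noiseless gravity direction, so a pure 15 deg flexion has ground
truth pitch exactly 15 deg. Yaw is rotation about the gravity axis and is
invisible to the accelerometer by construction.

Composition order for mixed-plane orientations: the tilt rotation (the
minimal rotation carrying the upright gravity direction to the tilted
one) is applied first, then yaw about the world vertical axis
(yaw ∘ tilt(pitch, roll)).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import PostureConfig
from .imu import G0, AccelSample
from .monitor import run_session
from .sessionlog import SessionLog

_UP = np.array([0.0, 1.0, 0.0])


class MovementKind(str, Enum):
    FLEXION = "FLEXION"            # forward lean, +pitch
    EXTENSION = "EXTENSION"        # backward lean, -pitch
    BEND_LEFT = "BEND_LEFT"        # -roll
    BEND_RIGHT = "BEND_RIGHT"      # +roll
    ROTATE_LEFT = "ROTATE_LEFT"    # +yaw (unobservable)
    ROTATE_RIGHT = "ROTATE_RIGHT"  # -yaw (unobservable)
    HOLD = "HOLD"                  # stay upright


_AXIS_SIGN = {
    MovementKind.FLEXION: ("pitch", +1.0),
    MovementKind.EXTENSION: ("pitch", -1.0),
    MovementKind.BEND_RIGHT: ("roll", +1.0),
    MovementKind.BEND_LEFT: ("roll", -1.0),
    MovementKind.ROTATE_LEFT: ("yaw", +1.0),
    MovementKind.ROTATE_RIGHT: ("yaw", -1.0),
}


@dataclass(frozen=True)
class MovementPrimitive:
    """One movement: cosine ramp up over ``rise_s``, hold, ramp back down."""

    kind: MovementKind
    amplitude_deg: float = 0.0
    rise_s: float = 1.5
    hold_s: float = 0.0
    return_s: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude_deg < 0:
            raise ValueError("amplitude must be non-negative")
        if min(self.rise_s, self.hold_s, self.return_s) < 0:
            raise ValueError("durations must be non-negative")

    @property
    def duration_s(self) -> float:
        if self.kind is MovementKind.HOLD:
            return self.hold_s
        return self.rise_s + self.hold_s + self.return_s

    def angle_at(self, tau: float) -> float:
        """Deflection angle at time ``tau`` since primitive onset, degrees."""
        if self.kind is MovementKind.HOLD:
            return 0.0
        a = self.amplitude_deg
        if tau < 0 or tau > self.duration_s:
            return 0.0
        if tau < self.rise_s:
            return a * 0.5 * (1.0 - math.cos(math.pi * tau / self.rise_s))
        if tau <= self.rise_s + self.hold_s:
            return a
        back = self.duration_s - tau
        if self.return_s == 0:
            return 0.0
        return a * 0.5 * (1.0 - math.cos(math.pi * back / self.return_s))


@dataclass(frozen=True)
class GroundTruth:
    """Per-sample true orientation angles (degrees)."""

    t: np.ndarray
    pitch_deg: np.ndarray
    roll_deg: np.ndarray
    yaw_deg: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "pitch_deg": self.pitch_deg,
                             "roll_deg": self.roll_deg, "yaw_deg": self.yaw_deg})


def tilt_gravity_direction(pitch_deg: np.ndarray, roll_deg: np.ndarray) -> np.ndarray:
    """Unit device-frame gravity direction for given projected tilt angles.

    Defined so that atan2(g_z, g_y) = pitch and atan2(g_x, g_y) = roll
    exactly (|angles| < 90 deg).
    """
    p = np.radians(np.asarray(pitch_deg, dtype=float))
    r = np.radians(np.asarray(roll_deg, dtype=float))
    g = np.stack([np.tan(r), np.ones_like(p), np.tan(p)], axis=-1)
    return g / np.linalg.norm(g, axis=-1, keepdims=True)


def _rotation_to_up(ghat: np.ndarray) -> np.ndarray:
    """Minimal rotations R with R @ ghat = (0,1,0), vectorised Rodrigues."""
    ghat = np.atleast_2d(ghat)
    n = ghat.shape[0]
    u = np.cross(ghat, _UP)          # rotation axis * sin(angle)
    c = ghat @ _UP                   # cos(angle)
    s2 = np.einsum("ij,ij->i", u, u)
    K = np.zeros((n, 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -u[:, 2], u[:, 1]
    K[:, 1, 0], K[:, 1, 2] = u[:, 2], -u[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -u[:, 1], u[:, 0]
    R = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    ok = s2 > 1e-30
    factor = np.zeros(n)
    factor[ok] = (1.0 - c[ok]) / s2[ok]
    R += K + factor[:, None, None] * (K @ K)
    return R


def rotations_from_angles(
    pitch_deg: np.ndarray, roll_deg: np.ndarray, yaw_deg: np.ndarray
) -> np.ndarray:
    """Device-to-world rotation matrices for angle arrays (yaw ∘ tilt)."""
    ghat = tilt_gravity_direction(pitch_deg, roll_deg)
    tilt = _rotation_to_up(ghat)
    y = np.radians(np.asarray(yaw_deg, dtype=float))
    cy, sy = np.cos(y), np.sin(y)
    n = tilt.shape[0]
    ry = np.zeros((n, 3, 3))
    ry[:, 0, 0], ry[:, 0, 2] = cy, sy
    ry[:, 1, 1] = 1.0
    ry[:, 2, 0], ry[:, 2, 2] = -sy, cy
    return ry @ tilt


def trajectory(
    primitives: Sequence[MovementPrimitive], rate: float
) -> tuple[np.ndarray, GroundTruth]:
    """Sample a primitive sequence at ``rate`` Hz.

    Returns (rotations (n,3,3), ground truth). Primitives execute
    sequentially; at most one is active at any instant.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    total = sum(p.duration_s for p in primitives)
    n = int(math.floor(total * rate)) + 1
    t = np.arange(n) / rate
    pitch = np.zeros(n)
    roll = np.zeros(n)
    yaw = np.zeros(n)
    onset = 0.0
    for p in primitives:
        end = onset + p.duration_s
        if p.kind is not MovementKind.HOLD and p.amplitude_deg > 0:
            i0 = int(math.ceil(onset * rate - 1e-9))
            i1 = min(n - 1, int(math.floor(end * rate + 1e-9)))
            axis, sign = _AXIS_SIGN[p.kind]
            target = {"pitch": pitch, "roll": roll, "yaw": yaw}[axis]
            for i in range(i0, i1 + 1):
                target[i] = sign * p.angle_at(t[i] - onset)
        onset = end
    rotations = rotations_from_angles(pitch, roll, yaw)
    return rotations, GroundTruth(t=t, pitch_deg=pitch, roll_deg=roll, yaw_deg=yaw)


def synth_accel(
    rotations: np.ndarray,
    noise_sd: float,
    rate: float,
    seed: int | np.random.Generator = 0,
) -> list[AccelSample]:
    """Accelerometer stream for a rotation sequence: R^T (0, g0, 0) + noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.einsum("nji,j->ni", rotations, _UP * G0)  # R^T applied to upright gravity
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    t = np.arange(a.shape[0]) / rate
    return [
        AccelSample(t=float(t[i]), ax=float(a[i, 0]), ay=float(a[i, 1]),
                    az=float(a[i, 2]))
        for i in range(a.shape[0])
    ]


def kinematic_assessment_primitives(
    amplitude_deg: float = 20.0, hold_s: float = 3.0, settle_s: float = 3.0
) -> list[MovementPrimitive]:
    """The six standard trunk movements, upright settles in between.

    Flexion, extension, left and right side bending, left and right axial
    rotation — each starting and ending upright.
    """
    kinds = [MovementKind.FLEXION, MovementKind.EXTENSION, MovementKind.BEND_LEFT,
             MovementKind.BEND_RIGHT, MovementKind.ROTATE_LEFT, MovementKind.ROTATE_RIGHT]
    prims: list[MovementPrimitive] = [MovementPrimitive(MovementKind.HOLD, hold_s=settle_s)]
    for kind in kinds:
        prims.append(MovementPrimitive(kind, amplitude_deg=amplitude_deg,
                                       rise_s=1.5, hold_s=hold_s, return_s=1.5))
        prims.append(MovementPrimitive(MovementKind.HOLD, hold_s=settle_s))
    return prims


@dataclass(frozen=True)
class LatencyModel:
    """Log-normal correction latency: time spent out of posture."""

    median_s: float
    sigma: float

    def draw(self, rng: np.random.Generator) -> float:
        return float(np.exp(rng.normal(math.log(self.median_s), self.sigma)))


@dataclass(frozen=True)
class SessionScenario:
    """Study-stage conditions for the simulator.

    Defaults emulate a ~10 minute rehabilitation stage sampled at a
    typical smartphone accelerometer rate, with episodic trunk deviations
    arriving as a Poisson process. With feedback the wearer corrects
    shortly after the first voice directive; without feedback corrections
    come much later, on the wearer's own initiative.
    """

    duration_s: float = 600.0
    sample_rate_hz: float = 50.0
    noise_sd_ms2: float = 0.15
    deviation_rate_per_min: float = 2.0
    amplitude_range_deg: tuple[float, float] = (15.0, 30.0)
    latency_on: LatencyModel = field(default_factory=lambda: LatencyModel(4.0, 0.4))
    latency_off: LatencyModel = field(default_factory=lambda: LatencyModel(15.0, 0.5))
    rise_s: float = 1.5
    return_s: float = 1.5
    calibration_lead_s: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if min(self.noise_sd_ms2, self.deviation_rate_per_min) < 0:
            raise ValueError("rates and noise SDs must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "SessionScenario":
        d = json.loads(Path(path).read_text("utf-8"))
        for key in ("latency_on", "latency_off"):
            if key in d and isinstance(d[key], dict):
                d[key] = LatencyModel(**d[key])
        if "amplitude_range_deg" in d:
            d["amplitude_range_deg"] = tuple(d["amplitude_range_deg"])
        return cls(**d)


_DEVIATION_KINDS = (MovementKind.FLEXION, MovementKind.EXTENSION,
                    MovementKind.BEND_LEFT, MovementKind.BEND_RIGHT)


def scenario_primitives(
    scenario: SessionScenario, feedback: bool, cfg: PostureConfig,
    rng: np.random.Generator,
) -> list[MovementPrimitive]:
    """Draw the movement script for one stage.

    Deviation onsets form a Poisson process; each deviation peaks in a
    random plane/direction at a random amplitude and is held until the
    wearer corrects. With feedback on, the hold lasts the engine's
    tolerance window plus a (short) latency after the first directive;
    with feedback off it lasts a (long) self-initiated latency.
    """
    prims = [MovementPrimitive(MovementKind.HOLD, hold_s=scenario.calibration_lead_s)]
    cursor = scenario.calibration_lead_s
    if scenario.deviation_rate_per_min <= 0:
        prims.append(MovementPrimitive(
            MovementKind.HOLD, hold_s=max(0.0, scenario.duration_s - cursor)))
        return prims
    mean_gap = 60.0 / scenario.deviation_rate_per_min
    latency = scenario.latency_on if feedback else scenario.latency_off
    while True:
        gap = float(rng.exponential(mean_gap))
        kind = _DEVIATION_KINDS[int(rng.integers(len(_DEVIATION_KINDS)))]
        amp = float(rng.uniform(*scenario.amplitude_range_deg))
        hold = latency.draw(rng)
        if feedback:
            hold += cfg.tolerance_s
        dur = scenario.rise_s + hold + scenario.return_s
        if cursor + gap + dur > scenario.duration_s:
            prims.append(MovementPrimitive(
                MovementKind.HOLD, hold_s=max(0.0, scenario.duration_s - cursor)))
            return prims
        prims.append(MovementPrimitive(MovementKind.HOLD, hold_s=gap))
        prims.append(MovementPrimitive(kind, amplitude_deg=amp, rise_s=scenario.rise_s,
                                       hold_s=hold, return_s=scenario.return_s))
        cursor += gap + dur


def simulate_stage(
    scenario: SessionScenario,
    cfg: PostureConfig,
    feedback: bool,
    subject_id: str = "S00",
) -> SessionLog:
    """Generate a stream for one stage and run the full engine over it.

    A feedback-off stage runs the engine with every feedback channel
    disabled (silent recording); the log still registers all movements.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    prims = scenario_primitives(scenario, feedback, cfg, rng)
    rotations, _ = trajectory(prims, scenario.sample_rate_hz)
    samples = synth_accel(rotations, scenario.noise_sd_ms2, scenario.sample_rate_hz, rng)
    if feedback:
        stage_cfg, stage = cfg, "feedback_on"
    else:
        stage_cfg = replace(cfg, vibration_enabled=False, audio_enabled=False,
                            visual_enabled=False)
        stage = "feedback_off"
    return run_session(
        samples, stage_cfg,
        calibration_window_s=min(1.0, scenario.calibration_lead_s),
        subject_id=subject_id, stage=stage,
    )


def simulate_study(
    n_subjects: int,
    scenario: SessionScenario,
    cfg: PostureConfig,
    seed: int = 0,
) -> list[tuple[SessionLog, SessionLog]]:
    """Simulate a within-subjects study: each subject runs both stages.

    Returns (feedback_on, feedback_off) log pairs. Per-subject randomness
    is derived from ``seed``; the two stages of one subject use distinct
    streams (consecutive stages, not a replay).
    """
    base = np.random.default_rng(seed)
    pairs: list[tuple[SessionLog, SessionLog]] = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        seed_off, seed_on = (int(s) for s in base.integers(0, 2**31 - 1, size=2))
        log_off = simulate_stage(replace(scenario, rng_seed=seed_off), cfg,
                                 feedback=False, subject_id=sid)
        log_on = simulate_stage(replace(scenario, rng_seed=seed_on), cfg,
                                feedback=True, subject_id=sid)
        pairs.append((log_on, log_off))
    return pairs
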