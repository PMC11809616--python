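"""Accelerometer samples, gravity estimation, and trunk deviation angles.

Device-frame convention (shared with the simulator): the phone sits in
portrait orientation on the sternum, screen facing outward; +y points
toward the head, +x toward the wearer's right, +z out of the screen.
At rest, upright, the accelerometer reads specific force ~= (0, +g0, 0).

Deviation angles are per-plane projected tilt angles of the gravity
direction relative to a calibrated reference:

* ``frontal_deg``  -- forward/backward lean, the angle of the gravity
  vector's projection onto the device y-z plane (positive = lean forward,
  i.e. gravity tips toward +z);
* ``lateral_deg``  -- left/right lean, the angle of the projection onto
  the x-y plane (positive = lean toward the wearer's right).

The two planes are decoupled for small and moderate tilts, matching
independent per-plane thresholds. Axial (yaw) rotation about the gravity
axis leaves the gravity vector unchanged and is therefore unobservable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

#: Standard gravity, m/s^2.
G0 = 9.80665

#: Acceptance band for a plausible quasi-static sample, as multiples of g0.
MAGNITUDE_MIN = 0.5 * G0
MAGNITUDE_MAX = 3.0 * G0

#: Default exponential-moving-average smoothing factor (per sample at 50 Hz).
DEFAULT_ALPHA = 0.2


class NoGravityEstimateError(ValueError):
    """Raised when deviation angles are requested from an invalid estimate."""


class CalibrationError(ValueError):
    """Raised when a calibration window holds no usable gravity estimate."""


@dataclass(frozen=True)
class AccelSample:
    """One time-stamped 3-axis accelerometer reading, device frame, m/s^2."""

    t: float
    ax: float
    ay: float
    az: float
    valid: bool = True

    @property
    def magnitude(self) -> float:
        return math.sqrt(self.ax**2 + self.ay**2 + self.az**2)


@dataclass(frozen=True)
class GravityEstimate:
    """Low-pass-filtered specific force (gravity direction estimate)."""

    t: float
    gx: float
    gy: float
    gz: float
    valid: bool = True

    @property
    def magnitude(self) -> float:
        return math.sqrt(self.gx**2 + self.gy**2 + self.gz**2)


@dataclass(frozen=True)
class CalibrationReference:
    """Unit gravity direction of the best-at-the-time posture.

    Persists until a new calibration is performed.
    """

    r0: tuple[float, float, float]
    created_at: float = 0.0

    def __post_init__(self) -> None:
        norm = math.sqrt(sum(c * c for c in self.r0))
        if not math.isclose(norm, 1.0, abs_tol=1e-9):
            raise ValueError(f"calibration reference must be a unit vector, |r0|={norm!r}")


@dataclass(frozen=True)
class DeviationAngles:
    """Signed deviation from the calibrated posture, degrees.

    ``frontal_deg`` > 0 means leaning forward; ``lateral_deg`` > 0 means
    leaning toward the wearer's right. Both are wrapped to (-180, 180].
    """

    frontal_deg: float
    lateral_deg: float


#: Upright reference: gravity along the device +y axis.
UPRIGHT_REFERENCE = CalibrationReference(r0=(0.0, 1.0, 0.0))


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = math.fmod(angle, 360.0)
    if wrapped > 180.0:
        wrapped -= 360.0
    elif wrapped <= -180.0:
        wrapped += 360.0
    return wrapped


def validate_sample(s: AccelSample) -> AccelSample:
    """Flag free-fall / impact samples; never drops them.

    A sample is invalid when its magnitude is below 0.5*g0 (free fall)
    or above 3*g0 (impact or vigorous shaking).
    """
    ok = MAGNITUDE_MIN <= s.magnitude <= MAGNITUDE_MAX
    if s.valid == ok:
        return s
    return replace(s, valid=ok)


def validate_stream(samples: Iterable[AccelSample]) -> list[AccelSample]:
    """Flag every sample and check that timestamps strictly increase."""
    out: list[AccelSample] = []
    prev_t = -math.inf
    for s in samples:
        if s.t <= prev_t:
            raise ValueError(
                f"sample timestamps must be strictly increasing (t={s.t} after t={prev_t})"
            )
        prev_t = s.t
        out.append(validate_sample(s))
    return out


def _ema_with_gaps(
    x: np.ndarray, valid: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """EMA over the valid entries, holding the last estimate across gaps.

    Entries before the first valid sample carry no estimate (mask False).
    """
    n = x.shape[0]
    out = np.zeros_like(x)
    have = np.zeros(n, dtype=bool)
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return out, have
    xv = x[idx]
    # y[k] = alpha*x[k] + (1-alpha)*y[k-1], seeded with the first valid sample
    zi = np.array([(1.0 - alpha) * xv[0]])
    yv, _ = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], xv, zi=zi)
    # forward-fill each valid estimate over the following invalid stretch
    fill_pos = np.zeros(n, dtype=int)
    fill_pos[idx] = np.arange(idx.size)
    fill_pos = np.maximum.accumulate(np.where(valid, fill_pos, -1))
    have = fill_pos >= 0
    out[have] = yv[fill_pos[have]]
    return out, have


def gravity_filter(
    samples: Sequence[AccelSample], alpha: float = DEFAULT_ALPHA
) -> list[GravityEstimate]:
    """Exponential moving average of the specific force, per axis.

    Seeded with the first valid sample. Invalid samples do not update the
    average; they propagate the last estimate (still flagged valid) if one
    exists, and yield an invalid estimate before any valid sample arrived.
    An empty stream yields an empty output.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if len(samples) == 0:
        return []
    t, a, valid = stream_arrays(samples)
    gx, gy, gz, have = gravity_filter_arrays(a, valid, alpha)
    return [
        GravityEstimate(t=float(t[i]), gx=float(gx[i]), gy=float(gy[i]), gz=float(gz[i]),
                        valid=bool(have[i]))
        for i in range(len(samples))
    ]


def gravity_filter_arrays(
    a: np.ndarray, valid: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Array form of :func:`gravity_filter`: ``a`` is (n, 3); returns gx, gy, gz, valid."""
    gx, have = _ema_with_gaps(a[:, 0], valid, alpha)
    gy, _ = _ema_with_gaps(a[:, 1], valid, alpha)
    gz, _ = _ema_with_gaps(a[:, 2], valid, alpha)
    return gx, gy, gz, have


def stream_arrays(
    samples: Sequence[AccelSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unpack a sample sequence into (t, a[n,3], valid) arrays."""
    t = np.array([s.t for s in samples], dtype=float)
    a = np.array([(s.ax, s.ay, s.az) for s in samples], dtype=float)
    valid = np.array([s.valid for s in samples], dtype=bool)
    return t, a, valid


def deviation_angles(g: GravityEstimate, ref: CalibrationReference) -> DeviationAngles:
    """Signed frontal/lateral deviation of the gravity estimate from the reference.

    With ghat = g/|g|:

    * frontal = atan2(ghat_z, ghat_y) - atan2(r0_z, r0_y)
    * lateral = atan2(ghat_x, ghat_y) - atan2(r0_x, r0_y)

    each wrapped to (-180, 180]. Raises when the estimate is invalid.
    """
    if not g.valid:
        raise NoGravityEstimateError("no gravity estimate")
    frontal = math.degrees(math.atan2(g.gz, g.gy) - math.atan2(ref.r0[2], ref.r0[1]))
    lateral = math.degrees(math.atan2(g.gx, g.gy) - math.atan2(ref.r0[0], ref.r0[1]))
    return DeviationAngles(wrap_angle_deg(frontal), wrap_angle_deg(lateral))


def deviation_angles_arrays(
    gx: np.ndarray, gy: np.ndarray, gz: np.ndarray, ref: CalibrationReference
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`deviation_angles` over axis arrays (degrees)."""
    frontal = np.degrees(np.arctan2(gz, gy) - math.atan2(ref.r0[2], ref.r0[1]))
    lateral = np.degrees(np.arctan2(gx, gy) - math.atan2(ref.r0[0], ref.r0[1]))
    wrap = lambda x: x - 360.0 * np.ceil((x - 180.0) / 360.0)  # noqa: E731
    return wrap(frontal), wrap(lateral)


def calibrate(
    window: Sequence[GravityEstimate], created_at: float | None = None
) -> CalibrationReference:
    """Register the current posture: r0 = normalised mean of valid estimates.

    The window is typically the last second of gravity estimates while the
    patient holds their best-at-the-time posture. Raises
    :class:`CalibrationError` when the window holds no valid estimate.
    """
    vecs = [(g.gx, g.gy, g.gz) for g in window if g.valid]
    if not vecs:
        raise CalibrationError("cannot calibrate: no valid gravity estimate in window")
    mean = np.mean(np.asarray(vecs, dtype=float), axis=0)
    norm = float(np.linalg.norm(mean))
    if norm == 0.0:
        raise CalibrationError("cannot calibrate: mean gravity vector is zero")
    r0 = tuple(float(c) for c in mean / norm)
    if created_at is None:
        created_at = window[-1].t
    return CalibrationReference(r0=r0, created_at=created_at)
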