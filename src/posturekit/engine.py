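"""Multisensory posture-feedback state machine.

Converts the deviation-angle stream into the feedback behaviour of the
monitoring app: the screen turns green when monitoring starts and red the
moment either plane's deviation exceeds its threshold (with an optional
vibration pulse); if the wearer stays out of posture beyond the configured
tolerance, a directional voice directive is issued (and repeated); on
return to posture the screen turns green again and a randomly varied
congratulation is spoken; every ``praise_interval_s`` seconds of
continuously maintained posture earns a praise message.

Hardware channels (screen, vibration motor, speaker) are represented as
emitted :class:`FeedbackEvent` records, so the engine runs headless and is
fully testable. All time comes from the sample stream, never the wall
clock, so runs are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Any

import numpy as np

from .imu import DeviationAngles
from .messages import CONGRATULATION_KEYS, LANGUAGES, resolve


class PostureState(str, Enum):
    IN_POSTURE = "IN_POSTURE"
    OUT_OF_POSTURE = "OUT_OF_POSTURE"


class EventKind(str, Enum):
    COLOR_GREEN = "COLOR_GREEN"
    COLOR_RED = "COLOR_RED"
    VIBRATION = "VIBRATION"
    AUDIO_DIRECTIVE = "AUDIO_DIRECTIVE"
    AUDIO_PRAISE = "AUDIO_PRAISE"
    AUDIO_CONGRATULATION = "AUDIO_CONGRATULATION"
    CALIBRATED = "CALIBRATED"
    SETTINGS_CHANGED = "SETTINGS_CHANGED"
    MONITORING_STARTED = "MONITORING_STARTED"
    MONITORING_PAUSED = "MONITORING_PAUSED"


@dataclass(frozen=True)
class FeedbackEvent:
    """A typed, timestamped engine output."""

    t: float
    kind: EventKind
    payload: dict[str, Any] | None = None


class EnginePausedError(RuntimeError):
    """step() was called while monitoring is paused."""


class NoDirectiveError(ValueError):
    """directive_for() was called while in posture."""


@dataclass
class PostureConfig:
    """Therapist-facing engine configuration.

    Thresholds are the per-plane deviation angles (degrees) beyond which
    the wearer counts as out of posture; ``tolerance_s`` is how long a
    temporary deviation is allowed before voice guidance starts.
    ``visual_enabled`` exists for silent-recording stages in which the
    engine registers all movements but emits no feedback at all.
    """

    frontal_threshold_deg: float = 5.0
    lateral_threshold_deg: float = 5.0
    tolerance_s: float = 3.0
    vibration_enabled: bool = True
    audio_enabled: bool = True
    visual_enabled: bool = True
    language: str = "en"
    hysteresis_deg: float = 0.0
    directive_repeat_s: float | None = None  # None -> tolerance_s
    praise_interval_s: float = 300.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frontal_threshold_deg <= 0 or self.lateral_threshold_deg <= 0:
            raise ValueError("thresholds must be positive")
        if self.tolerance_s < 0:
            raise ValueError("tolerance_s must be non-negative")
        if self.praise_interval_s <= 0:
            raise ValueError("praise_interval_s must be positive")
        if self.hysteresis_deg < 0 or self.hysteresis_deg >= min(
            self.frontal_threshold_deg, self.lateral_threshold_deg
        ):
            raise ValueError("hysteresis_deg must be in [0, min(thresholds))")
        if self.directive_repeat_s is not None and self.directive_repeat_s <= 0:
            raise ValueError("directive_repeat_s must be positive")
        if self.language not in LANGUAGES:
            raise ValueError(f"language must be one of {LANGUAGES}, got {self.language!r}")

    @property
    def effective_directive_repeat_s(self) -> float:
        return self.tolerance_s if self.directive_repeat_s is None else self.directive_repeat_s

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PostureConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PostureConfig":
        """Read a JSON or ``key=value`` config file; absent fields keep defaults."""
        text = Path(path).read_text("utf-8")
        stripped = text.lstrip()
        if stripped.startswith("{"):
            return cls.from_dict(json.loads(text))
        d: dict[str, Any] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            d[key.strip()] = _coerce(value.strip())
        return cls.from_dict(d)


def _coerce(value: str) -> Any:
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    if low in ("none", "null", ""):
        return None
    try:
        return int(value)
    except ValueError:
        pass
    try:
        return float(value)
    except ValueError:
        return value


def classify(
    d: DeviationAngles, cfg: PostureConfig, current: PostureState = PostureState.IN_POSTURE
) -> PostureState:
    """Threshold classifier with optional hysteresis on re-entry.

    Out of posture when either |frontal| or |lateral| exceeds its
    threshold; once out, re-entry requires both planes back inside the
    threshold minus ``hysteresis_deg`` (default 0, i.e. plain thresholds).
    """
    af, al = abs(d.frontal_deg), abs(d.lateral_deg)
    if current is PostureState.IN_POSTURE:
        if af > cfg.frontal_threshold_deg or al > cfg.lateral_threshold_deg:
            return PostureState.OUT_OF_POSTURE
        return PostureState.IN_POSTURE
    h = cfg.hysteresis_deg
    if af <= cfg.frontal_threshold_deg - h and al <= cfg.lateral_threshold_deg - h:
        return PostureState.IN_POSTURE
    return PostureState.OUT_OF_POSTURE


def directive_for(d: DeviationAngles, cfg: PostureConfig) -> str:
    """Message key of the corrective directive for an out-of-posture deviation.

    The dominant plane is the one with the larger |deviation|/threshold
    ratio (tie goes to frontal); the directive points opposite the lean.
    """
    if classify(d, cfg, PostureState.IN_POSTURE) is PostureState.IN_POSTURE:
        raise NoDirectiveError("no directive needed: wearer is in posture")
    ratio_f = abs(d.frontal_deg) / cfg.frontal_threshold_deg
    ratio_l = abs(d.lateral_deg) / cfg.lateral_threshold_deg
    if ratio_f >= ratio_l:
        return "LEAN_BACKWARD" if d.frontal_deg > 0 else "LEAN_FORWARD"
    return "LEAN_LEFT" if d.lateral_deg > 0 else "LEAN_RIGHT"


@dataclass
class EngineState:
    """Mutable run state of the feedback engine."""

    monitoring: bool = False
    posture: PostureState = PostureState.IN_POSTURE
    entered_at: float = 0.0
    last_praise_at: float | None = None
    next_directive_at: float | None = None
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))


class FeedbackEngine:
    """Drives the feedback state machine over a deviation-angle stream.

    Identical input stream + config + seed yields an identical event list.
    """

    def __init__(self, cfg: PostureConfig):
        self.cfg = cfg
        self.state = EngineState(rng=np.random.default_rng(cfg.rng_seed))
        self.events: list[FeedbackEvent] = []

    # -- helpers -----------------------------------------------------------

    def _emit(self, t: float, kind: EventKind, payload: dict[str, Any] | None = None
              ) -> FeedbackEvent:
        ev = FeedbackEvent(t=t, kind=kind, payload=payload)
        self.events.append(ev)
        return ev

    def _audio_payload(self, key: str) -> dict[str, Any]:
        return {
            "message_key": key,
            "language": self.cfg.language,
            "text": resolve(key, self.cfg.language),
        }

    # -- operations --------------------------------------------------------

    def control(
        self, command: str, t: float, payload: dict[str, Any] | None = None
    ) -> list[FeedbackEvent]:
        """Handle play/pause/stop/update_settings; returns the events emitted."""
        start = len(self.events)
        if command == "play":
            self.state.monitoring = True
            self.state.posture = PostureState.IN_POSTURE
            self.state.entered_at = t
            self.state.last_praise_at = None
            self.state.next_directive_at = None
            self._emit(t, EventKind.MONITORING_STARTED)
            if self.cfg.visual_enabled:
                self._emit(t, EventKind.COLOR_GREEN)
        elif command in ("pause", "stop"):
            self.state.monitoring = False
            self._emit(t, EventKind.MONITORING_PAUSED)
        elif command == "update_settings":
            if not payload:
                raise ValueError("update_settings requires a payload of new values")
            old = self.cfg.to_dict()
            new = dict(old)
            new.update(payload)
            self.cfg = PostureConfig.from_dict(new)
            changed = {k: {"old": old[k], "new": new[k]} for k in payload}
            self._emit(t, EventKind.SETTINGS_CHANGED, {"changed": changed})
        else:
            raise ValueError(f"unknown engine command: {command!r}")
        return self.events[start:]

    def calibrated(self, t: float) -> list[FeedbackEvent]:
        """Record a calibration event (with its audio confirmation payload)."""
        start = len(self.events)
        payload: dict[str, Any] = {}
        if self.cfg.audio_enabled:
            payload = self._audio_payload("CALIBRATION_DONE")
        self._emit(t, EventKind.CALIBRATED, payload or None)
        return self.events[start:]

    def step(self, d: DeviationAngles, t: float) -> list[FeedbackEvent]:
        """Advance the state machine to time ``t`` with deviation ``d``."""
        return self.step_angles(d.frontal_deg, d.lateral_deg, t)

    def step_angles(self, frontal_deg: float, lateral_deg: float, t: float
                    ) -> list[FeedbackEvent]:
        """Scalar fast path of :func:`step` (same semantics, no wrapper object)."""
        st, cfg = self.state, self.cfg
        if not st.monitoring:
            raise EnginePausedError("engine paused: press play before stepping")
        start = len(self.events)

        af, al = abs(frontal_deg), abs(lateral_deg)
        if st.posture is PostureState.IN_POSTURE:
            out = af > cfg.frontal_threshold_deg or al > cfg.lateral_threshold_deg
        else:
            h = cfg.hysteresis_deg
            out = not (af <= cfg.frontal_threshold_deg - h
                       and al <= cfg.lateral_threshold_deg - h)

        if out and st.posture is PostureState.IN_POSTURE:
            st.posture = PostureState.OUT_OF_POSTURE
            st.entered_at = t
            st.next_directive_at = t + cfg.tolerance_s if cfg.audio_enabled else None
            if cfg.visual_enabled:
                self._emit(t, EventKind.COLOR_RED)
            if cfg.vibration_enabled:
                self._emit(t, EventKind.VIBRATION)
        elif not out and st.posture is PostureState.OUT_OF_POSTURE:
            st.posture = PostureState.IN_POSTURE
            st.entered_at = t
            st.last_praise_at = None
            st.next_directive_at = None
            if cfg.visual_enabled:
                self._emit(t, EventKind.COLOR_GREEN)
            if cfg.audio_enabled:
                key = CONGRATULATION_KEYS[int(st.rng.integers(len(CONGRATULATION_KEYS)))]
                self._emit(t, EventKind.AUDIO_CONGRATULATION, self._audio_payload(key))

        if st.posture is PostureState.OUT_OF_POSTURE:
            if st.next_directive_at is not None and t >= st.next_directive_at:
                # dominant-plane rule; computed inline so that a deviation sitting
                # inside the hysteresis band (still OUT) gets a directive too
                ratio_f = af / cfg.frontal_threshold_deg
                ratio_l = al / cfg.lateral_threshold_deg
                if ratio_f >= ratio_l:
                    key = "LEAN_BACKWARD" if frontal_deg > 0 else "LEAN_FORWARD"
                else:
                    key = "LEAN_LEFT" if lateral_deg > 0 else "LEAN_RIGHT"
                self._emit(t, EventKind.AUDIO_DIRECTIVE, self._audio_payload(key))
                st.next_directive_at = t + cfg.effective_directive_repeat_s
        else:
            since = st.entered_at if st.last_praise_at is None else max(
                st.entered_at, st.last_praise_at)
            if cfg.audio_enabled and t - since >= cfg.praise_interval_s:
                self._emit(t, EventKind.AUDIO_PRAISE, self._audio_payload("PRAISE_MAINTAINED"))
                st.last_praise_at = t

        return self.events[start:]


def step(
    state_engine: FeedbackEngine, d: DeviationAngles, t: float
) -> list[FeedbackEvent]:
    """Functional alias: advance ``state_engine`` one step."""
    return state_engine.step(d, t)


def replace_config(cfg: PostureConfig, **changes: Any) -> PostureConfig:
    """A modified copy of a config (validated)."""
    return replace(cfg, **changes)
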