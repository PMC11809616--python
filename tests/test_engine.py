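"""Feedback state machine: classification, directives, event timing."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posturekit.engine import (
    EnginePausedError,
    EventKind,
    FeedbackEngine,
    NoDirectiveError,
    PostureConfig,
    PostureState,
    classify,
    directive_for,
)
from posturekit.imu import DeviationAngles

IN, OUT = PostureState.IN_POSTURE, PostureState.OUT_OF_POSTURE


def dev(f, l=0.0):
    return DeviationAngles(f, l)


def kinds(events):
    return [e.kind for e in events]


class TestClassify:
    @pytest.mark.parametrize(
        "d, current, hysteresis, expected",
        [
            (dev(0, 0), IN, 0.0, IN),
            (dev(6, 0), IN, 0.0, OUT),          # frontal beyond threshold
            (dev(0, -6), IN, 0.0, OUT),         # lateral beyond threshold
            (dev(5, 0), IN, 0.0, IN),           # at threshold is still in
            (dev(4.5, 0), OUT, 1.0, OUT),       # hysteresis: needs <= 4 to re-enter
            (dev(4.0, 0), OUT, 1.0, IN),
            (dev(4.5, 0), OUT, 0.0, IN),        # no hysteresis: plain threshold
        ],
    )
    def test_threshold_and_hysteresis(self, d, current, hysteresis, expected):
        cfg = PostureConfig(hysteresis_deg=hysteresis)
        assert classify(d, cfg, current) is expected


class TestDirectiveFor:
    @pytest.mark.parametrize(
        "d, key",
        [
            (dev(8, 0), "LEAN_BACKWARD"),    # leaning forward -> corrective opposite
            (dev(-8, 0), "LEAN_FORWARD"),
            (dev(0, 7), "LEAN_LEFT"),        # leaning right
            (dev(0, -7), "LEAN_RIGHT"),
            (dev(6, 6), "LEAN_BACKWARD"),    # equal ratios: tie goes to frontal
            (dev(6, 12), "LEAN_LEFT"),       # lateral dominates
        ],
    )
    def test_opposite_direction_rule(self, d, key, cfg):
        assert directive_for(d, cfg) == key

    def test_in_posture_has_no_directive(self, cfg):
        with pytest.raises(NoDirectiveError):
            directive_for(dev(1, 1), cfg)


def run_schedule(engine, schedule):
    """Step the engine through (t, frontal, lateral) triples; return all events."""
    for t, f, l in schedule:
        engine.step_angles(f, l, t)
    return engine.events


class TestStep:
    def test_paused_engine_refuses_steps(self, cfg):
        with pytest.raises(EnginePausedError):
            FeedbackEngine(cfg).step_angles(0, 0, 0.0)

    def test_quiet_stage_emits_only_startup_green(self, cfg):
        eng = FeedbackEngine(cfg)
        eng.control("play", 0.0)
        run_schedule(eng, [(float(t), 0.0, 0.0) for t in range(11)])
        assert kinds(eng.events) == [EventKind.MONITORING_STARTED, EventKind.COLOR_GREEN]

    def test_transition_red_vibration_then_directives(self, cfg):
        # deviation jumps to frontal 8 deg at t=10 and stays (tolerance 3 s)
        eng = FeedbackEngine(cfg)
        eng.control("play", 0.0)
        sched = [(float(t), 0.0, 0.0) for t in range(10)]
        sched += [(float(t), 8.0, 0.0) for t in range(10, 17)]
        run_schedule(eng, sched)
        ev = [e for e in eng.events if e.kind is not EventKind.MONITORING_STARTED]
        assert [(e.t, e.kind) for e in ev] == [
            (0.0, EventKind.COLOR_GREEN),
            (10.0, EventKind.COLOR_RED),
            (10.0, EventKind.VIBRATION),
            (13.0, EventKind.AUDIO_DIRECTIVE),
            (16.0, EventKind.AUDIO_DIRECTIVE),
        ]
        assert all(e.payload["message_key"] == "LEAN_BACKWARD"
                   for e in ev if e.kind is EventKind.AUDIO_DIRECTIVE)
        assert ev[3].payload["text"] == "please lean backward"

    def test_no_directive_before_tolerance_elapses(self, cfg):
        eng = FeedbackEngine(cfg)
        eng.control("play", 0.0)
        run_schedule(eng, [(0.0, 0, 0), (1.0, 8, 0), (2.0, 8, 0), (3.9, 8, 0)])
        assert EventKind.AUDIO_DIRECTIVE not in kinds(eng.events)
        eng.step_angles(8, 0, 4.0)  # tolerance 3 s after the t=1 transition
        assert eng.events[-1].kind is EventKind.AUDIO_DIRECTIVE

    def test_return_to_posture_green_and_congratulation(self, cfg):
        eng = FeedbackEngine(cfg)
        eng.control("play", 0.0)
        run_schedule(eng, [(0.0, 0, 0), (1.0, 8, 0), (2.0, 0, 0)])
        tail = kinds(eng.events)[-2:]
        assert tail == [EventKind.COLOR_GREEN, EventKind.AUDIO_CONGRATULATION]
        payload = eng.events[-1].payload
        assert payload["message_key"].startswith("CONGRATULATION_")
        assert payload["text"]

    def test_praise_every_five_minutes_in_posture(self, cfg):
        eng = FeedbackEngine(cfg)
        eng.control("play", 0.0)
        run_schedule(eng, [(float(t), 0.0, 0.0) for t in range(0, 601, 1)])
        praises = [e for e in eng.events if e.kind is EventKind.AUDIO_PRAISE]
        assert [e.t for e in praises] == [300.0, 600.0]

    def test_praise_clock_resets_on_return(self, cfg):
        eng = FeedbackEngine(cfg)
        eng.control("play", 0.0)
        sched = [(float(t), 0.0, 0.0) for t in range(0, 290)]
        sched += [(290.0, 8.0, 0.0), (291.0, 0.0, 0.0)]       # brief excursion
        sched += [(float(t), 0.0, 0.0) for t in range(292, 600)]
        run_schedule(eng, sched)
        praises = [e.t for e in eng.events if e.kind is EventKind.AUDIO_PRAISE]
        assert praises == [591.0]  # 300 s after the t=291 return, not t=300

    def test_disabled_channels_stay_silent(self):
        cfg = PostureConfig(audio_enabled=False, vibration_enabled=False)
        eng = FeedbackEngine(cfg)
        eng.control("play", 0.0)
        sched = [(float(t), 8.0 if 5 <= t < 60 else 0.0, 0.0) for t in range(0, 601)]
        run_schedule(eng, sched)
        got = set(kinds(eng.events))
        assert EventKind.VIBRATION not in got
        assert not any(k.value.startswith("AUDIO_") for k in got)
        assert EventKind.COLOR_RED in got  # visual channel still on

    def test_silent_recording_mode_emits_nothing(self):
        cfg = PostureConfig(audio_enabled=False, vibration_enabled=False,
                            visual_enabled=False)
        eng = FeedbackEngine(cfg)
        eng.control("play", 0.0)
        run_schedule(eng, [(float(t), 8.0 if t % 7 < 3 else 0.0, 0.0)
                           for t in range(0, 120)])
        assert kinds(eng.events) == [EventKind.MONITORING_STARTED]
        # ... but the posture state machine still ran
        assert eng.state.posture is not None

    def test_determinism_identical_streams(self, cfg):
        sched = [(float(t), 8.0 if 10 <= t % 40 < 20 else 0.0, 0.0)
                 for t in range(0, 400)]
        runs = []
        for _ in range(2):
            eng = FeedbackEngine(cfg)
            eng.control("play", 0.0)
            run_schedule(eng, sched)
            runs.append(json.dumps([(e.t, e.kind.value, e.payload) for e in eng.events]))
        assert runs[0] == runs[1]

    @given(st.lists(st.tuples(st.floats(-20, 20), st.floats(-20, 20)),
                    min_size=1, max_size=200))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_colors_strictly_alternate(self, devs):
        cfg = PostureConfig()
        eng = FeedbackEngine(cfg)
        eng.control("play", 0.0)
        for i, (f, l) in enumerate(devs):
            eng.step_angles(f, l, float(i + 1))
        colors = [e.kind for e in eng.events
                  if e.kind in (EventKind.COLOR_GREEN, EventKind.COLOR_RED)]
        for a, b in zip(colors, colors[1:]):
            assert a is not b
        # every red is followed by a green or by end-of-stage
        assert colors[0] is EventKind.COLOR_GREEN


class TestControl:
    def test_play_pause_cycle(self, cfg):
        eng = FeedbackEngine(cfg)
        ev = eng.control("play", 0.0)
        assert kinds(ev) == [EventKind.MONITORING_STARTED, EventKind.COLOR_GREEN]
        assert eng.state.monitoring
        ev = eng.control("pause", 5.0)
        assert kinds(ev) == [EventKind.MONITORING_PAUSED]
        assert not eng.state.monitoring

    def test_update_settings_logged_with_old_and_new(self, cfg):
        eng = FeedbackEngine(cfg)
        ev = eng.control("update_settings", 2.0, {"tolerance_s": 5.0})
        assert ev[0].kind is EventKind.SETTINGS_CHANGED
        assert ev[0].payload["changed"]["tolerance_s"] == {"old": 3.0, "new": 5.0}
        assert eng.cfg.tolerance_s == 5.0

    def test_unknown_command(self, cfg):
        with pytest.raises(ValueError, match="unknown engine command"):
            FeedbackEngine(cfg).control("reboot", 0.0)


class TestConfig:
    @pytest.mark.parametrize("bad", [
        {"frontal_threshold_deg": 0.0},
        {"tolerance_s": -1.0},
        {"praise_interval_s": 0.0},
        {"hysteresis_deg": 5.0},   # must stay below min threshold
        {"language": "de"},
    ])
    def test_invariants_enforced(self, bad):
        with pytest.raises(ValueError):
            PostureConfig(**bad)

    def test_from_file_json_and_keyvalue(self, tmp_path):
        j = tmp_path / "cfg.json"
        j.write_text('{"tolerance_s": 7.0, "language": "es"}')
        cfg = PostureConfig.from_file(j)
        assert cfg.tolerance_s == 7.0 and cfg.language == "es"
        k = tmp_path / "cfg.conf"
        k.write_text("tolerance_s = 7\nvibration_enabled = false\n# comment\n")
        cfg = PostureConfig.from_file(k)
        assert cfg.tolerance_s == 7 and cfg.vibration_enabled is False

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown config fields"):
            PostureConfig.from_dict({"volume": 11})
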