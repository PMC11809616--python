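import numpy as np
import pytest

from posturekit import (
    AngleRecord,
    PostureConfig,
    PostureState,
    SessionHeader,
    SessionLog,
)


@pytest.fixture
def cfg() -> PostureConfig:
    """Thresholds 5/5 degrees, tolerance 3 s, everything enabled."""
    return PostureConfig()


def make_log(states: list[PostureState], stage: str = "feedback_on",
             subject_id: str = "S01", cfg: PostureConfig | None = None) -> SessionLog:
    """A 1 Hz log with the given per-second posture states (angles synthetic)."""
    cfg = cfg or PostureConfig()
    records = [
        AngleRecord(t=float(i), frontal_deg=0.0 if st is PostureState.IN_POSTURE else 8.0,
                    lateral_deg=0.0, posture=st)
        for i, st in enumerate(states)
    ]
    return SessionLog(
        header=SessionHeader(subject_id=subject_id, stage=stage, config=cfg),
        angle_records=records,
    )


@pytest.fixture
def toy_log() -> SessionLog:
    """Hand-enumerated 120 s stage: IN [0,20), OUT [20,30), IN [30,100),
    OUT [100,105), IN [105,120]."""
    IN, OUT = PostureState.IN_POSTURE, PostureState.OUT_OF_POSTURE
    states = [IN] * 20 + [OUT] * 10 + [IN] * 70 + [OUT] * 5 + [IN] * 16  # t = 0..120
    return make_log(states)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
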