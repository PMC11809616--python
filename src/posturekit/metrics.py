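"""Per-stage rehabilitation session metrics and two-condition comparisons.

From a session log's per-second posture states we segment the stage into
maximal constant-state episodes, and derive:

* ``maintained_positions`` — in-posture episodes held at least
  ``min_hold_s`` seconds (how often the wearer attained and kept the
  best-at-the-time posture);
* ``corrective_movements`` — completed returns to posture (OUT->IN
  transitions), the log-derivable correlate of "movements performed to
  attain the best posture"; the raw count of out-of-posture episodes is
  also reported;
* ``time_in_posture_fraction`` — summed in-posture episode time over
  stage duration.

For the condition comparison (stage with feedback vs stage without) both
a paired t-test on per-subject metric pairs and a Welch two-sample test
computable from printed group summaries (mean, SD, n) are provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import PostureState
from .sessionlog import SessionLog

DEFAULT_MIN_HOLD_S = 5.0


class DegenerateDataError(ValueError):
    """A test statistic is undefined (e.g. zero-variance differences)."""


@dataclass(frozen=True)
class Episode:
    state: PostureState
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SessionMetrics:
    stage_duration_min: float
    maintained_positions: int
    corrective_movements: int
    out_episode_count: int
    time_in_posture_fraction: float
    in_episode_durations_s: tuple[float, ...]
    out_episode_durations_s: tuple[float, ...]
    min_hold_s: float


@dataclass(frozen=True)
class GroupSummary:
    """Printed-style group summary: mean, SD, and group size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def episodes(log: SessionLog) -> list[Episode]:
    """Maximal constant-state runs partitioning [stage start, stage end].

    Episode boundaries fall on the first record of each new state; the
    last episode ends at the final record's timestamp. Adjacent episodes
    always differ in state.
    """
    records = log.angle_records
    if not records:
        raise ValueError("empty log: no angle records to segment")
    out: list[Episode] = []
    run_state = records[0].posture
    run_start = records[0].t
    for rec in records[1:]:
        if rec.posture is not run_state:
            out.append(Episode(run_state, run_start, rec.t))
            run_state = rec.posture
            run_start = rec.t
    out.append(Episode(run_state, run_start, records[-1].t))
    return out


def metrics(log: SessionLog, min_hold_s: float = DEFAULT_MIN_HOLD_S) -> SessionMetrics:
    """Derive the per-stage session metrics from a log."""
    eps = episodes(log)
    stage_start = log.angle_records[0].t
    stage_end = log.angle_records[-1].t
    duration = stage_end - stage_start

    in_eps = [e for e in eps if e.state is PostureState.IN_POSTURE]
    out_eps = [e for e in eps if e.state is PostureState.OUT_OF_POSTURE]
    # an OUT episode "ends within the stage" when a later episode follows it
    completed_out = sum(1 for e in out_eps if e.end < stage_end)
    in_time = sum(e.duration for e in in_eps)

    return SessionMetrics(
        stage_duration_min=duration / 60.0,
        maintained_positions=sum(1 for e in in_eps if e.duration >= min_hold_s),
        corrective_movements=completed_out,
        out_episode_count=len(out_eps),
        time_in_posture_fraction=(in_time / duration) if duration > 0 else
        (1.0 if in_eps else 0.0),
        in_episode_durations_s=tuple(e.duration for e in in_eps),
        out_episode_durations_s=tuple(e.duration for e in out_eps),
        min_hold_s=min_hold_s,
    )


def welch_t_from_summaries(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Welch's unequal-variance two-sample t-test from group summaries.

    t = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with the
    Welch-Satterthwaite degrees of freedom and a two-tailed p from the
    t distribution. When both SDs are zero: p = 1 for equal means (by
    convention), p = 0 otherwise.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0.0:
        if a.mean == b.mean:
            return TTestResult(0.0, float(a.n + b.n - 2), 1.0)
        return TTestResult(np.inf if a.mean > b.mean else -np.inf,
                           float(a.n + b.n - 2), 0.0)
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def paired_t(pairs: list[tuple[float, float]]) -> TTestResult:
    """Paired (within-subjects) t-test on (condition A, condition B) pairs.

    Tests whether the mean within-subject difference A - B is zero.
    All-zero differences give t = 0, p = 1; constant nonzero differences
    (zero variance) are flagged as degenerate.
    """
    if len(pairs) < 2:
        raise ValueError("paired_t requires at least 2 pairs")
    d = np.asarray([x - y for x, y in pairs], dtype=float)
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0.0:
        if np.all(d == 0.0):
            return TTestResult(0.0, float(n - 1), 1.0)
        raise DegenerateDataError(
            "paired differences have zero variance but nonzero mean; "
            "t statistic is undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def metrics_table(
    logs: list[SessionLog], min_hold_s: float = DEFAULT_MIN_HOLD_S
) -> pd.DataFrame:
    """Per-stage metrics for a set of logs, one row per log."""
    rows = []
    for log in logs:
        m = metrics(log, min_hold_s=min_hold_s)
        rows.append({
            "subject_id": log.header.subject_id,
            "stage": log.header.stage,
            "stage_duration_min": m.stage_duration_min,
            "maintained_positions": m.maintained_positions,
            "corrective_movements": m.corrective_movements,
            "out_episode_count": m.out_episode_count,
            "time_in_posture_fraction": m.time_in_posture_fraction,
            "min_hold_s": m.min_hold_s,
        })
    return pd.DataFrame(rows)


def compare_conditions(
    table: pd.DataFrame, metric: str = "maintained_positions"
) -> dict:
    """Paired + Welch comparison of a metric between feedback_on and feedback_off.

    The table must come from :func:`metrics_table` with both stages per
    subject for the paired test; the Welch test uses the group summaries.
    """
    on = table[table["stage"] == "feedback_on"]
    off = table[table["stage"] == "feedback_off"]
    if on.empty or off.empty:
        raise ValueError("need at least one log per stage label for a comparison")
    def group(frame: pd.DataFrame) -> dict:
        return {"mean": float(frame[metric].mean()),
                "sd": float(frame[metric].std(ddof=1)) if len(frame) >= 2 else None,
                "n": int(len(frame))}

    report: dict = {
        "metric": metric,
        "feedback_on": group(on),
        "feedback_off": group(off),
    }
    if len(on) >= 2 and len(off) >= 2:
        welch = welch_t_from_summaries(
            GroupSummary(**report["feedback_on"]), GroupSummary(**report["feedback_off"]))
        report["welch"] = {"t": welch.statistic, "df": welch.df, "p": welch.pvalue}
    merged = on.merge(off, on="subject_id", suffixes=("_on", "_off"))
    if len(merged) >= 2:
        try:
            pt = paired_t(list(zip(merged[f"{metric}_on"], merged[f"{metric}_off"])))
            report["paired"] = {"t": pt.statistic, "df": pt.df, "p": pt.pvalue,
                                "n_pairs": int(len(merged))}
        except DegenerateDataError as exc:
            report["paired"] = {"error": str(exc), "n_pairs": int(len(merged))}
    return report
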