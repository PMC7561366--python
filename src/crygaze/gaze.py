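"""Scoring of raw gaze streams into attention outcomes.

Two tasks share one scorer. *Oculomotor orienting*: the saccadic reaction
time (SRT) is the time the gaze first lands inside the peripheral target's
area of interest, relative to target onset; shifts earlier than 150 ms or
later than 1000 ms, and shifts leaving the screen, are excluded. *Attention
disengagement*: the saccade time x is the last gaze point inside the
central stimulus area preceding the saccade toward the lateral distractor;
trials without a shift enter at x = 1000 ms, and each scorable trial
contributes 1 - (1000 - x)/850 to the condition's dwell-time index.

Trial validity (both tasks): >70% of pre-shift valid samples must fixate
the central area, no run of missing/invalid data longer than 200 ms may
fall in the analysis period, and the central-to-lateral transition must not
occur inside a missing-data run.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    DISENGAGEMENT_CONDITIONS,
    INVALID,
    VALID_NO_SHIFT,
    VALID_SHIFT,
    AOI,
    ParticipantAttention,
    ScoringConfig,
    TrialRecord,
    TrialScore,
)

__all__ = [
    "read_gaze_file",
    "validate_trial",
    "orienting_latency",
    "dwell_contribution",
    "dwell_index_for_condition",
    "aggregate_participant",
    "score_trial",
    "score_participants",
]


class GazeParseError(ValueError):
    pass


_GAZE_COLUMNS = ["trial_id", "task", "condition", "time_ms", "x", "y", "valid"]
_EVENT_COLUMNS = [
    "trial_id", "lateral_onset_ms",
    "central_cx", "central_cy", "central_w", "central_h",
    "lateral_cx", "lateral_cy", "lateral_w", "lateral_h",
]


def read_gaze_file(gaze_path: str | os.PathLike,
                   events_path: str | os.PathLike) -> list[TrialRecord]:
    """Assemble trials from a gaze-sample CSV and its events sidecar.

    The gaze CSV needs columns (trial_id, task, condition, time_ms, x, y,
    valid); the events CSV needs per-trial lateral onset and AOI geometry.
    An optional ``participant_id`` column is carried through by
    :func:`read_gaze_dataset`; this function returns the flat trial list.
    """
    gaze = pd.read_csv(gaze_path)
    events = pd.read_csv(events_path)
    missing = [c for c in _GAZE_COLUMNS if c not in gaze.columns]
    if missing:
        raise GazeParseError(f"gaze file missing columns: {missing}")
    missing = [c for c in _EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise GazeParseError(f"events file missing columns: {missing}")
    ev_by_trial = events.set_index(events["trial_id"].astype(str))
    if ev_by_trial.index.has_duplicates:
        dup = ev_by_trial.index[ev_by_trial.index.duplicated()][0]
        raise GazeParseError(f"duplicate events row for trial {dup}")

    trials: list[TrialRecord] = []
    for trial_id, g in gaze.groupby(gaze["trial_id"].astype(str), sort=False):
        if str(trial_id) not in ev_by_trial.index:
            raise GazeParseError(f"trial {trial_id}: no events row")
        ev = ev_by_trial.loc[str(trial_id)]
        t = g["time_ms"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise GazeParseError(f"trial {trial_id}: timestamps not increasing")
        task = str(g["task"].iloc[0])
        condition = str(g["condition"].iloc[0])
        try:
            trial = TrialRecord(
                trial_id=str(trial_id),
                task=task,
                condition=condition,
                central_aoi=AOI(ev["central_cx"], ev["central_cy"],
                                ev["central_w"], ev["central_h"]),
                lateral_aoi=AOI(ev["lateral_cx"], ev["lateral_cy"],
                                ev["lateral_w"], ev["lateral_h"]),
                lateral_onset_ms=float(ev["lateral_onset_ms"]),
                time_ms=t,
                x=g["x"].to_numpy(dtype=float),
                y=g["y"].to_numpy(dtype=float),
                valid=g["valid"].to_numpy(dtype=bool),
            )
        except ValueError as exc:
            raise GazeParseError(f"trial {trial_id}: {exc}") from exc
        trials.append(trial)
    return trials


def read_gaze_dataset(gaze_path, events_path) -> dict[str, list[TrialRecord]]:
    """Like :func:`read_gaze_file` but grouped by ``participant_id`` column."""
    gaze = pd.read_csv(gaze_path)
    if "participant_id" not in gaze.columns:
        return {"P1": read_gaze_file(gaze_path, events_path)}
    events = pd.read_csv(events_path)
    out: dict[str, list[TrialRecord]] = {}
    import io

    for pid, g in gaze.groupby("participant_id", sort=False):
        ev = events[events["participant_id"] == pid] if "participant_id" in events.columns else events
        gbuf, ebuf = io.StringIO(), io.StringIO()
        g.to_csv(gbuf, index=False)
        ev.to_csv(ebuf, index=False)
        gbuf.seek(0), ebuf.seek(0)
        out[str(pid)] = read_gaze_file(gbuf, ebuf)
    return out


def _first_lateral_index(trial: TrialRecord) -> Optional[int]:
    """Index of the first valid sample inside the lateral AOI after onset."""
    mask = (
        trial.valid
        & (trial.time_ms > trial.lateral_onset_ms)
        & trial.lateral_aoi.contains_array(trial.x, trial.y)
    )
    idx = np.nonzero(mask)[0]
    return int(idx[0]) if idx.size else None


def _max_invalid_gap_ms(trial: TrialRecord, end_ms: float) -> float:
    """Longest missing-data run in [0, end_ms], bracketed by timestamps.

    A run of invalid samples (or a hole in the sample stream) is measured
    from the last valid timestamp before it to the first valid timestamp
    after it.
    """
    in_period = trial.time_ms <= end_ms
    t_valid = trial.time_ms[in_period & trial.valid]
    if t_valid.size == 0:
        return end_ms
    bounds = np.concatenate([[0.0], t_valid, [min(end_ms, trial.time_ms[in_period][-1])]])
    diffs = np.diff(bounds)
    return float(diffs.max()) if diffs.size else 0.0


def score_trial(trial: TrialRecord, cfg: ScoringConfig | None = None) -> TrialScore:
    """Score one trial: validity checks, then the task-specific saccade time."""
    cfg = cfg or ScoringConfig()
    onset = trial.lateral_onset_ms
    window_end_abs = onset + cfg.window_end_ms

    shift_idx = _first_lateral_index(trial)
    shift_abs_ms = trial.time_ms[shift_idx] if shift_idx is not None else None
    analysis_end = min(shift_abs_ms, window_end_abs) if shift_abs_ms is not None else window_end_abs

    def invalid(reason: str) -> TrialScore:
        return TrialScore(trial.trial_id, trial.task, trial.condition,
                          INVALID, reason=reason)

    if _max_invalid_gap_ms(trial, analysis_end) > cfg.max_gap_ms:
        return invalid("data_gap")

    pre = trial.valid & (trial.time_ms <= analysis_end)
    if shift_idx is not None:
        pre &= trial.time_ms < shift_abs_ms
    n_pre = int(pre.sum())
    if n_pre == 0:
        return invalid("insufficient_fixation")
    central = trial.central_aoi.contains_array(trial.x[pre], trial.y[pre])
    central_idx_all = np.nonzero(pre & trial.central_aoi.contains_array(trial.x, trial.y))[0]
    if central.mean() <= cfg.fixation_min_fraction:
        return invalid("insufficient_fixation")

    if shift_idx is not None and shift_abs_ms <= window_end_abs:
        if central_idx_all.size == 0:
            return invalid("insufficient_fixation")
        last_central_idx = int(central_idx_all[-1])
        between = trial.valid[last_central_idx + 1 : shift_idx]
        if between.size and not between.all():
            return invalid("shift_in_gap")
        # gaze leaving the screen before reaching the lateral area
        seg = slice(last_central_idx + 1, shift_idx)
        off = (
            (np.abs(trial.x[seg]) > cfg.screen_half_width_deg)
            | (np.abs(trial.y[seg]) > cfg.screen_half_height_deg)
        ) & trial.valid[seg]
        if np.any(off):
            return invalid("off_screen")

    if trial.task == "orienting":
        if shift_idx is None or shift_abs_ms > window_end_abs:
            return invalid("too_late")
        srt = shift_abs_ms - onset
        if srt < cfg.window_start_ms:
            return invalid("too_early")
        return TrialScore(trial.trial_id, trial.task, trial.condition,
                          VALID_SHIFT, saccade_time_ms=float(srt))

    # disengagement: saccade time = last central gaze point before the shift
    if shift_idx is None or shift_abs_ms > window_end_abs:
        return TrialScore(trial.trial_id, trial.task, trial.condition,
                          VALID_NO_SHIFT)
    last_central_ms = trial.time_ms[int(central_idx_all[-1])]
    x_i = float(max(last_central_ms - onset, 0.0))
    if x_i < cfg.window_start_ms:
        return invalid("too_early")
    return TrialScore(trial.trial_id, trial.task, trial.condition,
                      VALID_SHIFT, saccade_time_ms=x_i)


def validate_trial(trial: TrialRecord, cfg: ScoringConfig | None = None) -> TrialScore:
    """Spec-shaped alias of :func:`score_trial` (validity plus scoring)."""
    return score_trial(trial, cfg)


def orienting_latency(trial: TrialRecord,
                      cfg: ScoringConfig | None = None) -> TrialScore:
    """Score an orienting trial; the SRT is in ``saccade_time_ms`` if valid."""
    if trial.task != "orienting":
        raise ValueError("orienting_latency expects an orienting trial")
    return score_trial(trial, cfg)


def dwell_contribution(x: float, cfg: ScoringConfig | None = None) -> float:
    """Per-trial dwell-time contribution 1 - (window_end - x)/norm_range.

    With the default window this is 1 - (1000 - x)/850: a saccade at the
    shortest acceptable reaction time (150 ms) contributes 0, a trial with
    no shift (x = 1000 ms) contributes 1.
    """
    cfg = cfg or ScoringConfig()
    if not (cfg.window_start_ms <= x <= cfg.window_end_ms):
        raise ValueError(
            f"saccade time {x} ms outside "
            f"[{cfg.window_start_ms}, {cfg.window_end_ms}] ms"
        )
    return 1.0 - (cfg.window_end_ms - x) / cfg.norm_range_ms


def dwell_index_for_condition(scores: Sequence[TrialScore],
                              cfg: ScoringConfig | None = None
                              ) -> Optional[float]:
    """Mean dwell contribution over one condition's scorable trials.

    Scorable = valid shifts within the window (at their saccade time) plus
    no-shift trials (at the window end). Returns None with fewer than
    ``min_trials_per_condition`` scorable trials.
    """
    cfg = cfg or ScoringConfig()
    xs = []
    for s in scores:
        if s.status == VALID_SHIFT:
            xs.append(s.saccade_time_ms)
        elif s.status == VALID_NO_SHIFT:
            xs.append(cfg.window_end_ms)
    if len(xs) < cfg.min_trials_per_condition:
        return None
    return float(np.mean([dwell_contribution(x, cfg) for x in xs]))


def aggregate_participant(participant_id: str,
                          scores: Iterable[TrialScore],
                          cfg: ScoringConfig | None = None
                          ) -> ParticipantAttention:
    """Participant-level mean SRT and dwell index with inclusion flags.

    Orienting is included with >= 4 scorable trials; the dwell index is the
    unweighted mean over the three stimulus conditions and is included only
    when every condition has >= 3 scorable trials.
    """
    cfg = cfg or ScoringConfig()
    scores = list(scores)
    srts = [
        s.saccade_time_ms
        for s in scores
        if s.task == "orienting" and s.status == VALID_SHIFT
    ]
    n_orient = len(srts)
    orienting = float(np.mean(srts)) if srts else None

    by_cond: dict[str, Optional[float]] = {}
    for cond in DISENGAGEMENT_CONDITIONS:
        cond_scores = [
            s for s in scores if s.task == "disengagement" and s.condition == cond
        ]
        by_cond[cond] = dwell_index_for_condition(cond_scores, cfg)
    included_dwell = all(v is not None for v in by_cond.values())
    dwell = float(np.mean([v for v in by_cond.values()])) if included_dwell else None

    return ParticipantAttention(
        participant_id=participant_id,
        orienting_latency_ms=orienting,
        n_orienting_trials=n_orient,
        dwell_index_by_condition=by_cond,
        dwell_index=dwell,
        included_orienting=n_orient >= cfg.min_orienting_trials,
        included_dwell=included_dwell,
    )


def score_participants(dataset: dict[str, list[TrialRecord]],
                       cfg: ScoringConfig | None = None) -> pd.DataFrame:
    """Score every participant's trials into the participant table."""
    cfg = cfg or ScoringConfig()
    rows = []
    for pid, trials in dataset.items():
        scores = [score_trial(t, cfg) for t in trials]
        agg = aggregate_participant(pid, scores, cfg)
        rows.append(
            {
                "participant_id": pid,
                "orienting_latency_ms": agg.orienting_latency_ms,
                "n_orienting_trials": agg.n_orienting_trials,
                "dwell_happy": agg.dwell_index_by_condition.get("happy"),
                "dwell_fear": agg.dwell_index_by_condition.get("fearful"),
                "dwell_nonface": agg.dwell_index_by_condition.get("nonface"),
                "dwell_index": agg.dwell_index,
                "included_orienting": agg.included_orienting,
                "included_dwell": agg.included_dwell,
            }
        )
    return pd.DataFrame(rows)
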