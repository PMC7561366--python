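import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crygaze.gaze import (
    GazeParseError,
    aggregate_participant,
    dwell_contribution,
    dwell_index_for_condition,
    orienting_latency,
    read_gaze_file,
    score_trial,
    validate_trial,
)
from crygaze.simulate import GazeSpec, synth_gaze
from crygaze.types import (
    INVALID,
    VALID_NO_SHIFT,
    VALID_SHIFT,
    ScoringConfig,
    TrialScore,
)

from .conftest import ONSET_MS, build_trial


class TestReadGazeFile:
    def _bundle(self, tmp_path, n_trials=2, drop_event_for=None, scramble=False):
        spec = GazeSpec(seed=0, n_orienting_trials=n_trials,
                        n_disengagement_trials_per_condition=0)
        gaze, events, _ = synth_gaze(spec)
        if drop_event_for is not None:
            events = events[events.trial_id != drop_event_for]
        if scramble:
            gaze = gaze.iloc[::-1]
        gp, ep = tmp_path / "gaze.csv", tmp_path / "events.csv"
        gaze.to_csv(gp, index=False)
        events.to_csv(ep, index=False)
        return gp, ep

    def test_well_formed_two_trial_file(self, tmp_path):
        gp, ep = self._bundle(tmp_path)
        trials = read_gaze_file(gp, ep)
        assert len(trials) == 2
        # 300-Hz stream of 2200 ms -> 660 samples
        assert all(len(t.time_ms) == 660 for t in trials)

    def test_300hz_sample_count(self, tmp_path):
        spec = GazeSpec(seed=1, n_orienting_trials=1,
                        n_disengagement_trials_per_condition=0,
                        lateral_onset_ms=500.0, trial_tail_ms=1000.0)
        gaze, events, _ = synth_gaze(spec)
        gp, ep = tmp_path / "g.csv", tmp_path / "e.csv"
        gaze.to_csv(gp, index=False)
        events.to_csv(ep, index=False)
        (trial,) = read_gaze_file(gp, ep)
        assert len(trial.time_ms) == pytest.approx(450, abs=1)

    def test_missing_events_row_names_trial(self, tmp_path):
        gp, ep = self._bundle(tmp_path, drop_event_for="orient_001")
        with pytest.raises(GazeParseError, match="orient_001"):
            read_gaze_file(gp, ep)

    def test_unsorted_timestamps_rejected(self, tmp_path):
        gp, ep = self._bundle(tmp_path, scramble=True)
        with pytest.raises(GazeParseError, match="timestamps"):
            read_gaze_file(gp, ep)

    def test_missing_column_rejected(self, tmp_path):
        gp, ep = self._bundle(tmp_path)
        import pandas as pd

        pd.read_csv(gp).drop(columns=["valid"]).to_csv(gp, index=False)
        with pytest.raises(GazeParseError, match="valid"):
            read_gaze_file(gp, ep)

    def test_unknown_condition_rejected(self, tmp_path):
        gp, ep = self._bundle(tmp_path)
        import pandas as pd

        g = pd.read_csv(gp)
        g["condition"] = "surprise"
        g.to_csv(gp, index=False)
        with pytest.raises(GazeParseError):
            read_gaze_file(gp, ep)


class TestValidity:
    def test_insufficient_fixation(self, scoring_cfg):
        trial = build_trial(shift_at_ms=400.0, fixate_fraction=0.60)
        score = validate_trial(trial, scoring_cfg)
        assert score.status == INVALID
        assert score.reason == "insufficient_fixation"

    def test_fixation_boundary_is_strict(self, scoring_cfg):
        # exactly 70% is not "more than 70%"; tail trimmed so the whole
        # stream lies in the analysis period (600 samples, 180 strays)
        trial = build_trial(shift_at_ms=None, fixate_fraction=0.70,
                            tail_ms=1000.0)
        assert validate_trial(trial, scoring_cfg).reason == "insufficient_fixation"

    def test_long_gap_invalidates(self, scoring_cfg):
        trial = build_trial(shift_at_ms=400.0, gap_ms=(500.0, 250.0))
        score = validate_trial(trial, scoring_cfg)
        assert (score.status, score.reason) == (INVALID, "data_gap")

    def test_short_gap_keeps_trial_valid(self, scoring_cfg):
        trial = build_trial(shift_at_ms=400.0, gap_ms=(500.0, 150.0))
        assert validate_trial(trial, scoring_cfg).status == VALID_SHIFT

    def test_gap_after_analysis_period_ignored(self, scoring_cfg):
        trial = build_trial(shift_at_ms=400.0,
                            gap_ms=(ONSET_MS + 600.0, 300.0))
        assert validate_trial(trial, scoring_cfg).status == VALID_SHIFT

    def test_shift_inside_gap_invalid(self, scoring_cfg):
        trial = build_trial(shift_at_ms=400.0,
                            gap_ms=(ONSET_MS + 380.0, 30.0))
        score = validate_trial(trial, scoring_cfg)
        assert score.reason == "shift_in_gap"

    def test_clean_shift_valid(self, scoring_cfg):
        trial = build_trial(shift_at_ms=400.0)
        score = validate_trial(trial, scoring_cfg)
        assert score.status == VALID_SHIFT


class TestOrienting:
    def test_srt_definition_first_target_sample(self, scoring_cfg):
        trial = build_trial(shift_at_ms=300.0, task="orienting",
                            condition="target",
                            extra_times=(ONSET_MS + 300.0,))
        score = orienting_latency(trial, scoring_cfg)
        assert score.status == VALID_SHIFT
        assert score.saccade_time_ms == pytest.approx(300.0, abs=1e-9)

    def test_late_shift_excluded(self, scoring_cfg):
        trial = build_trial(shift_at_ms=1200.0, task="orienting",
                            condition="target", tail_ms=1500.0)
        assert orienting_latency(trial, scoring_cfg).reason == "too_late"

    def test_early_shift_excluded(self, scoring_cfg):
        trial = build_trial(shift_at_ms=100.0, task="orienting",
                            condition="target",
                            extra_times=(ONSET_MS + 100.0,))
        assert orienting_latency(trial, scoring_cfg).reason == "too_early"

    def test_off_screen_shift_excluded(self, scoring_cfg):
        trial = build_trial(shift_at_ms=400.0, task="orienting",
                            condition="target", off_screen_before_shift=True)
        assert orienting_latency(trial, scoring_cfg).reason == "off_screen"

    def test_recovers_generator_latencies_within_one_sample(self):
        dt = 1000.0 / 300.0
        for latency in range(200, 901, 100):
            trial = build_trial(shift_at_ms=float(latency), task="orienting",
                                condition="target")
            score = orienting_latency(trial)
            assert score.status == VALID_SHIFT
            assert 0 <= score.saccade_time_ms - latency <= dt + 1e-9


class TestDwell:
    def test_anchor_values(self, scoring_cfg):
        assert dwell_contribution(150.0, scoring_cfg) == pytest.approx(0.0)
        assert dwell_contribution(1000.0, scoring_cfg) == pytest.approx(1.0)
        assert dwell_contribution(575.0, scoring_cfg) == pytest.approx(0.5)

    def test_out_of_window_is_contract_error(self, scoring_cfg):
        with pytest.raises(ValueError):
            dwell_contribution(149.0, scoring_cfg)
        with pytest.raises(ValueError):
            dwell_contribution(1001.0, scoring_cfg)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(x=st.floats(min_value=150.0, max_value=999.0),
           dx=st.floats(min_value=0.01, max_value=1.0))
    def test_affine_strictly_increasing_range_01(self, x, dx):
        cfg = ScoringConfig()
        lo, hi = dwell_contribution(x, cfg), dwell_contribution(min(x + dx, 1000.0), cfg)
        assert 0.0 <= lo < hi <= 1.0
        # affine: equal increments produce equal index increments
        assert hi - lo == pytest.approx((min(x + dx, 1000.0) - x) / 850.0, abs=1e-12)

    def _score(self, x, status=VALID_SHIFT, cond="happy"):
        return TrialScore("t", "disengagement", cond, status,
                          saccade_time_ms=x if status == VALID_SHIFT else None)

    def test_condition_index_mean_of_contributions(self, scoring_cfg):
        scores = [self._score(150.0), self._score(None, VALID_NO_SHIFT),
                  self._score(575.0)]
        assert dwell_index_for_condition(scores, scoring_cfg) == pytest.approx(0.5)

    def test_three_no_shift_trials_give_one(self, scoring_cfg):
        scores = [self._score(None, VALID_NO_SHIFT)] * 3
        assert dwell_index_for_condition(scores, scoring_cfg) == pytest.approx(1.0)

    def test_two_scorable_trials_excluded(self, scoring_cfg):
        scores = [self._score(400.0), self._score(500.0)]
        assert dwell_index_for_condition(scores, scoring_cfg) is None

    def test_shift_after_window_counts_as_no_shift(self, scoring_cfg):
        trial = build_trial(shift_at_ms=1100.0, tail_ms=1500.0)
        assert score_trial(trial, scoring_cfg).status == VALID_NO_SHIFT


def _orient_score(srt):
    return TrialScore("t", "orienting", "target", VALID_SHIFT,
                      saccade_time_ms=srt)


def _dwell_scores(cond, xs):
    return [TrialScore("t", "disengagement", cond, VALID_SHIFT,
                       saccade_time_ms=x) for x in xs]


class TestAggregate:
    def test_orienting_mean_and_inclusion(self, scoring_cfg):
        scores = [_orient_score(s) for s in (300.0, 400.0, 350.0, 450.0)]
        agg = aggregate_participant("p", scores, scoring_cfg)
        assert agg.orienting_latency_ms == pytest.approx(375.0)
        assert agg.included_orienting

    def test_three_orienting_trials_not_included(self, scoring_cfg):
        scores = [_orient_score(s) for s in (300.0, 400.0, 350.0)]
        agg = aggregate_participant("p", scores, scoring_cfg)
        assert not agg.included_orienting
        assert agg.n_orienting_trials == 3

    def test_dwell_index_unweighted_mean_of_conditions(self, scoring_cfg):
        # per-condition indices 0.2, 0.4, 0.6 via x = 1000 - 850*(1 - idx)
        xs = {cond: 1000.0 - 850.0 * (1.0 - idx)
              for cond, idx in zip(("happy", "fearful", "nonface"), (0.2, 0.4, 0.6))}
        scores = list(itertools.chain.from_iterable(
            _dwell_scores(cond, [x] * 3) for cond, x in xs.items()
        ))
        agg = aggregate_participant("p", scores, scoring_cfg)
        assert agg.included_dwell
        assert agg.dwell_index == pytest.approx(0.4)

    def test_missing_condition_excludes_dwell(self, scoring_cfg):
        scores = _dwell_scores("happy", [400.0] * 3) + _dwell_scores("fearful", [400.0] * 3)
        agg = aggregate_participant("p", scores, scoring_cfg)
        assert not agg.included_dwell
        assert agg.dwell_index is None

    def test_permutation_invariance(self, scoring_cfg):
        rng = np.random.default_rng(4)
        scores = (
            [_orient_score(float(s)) for s in rng.uniform(200, 900, 6)]
            + _dwell_scores("happy", list(rng.uniform(200, 900, 4)))
            + _dwell_scores("fearful", list(rng.uniform(200, 900, 4)))
            + _dwell_scores("nonface", list(rng.uniform(200, 900, 4)))
        )
        a = aggregate_participant("p", scores, scoring_cfg)
        shuffled = list(scores)
        rng.shuffle(shuffled)
        b = aggregate_participant("p", shuffled, scoring_cfg)
        assert a.orienting_latency_ms == pytest.approx(b.orienting_latency_ms)
        assert a.dwell_index == pytest.approx(b.dwell_index)


class TestSyntheticRecovery:
    def test_gap_injection_flips_validity_and_back(self, scoring_cfg):
        base = build_trial(shift_at_ms=500.0)
        assert score_trial(base, scoring_cfg).status == VALID_SHIFT
        gapped = build_trial(shift_at_ms=500.0, gap_ms=(400.0, 250.0))
        assert score_trial(gapped, scoring_cfg).reason == "data_gap"
        shrunk = build_trial(shift_at_ms=500.0, gap_ms=(400.0, 180.0))
        assert score_trial(shrunk, scoring_cfg).status == VALID_SHIFT

    def test_generator_gap_trials_invalid_exactly(self):
        spec = GazeSpec(seed=8, n_orienting_trials=10,
                        n_disengagement_trials_per_condition=0,
                        gap_probability=0.5, gap_dur_ms=(250.0, 250.0))
        gaze, events, truth = synth_gaze(spec)
        import io

        g, e = io.StringIO(), io.StringIO()
        gaze.to_csv(g, index=False)
        events.to_csv(e, index=False)
        g.seek(0), e.seek(0)
        trials = read_gaze_file(g, e)
        by_id = {t["trial_id"]: t for t in truth["trials"]}
        n_gapped = 0
        for trial in trials:
            score = score_trial(trial)
            if by_id[trial.trial_id]["gap_injected"]:
                assert score.reason == "data_gap"
                n_gapped += 1
            else:
                assert score.status == VALID_SHIFT
        assert 0 < n_gapped < len(trials)
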