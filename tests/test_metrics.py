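"""Segmentation, onset detection, and the four outcome measures."""

import numpy as np
import pytest

from cuedex import (
    GameSession,
    MovementResponse,
    ResponderParams,
    ScreenGeometry,
    TrajectorySample,
    compute_movement_error,
    compute_movement_onset_time,
    compute_movement_variation,
    compute_success_rate,
    detect_onset,
    segment_events,
    simulate_session,
    summarize_session,
    synthesize_response,
)
from cuedex.metrics import GRID_POINTS
from cuedex.session import GameEvent
from cuedex.simulate import make_event_schedule

from conftest import make_manual_session


def _response(direction="RF", caught=True, onset=None, miss=None, trace=None):
    x = list(trace) if trace is not None else [0.5] * GRID_POINTS
    return MovementResponse(event_index=0, direction_label=direction,
                            target_x=0.5, t=list(np.linspace(0, 2, GRID_POINTS)),
                            x=x, caught=caught, onset_time=onset,
                            miss_distance=miss)


class TestSegmentation:
    def test_default_session_gives_30_responses_15_per_direction(self, default_session):
        responses = segment_events(default_session)
        assert len(responses) == 30
        by_dir = [r.direction_label for r in responses]
        assert by_dir.count("RF") == by_dir.count("RB") == 15
        assert all(len(r.x) == GRID_POINTS for r in responses)

    def test_truncated_session_yields_half_the_responses(self, default_session):
        default_session.samples = [s for s in default_session.samples if s.t < 30.0]
        responses = segment_events(default_session)
        filled = [r for r in responses if not r.empty]
        assert len(filled) == 15
        assert all(r.empty for r in responses if r.event_index >= 15)

    def test_resampling_matches_linear_interpolation(self):
        # Samples at off-grid times: grid values must equal the hand-computed
        # linear interpolation.
        events = [GameEvent(event_index=0, appear_time=0.0, target_x=0.9,
                            direction_label="RF"),
                  GameEvent(event_index=1, appear_time=2.0, target_x=0.1,
                            direction_label="RB")]
        knots_t = [0.0, 0.7, 1.3, 2.0, 3.1, 4.0]
        knots_x = [0.2, 0.2, 0.8, 0.8, 0.3, 0.3]
        samples = [TrajectorySample(t=t, paddle_x=x)
                   for t, x in zip(knots_t, knots_x)]
        session = GameSession(session_id="k", subject_id="s", occasion=1,
                              task_name="peanut_ball", geometry=ScreenGeometry(),
                              events=events, samples=samples, sample_rate_hz=50.0)
        r0 = segment_events(session)[0]
        grid = np.array(r0.t)
        expected = np.interp(grid, [0.0, 0.7, 1.3, 2.0], [0.2, 0.2, 0.8, 0.8])
        np.testing.assert_allclose(r0.x, expected, atol=1e-12)


class TestOnsetDetection:
    grid = np.linspace(0.0, 2.0, GRID_POINTS)

    def test_flat_trace_has_no_onset(self):
        assert detect_onset(self.grid, np.full(GRID_POINTS, 0.4)) is None

    def test_ramp_after_hold_detected_at_ramp_start(self):
        # stationary until 0.9 s, then 0.5 widths/s: onset within one grid step
        x = np.where(self.grid < 0.9, 0.3, 0.3 + 0.5 * (self.grid - 0.9))
        onset = detect_onset(self.grid, x, speed_threshold=0.05, sustain_ms=100)
        assert onset == pytest.approx(0.9, abs=0.02 + 1e-9)

    def test_movement_from_start_detected_at_zero(self):
        x = 0.1 + 0.4 * self.grid
        assert detect_onset(self.grid, x) == pytest.approx(0.0)

    def test_brief_jitter_below_sustain_ignored(self):
        x = np.full(GRID_POINTS, 0.5)
        x[30] = 0.52  # single-sample blip: two fast intervals, not 100 ms
        assert detect_onset(self.grid, x, sustain_ms=100) is None

    def test_programmed_latency_recovered_over_500_events(self, geometry):
        # Close the loop with the simulator: mean detected onset over 500
        # synthesized events must recover onset_mean within 3 SE.
        rng = np.random.default_rng(99)
        params = ResponderParams(onset_mean=0.9, onset_sd=0.2, lapse_prob=0.0)
        event = GameEvent(event_index=0, appear_time=0.0, target_x=0.8,
                          direction_label="RF")
        onsets = []
        for _ in range(500):
            t, x, _ = synthesize_response(event, 0.2, params, geometry, rng)
            onset = detect_onset(t, x)
            if onset is not None:
                onsets.append(onset)
        onsets = np.asarray(onsets)
        assert len(onsets) > 450
        se = onsets.std(ddof=1) / np.sqrt(onsets.size)
        assert abs(onsets.mean() - 0.9) < 3 * se


class TestSuccessRate:
    def test_all_caught_is_100(self):
        rs = [_response(caught=True) for _ in range(15)]
        assert compute_success_rate(rs, "RF") == 100.0

    def test_six_of_fifteen_is_40(self):
        rs = [_response(caught=i < 6, miss=None if i < 6 else 0.2)
              for i in range(15)]
        assert compute_success_rate(rs, "RF") == pytest.approx(40.0)

    def test_matches_brute_force_count(self, default_session):
        responses = segment_events(default_session)
        for direction in ("RF", "RB", None):
            sel = [r for r in responses
                   if direction is None or r.direction_label == direction]
            expected = 100.0 * sum(r.caught for r in sel) / len(sel)
            assert compute_success_rate(responses, direction) == pytest.approx(expected)

    def test_empty_scope_is_an_error(self):
        with pytest.raises(ValueError, match="no responses"):
            compute_success_rate([_response(direction="RF")], "XX")


class TestOnsetAndErrorAverages:
    def test_mot_is_mean_of_detected_onsets(self):
        rs = [_response(onset=0.8), _response(onset=1.0), _response(onset=None)]
        assert compute_movement_onset_time(rs, "RF") == pytest.approx(0.9)

    def test_mot_absent_when_no_onsets(self):
        rs = [_response(onset=None) for _ in range(5)]
        assert compute_movement_onset_time(rs, "RF") is None

    def test_me_is_mean_over_misses_only(self):
        rs = [_response(caught=False, miss=0.2), _response(caught=False, miss=0.3),
              _response(caught=True)]
        assert compute_movement_error(rs, "RF") == pytest.approx(0.25)

    def test_me_absent_when_all_caught(self):
        rs = [_response(caught=True) for _ in range(5)]
        assert compute_movement_error(rs, "RF") is None


class TestMovementVariation:
    def test_identical_traces_give_zero_in_both_modes(self):
        rs = [_response(trace=np.linspace(0.1, 0.9, GRID_POINTS)) for _ in range(5)]
        assert compute_movement_variation(rs, "RF", "mean_sd") == 0.0
        assert compute_movement_variation(rs, "RF", "summed_sd") == 0.0

    def test_two_constant_traces_closed_form(self):
        # sample SD of {0.2, 0.4} at every grid point = 0.1*sqrt(2)
        rs = [_response(trace=[0.2] * GRID_POINTS),
              _response(trace=[0.4] * GRID_POINTS)]
        sd = 0.1 * np.sqrt(2.0)
        assert compute_movement_variation(rs, "RF", "mean_sd") == pytest.approx(sd)
        assert compute_movement_variation(rs, "RF", "summed_sd") == pytest.approx(
            GRID_POINTS * sd)

    def test_summed_equals_grid_points_times_mean(self, default_session):
        responses = segment_events(default_session)
        mean_sd = compute_movement_variation(responses, "RF", "mean_sd")
        summed = compute_movement_variation(responses, "RF", "summed_sd")
        assert summed == pytest.approx(GRID_POINTS * mean_sd)

    def test_fewer_than_two_traces_rejected(self):
        with pytest.raises(ValueError, match=">=2 traces"):
            compute_movement_variation([_response()], "RF")


class TestSummarize:
    def test_all_lapse_session_manual(self):
        # Stationary paddle, targets well outside the capture zone:
        # SR 0, MOT absent, ME = mean |paddle - target| per direction.
        session = make_manual_session([0.9, 0.8, 0.95], [0.1, 0.2, 0.05])
        sm = summarize_session(session)
        assert sm.overall_success_rate == 0.0
        rf, rb = sm.per_direction["RF"], sm.per_direction["RB"]
        assert rf.movement_onset_time is None and rb.movement_onset_time is None
        assert rf.movement_error == pytest.approx(np.mean([0.4, 0.3, 0.45]))
        assert rb.movement_error == pytest.approx(np.mean([0.4, 0.3, 0.45]))
        assert rf.movement_variation == 0.0

    def test_all_caught_session_has_absent_me(self, geometry):
        rng = np.random.default_rng(2)
        params = ResponderParams(onset_mean=0.2, onset_sd=0.05,
                                 movement_speed=3.0, endpoint_noise_sd=0.0,
                                 lapse_prob=0.0)
        sm = summarize_session(simulate_session("S1", 1, "soccer_ball", params,
                                                geometry, rng))
        assert sm.overall_success_rate == 100.0
        for dm in sm.per_direction.values():
            assert dm.movement_error is None
            assert "movement_error absent: no misses" in dm.diagnostics

    def test_summary_equals_independent_recomputation(self, default_session):
        sm = summarize_session(default_session)
        responses = segment_events(default_session)
        for direction, dm in sm.per_direction.items():
            assert dm.success_rate == pytest.approx(
                compute_success_rate(responses, direction))
            assert dm.movement_onset_time == pytest.approx(
                compute_movement_onset_time(responses, direction))
            me = compute_movement_error(responses, direction)
            if me is None:
                assert dm.movement_error is None
            else:
                assert dm.movement_error == pytest.approx(me)
            assert dm.movement_variation == pytest.approx(
                compute_movement_variation(responses, direction))
            assert dm.n_caught + dm.n_missed == dm.n_events

    def test_metrics_invariant_to_uniform_time_shift(self, default_session):
        sm0 = summarize_session(default_session)
        shift = 5.0
        shifted = GameSession(
            session_id=default_session.session_id,
            subject_id=default_session.subject_id,
            occasion=default_session.occasion,
            task_name=default_session.task_name,
            geometry=default_session.geometry,
            events=[GameEvent(event_index=e.event_index,
                              appear_time=e.appear_time + shift,
                              duration=e.duration, target_x=e.target_x,
                              direction_label=e.direction_label)
                    for e in default_session.events],
            samples=[TrajectorySample(t=s.t + shift, paddle_x=s.paddle_x)
                     for s in default_session.samples],
            sample_rate_hz=default_session.sample_rate_hz)
        sm1 = summarize_session(shifted)
        assert sm1.overall_success_rate == sm0.overall_success_rate
        for d in sm0.per_direction:
            a, b = sm0.per_direction[d], sm1.per_direction[d]
            assert b.movement_onset_time == pytest.approx(a.movement_onset_time)
            assert b.movement_variation == pytest.approx(a.movement_variation)

    def test_success_rate_non_increasing_in_endpoint_noise(self, geometry):
        means = []
        for noise in (0.02, 0.15, 0.40):
            rng = np.random.default_rng(123)
            params = ResponderParams(endpoint_noise_sd=noise, lapse_prob=0.0)
            means.append(np.mean([summarize_session(simulate_session(
                f"S{i}", 1, "peanut_ball", params, geometry, rng)
            ).overall_success_rate for i in range(6)]))
        assert means[0] >= means[1] >= means[2]
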