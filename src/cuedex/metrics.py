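"""Per-event segmentation and the four CUE outcome measures.

From each validated session the paddle trajectory is cut into one movement
response per game event, aligned to target appearance and resampled onto a
fixed 101-point grid (50 Hz over the 2 s event, endpoints included). The four
outcome measures, computed per movement direction:

Success rate (SR)
    Percentage of targets caught (per direction, and overall for the session).
Movement onset time (MOT)
    Mean latency from target appearance to the detected start of paddle
    movement, over responses with a detectable onset.
Movement error (ME)
    Mean paddle-target distance at the target's arrival instant, over missed
    events only; absent (not zero) when nothing was missed.
Movement variation (MV)
    Dispersion of the direction's aligned traces: the sample SD across traces
    at each grid point, reduced to one number. The default reduction is the
    mean over grid points, whose magnitude matches the reported values
    (~0.26-0.32 screen widths); the literal sum over the 101 points is kept
    as ``mode='summed_sd'``.

Onset detection is a speed-threshold rule: the first time the finite-difference
paddle speed exceeds a threshold (default 0.05 screen-widths/s) and stays above
it for a sustain window (default 100 ms). The game logs do not define "start of
movement", so both parameters are explicit and configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from cuedex.session import (
    GameSession,
    MovementResponse,
    SessionValidationError,
    validate_session,
)

__all__ = [
    "GRID_POINTS", "DirectionMetrics", "SessionMetrics", "MetricsConfig",
    "segment_events", "detect_onset", "compute_success_rate",
    "compute_movement_onset_time", "compute_movement_error",
    "compute_movement_variation", "summarize_session",
]

logger = logging.getLogger(__name__)

#: Fixed alignment grid: 50 Hz over the 2 s event plus the endpoint.
GRID_POINTS = 101


@dataclass(frozen=True)
class MetricsConfig:
    """Tunable analysis parameters, logged alongside any computed metrics."""

    speed_threshold: float = 0.05   # screen-widths/s
    sustain_ms: float = 100.0
    mv_mode: str = "mean_sd"        # or "summed_sd"
    grid_points: int = GRID_POINTS


@dataclass
class DirectionMetrics:
    """The four outcome measures for one movement direction."""

    direction: str
    success_rate: float                      # %
    movement_onset_time: float | None        # s; absent if no onset detected
    movement_error: float | None             # screen widths; absent if no miss
    movement_variation: float | None         # screen widths; absent if <2 traces
    n_events: int = 0
    n_caught: int = 0
    n_missed: int = 0
    n_onsets_detected: int = 0
    diagnostics: list[str] = field(default_factory=list)


@dataclass
class SessionMetrics:
    """All four measures per direction plus the overall success rate."""

    session_id: str
    subject_id: str
    occasion: int
    task_name: str
    overall_success_rate: float
    per_direction: dict[str, DirectionMetrics]
    config: MetricsConfig = field(default_factory=MetricsConfig)


# ---------------------------------------------------------------------------
# Segmentation

def segment_events(session: GameSession,
                   config: MetricsConfig | None = None) -> list[MovementResponse]:
    """Cut the session trajectory into one aligned response per game event.

    Each response holds the samples with t in [appear, appear + duration),
    re-expressed relative to appearance and linearly resampled onto the fixed
    grid. The caught flag and (for misses) the miss distance are derived from
    the trace endpoint and the capture-zone rule; onsets come from
    :func:`detect_onset`. Events whose window contains no samples are flagged
    ``empty``. Truncated sessions yield fewer responses, with a warning.
    """
    config = config or MetricsConfig()
    issues = validate_session(session)
    # A truncated recording (samples not covering the full schedule) is
    # analysable — the uncovered events come back flagged empty. Anything
    # else is a hard error.
    blocking = [i for i in issues if not i.startswith("samples: must cover")]
    if blocking:
        raise SessionValidationError(
            "cannot segment an invalid session:\n  " + "\n  ".join(blocking))
    if len(blocking) != len(issues):
        logger.warning("session %s: trajectory does not cover the full "
                       "event schedule; uncovered events will be empty",
                       session.session_id)

    ts = np.array([s.t for s in session.samples], dtype=float)
    xs = np.array([s.paddle_x for s in session.samples], dtype=float)

    responses: list[MovementResponse] = []
    n_empty = 0
    for ev in session.events:
        grid = np.linspace(0.0, ev.duration, config.grid_points)
        in_win = (ts >= ev.appear_time) & (ts < ev.appear_time + ev.duration)
        if not in_win.any():
            n_empty += 1
            responses.append(MovementResponse(
                event_index=ev.event_index, direction_label=ev.direction_label,
                target_x=ev.target_x, t=grid.tolist(), x=[], empty=True))
            continue
        t_rel = ts[in_win] - ev.appear_time
        x_win = xs[in_win]
        x_grid = np.interp(grid, t_rel, x_win)

        miss = abs(float(x_grid[-1]) - ev.target_x)
        caught = miss <= session.geometry.capture_halfwidth
        onset = detect_onset(grid, x_grid, config.speed_threshold, config.sustain_ms)
        responses.append(MovementResponse(
            event_index=ev.event_index, direction_label=ev.direction_label,
            target_x=ev.target_x, t=grid.tolist(), x=x_grid.tolist(),
            caught=caught, onset_time=onset,
            miss_distance=None if caught else miss))
    if n_empty:
        logger.warning("%d of %d event windows contained no samples "
                       "(truncated session?)", n_empty, len(session.events))
    return responses


def detect_onset(t: np.ndarray, x: np.ndarray,
                 speed_threshold: float = 0.05,
                 sustain_ms: float = 100.0) -> float | None:
    """First time the paddle speed exceeds ``speed_threshold`` for at least
    ``sustain_ms``; None when the trace never sustains movement."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.size < 2:
        return None
    dt = np.diff(t)
    speed = np.abs(np.diff(x)) / np.where(dt > 0, dt, np.inf)
    step = float(np.median(dt[dt > 0])) if (dt > 0).any() else 0.0
    if step == 0.0:
        return None
    need = max(1, int(math.ceil(sustain_ms / 1000.0 / step)))

    above = speed > speed_threshold
    run = 0
    for i, ok in enumerate(above):
        run = run + 1 if ok else 0
        if run >= need:
            return float(t[i - need + 1])
    return None


# ---------------------------------------------------------------------------
# The four outcome measures

def _in_scope(responses: list[MovementResponse],
              direction: str | None) -> list[MovementResponse]:
    sel = [r for r in responses if not r.empty
           and (direction is None or r.direction_label == direction)]
    return sel


def compute_success_rate(responses: list[MovementResponse],
                         direction: str | None = None) -> float:
    """Percentage of targets caught, per direction or (direction=None) overall."""
    sel = _in_scope(responses, direction)
    if not sel:
        raise ValueError(f"no responses in scope (direction={direction!r})")
    return 100.0 * sum(r.caught for r in sel) / len(sel)


def compute_movement_onset_time(responses: list[MovementResponse],
                                direction: str) -> float | None:
    """Mean detected onset latency for the direction; None (with a log line)
    when no response had a detectable onset."""
    onsets = [r.onset_time for r in _in_scope(responses, direction)
              if r.onset_time is not None]
    if not onsets:
        logger.info("no detectable onsets in direction %s", direction)
        return None
    return float(np.mean(onsets))


def compute_movement_error(responses: list[MovementResponse],
                           direction: str) -> float | None:
    """Mean paddle-target distance at target arrival over missed events;
    None when every target in the direction was caught (absent, not zero)."""
    misses = [r.miss_distance for r in _in_scope(responses, direction)
              if not r.caught]
    if not misses:
        return None
    if any(m is None for m in misses):
        raise ValueError("missed response without a miss_distance")
    return float(np.mean(misses))


def compute_movement_variation(responses: list[MovementResponse],
                               direction: str,
                               mode: str = "mean_sd") -> float:
    """Trace dispersion for the direction from per-grid-point sample SDs.

    The SD across traces (n-1 denominator) is computed at every grid point;
    ``mode='mean_sd'`` (default) averages the 101 per-point SDs, while
    ``mode='summed_sd'`` returns their literal sum (= grid_points x mean).
    Requires at least two non-empty traces.
    """
    traces = [r.x for r in _in_scope(responses, direction)]
    if len(traces) < 2:
        raise ValueError(
            f"movement variation needs >=2 traces in direction {direction!r}, "
            f"got {len(traces)}")
    stack = np.asarray(traces, dtype=float)
    per_point_sd = stack.std(axis=0, ddof=1)
    # identical values must give exactly 0, not mean-subtraction rounding dust
    per_point_sd[(stack == stack[0]).all(axis=0)] = 0.0
    if mode == "mean_sd":
        return float(per_point_sd.mean())
    if mode == "summed_sd":
        return float(per_point_sd.sum())
    raise ValueError(f"unknown mode {mode!r}; expected 'mean_sd' or 'summed_sd'")


def summarize_session(session: GameSession,
                      config: MetricsConfig | None = None) -> SessionMetrics:
    """Segment the session and compute all four measures per direction.

    Component errors (no misses, no detectable onsets, too few traces) become
    absent values with a diagnostic string rather than exceptions, so a
    degenerate session still yields a complete summary.
    """
    config = config or MetricsConfig()
    responses = segment_events(session, config)
    per_direction: dict[str, DirectionMetrics] = {}
    for direction in session.direction_labels():
        sel = _in_scope(responses, direction)
        diags: list[str] = []
        n_caught = sum(r.caught for r in sel)
        onsets = [r for r in sel if r.onset_time is not None]

        sr = compute_success_rate(responses, direction) if sel else float("nan")
        mot = compute_movement_onset_time(responses, direction)
        if mot is None:
            diags.append("movement_onset_time absent: no detectable onsets")
        me = compute_movement_error(responses, direction)
        if me is None:
            diags.append("movement_error absent: no misses")
        try:
            mv = compute_movement_variation(responses, direction, config.mv_mode)
        except ValueError as exc:
            mv = None
            diags.append(f"movement_variation absent: {exc}")

        per_direction[direction] = DirectionMetrics(
            direction=direction, success_rate=sr, movement_onset_time=mot,
            movement_error=me, movement_variation=mv,
            n_events=len(sel), n_caught=n_caught, n_missed=len(sel) - n_caught,
            n_onsets_detected=len(onsets), diagnostics=diags)

    return SessionMetrics(
        session_id=session.session_id, subject_id=session.subject_id,
        occasion=session.occasion, task_name=session.task_name,
        overall_success_rate=compute_success_rate(responses, None),
        per_direction=per_direction, config=config)
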