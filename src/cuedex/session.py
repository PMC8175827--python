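"""Domain types, coordinate conventions and log I/O for CUE game sessions.

A session is one 60 s recording of a target-catching game played by moving a
paddle along the bottom edge of the screen. Targets appear at random horizontal
positions at the top of the screen and fall to the bottom in 2 s; one *game
event* is the interval between a target's appearance and its disappearance.
All horizontal positions are dimensionless fractions of screen width in [0, 1]
(reports may display them as % of screen width).

Log formats
-----------
JSONL: one file. Line 1 is a header object with session metadata and screen
geometry, followed by one object per game event (``"record": "event"``), then
one object per trajectory sample (``"record": "sample"``). UTF-8, '.' decimal,
floats serialized to six decimal places in a fixed key order, so the writer is
canonical: the same session always produces identical bytes.

CSV: a directory holding ``events.csv`` and ``samples.csv``. Session metadata
and geometry are carried as ``# key=value`` comment lines at the top of
``events.csv``; both files then have ordinary header rows
(``event_index,appear_time,duration,target_x,direction_label`` and
``t,paddle_x``).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

__all__ = [
    "ScreenGeometry", "GameEvent", "TrajectorySample", "GameSession",
    "MovementResponse", "TASK_NAMES", "TASK_DIRECTIONS",
    "SessionValidationError", "SessionParseError",
    "read_session_log", "write_session_log", "validate_session",
]

#: The five instrumented object-manipulation tasks.
TASK_NAMES = ("peanut_ball", "soccer_ball", "tethered_tennis_ball", "cone", "ring")

#: Direction-label pair per task. Rolling tasks use roll-forward/roll-backward;
#: rotation tasks use concentric-pronation/eccentric-supination tags (for the
#: tethered tennis ball these correspond to ulnar/radial deviation, but the
#: same two-letter tags are kept for uniform table layout).
TASK_DIRECTIONS: dict[str, tuple[str, str]] = {
    "peanut_ball": ("RF", "RB"),
    "soccer_ball": ("RF", "RB"),
    "tethered_tennis_ball": ("CP", "ES"),
    "cone": ("CP", "ES"),
    "ring": ("CP", "ES"),
}


class SessionParseError(ValueError):
    """A session log file is malformed; the message names the offending line."""


class SessionValidationError(ValueError):
    """A session violates its invariants; the message lists the failed rules."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen coordinate conventions and capture-zone sizes.

    Positions are fractions of screen width in [0, 1]; y runs 0 (top) to
    1 (bottom). A target is caught when, at the moment it reaches the bottom,
    the paddle centre is within ``paddle_halfwidth + target_halfwidth`` of the
    target centre.
    """

    paddle_halfwidth: float = 0.05
    target_halfwidth: float = 0.04

    @property
    def capture_halfwidth(self) -> float:
        return self.paddle_halfwidth + self.target_halfwidth


@dataclass(frozen=True)
class GameEvent:
    """One falling target: appears at ``appear_time``, reaches the bottom
    ``duration`` seconds later at horizontal position ``target_x``."""

    event_index: int
    appear_time: float
    target_x: float
    direction_label: str
    duration: float = 2.0

    @property
    def end_time(self) -> float:
        return self.appear_time + self.duration


@dataclass(frozen=True)
class TrajectorySample:
    """One logged paddle position: time ``t`` (s from session start) and
    horizontal position ``paddle_x`` (fraction of screen width)."""

    t: float
    paddle_x: float


@dataclass
class GameSession:
    """One 60 s recording: event schedule plus the paddle trajectory."""

    session_id: str
    subject_id: str
    occasion: int
    task_name: str
    geometry: ScreenGeometry
    events: list[GameEvent]
    samples: list[TrajectorySample]
    sample_rate_hz: float = 50.0

    @property
    def duration(self) -> float:
        return max((e.end_time for e in self.events), default=0.0)

    def direction_labels(self) -> tuple[str, ...]:
        """Distinct direction labels in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.direction_label, None)
        return tuple(seen)


@dataclass
class MovementResponse:
    """One event's paddle trace, time-aligned to target appearance.

    ``t`` and ``x`` are the resampled trace on a fixed grid (seconds from
    appearance / fraction of screen width). ``miss_distance`` is present iff
    the target was not caught; ``onset_time`` is absent when no movement was
    detected. ``empty`` marks an event window that contained no samples.
    """

    event_index: int
    direction_label: str
    target_x: float
    t: "list[float]"
    x: "list[float]"
    caught: bool = False
    onset_time: float | None = None
    miss_distance: float | None = None
    empty: bool = False


# ---------------------------------------------------------------------------
# Validation

def validate_session(session: GameSession) -> list[str]:
    """Check every session invariant; return a list of issue descriptions.

    An empty list means the session is valid. Each issue names the field, the
    rule and the observed value. Never raises.
    """
    issues: list[str] = []
    geo = session.geometry

    if session.occasion not in (1, 2):
        issues.append(f"occasion: must be 1 or 2, got {session.occasion}")
    if session.task_name not in TASK_NAMES:
        issues.append(f"task_name: unknown task {session.task_name!r}")
    if not session.sample_rate_hz > 0:
        issues.append(f"sample_rate_hz: must be > 0, got {session.sample_rate_hz}")
    for name, hw in (("paddle_halfwidth", geo.paddle_halfwidth),
                     ("target_halfwidth", geo.target_halfwidth)):
        if not (0.0 < hw < 0.5):
            issues.append(f"geometry.{name}: must be in (0, 0.5), got {hw}")

    labels: dict[str, int] = {}
    prev_end = -math.inf
    prev_appear = -math.inf
    for e in session.events:
        if e.event_index < 0:
            issues.append(f"events[{e.event_index}].event_index: must be >= 0")
        if not e.duration > 0:
            issues.append(f"events[{e.event_index}].duration: must be > 0, got {e.duration}")
        if not (0.0 <= e.target_x <= 1.0):
            issues.append(f"events[{e.event_index}].target_x: target_x out of [0,1]: {e.target_x}")
        if e.appear_time < prev_appear:
            issues.append(
                f"events[{e.event_index}].appear_time: event order violated "
                f"({e.appear_time} after {prev_appear})")
        if e.appear_time < prev_end - 1e-9:
            issues.append(
                f"events[{e.event_index}].appear_time: overlaps previous event "
                f"(starts {e.appear_time}, previous ends {prev_end})")
        prev_appear = e.appear_time
        prev_end = e.end_time
        labels[e.direction_label] = labels.get(e.direction_label, 0) + 1

    if session.events:
        if len(labels) != 2:
            issues.append(
                f"events.direction_label: exactly two distinct labels required, "
                f"got {sorted(labels)}")
        elif len(set(labels.values())) != 1:
            issues.append(f"events.direction_label: direction imbalance {labels}")
        expected = TASK_DIRECTIONS.get(session.task_name)
        if expected is not None and set(labels) - set(expected):
            issues.append(
                f"events.direction_label: labels {sorted(labels)} do not match "
                f"task pair {expected}")

    prev_t = -math.inf
    for i, s in enumerate(session.samples):
        if s.t < prev_t:
            issues.append(f"samples[{i}].t: non-decreasing violated ({s.t} after {prev_t})")
        prev_t = s.t
        if not (0.0 <= s.paddle_x <= 1.0):
            issues.append(f"samples[{i}].paddle_x: out of [0,1]: {s.paddle_x}")

    if session.events and session.samples:
        if session.samples[0].t > 1e-9 or session.samples[-1].t < session.duration - 1e-9:
            issues.append(
                f"samples: must cover [0, {session.duration}], got "
                f"[{session.samples[0].t}, {session.samples[-1].t}]")

    return issues


def _require_valid(session: GameSession) -> None:
    issues = validate_session(session)
    if issues:
        raise SessionValidationError(
            "session failed validation:\n  " + "\n  ".join(issues))


# ---------------------------------------------------------------------------
# Canonical serialization helpers

_FLOAT_FMT = "{:.6f}"


def _f(x: float) -> float:
    # Quantize through the canonical decimal form so serialization is stable.
    return float(_FLOAT_FMT.format(float(x)))


def _header_dict(session: GameSession) -> dict:
    return {
        "record": "header",
        "session_id": session.session_id,
        "subject_id": session.subject_id,
        "occasion": session.occasion,
        "task_name": session.task_name,
        "sample_rate_hz": _f(session.sample_rate_hz),
        "paddle_halfwidth": _f(session.geometry.paddle_halfwidth),
        "target_halfwidth": _f(session.geometry.target_halfwidth),
    }


def _event_dict(e: GameEvent) -> dict:
    return {
        "record": "event",
        "event_index": e.event_index,
        "appear_time": _f(e.appear_time),
        "duration": _f(e.duration),
        "target_x": _f(e.target_x),
        "direction_label": e.direction_label,
    }


def _sample_dict(s: TrajectorySample) -> dict:
    return {"record": "sample", "t": _f(s.t), "paddle_x": _f(s.paddle_x)}


# ---------------------------------------------------------------------------
# Writers

def write_session_log(session: GameSession, path_or_stream, format: str = "jsonl") -> None:
    """Write a session log canonically (stable key order, 6-decimal floats).

    ``format='jsonl'`` writes one file (or text stream); ``format='csv'``
    treats ``path_or_stream`` as a directory and writes ``events.csv`` and
    ``samples.csv`` inside it. The session must pass :func:`validate_session`.
    """
    _require_valid(session)
    if format == "jsonl":
        _write_jsonl(session, path_or_stream)
    elif format == "csv":
        _write_csv(session, Path(path_or_stream))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")


def _write_jsonl(session: GameSession, path_or_stream) -> None:
    def dump(fh: IO[str]) -> None:
        fh.write(json.dumps(_header_dict(session)) + "\n")
        for e in session.events:
            fh.write(json.dumps(_event_dict(e)) + "\n")
        for s in session.samples:
            fh.write(json.dumps(_sample_dict(s)) + "\n")

    if hasattr(path_or_stream, "write"):
        dump(path_or_stream)
    else:
        with open(path_or_stream, "w", encoding="utf-8", newline="\n") as fh:
            dump(fh)


def _write_csv(session: GameSession, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    head = _header_dict(session)
    lines = [f"# {k}={head[k]}" for k in head if k != "record"]
    lines.append("event_index,appear_time,duration,target_x,direction_label")
    for e in session.events:
        d = _event_dict(e)
        lines.append(",".join(str(d[k]) for k in
                              ("event_index", "appear_time", "duration",
                               "target_x", "direction_label")))
    (directory / "events.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    lines = ["t,paddle_x"]
    for s in session.samples:
        d = _sample_dict(s)
        lines.append(f"{d['t']},{d['paddle_x']}")
    (directory / "samples.csv").write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Readers

def read_session_log(path_or_stream, format: str = "jsonl") -> GameSession:
    """Read and validate a session log; round-trips with :func:`write_session_log`.

    Raises :class:`SessionParseError` for malformed records (naming the line)
    and :class:`SessionValidationError` when invariants fail.
    """
    if format == "jsonl":
        session = _read_jsonl(path_or_stream)
    elif format == "csv":
        session = _read_csv(Path(path_or_stream))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")
    _require_valid(session)
    return session


def _build_session(head: dict, events: list[GameEvent],
                   samples: list[TrajectorySample]) -> GameSession:
    try:
        return GameSession(
            session_id=str(head["session_id"]),
            subject_id=str(head["subject_id"]),
            occasion=int(head["occasion"]),
            task_name=str(head["task_name"]),
            geometry=ScreenGeometry(
                paddle_halfwidth=float(head["paddle_halfwidth"]),
                target_halfwidth=float(head["target_halfwidth"]),
            ),
            events=events,
            samples=samples,
            sample_rate_hz=float(head["sample_rate_hz"]),
        )
    except KeyError as exc:
        raise SessionParseError(f"header missing field {exc}") from exc


def _read_jsonl(path_or_stream) -> GameSession:
    if hasattr(path_or_stream, "read"):
        lines = path_or_stream.read().splitlines()
    else:
        lines = Path(path_or_stream).read_text(encoding="utf-8").splitlines()

    head: dict | None = None
    events: list[GameEvent] = []
    samples: list[TrajectorySample] = []
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip():
            continue
        try:
            obj = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise SessionParseError(f"line {lineno}: invalid JSON: {exc}") from exc
        kind = obj.get("record")
        try:
            if kind == "header":
                head = obj
            elif kind == "event":
                events.append(GameEvent(
                    event_index=int(obj["event_index"]),
                    appear_time=float(obj["appear_time"]),
                    duration=float(obj["duration"]),
                    target_x=float(obj["target_x"]),
                    direction_label=str(obj["direction_label"]),
                ))
            elif kind == "sample":
                samples.append(TrajectorySample(t=float(obj["t"]),
                                                paddle_x=float(obj["paddle_x"])))
            else:
                raise SessionParseError(
                    f"line {lineno}: unknown record type {kind!r}")
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, SessionParseError):
                raise
            raise SessionParseError(f"line {lineno}: bad record: {exc}") from exc
    if head is None:
        raise SessionParseError("line 1: missing header record")
    return _build_session(head, events, samples)


def _read_csv(directory: Path) -> GameSession:
    events_path = directory / "events.csv"
    samples_path = directory / "samples.csv"
    head: dict = {}
    events: list[GameEvent] = []
    body_started = False
    for lineno, raw in enumerate(
            events_path.read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip():
            continue
        if raw.startswith("#"):
            try:
                key, val = raw[1:].strip().split("=", 1)
            except ValueError as exc:
                raise SessionParseError(
                    f"events.csv line {lineno}: bad metadata line {raw!r}") from exc
            head[key.strip()] = val.strip()
            continue
        if not body_started:
            body_started = True  # header row
            continue
        parts = raw.split(",")
        if len(parts) != 5:
            raise SessionParseError(
                f"events.csv line {lineno}: expected 5 fields, got {len(parts)}")
        try:
            events.append(GameEvent(
                event_index=int(parts[0]), appear_time=float(parts[1]),
                duration=float(parts[2]), target_x=float(parts[3]),
                direction_label=parts[4]))
        except ValueError as exc:
            raise SessionParseError(f"events.csv line {lineno}: {exc}") from exc

    samples: list[TrajectorySample] = []
    for lineno, raw in enumerate(
            samples_path.read_text(encoding="utf-8").splitlines(), start=1):
        if lineno == 1 or not raw.strip():
            continue
        parts = raw.split(",")
        if len(parts) != 2:
            raise SessionParseError(
                f"samples.csv line {lineno}: expected 2 fields, got {len(parts)}")
        try:
            samples.append(TrajectorySample(t=float(parts[0]), paddle_x=float(parts[1])))
        except ValueError as exc:
            raise SessionParseError(f"samples.csv line {lineno}: {exc}") from exc

    return _build_session(head, events, samples)
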