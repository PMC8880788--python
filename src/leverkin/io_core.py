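"""Reading and writing of lever-press event logs and forelimb trajectory tables.

The on-disk formats are plain delimited tables with headers:

* **Event logs** (one row per event): ``animal_id, time_s, kind, magnitude``.
  ``kind`` is ``press`` or ``reward``; ``magnitude`` is the integer reward
  level (1-5) for reward events and 0 for presses.  Times are seconds and must
  be strictly increasing within an animal.

* **Trajectory tables** (long format, one row per frame and limb):
  ``trial_id, frame, limb, x, y, score[, press]``.  Coordinates are image
  pixels (y grows downward; analyses that need "vertical position" negate y so
  up is positive), ``score`` is the tracker confidence in [0, 1], and
  ``press`` flags frames at which a lever-press was detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("leverkin")

LIMBS = ("dominant", "nondominant")
EVENT_COLUMNS = ("animal_id", "time_s", "kind", "magnitude")
TRAJ_COLUMNS = ("trial_id", "frame", "limb", "x", "y", "score")


class ParseError(ValueError):
    """A file row could not be parsed (reported with its line number)."""


class SchemaError(ValueError):
    """A required column is missing from a delimited table."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


@dataclass(frozen=True)
class Event:
    time: float
    kind: str  # "press" | "reward"
    magnitude: int = 0


@dataclass
class EventLog:
    """Ordered press/reward events for one animal."""

    animal_id: str
    events: list[Event]

    def validate(self) -> "EventLog":
        seen_press = False
        prev = -np.inf
        for i, ev in enumerate(self.events):
            if ev.kind not in ("press", "reward"):
                raise ValidationError(f"event {i}: unknown kind {ev.kind!r}")
            if not np.isfinite(ev.time) or ev.time <= prev:
                raise ValidationError(
                    f"event {i}: times must be strictly increasing "
                    f"({ev.time} after {prev})"
                )
            if ev.kind == "press":
                if ev.magnitude != 0:
                    raise ValidationError(f"event {i}: press with magnitude != 0")
                seen_press = True
            else:
                if not seen_press:
                    raise ValidationError(f"event {i}: reward before any press")
                if ev.magnitude < 1:
                    raise ValidationError(f"event {i}: reward with magnitude < 1")
            prev = ev.time
        return self

    @property
    def press_times(self) -> np.ndarray:
        return np.array([e.time for e in self.events if e.kind == "press"])

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class LimbData:
    """Per-frame tracker output for one forelimb (image coordinates)."""

    x: np.ndarray
    y: np.ndarray
    score: np.ndarray


@dataclass
class RawTrack:
    """Tracked 2-limb positions and confidences for a single trial."""

    trial_id: int
    limbs: dict[str, LimbData]
    press_frames: np.ndarray
    frame_rate: float = 30.0

    @property
    def n_frames(self) -> int:
        first = next(iter(self.limbs.values()))
        return len(first.x)

    def validate(self) -> "RawTrack":
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        n = self.n_frames
        for limb, d in self.limbs.items():
            if not (len(d.x) == len(d.y) == len(d.score) == n):
                raise ValidationError(
                    f"trial {self.trial_id}: unequal array lengths across limbs"
                )
            if np.any(d.score < 0) or np.any(d.score > 1):
                raise ValidationError(
                    f"trial {self.trial_id}, limb {limb}: scores outside [0, 1]"
                )
        pf = np.asarray(self.press_frames)
        if pf.size and (np.any(np.diff(pf) <= 0) or pf.min() < 0 or pf.max() >= n):
            raise ValidationError(
                f"trial {self.trial_id}: press_frames must be sorted and in bounds"
            )
        return self


# ---------------------------------------------------------------------------
# event logs


def _parse_events_frame(df: pd.DataFrame, path: str) -> list[EventLog]:
    logs = []
    for animal_id, grp in df.groupby("animal_id", sort=False):
        events = [
            Event(time=t, kind=k, magnitude=m)
            for t, k, m in zip(grp["time_s"], grp["kind"], grp["magnitude"])
        ]
        try:
            logs.append(EventLog(str(animal_id), events).validate())
        except ValidationError as err:
            raise ValidationError(f"{path}: animal {animal_id}: {err}") from err
    return logs


def read_event_logs(path: str | Path, dialect: Mapping | None = None) -> list[EventLog]:
    """Read a delimited event-log file, one :class:`EventLog` per animal."""
    sep = (dialect or {}).get("delimiter", ",")
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col, cast in (("time_s", float), ("magnitude", int)):
        try:
            df[col] = df[col].map(cast)
        except (TypeError, ValueError):  # locate the offending line for the report
            bad = df[col].map(lambda v: _fails(cast, v))
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ParseError(f"{path}, line {line}: cannot parse {col!r}") from None
    return _parse_events_frame(df, str(path))


def read_event_log(path: str | Path, dialect: Mapping | None = None) -> EventLog:
    """Read an event-log file that contains exactly one animal."""
    logs = read_event_logs(path, dialect)
    if len(logs) != 1:
        raise ValidationError(
            f"{path}: expected one animal, found {len(logs)}; use read_event_logs"
        )
    return logs[0]


def _fails(cast, value) -> bool:
    try:
        cast(value)
        return False
    except (TypeError, ValueError):
        return True


def write_event_log(logs: EventLog | Iterable[EventLog], path: str | Path) -> None:
    if isinstance(logs, EventLog):
        logs = [logs]
    rows = [
        (log.animal_id, ev.time, ev.kind, ev.magnitude)
        for log in logs
        for ev in log.events
    ]
    pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(
        path, index=False, float_format=_float_repr
    )


def _float_repr(v: float) -> str:
    """Shortest decimal representation that round-trips the float exactly."""
    return repr(float(v))


# ---------------------------------------------------------------------------
# trajectory tables


def read_trajectory_table(path: str | Path, dialect: Mapping | None = None) -> list[RawTrack]:
    """Read a long-format trajectory table into one :class:`RawTrack` per trial."""
    sep = (dialect or {}).get("delimiter", ",")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.duplicated(subset=["trial_id", "frame", "limb"]).any():
        raise ValidationError(f"{path}: duplicate (trial_id, frame, limb) rows")
    has_press = "press" in df.columns
    tracks = []
    for trial_id, grp in df.groupby("trial_id", sort=True):
        limbs: dict[str, LimbData] = {}
        n = None
        for limb, sub in grp.groupby("limb", sort=False):
            sub = sub.sort_values("frame")
            frames = sub["frame"].to_numpy()
            if not np.array_equal(frames, np.arange(len(frames))):
                raise ValidationError(
                    f"{path}: trial {trial_id}, limb {limb}: frames not contiguous from 0"
                )
            if n is None:
                n = len(frames)
            limbs[str(limb)] = LimbData(
                x=sub["x"].to_numpy(float),
                y=sub["y"].to_numpy(float),
                score=sub["score"].to_numpy(float),
            )
        if has_press:
            dom = grp[grp["limb"] == grp["limb"].iloc[0]].sort_values("frame")
            press_frames = dom.loc[dom["press"] > 0, "frame"].to_numpy(int)
        else:
            press_frames = np.array([], dtype=int)
        tracks.append(
            RawTrack(trial_id=trial_id, limbs=limbs, press_frames=press_frames).validate()
        )
    return tracks


def write_trajectory_table(tracks: Sequence[RawTrack], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        press = np.zeros(tr.n_frames, dtype=int)
        press[np.asarray(tr.press_frames, dtype=int)] = 1
        for limb, d in tr.limbs.items():
            frames.append(
                pd.DataFrame(
                    {
                        "trial_id": tr.trial_id,
                        "frame": np.arange(tr.n_frames),
                        "limb": limb,
                        "x": d.x,
                        "y": d.y,
                        "score": d.score,
                        "press": press,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_float_repr
    )


# ---------------------------------------------------------------------------
# config

def load_config(path: str | Path) -> dict:
    """Parse a flat ``key = value`` text file; numeric values are coerced."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}, line {lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        out[key] = _coerce(value)
    return out


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value.lower() in ("true", "false"):
        return value.lower() == "true"
    return value
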