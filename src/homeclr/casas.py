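"""Reading, cleaning, labeling and writing CASAS-style smart-home event logs.

A CASAS log is a plain-text file with one sensor firing per line::

    2010-11-04 08:33:52.929406 M018 ON Meal_Preparation begin
    2010-11-04 08:33:53.911115 M019 OFF

Fields are whitespace-delimited: date, time (microsecond precision),
sensor id (``M*`` motion, ``D*`` door, ``T*`` temperature), sensor state
(ON/OFF/OPEN/CLOSE or a numeric temperature reading), and an optional
activity annotation consisting of an activity name plus a ``begin`` or
``end`` marker. Only the first and last events of an activity episode are
annotated; the events in between inherit the label by bracket propagation
(:func:`propagate_activity_labels`).
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "Marker",
    "Modality",
    "SensorEvent",
    "SensorMap",
    "ParseReport",
    "MalformedLineError",
    "parse_casas_log",
    "clean_events",
    "propagate_activity_labels",
    "remap_milan_activities",
    "write_casas_log",
    "load_sensor_map",
    "packaged_sensor_map",
    "MILAN_ACTIVITY_MAP",
    "ARUBA_DROPPED_ACTIVITIES",
]


class Marker(str, Enum):
    begin = "begin"
    end = "end"


class Modality(str, Enum):
    motion = "motion"
    door = "door"
    temperature = "temperature"


_MODALITY_BY_PREFIX = {"M": Modality.motion, "D": Modality.door, "T": Modality.temperature}

# Accepted time formats: CASAS dialects write fractional seconds after "."
# (canonical) or ":"; some lines carry no fraction at all.
_TIME_FORMATS = ("%H:%M:%S.%f", "%H:%M:%S")


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped sensor firing, optionally annotated."""

    timestamp: datetime
    sensor_id: str
    state: str
    activity: str | None = None
    marker: Marker | None = None

    def __post_init__(self):
        if not self.sensor_id:
            raise ValueError("sensor_id must be non-empty")
        if self.marker is not None and self.activity is None:
            raise ValueError("a begin/end marker requires an activity name")

    @property
    def modality(self) -> Modality | None:
        return _MODALITY_BY_PREFIX.get(self.sensor_id[:1])


@dataclass
class SensorMap:
    """sensor_id -> (room location, modality), e.g. ``M018 -> (Kitchen, motion)``."""

    entries: dict[str, tuple[str, Modality]]

    def __post_init__(self):
        for sensor_id, (_, modality) in self.entries.items():
            inferred = _MODALITY_BY_PREFIX.get(sensor_id[:1])
            if inferred is not None and inferred != modality:
                raise ValueError(
                    f"sensor {sensor_id}: declared modality {modality.value!r} "
                    f"contradicts its id prefix ({inferred.value!r})"
                )

    def __contains__(self, sensor_id: str) -> bool:
        return sensor_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def location(self, sensor_id: str) -> str:
        return self.entries[sensor_id][0]

    def modality(self, sensor_id: str) -> Modality:
        return self.entries[sensor_id][1]

    @property
    def sensor_ids(self) -> list[str]:
        """Sensor ids in a stable, sorted order (defines feature indices)."""
        return sorted(self.entries)

    @property
    def locations(self) -> list[str]:
        """Distinct room names, sorted (defines location indices)."""
        return sorted({loc for loc, _ in self.entries.values()})

    def non_temperature(self) -> "SensorMap":
        return SensorMap(
            {s: lm for s, lm in self.entries.items() if lm[1] != Modality.temperature}
        )


class MalformedLineError(ValueError):
    def __init__(self, lineno: int, line: str, reason: str):
        self.lineno = lineno
        self.line = line
        self.reason = reason
        super().__init__(f"line {lineno}: {reason}: {line!r}")


@dataclass
class ParseReport:
    """Per-line rejects recorded while parsing in lenient mode."""

    rejects: list[tuple[int, str, str]] = field(default_factory=list)

    def add(self, lineno: int, line: str, reason: str):
        self.rejects.append((lineno, line, reason))

    def __len__(self) -> int:
        return len(self.rejects)


def _parse_timestamp(date_tok: str, time_tok: str) -> datetime:
    # normalize the ":"-separated fraction dialect to the "." canonical form
    if time_tok.count(":") == 3:
        head, frac = time_tok.rsplit(":", 1)
        time_tok = f"{head}.{frac}"
    for fmt in _TIME_FORMATS:
        try:
            return datetime.strptime(f"{date_tok} {time_tok}", f"%Y-%m-%d {fmt}")
        except ValueError:
            continue
    raise ValueError(f"unparseable timestamp {date_tok!r} {time_tok!r}")


def _parse_line(tokens: list[str], allow_bare_activity: bool) -> SensorEvent:
    n = len(tokens)
    if n < 4 or n > 6:
        raise ValueError(f"expected 4-6 fields, got {n}")
    timestamp = _parse_timestamp(tokens[0], tokens[1])
    sensor_id, state = tokens[2], tokens[3]
    activity = marker = None
    if n == 6:
        activity = tokens[4]
        try:
            marker = Marker(tokens[5].lower())
        except ValueError:
            raise ValueError(f"unknown activity status {tokens[5]!r}")
    elif n == 5:
        if not allow_bare_activity:
            raise ValueError("5-field line (activity without begin/end marker)")
        activity = tokens[4]
    return SensorEvent(timestamp, sensor_id, state, activity, marker)


def parse_casas_log(
    source: str | Path | TextIO | Iterable[str],
    *,
    strict: bool = False,
    allow_bare_activity: bool = False,
    report: ParseReport | None = None,
) -> list[SensorEvent]:
    """Parse a CASAS log into events, in file order.

    Malformed lines are recorded in ``report`` (if given) and skipped; with
    ``strict=True`` they raise :class:`MalformedLineError` instead. A
    5-field line (activity name without its begin/end marker) is malformed
    unless ``allow_bare_activity`` is set.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return parse_casas_log(
                fh, strict=strict, allow_bare_activity=allow_bare_activity, report=report
            )
    events: list[SensorEvent] = []
    for lineno, line in enumerate(source, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        try:
            events.append(_parse_line(stripped.split(), allow_bare_activity))
        except ValueError as exc:
            if strict:
                raise MalformedLineError(lineno, stripped, str(exc)) from exc
            if report is not None:
                report.add(lineno, stripped, str(exc))
            logger.debug("rejected line %d: %s", lineno, exc)
    return events


def clean_events(
    events: Sequence[SensorEvent], *, drop_temperature: bool = True
) -> list[SensorEvent]:
    """Deduplicate, drop temperature readings, and time-sort an event stream.

    A duplicate is a repeat of an already-seen (timestamp, sensor_id, state)
    triple, regardless of annotation differences. Sorting is stable, so
    equal timestamps keep file order. The operation is idempotent.
    """
    removed = Counter()
    seen: set[tuple[datetime, str, str]] = set()
    kept: list[SensorEvent] = []
    for ev in events:
        if not ev.sensor_id or not ev.state:
            removed["missing_field"] += 1
            continue
        if drop_temperature and ev.modality == Modality.temperature:
            removed["temperature"] += 1
            continue
        key = (ev.timestamp, ev.sensor_id, ev.state)
        if key in seen:
            removed["duplicate"] += 1
            continue
        seen.add(key)
        kept.append(ev)
    kept.sort(key=lambda ev: ev.timestamp)  # stable: ties keep file order
    if removed:
        logger.info("clean_events removed %s", dict(removed))
    return kept


def propagate_activity_labels(
    events: Sequence[SensorEvent],
) -> list[tuple[SensorEvent, str | None]]:
    """Expand begin/end annotation brackets into per-event labels.

    Every event from ``X begin`` to the matching ``X end`` (inclusive)
    is labeled ``X``. Brackets that nest or interleave are resolved
    innermost-wins (the most recently opened activity claims the event),
    with a warning. An unmatched ``begin`` is closed at the last event; an
    ``end`` without a matching ``begin`` leaves its event unlabeled. Event
    count and order are never changed.
    """
    out: list[tuple[SensorEvent, str | None]] = []
    open_stack: list[str] = []  # innermost-active activity is last
    for ev in events:
        if ev.marker is Marker.begin:
            if open_stack:
                logger.warning(
                    "activity %r begins inside open bracket(s) %s; innermost wins",
                    ev.activity,
                    open_stack,
                )
            open_stack.append(ev.activity)
            out.append((ev, ev.activity))
        elif ev.marker is Marker.end:
            if ev.activity in open_stack:
                open_stack.remove(ev.activity)
                out.append((ev, ev.activity))
            else:
                logger.warning("end of %r with no matching begin", ev.activity)
                out.append((ev, None))
        else:
            out.append((ev, open_stack[-1] if open_stack else None))
    if open_stack:
        logger.warning("unclosed activity bracket(s) at end of stream: %s", open_stack)
    return out


#: Raw Milan annotations -> consolidated activity-of-daily-living categories.
MILAN_ACTIVITY_MAP: dict[str, str] = {
    "Read": "Relax",
    "Watch_TV": "Relax",
    "Morning_Meds": "Medication",
    "Eve_Meds": "Medication",
    "Master_Bathroom": "Bathing",
    "Guest_Bathroom": "Bathing",
    "Desk_Activity": "Work",
    "Chores": "Work",
    "Meditate": "Other",
    "Master_Bedroom_Activity": "Other",
    "Dining_Rm_Activity": "Eating",
    "Kitchen_Activity": "Meal_Preparation",
    "Sleep": "Sleeping",
    "Bed_to_Toilet": "Bed_to_Toilet",
    "Leave_Home": "Leave_Home",
}

#: Canonical consolidated categories (targets of the Milan remapping).
_MILAN_CANONICAL = {
    "Meal_Preparation",
    "Relax",
    "Eating",
    "Work",
    "Sleeping",
    "Bed_to_Toilet",
    "Leave_Home",
    "Medication",
    "Bathing",
    "Other",
}

#: Aruba-1 activities removed before modeling (too few episodes).
ARUBA_DROPPED_ACTIVITIES = frozenset({"Resperate"})


def remap_milan_activities(label: str | None, *, on_unknown: str = "other") -> str:
    """Map a raw Milan annotation onto its consolidated category.

    Unlabeled events (``None``) map to ``"Other"`` — idle time between
    annotated episodes. Unknown raw labels map to ``"Other"`` by default or
    raise with ``on_unknown="raise"``.
    """
    if label is None:
        return "Other"
    # tolerate space-separated raw names as they appear in the annotations
    key = label.replace(" ", "_")
    if key in MILAN_ACTIVITY_MAP:
        return MILAN_ACTIVITY_MAP[key]
    if key in _MILAN_CANONICAL:
        return key
    if on_unknown == "raise":
        raise KeyError(f"unknown Milan activity {label!r}")
    return "Other"


def format_event(ev: SensorEvent) -> str:
    ts = ev.timestamp.strftime("%Y-%m-%d %H:%M:%S.%f")
    parts = [ts, ev.sensor_id, ev.state]
    if ev.activity is not None and ev.marker is not None:
        parts += [ev.activity, ev.marker.value]
    return " ".join(parts)


def write_casas_log(events: Sequence[SensorEvent], path: str | Path | TextIO) -> None:
    """Write events in the canonical CASAS text format (byte-stable)."""
    if not isinstance(path, io.TextIOBase):
        with open(path, "w", encoding="utf-8") as fh:
            write_casas_log(events, fh)
            return
    for ev in events:
        path.write(format_event(ev) + "\n")


# -- sensor maps ------------------------------------------------------------

def load_sensor_map(path: str | Path | TextIO) -> SensorMap:
    """Read a sensor map from a 3-column TSV: sensor_id, location, modality."""
    if isinstance(path, (str, Path)):
        with open(path, "r", encoding="utf-8") as fh:
            return load_sensor_map(fh)
    entries: dict[str, tuple[str, Modality]] = {}
    for line in path:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sensor_id, location, modality = line.split("\t")
        if sensor_id in entries:
            raise ValueError(f"duplicate sensor id {sensor_id!r} in sensor map")
        entries[sensor_id] = (location, Modality(modality))
    return SensorMap(entries)


def packaged_sensor_map(name: str) -> SensorMap:
    """Load one of the packaged testbed sensor maps (``"aruba"`` or ``"milan"``)."""
    resource = Path(__file__).parent / "data" / f"{name.lower()}_sensors.tsv"
    if not resource.exists():
        raise KeyError(f"no packaged sensor map named {name!r}")
    return load_sensor_map(resource)
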