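"""Canonical event-stream types plus CSV/JSON readers and writers.

All timestamps are UTC epoch milliseconds (``int``).  Per-day statistics in
downstream modules interpret times through a per-subject timezone offset
carried on :class:`SubjectStream` (``tz_offset_hours``); the offset defaults
to 0 (UTC days).

On disk a subject is either a directory of per-kind CSV files
(``accel.csv``, ``gps.csv``, ``wifi.csv``, ``comm.csv``, ``calendar.csv``,
``phoneuse.csv``, ``sessions.csv``, ``phq9.csv`` plus ``subject.json``) or a
single JSON document.  Both round-trip losslessly.
"""

from __future__ import annotations

import csv
import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Callable, Iterable, Sequence

MS_PER_SEC = 1_000
MS_PER_MIN = 60_000
MS_PER_HOUR = 3_600_000
MS_PER_DAY = 86_400_000
_EPOCH = date(1970, 1, 1)

WINDOW_DURATION_S = 120
PHQ9_MAX = 27
PHQ9_CUTOFF = 11  # clinical flag: score >= 11

#: Local-hour boundaries of the calendar day slots.  Hours outside every
#: interval (late night, [0, 5)) fold into "evening".
SLOT_BOUNDS: dict[str, tuple[float, float]] = {
    "morning": (5.0, 12.0),
    "afternoon": (12.0, 18.0),
    "evening": (18.0, 24.0),
}
SLOTS = ("morning", "afternoon", "evening")


class SchemaError(ValueError):
    """A persisted file is missing mandatory columns or fields."""


class StreamValidationError(ValueError):
    """An event or stream violates a domain invariant."""

    def __init__(self, stream: str, message: str, row: int | None = None):
        self.stream = stream
        self.row = row
        loc = stream if row is None else f"{stream} row {row}"
        super().__init__(f"{loc}: {message}")


# ---------------------------------------------------------------------------
# local-time helpers
# ---------------------------------------------------------------------------

def to_local_ms(t: int, tz_offset_hours: float = 0.0) -> int:
    return t + round(tz_offset_hours * MS_PER_HOUR)


def local_date(t: int, tz_offset_hours: float = 0.0) -> date:
    """Calendar date of an epoch-ms timestamp in the subject's local time."""
    return _EPOCH + timedelta(days=to_local_ms(t, tz_offset_hours) // MS_PER_DAY)


def day_start_ms(day: date, tz_offset_hours: float = 0.0) -> int:
    """UTC epoch ms at local midnight opening ``day``."""
    return (day - _EPOCH).days * MS_PER_DAY - round(tz_offset_hours * MS_PER_HOUR)


def local_hour(t: int, tz_offset_hours: float = 0.0) -> float:
    return (to_local_ms(t, tz_offset_hours) % MS_PER_DAY) / MS_PER_HOUR


def slot_of(t: int, tz_offset_hours: float = 0.0,
            bounds: dict[str, tuple[float, float]] = SLOT_BOUNDS) -> str:
    h = local_hour(t, tz_offset_hours)
    for name, (lo, hi) in bounds.items():
        if lo <= h < hi:
            return name
    return "evening"


# ---------------------------------------------------------------------------
# event types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class AccelSample:
    """One tri-axial accelerometer reading (nominal 100 Hz per axis)."""
    t: int
    ax: float
    ay: float
    az: float


@dataclass(frozen=True, slots=True)
class ActivityWindow:
    """A 2-minute activity window summarised by the standard deviation of
    the gravity-corrected acceleration-norm signal."""
    start: int
    stdev_norm: float
    is_walking: bool
    duration_s: int = WINDOW_DURATION_S

    def __post_init__(self):
        if self.stdev_norm < 0:
            raise StreamValidationError("accel", f"stdev_norm must be >= 0, got {self.stdev_norm}")

    @property
    def t(self) -> int:  # uniform sort key
        return self.start


@dataclass(frozen=True, slots=True)
class GpsFix:
    t: int
    lat: float
    lon: float

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise StreamValidationError("gps", f"latitude out of bounds: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise StreamValidationError("gps", f"longitude out of bounds: {self.lon}")


@dataclass(frozen=True, slots=True)
class WifiScan:
    """A 15-minute-cadence scan of surrounding hotspot identifiers."""
    t: int
    bssids: frozenset[str] = frozenset()


@dataclass(frozen=True, slots=True)
class CommEvent:
    t: int
    kind: str            # {"call", "sms"}
    direction: str       # {"in", "out"}
    contact: str
    duration_s: float | None = None  # calls only

    def __post_init__(self):
        if self.kind not in ("call", "sms"):
            raise StreamValidationError("comm", f"unknown kind {self.kind!r}")
        if self.direction not in ("in", "out"):
            raise StreamValidationError("comm", f"unknown direction {self.direction!r}")
        if self.kind == "call":
            if self.duration_s is None or self.duration_s < 0:
                raise StreamValidationError("comm", "calls require duration_s >= 0")
        elif self.duration_s is not None:
            raise StreamValidationError("comm", "sms must not carry a duration")


@dataclass(frozen=True, slots=True)
class CalendarEvent:
    t_start: int
    slot: str

    def __post_init__(self):
        if self.slot not in SLOTS:
            raise StreamValidationError("calendar", f"unknown slot {self.slot!r}")

    @property
    def t(self) -> int:
        return self.t_start

    @classmethod
    def at(cls, t_start: int, tz_offset_hours: float = 0.0) -> "CalendarEvent":
        """Build an event with the slot derived from its start time."""
        return cls(t_start, slot_of(t_start, tz_offset_hours))


@dataclass(frozen=True, slots=True)
class PhoneUseInterval:
    """An unlocked interval; ``in_moss_app`` seconds are excluded from the
    phone-usage feature."""
    t_unlock: int
    t_lock: int
    in_moss_app: float = 0.0

    def __post_init__(self):
        if self.t_lock <= self.t_unlock:
            raise StreamValidationError("phoneuse", "t_lock must be > t_unlock")
        span_s = (self.t_lock - self.t_unlock) / MS_PER_SEC
        if not 0.0 <= self.in_moss_app <= span_s + 1e-9:
            raise StreamValidationError(
                "phoneuse", f"in_moss_app {self.in_moss_app} outside [0, {span_s}]")

    @property
    def t(self) -> int:
        return self.t_unlock


@dataclass(frozen=True, slots=True)
class AppSession:
    t: int
    interventions_executed: int = 0

    def __post_init__(self):
        if self.interventions_executed < 0:
            raise StreamValidationError("sessions", "interventions_executed must be >= 0")

    @property
    def qualifies(self) -> bool:
        """One app use = at least one intervention execution in the session."""
        return self.interventions_executed >= 1


@dataclass(frozen=True, slots=True)
class Phq9Record:
    t: int
    score: int

    def __post_init__(self):
        if not 0 <= self.score <= PHQ9_MAX:
            raise StreamValidationError("phq9", f"score out of range: {self.score}")

    @property
    def clinical(self) -> bool:
        return self.score >= PHQ9_CUTOFF


@dataclass
class SubjectStream:
    """All timestamped events for one subject, per-kind and time-sorted."""

    subject_id: str
    enrollment: int
    tz_offset_hours: float = 0.0
    windows: list[ActivityWindow] = field(default_factory=list)
    gps: list[GpsFix] = field(default_factory=list)
    wifi: list[WifiScan] = field(default_factory=list)
    comm: list[CommEvent] = field(default_factory=list)
    calendar: list[CalendarEvent] = field(default_factory=list)
    phone_use: list[PhoneUseInterval] = field(default_factory=list)
    sessions: list[AppSession] = field(default_factory=list)
    phq9: list[Phq9Record] = field(default_factory=list)

    def _kinds(self) -> dict[str, list]:
        return {
            "accel": self.windows, "gps": self.gps, "wifi": self.wifi,
            "comm": self.comm, "calendar": self.calendar,
            "phoneuse": self.phone_use, "sessions": self.sessions,
            "phq9": self.phq9,
        }

    def validate(self, walking_threshold: float = 1.5) -> "SubjectStream":
        """Check ordering, enrollment and per-type invariants; return self."""
        for name, events in self._kinds().items():
            prev = None
            for i, ev in enumerate(events):
                if ev.t < self.enrollment:
                    raise StreamValidationError(
                        name, f"event at {ev.t} precedes enrollment {self.enrollment}", row=i)
                if prev is not None and ev.t < prev:
                    raise StreamValidationError(name, "timestamps not sorted", row=i)
                prev = ev.t
        for i, w in enumerate(self.windows):
            if w.is_walking and w.stdev_norm < walking_threshold:
                raise StreamValidationError(
                    "accel", f"is_walking set but stdev_norm {w.stdev_norm} < {walking_threshold}",
                    row=i)
        return self

    def local_dates(self) -> list[date]:
        """Consecutive local calendar dates from enrollment through the last event."""
        last = max((ev.t for evs in self._kinds().values() for ev in evs),
                   default=self.enrollment)
        d0 = local_date(self.enrollment, self.tz_offset_hours)
        d1 = local_date(last, self.tz_offset_hours)
        return [d0 + timedelta(days=k) for k in range((d1 - d0).days + 1)]


def events_in(events: Sequence, lo: int, hi: int) -> list:
    """Events with lo <= t < hi from a time-sorted sequence (bisect slice)."""
    i = bisect_left(events, lo, key=lambda e: e.t)
    j = bisect_left(events, hi, key=lambda e: e.t)
    return list(events[i:j])


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_CSV_SCHEMAS: dict[str, tuple[str, list[str]]] = {
    "accel": ("accel.csv", ["start_ms", "duration_s", "stdev_norm", "is_walking"]),
    "gps": ("gps.csv", ["t_ms", "lat", "lon"]),
    "wifi": ("wifi.csv", ["t_ms", "bssids"]),
    "comm": ("comm.csv", ["t_ms", "kind", "direction", "contact", "duration_s"]),
    "calendar": ("calendar.csv", ["t_start_ms", "slot"]),
    "phoneuse": ("phoneuse.csv", ["t_unlock_ms", "t_lock_ms", "in_moss_app_s"]),
    "sessions": ("sessions.csv", ["t_ms", "interventions_executed"]),
    "phq9": ("phq9.csv", ["t_ms", "score"]),
}


def _fmt(x: float) -> str:
    return repr(float(x))


def _rows_for(kind: str, stream: SubjectStream) -> Iterable[list[str]]:
    if kind == "accel":
        for w in stream.windows:
            yield [str(w.start), str(w.duration_s), _fmt(w.stdev_norm), str(int(w.is_walking))]
    elif kind == "gps":
        for f in stream.gps:
            yield [str(f.t), _fmt(f.lat), _fmt(f.lon)]
    elif kind == "wifi":
        for s in stream.wifi:
            yield [str(s.t), ";".join(sorted(s.bssids))]
    elif kind == "comm":
        for c in stream.comm:
            yield [str(c.t), c.kind, c.direction, c.contact,
                   "" if c.duration_s is None else _fmt(c.duration_s)]
    elif kind == "calendar":
        for e in stream.calendar:
            yield [str(e.t_start), e.slot]
    elif kind == "phoneuse":
        for p in stream.phone_use:
            yield [str(p.t_unlock), str(p.t_lock), _fmt(p.in_moss_app)]
    elif kind == "sessions":
        for s in stream.sessions:
            yield [str(s.t), str(s.interventions_executed)]
    elif kind == "phq9":
        for r in stream.phq9:
            yield [str(r.t), str(r.score)]


def _parse_row(kind: str, row: dict[str, str], rownum: int):
    try:
        if kind == "accel":
            return ActivityWindow(start=int(row["start_ms"]),
                                  duration_s=int(row["duration_s"]),
                                  stdev_norm=float(row["stdev_norm"]),
                                  is_walking=bool(int(row["is_walking"])))
        if kind == "gps":
            return GpsFix(t=int(row["t_ms"]), lat=float(row["lat"]), lon=float(row["lon"]))
        if kind == "wifi":
            raw = row["bssids"]
            bssids = frozenset(b for b in raw.split(";") if b) if raw else frozenset()
            return WifiScan(t=int(row["t_ms"]), bssids=bssids)
        if kind == "comm":
            dur = row["duration_s"]
            return CommEvent(t=int(row["t_ms"]), kind=row["kind"], direction=row["direction"],
                             contact=row["contact"],
                             duration_s=float(dur) if dur not in ("", None) else None)
        if kind == "calendar":
            return CalendarEvent(t_start=int(row["t_start_ms"]), slot=row["slot"])
        if kind == "phoneuse":
            return PhoneUseInterval(t_unlock=int(row["t_unlock_ms"]),
                                    t_lock=int(row["t_lock_ms"]),
                                    in_moss_app=float(row["in_moss_app_s"]))
        if kind == "sessions":
            return AppSession(t=int(row["t_ms"]),
                              interventions_executed=int(row["interventions_executed"]))
        if kind == "phq9":
            return Phq9Record(t=int(row["t_ms"]), score=int(row["score"]))
    except StreamValidationError as exc:
        raise StreamValidationError(kind, str(exc).split(": ", 1)[-1], row=rownum) from exc
    except (KeyError, ValueError, TypeError) as exc:
        raise StreamValidationError(kind, f"malformed row: {exc}", row=rownum) from exc
    raise ValueError(f"unknown stream kind {kind!r}")


def write_stream(stream: SubjectStream, path: str | Path, format: str = "csv-set") -> None:
    path = Path(path)
    if format == "csv-set":
        path.mkdir(parents=True, exist_ok=True)
        meta = {"subject_id": stream.subject_id, "enrollment_ms": stream.enrollment,
                "tz_offset_hours": stream.tz_offset_hours}
        (path / "subject.json").write_text(json.dumps(meta, indent=1))
        for kind, (fname, header) in _CSV_SCHEMAS.items():
            with open(path / fname, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(header)
                writer.writerows(_rows_for(kind, stream))
    elif format == "json":
        doc = stream_to_dict(stream)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_stream(path: str | Path, format: str = "csv-set") -> SubjectStream:
    path = Path(path)
    if format == "json":
        return stream_from_dict(json.loads(path.read_text())).validate()
    if format != "csv-set":
        raise ValueError(f"unknown format {format!r}")
    meta_path = path / "subject.json"
    if not meta_path.exists():
        raise SchemaError(f"missing subject.json in {path}")
    meta = json.loads(meta_path.read_text())
    stream = SubjectStream(subject_id=str(meta["subject_id"]),
                           enrollment=int(meta["enrollment_ms"]),
                           tz_offset_hours=float(meta.get("tz_offset_hours", 0.0)))
    dest = stream._kinds()
    for kind, (fname, header) in _CSV_SCHEMAS.items():
        fpath = path / fname
        if not fpath.exists():
            continue  # an absent file is an empty stream
        with open(fpath, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not set(header) <= set(reader.fieldnames):
                missing = set(header) - set(reader.fieldnames or [])
                raise SchemaError(f"{fname}: missing mandatory columns {sorted(missing)}")
            for rownum, row in enumerate(reader, start=2):
                dest[kind].append(_parse_row(kind, row, rownum))
    return stream.validate()


# -- JSON codec --------------------------------------------------------------

def stream_to_dict(stream: SubjectStream) -> dict:
    return {
        "subject_id": stream.subject_id,
        "enrollment_ms": stream.enrollment,
        "tz_offset_hours": stream.tz_offset_hours,
        "accel": [[w.start, w.duration_s, w.stdev_norm, int(w.is_walking)]
                  for w in stream.windows],
        "gps": [[f.t, f.lat, f.lon] for f in stream.gps],
        "wifi": [[s.t, sorted(s.bssids)] for s in stream.wifi],
        "comm": [[c.t, c.kind, c.direction, c.contact, c.duration_s] for c in stream.comm],
        "calendar": [[e.t_start, e.slot] for e in stream.calendar],
        "phoneuse": [[p.t_unlock, p.t_lock, p.in_moss_app] for p in stream.phone_use],
        "sessions": [[s.t, s.interventions_executed] for s in stream.sessions],
        "phq9": [[r.t, r.score] for r in stream.phq9],
    }


def stream_from_dict(doc: dict) -> SubjectStream:
    try:
        return SubjectStream(
            subject_id=str(doc["subject_id"]),
            enrollment=int(doc["enrollment_ms"]),
            tz_offset_hours=float(doc.get("tz_offset_hours", 0.0)),
            windows=[ActivityWindow(start=a, duration_s=d, stdev_norm=s, is_walking=bool(k))
                     for a, d, s, k in doc.get("accel", [])],
            gps=[GpsFix(t, lat, lon) for t, lat, lon in doc.get("gps", [])],
            wifi=[WifiScan(t, frozenset(b)) for t, b in doc.get("wifi", [])],
            comm=[CommEvent(t, k, dr, c, dur) for t, k, dr, c, dur in doc.get("comm", [])],
            calendar=[CalendarEvent(t, s) for t, s in doc.get("calendar", [])],
            phone_use=[PhoneUseInterval(u, l, m) for u, l, m in doc.get("phoneuse", [])],
            sessions=[AppSession(t, n) for t, n in doc.get("sessions", [])],
            phq9=[Phq9Record(t, s) for t, s in doc.get("phq9", [])],
        )
    except KeyError as exc:
        raise SchemaError(f"subject document missing field {exc}") from exc
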