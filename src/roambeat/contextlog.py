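"""Persistent log of beats, inferred activities and person events.

The store answers the four context questions -- identity (which artifact or
person), location (on the base location vs. roaming, read straight off the
beat direction), time (the beat's stamp) and activity (the inferred instance
that owns the beat, if any) -- and exports *activity representations*: the
ordered list of video frame indexes linked to an activity's beats, optionally
with the frame at the episode's temporal midpoint as an illustrative
mid-activity image.

Backend: a single-file embedded SQLite database (schema versioned) plus JSONL
export.  Appends are idempotent on the natural key of each record kind, so
re-running a pipeline against the same store cannot duplicate rows.

Person events (an RFID tag read at the room door) share the gain/loss ->
presence convention but are context only; they never feed activity criteria.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .beats import Beat, BeatSeries, FrameClock, link_frames
from .engine import ActivityInstance

__all__ = [
    "SCHEMA_VERSION",
    "PersonEvent",
    "LogRecord",
    "RepresentationBundle",
    "EventStore",
    "location_after",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PersonEvent:
    """A person's tag gained or lost at the room door."""

    person_id: str
    t: float
    direction: str  # "gain" (entered range) or "loss" (left range)

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")


@dataclass(frozen=True)
class LogRecord:
    """One stored item: a beat, an activity instance, or a person event."""

    record_kind: str  # beat | activity | person_event
    payload: object
    run_id: str

    def __post_init__(self) -> None:
        expected = {"beat": Beat, "activity": ActivityInstance, "person_event": PersonEvent}
        if self.record_kind not in expected:
            raise ValueError(f"unknown record_kind {self.record_kind!r}")
        if not isinstance(self.payload, expected[self.record_kind]):
            raise ValueError(
                f"payload type {type(self.payload).__name__} does not match "
                f"record_kind {self.record_kind!r}"
            )


@dataclass
class RepresentationBundle:
    """Beat-linked frame references for one inferred activity."""

    activity: ActivityInstance
    frames: list  # ordered (beat t, frame_index)
    midpoint_frame: int | None = None


def location_after(beat: Beat) -> str:
    """Artifact location implied by a beat: on the base location or roaming."""
    return "base" if beat.direction == "to_base" else "roaming"


class EventStore:
    """Embedded relational store for beats, activities and person events."""

    def __init__(self, path=":memory:") -> None:
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)
        self._conn.execute("PRAGMA journal_mode=MEMORY")
        self._init_schema()

    def _init_schema(self) -> None:
        cur = self._conn.cursor()
        cur.executescript(
            """
            CREATE TABLE IF NOT EXISTS meta (
                key TEXT PRIMARY KEY, value TEXT
            );
            CREATE TABLE IF NOT EXISTS beats (
                id INTEGER PRIMARY KEY,
                run_id TEXT NOT NULL,
                t REAL NOT NULL,
                artifact_id TEXT NOT NULL,
                direction TEXT NOT NULL,
                technology TEXT,
                frame_index INTEGER,
                UNIQUE (run_id, artifact_id, t, direction)
            );
            CREATE TABLE IF NOT EXISTS activities (
                id INTEGER PRIMARY KEY,
                run_id TEXT NOT NULL,
                name TEXT NOT NULL,
                start_t REAL NOT NULL,
                end_t REAL NOT NULL,
                inferred_at REAL NOT NULL,
                satisfied TEXT NOT NULL,
                beats TEXT NOT NULL,
                UNIQUE (run_id, name, inferred_at)
            );
            CREATE TABLE IF NOT EXISTS person_events (
                id INTEGER PRIMARY KEY,
                run_id TEXT NOT NULL,
                t REAL NOT NULL,
                person_id TEXT NOT NULL,
                direction TEXT NOT NULL,
                UNIQUE (run_id, person_id, t, direction)
            );
            """
        )
        cur.execute(
            "INSERT OR IGNORE INTO meta (key, value) VALUES ('schema_version', ?)",
            (str(SCHEMA_VERSION),),
        )
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "EventStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- writing -----------------------------------------------------------

    def record(self, item, run_id: str = "default") -> bool:
        """Durably append one Beat / ActivityInstance / PersonEvent.

        Idempotent: re-recording an identical item is a no-op.  Returns True
        when a new row was written.
        """
        cur = self._conn.cursor()
        if isinstance(item, Beat):
            cur.execute(
                "INSERT OR IGNORE INTO beats "
                "(run_id, t, artifact_id, direction, technology, frame_index) "
                "VALUES (?, ?, ?, ?, ?, ?)",
                (run_id, item.t, item.artifact_id, item.direction, item.technology,
                 item.frame_index),
            )
        elif isinstance(item, ActivityInstance):
            cur.execute(
                "INSERT OR IGNORE INTO activities "
                "(run_id, name, start_t, end_t, inferred_at, satisfied, beats) "
                "VALUES (?, ?, ?, ?, ?, ?, ?)",
                (
                    run_id,
                    item.name,
                    item.start_t,
                    item.end_t,
                    item.inferred_at,
                    json.dumps(list(item.satisfied_artifacts)),
                    json.dumps(
                        [
                            {
                                "t": b.t,
                                "artifact_id": b.artifact_id,
                                "direction": b.direction,
                                "technology": b.technology,
                                "frame_index": b.frame_index,
                            }
                            for b in item.beats
                        ]
                    ),
                ),
            )
        elif isinstance(item, PersonEvent):
            cur.execute(
                "INSERT OR IGNORE INTO person_events (run_id, t, person_id, direction) "
                "VALUES (?, ?, ?, ?)",
                (run_id, item.t, item.person_id, item.direction),
            )
        else:
            raise TypeError(f"cannot record {type(item).__name__}")
        self._conn.commit()
        return cur.rowcount > 0

    def record_many(self, items: Iterable, run_id: str = "default") -> int:
        return sum(1 for item in items if self.record(item, run_id=run_id))

    # -- querying ----------------------------------------------------------

    def query(
        self,
        t_min: float | None = None,
        t_max: float | None = None,
        activity: str | None = None,
        artifact_id: str | None = None,
        run_id: str | None = None,
    ) -> list:
        """Time-ordered LogRecords matching every given filter.

        The artifact filter selects beat records; the activity filter selects
        activity records (each filter restricts the record kinds that can
        carry it).  With no filters, everything comes back.
        """
        records: list[tuple[float, int, LogRecord]] = []

        def clauses(extra: str = "") -> tuple:
            conds = []
            args: list = []
            if run_id is not None:
                conds.append("run_id = ?")
                args.append(run_id)
            if t_min is not None:
                conds.append(f"{extra} >= ?")
                args.append(t_min)
            if t_max is not None:
                conds.append(f"{extra} <= ?")
                args.append(t_max)
            return conds, args

        if activity is None:
            conds, args = clauses("t")
            if artifact_id is not None:
                conds.append("artifact_id = ?")
                args.append(artifact_id)
            where = (" WHERE " + " AND ".join(conds)) if conds else ""
            for row in self._conn.execute(
                "SELECT run_id, t, artifact_id, direction, technology, frame_index "
                f"FROM beats{where} ORDER BY t, artifact_id",
                args,
            ):
                beat = Beat(
                    artifact_id=row[2],
                    t=row[1],
                    direction=row[3],
                    technology=row[4],
                    frame_index=row[5],
                )
                records.append((beat.t, 0, LogRecord("beat", beat, row[0])))

        if artifact_id is None:
            conds, args = clauses("start_t")
            if activity is not None:
                conds.append("name = ?")
                args.append(activity)
            where = (" WHERE " + " AND ".join(conds)) if conds else ""
            for row in self._conn.execute(
                "SELECT run_id, name, start_t, end_t, inferred_at, satisfied, beats "
                f"FROM activities{where} ORDER BY start_t, name",
                args,
            ):
                inst = self._row_to_instance(row[1:])
                records.append((inst.start_t, 1, LogRecord("activity", inst, row[0])))

        if activity is None and artifact_id is None:
            conds, args = clauses("t")
            where = (" WHERE " + " AND ".join(conds)) if conds else ""
            for row in self._conn.execute(
                "SELECT run_id, t, person_id, direction "
                f"FROM person_events{where} ORDER BY t, person_id",
                args,
            ):
                ev = PersonEvent(person_id=row[2], t=row[1], direction=row[3])
                records.append((ev.t, 2, LogRecord("person_event", ev, row[0])))

        records.sort(key=lambda r: (r[0], r[1]))
        return [rec for _, _, rec in records]

    def count(self, table: str = "beats") -> int:
        if table not in ("beats", "activities", "person_events"):
            raise ValueError(f"unknown table {table!r}")
        (n,) = self._conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()
        return int(n)

    def activity_ids(self, run_id: str | None = None) -> list:
        where = "" if run_id is None else " WHERE run_id = ?"
        args = () if run_id is None else (run_id,)
        return [
            int(row[0])
            for row in self._conn.execute(
                f"SELECT id FROM activities{where} ORDER BY inferred_at", args
            )
        ]

    def get_activity(self, instance_id: int) -> ActivityInstance:
        row = self._conn.execute(
            "SELECT name, start_t, end_t, inferred_at, satisfied, beats "
            "FROM activities WHERE id = ?",
            (instance_id,),
        ).fetchone()
        if row is None:
            raise KeyError(f"no activity instance with id {instance_id}")
        return self._row_to_instance(row)

    @staticmethod
    def _row_to_instance(row) -> ActivityInstance:
        name, start_t, end_t, inferred_at, satisfied, beats_json = row
        beats = [
            Beat(
                artifact_id=b["artifact_id"],
                t=b["t"],
                direction=b["direction"],
                technology=b.get("technology"),
                frame_index=b.get("frame_index"),
            )
            for b in json.loads(beats_json)
        ]
        return ActivityInstance(
            name=name,
            start_t=start_t,
            end_t=end_t,
            inferred_at=inferred_at,
            beats=beats,
            satisfied_artifacts=json.loads(satisfied),
        )

    # -- context -----------------------------------------------------------

    def owning_activity(self, beat: Beat, run_id: str | None = None):
        """The inferred instance whose episode contains this beat, or None."""
        conds = ["start_t <= ?", "end_t >= ?"]
        args: list = [beat.t, beat.t]
        if run_id is not None:
            conds.append("run_id = ?")
            args.append(run_id)
        for row in self._conn.execute(
            "SELECT name, start_t, end_t, inferred_at, satisfied, beats "
            "FROM activities WHERE " + " AND ".join(conds),
            args,
        ):
            inst = self._row_to_instance(row)
            if any(b.artifact_id == beat.artifact_id and b.t == beat.t for b in inst.beats):
                return inst
        return None

    # -- representation ----------------------------------------------------

    def export_representation(
        self,
        instance_id: int,
        clock: FrameClock,
        include_midpoint: bool = False,
    ) -> RepresentationBundle:
        """Frame references for each beat of one stored activity instance.

        With ``include_midpoint`` the frame at the episode's temporal
        midpoint is added -- not a state change, but the conventional
        illustrative image of the activity being performed.
        """
        inst = self.get_activity(instance_id)
        frames = []
        # Beats within one instance may share an artifact and differ only in
        # artifact; link each via a singleton series to keep directions intact.
        for beat in inst.beats:
            linked = link_frames(
                BeatSeries(artifact_id=beat.artifact_id, beats=[beat]), clock
            )
            frames.append((beat.t, linked.beats[0].frame_index))
        frames.sort(key=lambda x: x[0])
        midpoint_frame = None
        if include_midpoint:
            midpoint_frame = clock.index_at((inst.start_t + inst.end_t) / 2.0)
        return RepresentationBundle(
            activity=inst, frames=frames, midpoint_frame=midpoint_frame
        )

    # -- export ------------------------------------------------------------

    def export_jsonl(self, path) -> int:
        """Dump every record as JSONL; returns the number of lines written."""
        path = Path(path)
        n = 0
        with path.open("w", encoding="utf-8") as fh:
            for rec in self.query():
                payload = rec.payload
                if rec.record_kind == "beat":
                    body = {
                        "t": payload.t,
                        "artifact_id": payload.artifact_id,
                        "direction": payload.direction,
                        "technology": payload.technology,
                        "frame_index": payload.frame_index,
                    }
                elif rec.record_kind == "activity":
                    body = {
                        "name": payload.name,
                        "start_t": payload.start_t,
                        "end_t": payload.end_t,
                        "inferred_at": payload.inferred_at,
                        "satisfied_artifacts": list(payload.satisfied_artifacts),
                    }
                else:
                    body = {
                        "person_id": payload.person_id,
                        "t": payload.t,
                        "direction": payload.direction,
                    }
                fh.write(
                    json.dumps(
                        {"kind": rec.record_kind, "run_id": rec.run_id, **body}
                    )
                    + "\n"
                )
                n += 1
        return n

    def table2_summary(self, run_id: str | None = None) -> dict:
        """Per-activity inferred counts and beat totals by artifact."""
        where = "" if run_id is None else " WHERE run_id = ?"
        args = () if run_id is None else (run_id,)
        summary: dict[str, dict] = {}
        for row in self._conn.execute(
            f"SELECT name, beats FROM activities{where}", args
        ):
            name, beats_json = row
            entry = summary.setdefault(
                name, {"inferred": 0, "beats": 0, "beats_by_artifact": {}}
            )
            entry["inferred"] += 1
            for b in json.loads(beats_json):
                entry["beats"] += 1
                art = b["artifact_id"]
                entry["beats_by_artifact"][art] = (
                    entry["beats_by_artifact"].get(art, 0) + 1
                )
        return summary
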