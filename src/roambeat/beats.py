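"""Roaming beats: time-stamped artifact state changes.

A *beat* is one transition of an artifact's binary presence signal -- the
artifact either arrives on the base location (``to_base``, 0 -> 1) or leaves
it to be handled (``to_mobile``, 1 -> 0).  The ordered sequence of beats an
artifact produces while an activity is performed is its roaming beat, and it
is the only thing the inference engine ever looks at.

Beats can optionally be linked to the frame index of a synchronized video
sequence, which is what makes an inferred activity *representable*: each beat
points at the image captured the instant the state changed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .io_streams import BinarySignal

__all__ = [
    "TO_BASE",
    "TO_MOBILE",
    "Beat",
    "BeatSeries",
    "FrameClock",
    "extract_beats",
    "link_frames",
    "merge_beat_streams",
    "write_beats",
    "read_beats",
]

logger = logging.getLogger(__name__)

TO_BASE = "to_base"      # 0 -> 1: artifact recognized on the base location
TO_MOBILE = "to_mobile"  # 1 -> 0: artifact picked up / roaming


@dataclass(frozen=True)
class Beat:
    """One artifact state change."""

    artifact_id: str
    t: float
    direction: str
    technology: str | None = None
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in (TO_BASE, TO_MOBILE):
            raise ValueError(f"direction must be {TO_BASE!r} or {TO_MOBILE!r}")
        if self.frame_index is not None and self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")

    @property
    def state(self) -> int:
        """State the signal is in immediately after this beat."""
        return 1 if self.direction == TO_BASE else 0


@dataclass
class BeatSeries:
    """All beats of one artifact, time-ordered with alternating directions."""

    artifact_id: str
    beats: list = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_t = None
        prev_dir = None
        for beat in self.beats:
            if beat.artifact_id != self.artifact_id:
                raise ValueError(
                    f"beat for {beat.artifact_id!r} in series {self.artifact_id!r}"
                )
            if prev_t is not None and beat.t <= prev_t:
                raise ValueError(
                    f"series {self.artifact_id!r}: beat times must be strictly increasing"
                )
            if prev_dir is not None and beat.direction == prev_dir:
                raise ValueError(
                    f"series {self.artifact_id!r}: beat directions must alternate"
                )
            prev_t, prev_dir = beat.t, beat.direction

    def __len__(self) -> int:
        return len(self.beats)


@dataclass(frozen=True)
class FrameClock:
    """Maps time to video frame indexes: frame k spans [t0 + k/rate, ...)."""

    frame_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    def index_at(self, t: float) -> int:
        """Frame index current at time ``t``, clamped at 0 before t0."""
        if t < self.t0:
            return 0
        return int(math.floor((t - self.t0) * self.frame_rate))


def extract_beats(signal: BinarySignal) -> BeatSeries:
    """One beat per transition of ``signal``, in order."""
    beats = [
        Beat(
            artifact_id=signal.artifact_id,
            t=t,
            direction=TO_BASE if state == 1 else TO_MOBILE,
            technology=signal.technology,
        )
        for t, state in signal.transitions
    ]
    return BeatSeries(artifact_id=signal.artifact_id, beats=beats)


def link_frames(series: BeatSeries, clock: FrameClock) -> BeatSeries:
    """Attach ``frame_index = floor((t - t0) * frame_rate)`` to every beat.

    Beats stamped before the clock origin are clamped to frame 0 with a
    logged warning.
    """
    linked = []
    for beat in series.beats:
        if beat.t < clock.t0:
            logger.warning(
                "beat for %r at t=%s precedes frame clock origin t0=%s; "
                "clamping to frame 0",
                beat.artifact_id,
                beat.t,
                clock.t0,
            )
        linked.append(replace(beat, frame_index=clock.index_at(beat.t)))
    return BeatSeries(artifact_id=series.artifact_id, beats=linked)


def merge_beat_streams(series_list: Iterable[BeatSeries]) -> list:
    """Merge per-artifact series into one chronological beat stream.

    Ordered by ``t``; ties across artifacts break lexicographically by
    ``artifact_id`` (order within one artifact is already fixed by its series).
    """
    merged = [beat for series in series_list for beat in series.beats]
    merged.sort(key=lambda b: (b.t, b.artifact_id))
    return merged


# ---------------------------------------------------------------------------
# Beat import/export (CSV / JSONL)
# ---------------------------------------------------------------------------

_BEAT_COLUMNS = ("t", "artifact_id", "direction", "technology", "frame_index")


def write_beats(beats: Sequence[Beat], path, format: str | None = None) -> None:
    """Write a beat stream to CSV or JSONL with the canonical columns."""
    import csv as _csv
    import json as _json
    from pathlib import Path

    path = Path(path)
    fmt = format or ("jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv")
    rows = [
        {
            "t": beat.t,
            "artifact_id": beat.artifact_id,
            "direction": beat.direction,
            "technology": beat.technology or "",
            "frame_index": "" if beat.frame_index is None else beat.frame_index,
        }
        for beat in beats
    ]
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = _csv.DictWriter(fh, fieldnames=_BEAT_COLUMNS)
            writer.writeheader()
            for row in rows:
                out = dict(row)
                out["t"] = repr(float(row["t"]))
                writer.writerow(out)
    else:
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                record = {k: (None if v == "" else v) for k, v in row.items()}
                fh.write(_json.dumps(record) + "\n")


def read_beats(path, format: str | None = None) -> list:
    """Read a beat stream written by :func:`write_beats`, time-ordered."""
    import csv as _csv
    import json as _json
    from pathlib import Path

    path = Path(path)
    fmt = format or ("jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv")
    beats = []

    def from_row(row: dict) -> Beat:
        frame = row.get("frame_index")
        frame_index = None if frame in (None, "") else int(frame)
        technology = row.get("technology") or None
        return Beat(
            artifact_id=str(row["artifact_id"]),
            t=float(row["t"]),
            direction=str(row["direction"]),
            technology=technology,
            frame_index=frame_index,
        )

    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            for row in _csv.DictReader(fh):
                beats.append(from_row(row))
    else:
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    beats.append(from_row(_json.loads(line)))
    beats.sort(key=lambda b: (b.t, b.artifact_id))
    return beats
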