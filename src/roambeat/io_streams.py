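"""Raw sensor streams and their conversion to binary presence signals.

Every monitored artifact (a feeding tray, a blood-pressure device, a pillbox,
...) is observed by one of three technologies:

* **rfid** -- a reader under the base location emits discrete tag events:
  ``gain`` when the tag comes into range, ``loss`` when it leaves;
* **accelerometer** -- a motion tag on the artifact reports absolute
  acceleration magnitude in g; the artifact is at rest while the magnitude
  sits inside a configured rest band;
* **vision** -- a correlation filter scores each video frame for the
  artifact's presence on the base location.

All three are reduced to the same canonical form, a :class:`BinarySignal`:
state 1 means "the artifact is recognized on the base location", state 0
means "the artifact is being handled / is away".  Downstream modules only
ever see this binary presence signal, which is what makes the technologies
interchangeable.

Time is a real-valued offset in seconds from a per-run origin.  Wall-clock
origins, when known, belong in run metadata, not in the signals themselves.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TECHNOLOGIES",
    "RFID_GAIN",
    "RFID_LOSS",
    "StreamParseError",
    "StreamOrderError",
    "RawStream",
    "ThresholdSpec",
    "BinarySignal",
    "read_event_stream",
    "write_event_stream",
    "discretize_rfid",
    "discretize_accelerometer",
    "discretize_scores",
    "write_binary_signal",
]

TECHNOLOGIES = ("rfid", "accelerometer", "vision")

RFID_GAIN = "gain"
RFID_LOSS = "loss"

_STREAM_COLUMNS = ("t", "artifact_id", "technology", "value")


class StreamParseError(ValueError):
    """A stream file row could not be parsed."""


class StreamOrderError(ValueError):
    """Sample timestamps violate the strictly-increasing contract."""


@dataclass
class RawStream:
    """Time-stamped samples from one technology observing one artifact.

    ``samples`` is an ordered list of ``(t, value)`` pairs with strictly
    increasing ``t``.  The meaning of ``value`` depends on ``technology``:
    an event code (``"gain"``/``"loss"``) for rfid, a non-negative magnitude
    in g for accelerometer, a correlation score for vision.
    """

    artifact_id: str
    technology: str
    samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.technology not in TECHNOLOGIES:
            raise ValueError(
                f"unknown technology {self.technology!r}; expected one of {TECHNOLOGIES}"
            )
        prev = None
        for t, _ in self.samples:
            if prev is not None and t <= prev:
                raise StreamOrderError(
                    f"stream {self.artifact_id!r}: sample times must be strictly "
                    f"increasing (t={t} after t={prev})"
                )
            prev = t

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class ThresholdSpec:
    """Accelerometer discretization parameters.

    ``threshold`` is the magnitude above which the artifact is considered in
    motion.  ``rest_band_low``/``rest_band_high`` bound the at-rest magnitude
    (around 1 g for a stationary tag).  ``min_dwell`` is a debounce: the
    signal must stay inside the rest band that long before the artifact is
    declared back at rest.  ``min_dwell=0`` reproduces the bare-threshold
    rule; a positive dwell suppresses the beat inflation that a sensitive
    accelerometer otherwise produces.
    """

    threshold: float
    rest_band_low: float
    rest_band_high: float
    min_dwell: float = 0.0

    def __post_init__(self) -> None:
        if self.rest_band_low > self.rest_band_high:
            raise ValueError("rest_band_low must be <= rest_band_high")
        if self.min_dwell < 0:
            raise ValueError("min_dwell must be >= 0")


@dataclass
class BinarySignal:
    """Alternating step function of an artifact's presence on the base location.

    ``transitions`` is an ordered list of ``(t, state)`` with strictly
    increasing ``t`` and strictly alternating states; ``initial_state`` holds
    before the first transition (default 0: not yet on the base location).
    """

    artifact_id: str
    transitions: list = field(default_factory=list)
    initial_state: int = 0
    technology: str | None = None

    def __post_init__(self) -> None:
        if self.initial_state not in (0, 1):
            raise ValueError("initial_state must be 0 or 1")
        prev_t = None
        prev_state = self.initial_state
        for t, state in self.transitions:
            if state not in (0, 1):
                raise ValueError(f"state must be 0 or 1, got {state!r}")
            if state == prev_state:
                raise ValueError(
                    f"signal {self.artifact_id!r}: consecutive states must alternate"
                )
            if prev_t is not None and t <= prev_t:
                raise StreamOrderError(
                    f"signal {self.artifact_id!r}: transition times must be "
                    f"strictly increasing"
                )
            prev_t, prev_state = t, state

    def state_at(self, t: float) -> int:
        """State in effect at time ``t`` (transitions take effect at their t)."""
        state = self.initial_state
        for tt, s in self.transitions:
            if tt <= t:
                state = s
            else:
                break
        return state

    def time_in_state(self, state: int, t_start: float, t_end: float) -> float:
        """Total time spent in ``state`` over the window [t_start, t_end]."""
        if t_end < t_start:
            raise ValueError("t_end must be >= t_start")
        total = 0.0
        cur_state = self.initial_state
        cur_t = t_start
        for tt, s in self.transitions:
            if tt <= t_start:
                cur_state = s
                continue
            if tt > t_end:
                break
            if cur_state == state:
                total += tt - cur_t
            cur_t, cur_state = tt, s
        if cur_state == state:
            total += t_end - cur_t
        return total


# ---------------------------------------------------------------------------
# Reading and writing event streams
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    raise ValueError(f"cannot infer stream format from {path.name!r}; pass format=")


def _parse_value(technology: str, raw, lineno: int):
    if technology == "rfid":
        value = str(raw).strip().lower()
        return value
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise StreamParseError(
            f"line {lineno}: value {raw!r} is not numeric for technology "
            f"{technology!r}"
        ) from None


def _parse_row(row: dict, lineno: int) -> tuple[float, str, str, object]:
    missing = [c for c in _STREAM_COLUMNS if row.get(c) in (None, "")]
    if missing:
        raise StreamParseError(f"line {lineno}: missing column(s) {missing}")
    try:
        t = float(row["t"])
    except (TypeError, ValueError):
        raise StreamParseError(f"line {lineno}: t={row['t']!r} is not a number") from None
    technology = str(row["technology"]).strip().lower()
    if technology not in TECHNOLOGIES:
        raise StreamParseError(
            f"line {lineno}: unknown technology {row['technology']!r}"
        )
    value = _parse_value(technology, row["value"], lineno)
    return t, str(row["artifact_id"]), technology, value


def read_event_stream(path, format: str | None = None) -> list[RawStream]:
    """Read an event stream file and split it into one RawStream per artifact.

    Rows carry ``(t, artifact_id, technology, value)``.  Rows may appear in
    any order in the file; each artifact's samples are sorted by ``t``.
    Duplicate timestamps within one artifact are rejected (their relative
    order would be ambiguous).  An empty file yields an empty list.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    rows: list[tuple[float, str, str, object]] = []
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            missing = [c for c in _STREAM_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise StreamParseError(f"header missing column(s) {missing}")
            for lineno, row in enumerate(reader, start=2):
                rows.append(_parse_row(row, lineno))
    elif fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise StreamParseError(f"line {lineno}: invalid JSON ({exc})") from None
                if not isinstance(record, dict):
                    raise StreamParseError(f"line {lineno}: expected a JSON object")
                rows.append(_parse_row(record, lineno))
    else:
        raise ValueError(f"unknown stream format {fmt!r}")

    by_artifact: dict[str, list[tuple[float, str, object]]] = {}
    tech_of: dict[str, str] = {}
    for t, artifact_id, technology, value in rows:
        if artifact_id in tech_of and tech_of[artifact_id] != technology:
            raise StreamParseError(
                f"artifact {artifact_id!r} appears under two technologies "
                f"({tech_of[artifact_id]!r} and {technology!r})"
            )
        tech_of[artifact_id] = technology
        by_artifact.setdefault(artifact_id, []).append((t, technology, value))

    streams = []
    for artifact_id in sorted(by_artifact):
        samples = sorted(by_artifact[artifact_id], key=lambda x: x[0])
        for (t0, _, _), (t1, _, _) in zip(samples, samples[1:]):
            if t1 == t0:
                raise StreamOrderError(
                    f"artifact {artifact_id!r}: duplicate timestamp t={t0}"
                )
        streams.append(
            RawStream(
                artifact_id=artifact_id,
                technology=tech_of[artifact_id],
                samples=[(t, v) for t, _, v in samples],
            )
        )
    return streams


def write_event_stream(streams: Iterable[RawStream], path, format: str | None = None) -> None:
    """Write RawStreams to CSV or JSONL; inverse of :func:`read_event_stream`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    rows = []
    for stream in streams:
        for t, value in stream.samples:
            rows.append(
                {
                    "t": t,
                    "artifact_id": stream.artifact_id,
                    "technology": stream.technology,
                    "value": value,
                }
            )
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_STREAM_COLUMNS)
            writer.writeheader()
            for row in rows:
                out = dict(row)
                out["t"] = repr(float(row["t"]))
                writer.writerow(out)
    elif fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unknown stream format {fmt!r}")


def write_binary_signal(signal: BinarySignal, path) -> None:
    """Export a BinarySignal as a two-column (t, state) CSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "state"])
        for t, state in signal.transitions:
            writer.writerow([repr(float(t)), state])


# ---------------------------------------------------------------------------
# Discretizers: technology-specific samples -> binary presence signal
# ---------------------------------------------------------------------------

def discretize_rfid(stream: RawStream) -> BinarySignal:
    """Tag events to presence: gain -> state 1, loss -> state 0.

    Consecutive duplicate events (reader re-announcements) collapse onto the
    first occurrence, so the output alternates strictly.
    """
    if stream.technology != "rfid":
        raise ValueError(f"expected an rfid stream, got {stream.technology!r}")
    transitions: list[tuple[float, int]] = []
    state = 0
    for t, value in stream.samples:
        if value == RFID_GAIN:
            new_state = 1
        elif value == RFID_LOSS:
            new_state = 0
        else:
            raise ValueError(
                f"artifact {stream.artifact_id!r}: unknown rfid event {value!r} "
                f"(expected {RFID_GAIN!r} or {RFID_LOSS!r})"
            )
        if new_state != state:
            transitions.append((t, new_state))
            state = new_state
    return BinarySignal(
        artifact_id=stream.artifact_id,
        transitions=transitions,
        initial_state=0,
        technology="rfid",
    )


def discretize_accelerometer(stream: RawStream, spec: ThresholdSpec) -> BinarySignal:
    """Magnitude samples to presence via threshold, rest band and debounce.

    The artifact is at rest (state 1) while the magnitude sits inside
    ``[rest_band_low, rest_band_high]``.  A sample above ``threshold`` flips
    it to moving (state 0) at that sample's time.  It flips back to rest once
    the magnitude has re-entered the rest band and stayed there for
    ``min_dwell`` seconds; the transition is stamped at re-entry + dwell.
    The initial state is taken from the first sample (in-band -> at rest).
    """
    if stream.technology != "accelerometer":
        raise ValueError(f"expected an accelerometer stream, got {stream.technology!r}")
    transitions: list[tuple[float, int]] = []
    state: int | None = None
    dwell_start: float | None = None
    initial_state = 0
    in_band = lambda v: spec.rest_band_low <= v <= spec.rest_band_high

    for t, value in stream.samples:
        value = float(value)
        if value < 0:
            raise ValueError(
                f"artifact {stream.artifact_id!r}: negative magnitude {value} at t={t}"
            )
        if state is None:
            state = 1 if in_band(value) else 0
            initial_state = state
            continue
        if state == 1:
            if value > spec.threshold:
                transitions.append((t, 0))
                state = 0
                dwell_start = None
        else:
            if in_band(value):
                if dwell_start is None:
                    dwell_start = t
                if t - dwell_start >= spec.min_dwell:
                    transitions.append((dwell_start + spec.min_dwell, 1))
                    state = 1
                    dwell_start = None
            else:
                dwell_start = None
    return BinarySignal(
        artifact_id=stream.artifact_id,
        transitions=transitions,
        initial_state=initial_state,
        technology="accelerometer",
    )


def discretize_scores(stream: RawStream, threshold: float) -> BinarySignal:
    """Per-frame correlation scores to presence: score >= threshold -> state 1.

    Runs of equal state collapse into alternating transitions; each transition
    keeps the frame's time so beats can later be mapped back to frame indexes.
    """
    if stream.technology != "vision":
        raise ValueError(f"expected a vision stream, got {stream.technology!r}")
    transitions: list[tuple[float, int]] = []
    state = 0
    for t, value in stream.samples:
        new_state = 1 if float(value) >= threshold else 0
        if new_state != state:
            transitions.append((t, new_state))
            state = new_state
    return BinarySignal(
        artifact_id=stream.artifact_id,
        transitions=transitions,
        initial_state=0,
        technology="vision",
    )
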