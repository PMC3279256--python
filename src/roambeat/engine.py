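"""Criteria-driven temporal inference of activities from beat streams.

An activity is described by four criteria:

1. the set of artifacts involved;
2. per artifact, the minimum number of beats it must produce ("beats
   established");
3. the time span within which the activity is performed (``t_min``..``t_max``
   minutes) -- while an artifact is still collecting beats, the engine waits
   at most ``t_max`` between beats before giving the episode up;
4. the *quantum*: once an artifact has its beats, the activity is declared
   inferred after ``quantum`` minutes of silence following its last beat.
   By convention the quantum equals ``t_min``.

Each (activity, artifact) pair gets its own tracker -- a small state machine
fed beats and clock ticks.  A tracker raises its *flag* when its artifact's
beat requirement is met.  A parent coordinator per activity combines flags:
in the *strict* case every involved artifact must fly its flag; in the
*flexible* case ``k_required`` (>= 2) artifacts suffice.  The activity is
emitted at the first clock tick at least one quantum after the last beat
counted by any satisfied tracker, provided the episode's total span does not
exceed ``t_max``.  Emission resets all trackers of that activity, so
instances of one activity never overlap; different activities run their
trackers independently and may interleave freely (beats are delivered to
every activity that references the artifact).

The parent/child coordination is modeled as deterministic trackers stepped
by a single chronological event loop; results are a pure function of the
time-ordered beat stream.

:func:`oracle_inference` is an independent, declarative re-derivation of the
same semantics (chain decomposition of each artifact's beat list plus a scan
over candidate emission ticks).  It is deliberately structured nothing like
the event loop and exists only as a cross-check in tests.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .beats import Beat

__all__ = [
    "ConfigError",
    "OrderingError",
    "ArtifactCriterion",
    "ActivitySpec",
    "TrackerState",
    "ActivityInstance",
    "ClockTick",
    "load_criteria",
    "default_criteria_path",
    "tracker_step",
    "run_inference",
    "oracle_inference",
    "write_instances",
    "read_instances",
]

logger = logging.getLogger(__name__)

IDLE = "IDLE"
COUNTING = "COUNTING"
SATISFIED = "SATISFIED"


class ConfigError(ValueError):
    """An activity criteria configuration violates its invariants."""


class OrderingError(ValueError):
    """Events were presented out of time order."""


@dataclass(frozen=True)
class ArtifactCriterion:
    """Beat requirement for one artifact within one activity."""

    artifact_id: str
    min_beats: int
    max_beats: int | None = None

    def __post_init__(self) -> None:
        if self.min_beats < 1:
            raise ConfigError(
                f"artifact {self.artifact_id!r}: min_beats must be >= 1"
            )
        if self.max_beats is not None and self.max_beats < self.min_beats:
            raise ConfigError(
                f"artifact {self.artifact_id!r}: max_beats must be >= min_beats"
            )


@dataclass(frozen=True)
class ActivitySpec:
    """One activity's inference criteria.  Durations are in minutes."""

    name: str
    criteria: tuple
    t_min: float
    t_max: float
    quantum: float | None = None
    mode: str = "strict"
    k_required: int | None = None

    def __post_init__(self) -> None:
        if not self.criteria:
            raise ConfigError(f"activity {self.name!r}: needs at least one artifact")
        object.__setattr__(self, "criteria", tuple(self.criteria))
        ids = [c.artifact_id for c in self.criteria]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"activity {self.name!r}: duplicate artifact in criteria")
        if not (0 < self.t_min <= self.t_max):
            raise ConfigError(
                f"activity {self.name!r}: requires 0 < t_min <= t_max "
                f"(got t_min={self.t_min}, t_max={self.t_max})"
            )
        if self.quantum is None:
            object.__setattr__(self, "quantum", self.t_min)
        if self.quantum <= 0:
            raise ConfigError(f"activity {self.name!r}: quantum must be > 0")
        if self.mode not in ("strict", "flexible"):
            raise ConfigError(f"activity {self.name!r}: mode must be strict|flexible")
        if self.mode == "strict":
            if self.k_required is None:
                object.__setattr__(self, "k_required", len(self.criteria))
            elif self.k_required != len(self.criteria):
                raise ConfigError(
                    f"activity {self.name!r}: strict mode requires "
                    f"k_required == number of artifacts"
                )
        else:
            if self.k_required is None:
                object.__setattr__(self, "k_required", 2)
            if not (2 <= self.k_required <= len(self.criteria)):
                raise ConfigError(
                    f"activity {self.name!r}: flexible mode requires "
                    f"2 <= k_required <= number of artifacts"
                )

    # -- seconds-denominated views -----------------------------------------
    @property
    def t_min_s(self) -> float:
        return self.t_min * 60.0

    @property
    def t_max_s(self) -> float:
        return self.t_max * 60.0

    @property
    def quantum_s(self) -> float:
        return self.quantum * 60.0

    @property
    def artifact_ids(self) -> tuple:
        return tuple(c.artifact_id for c in self.criteria)

    def criterion_for(self, artifact_id: str) -> ArtifactCriterion:
        for c in self.criteria:
            if c.artifact_id == artifact_id:
                return c
        raise KeyError(artifact_id)


@dataclass
class TrackerState:
    """Per-(activity, artifact) beat-counting state machine."""

    activity: str
    artifact_id: str
    phase: str = IDLE
    beat_count: int = 0
    first_beat_t: float | None = None
    last_beat_t: float | None = None
    waiting_interval: float = 0.0
    flag: bool = False
    beats: list = field(default_factory=list)

    def reset(self) -> None:
        self.phase = IDLE
        self.beat_count = 0
        self.first_beat_t = None
        self.last_beat_t = None
        self.waiting_interval = 0.0
        self.flag = False
        self.beats = []


@dataclass(frozen=True)
class ClockTick:
    """A virtual clock event delivered between beats."""

    t: float


@dataclass
class ActivityInstance:
    """One inferred occurrence of an activity."""

    name: str
    start_t: float
    end_t: float
    inferred_at: float
    beats: list = field(default_factory=list)
    satisfied_artifacts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.start_t <= self.end_t < self.inferred_at):
            raise ValueError(
                f"instance {self.name!r}: requires start_t <= end_t < inferred_at"
            )

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


# ---------------------------------------------------------------------------
# Criteria configuration
# ---------------------------------------------------------------------------

def default_criteria_path() -> Path:
    """Path of the packaged nursing-home criteria configuration."""
    return Path(__file__).parent / "data" / "table1.yaml"


def load_criteria(source) -> list:
    """Load and validate activity criteria from YAML/JSON or a mapping.

    ``source`` may be a path to a ``.yaml``/``.yml``/``.json`` file or an
    already-parsed mapping of the same shape::

        activities:
          feeding:
            time_span: [5, 50]     # minutes
            quantum: 5             # optional, defaults to time_span[0]
            mode: strict           # strict | flexible
            artifacts:
              tray: {min_beats: 2, max_beats: 2}
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() == ".json":
            doc = json.loads(text)
        else:
            import yaml

            doc = yaml.safe_load(text)
    else:
        doc = source
    if not isinstance(doc, dict) or "activities" not in doc:
        raise ConfigError("criteria document must have a top-level 'activities' mapping")
    activities = doc["activities"]
    if not isinstance(activities, dict) or not activities:
        raise ConfigError("'activities' must be a non-empty mapping")

    specs = []
    for name, body in activities.items():
        if not isinstance(body, dict):
            raise ConfigError(f"activity {name!r}: body must be a mapping")
        try:
            span = body["time_span"]
            t_min, t_max = float(span[0]), float(span[1])
        except (KeyError, TypeError, ValueError, IndexError):
            raise ConfigError(
                f"activity {name!r}: 'time_span' must be [t_min, t_max] minutes"
            ) from None
        artifacts = body.get("artifacts")
        if not isinstance(artifacts, dict) or not artifacts:
            raise ConfigError(f"activity {name!r}: 'artifacts' must be a non-empty mapping")
        criteria = []
        for artifact_id, rule in artifacts.items():
            if not isinstance(rule, dict) or "min_beats" not in rule:
                raise ConfigError(
                    f"activity {name!r}, artifact {artifact_id!r}: needs 'min_beats'"
                )
            criteria.append(
                ArtifactCriterion(
                    artifact_id=str(artifact_id),
                    min_beats=int(rule["min_beats"]),
                    max_beats=(None if rule.get("max_beats") is None else int(rule["max_beats"])),
                )
            )
        quantum = body.get("quantum")
        specs.append(
            ActivitySpec(
                name=str(name),
                criteria=tuple(criteria),
                t_min=t_min,
                t_max=t_max,
                quantum=None if quantum is None else float(quantum),
                mode=body.get("mode", "strict"),
                k_required=body.get("k_required"),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Tracker state machine
# ---------------------------------------------------------------------------

def tracker_step(state: TrackerState, spec: ActivitySpec, event) -> tuple:
    """Advance one tracker by a beat or clock tick; returns (state, emissions).

    Emissions is a list of tokens describing what happened:
    ``"satisfied"`` (flag raised, quantum armed), ``"ready"`` (quantum has
    elapsed, tracker is prepared to infer), ``"aborted"`` (episode timed out
    before the beat requirement was met), ``"restarted"`` (a beat arrived
    past the waiting interval and opened a new episode).

    The state object is mutated in place and returned for convenience.
    """
    crit = spec.criterion_for(state.artifact_id)
    emissions: list[str] = []

    def start_episode(beat: Beat) -> None:
        # The first beat opens the episode; the waiting interval is loaded
        # with the activity's maximum duration.
        state.phase = COUNTING
        state.beat_count = 1
        state.first_beat_t = beat.t
        state.last_beat_t = beat.t
        state.waiting_interval = spec.t_max_s
        state.beats = [beat]
        check_satisfied()

    def check_satisfied() -> None:
        if not state.flag and state.beat_count >= crit.min_beats:
            # Beat requirement accomplished: raise the flag and shrink the
            # waiting interval to the quantum.
            state.flag = True
            state.phase = SATISFIED
            state.waiting_interval = spec.quantum_s
            emissions.append("satisfied")

    if isinstance(event, Beat):
        now = event.t
        if state.last_beat_t is not None and now < state.last_beat_t:
            raise OrderingError(
                f"tracker {state.activity!r}/{state.artifact_id!r}: beat at t={now} "
                f"after t={state.last_beat_t}"
            )
        if state.phase == IDLE:
            start_episode(event)
        elif now <= state.last_beat_t + state.waiting_interval:
            state.beat_count += 1
            state.last_beat_t = now
            state.beats.append(event)
            check_satisfied()
        else:
            # Beat past the waiting interval: the previous episode is dead;
            # this beat opens a new one.
            state.reset()
            start_episode(event)
            emissions.append("restarted")
    else:
        now = event.t if isinstance(event, ClockTick) else float(event)
        if state.phase == COUNTING and now > state.last_beat_t + state.waiting_interval:
            state.reset()
            emissions.append("aborted")
        elif state.phase == SATISFIED and now >= state.last_beat_t + spec.quantum_s:
            emissions.append("ready")
    return state, emissions


# ---------------------------------------------------------------------------
# Event-loop inference
# ---------------------------------------------------------------------------

def _align_at_or_after(x: float, tick: float) -> float:
    """First clock tick >= x (ticks at integer multiples of ``tick``)."""
    return math.ceil(x / tick - 1e-9) * tick


def _align_after(x: float, tick: float) -> float:
    """First clock tick strictly after x."""
    return (math.floor(x / tick + 1e-9) + 1) * tick


def run_inference(
    beat_stream: Sequence[Beat],
    specs: Sequence[ActivitySpec],
    tick: float = 1.0,
) -> tuple:
    """Run the inference engine over a merged, time-ordered beat stream.

    Returns ``(instances, log)``: the inferred :class:`ActivityInstance` list
    in emission order (same-tick emissions ordered by activity name) and a
    log of notable events (delivered beats, aborts, emissions).

    Between beats the engine advances a virtual clock in steps of ``tick``
    seconds (deadlines are computed analytically, so only the ticks at which
    something happens are visited; results are identical to ticking through
    every step).  Beats falling on the same tick as a deadline are delivered
    first, exactly as a per-tick loop that drains its input queue before
    checking timers would behave.
    """
    if tick <= 0:
        raise ValueError("tick must be > 0")
    specs = list(specs)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigError("duplicate activity names in specs")
    by_artifact: dict[str, list[ActivitySpec]] = {}
    trackers: dict[tuple, TrackerState] = {}
    for spec in specs:
        for artifact_id in spec.artifact_ids:
            by_artifact.setdefault(artifact_id, []).append(spec)
            trackers[(spec.name, artifact_id)] = TrackerState(spec.name, artifact_id)

    instances: list[ActivityInstance] = []
    log: list[dict] = []

    def emission_deadline(spec: ActivitySpec):
        """Tick at which this activity would currently be inferred, or None."""
        sats = [
            trackers[(spec.name, a)]
            for a in spec.artifact_ids
            if trackers[(spec.name, a)].flag
        ]
        if len(sats) < spec.k_required:
            return None
        last = max(trk.last_beat_t for trk in sats)
        return _align_at_or_after(last + spec.quantum_s, tick)

    def abort_deadline(trk: TrackerState):
        if trk.phase != COUNTING:
            return None
        return _align_after(trk.last_beat_t + trk.waiting_interval, tick)

    def emit(spec: ActivitySpec, at: float) -> None:
        sats = sorted(
            (
                trackers[(spec.name, a)]
                for a in spec.artifact_ids
                if trackers[(spec.name, a)].flag
            ),
            key=lambda trk: trk.artifact_id,
        )
        end_t = max(trk.last_beat_t for trk in sats)
        start_t = min(trk.first_beat_t for trk in sats)
        episode_beats = sorted(
            (b for trk in sats for b in trk.beats), key=lambda b: (b.t, b.artifact_id)
        )
        if end_t - start_t <= spec.t_max_s:
            instances.append(
                ActivityInstance(
                    name=spec.name,
                    start_t=start_t,
                    end_t=end_t,
                    inferred_at=at,
                    beats=episode_beats,
                    satisfied_artifacts=[trk.artifact_id for trk in sats],
                )
            )
            log.append({"event": "inferred", "activity": spec.name, "t": at})
        else:
            log.append(
                {
                    "event": "span_exceeded",
                    "activity": spec.name,
                    "t": at,
                    "span": end_t - start_t,
                }
            )
        for artifact_id in spec.artifact_ids:
            trackers[(spec.name, artifact_id)].reset()

    def advance_clock(limit: float | None) -> None:
        """Fire all deadlines strictly before ``limit`` (all of them if None)."""
        while True:
            next_emit: dict[str, float] = {}
            for spec in specs:
                deadline = emission_deadline(spec)
                if deadline is not None:
                    next_emit[spec.name] = deadline
            next_abort: dict[tuple, float] = {}
            for key, trk in trackers.items():
                deadline = abort_deadline(trk)
                if deadline is not None:
                    next_abort[key] = deadline
            candidates = list(next_emit.values()) + list(next_abort.values())
            if not candidates:
                return
            t_next = min(candidates)
            if limit is not None and t_next >= limit:
                return
            # Aborts first (they never interact with emissions: an aborting
            # tracker is unsatisfied, hence not part of any satisfied set).
            for key, deadline in sorted(next_abort.items()):
                if deadline == t_next:
                    tracker_step(trackers[key], _spec_named(key[0]), ClockTick(deadline))
                    log.append(
                        {
                            "event": "aborted",
                            "activity": key[0],
                            "artifact_id": key[1],
                            "t": deadline,
                        }
                    )
            for name in sorted(n for n, d in next_emit.items() if d == t_next):
                # Re-check: an earlier same-tick emission cannot affect another
                # activity, but be defensive about recomputed deadlines.
                spec = _spec_named(name)
                if emission_deadline(spec) == t_next:
                    emit(spec, t_next)

    def _spec_named(name: str) -> ActivitySpec:
        for spec in specs:
            if spec.name == name:
                return spec
        raise KeyError(name)

    prev_t = None
    for beat in beat_stream:
        if prev_t is not None and beat.t < prev_t:
            raise OrderingError(f"beat stream not time-ordered at t={beat.t}")
        prev_t = beat.t
        advance_clock(beat.t)
        recipients = by_artifact.get(beat.artifact_id)
        if not recipients:
            logger.warning("beat for unknown artifact %r ignored", beat.artifact_id)
            log.append(
                {"event": "unknown_artifact", "artifact_id": beat.artifact_id, "t": beat.t}
            )
            continue
        for spec in recipients:
            trk = trackers[(spec.name, beat.artifact_id)]
            _, emitted = tracker_step(trk, spec, beat)
            log.append(
                {
                    "event": "beat",
                    "activity": spec.name,
                    "artifact_id": beat.artifact_id,
                    "t": beat.t,
                    "count": trk.beat_count,
                    "notes": emitted,
                }
            )
    advance_clock(None)
    return instances, log


# ---------------------------------------------------------------------------
# Independent oracle (tests only)
# ---------------------------------------------------------------------------

def _chain_decompose(times: Sequence[float], min_beats: int, w_max: float, quantum: float):
    """Split one artifact's beat times into maximal tracker chains.

    Within a chain, the allowed gap to the next beat is the activity's
    maximum span while the chain is short of ``min_beats`` and the quantum
    afterwards.  A beat past the allowed gap starts a new chain.
    """
    chains: list[list[float]] = []
    cur: list[float] = []
    for t in times:
        if not cur:
            cur = [t]
            continue
        window = w_max if len(cur) < min_beats else quantum
        if t <= cur[-1] + window:
            cur.append(t)
        else:
            chains.append(cur)
            cur = [t]
    if cur:
        chains.append(cur)
    return chains


def oracle_inference(
    beat_stream: Sequence[Beat],
    specs: Sequence[ActivitySpec],
    tick: float = 1.0,
) -> list:
    """Declarative re-derivation of :func:`run_inference` results.

    Activities are evaluated independently.  For each one, the artifact beat
    lists are decomposed into chains, every tick at which some chain could
    trigger an inference is enumerated, and the criteria are applied
    literally at each candidate in ascending order.  Intended for small
    streams (brute force over candidate ticks); used only in tests.
    """
    out: list[ActivityInstance] = []
    for spec in specs:
        min_of = {c.artifact_id: c.min_beats for c in spec.criteria}
        beats_of = {
            a: [b for b in beat_stream if b.artifact_id == a] for a in spec.artifact_ids
        }
        pos = {a: 0 for a in spec.artifact_ids}
        while True:
            chains = {
                a: _chain_decompose(
                    [b.t for b in beats_of[a][pos[a]:]],
                    min_of[a],
                    spec.t_max_s,
                    spec.quantum_s,
                )
                for a in spec.artifact_ids
            }
            candidates = sorted(
                {
                    _align_at_or_after(chain[i] + spec.quantum_s, tick)
                    for a, chs in chains.items()
                    for chain in chs
                    for i in range(min_of[a] - 1, len(chain))
                }
            )
            consumed_at = None
            for cand in candidates:
                # Satisfaction state at the candidate tick: for each artifact,
                # the chain in force is the last one opened at or before it.
                sats: dict[str, list[float]] = {}
                for a, chs in chains.items():
                    current = None
                    for chain in chs:
                        if chain[0] <= cand:
                            current = chain
                        else:
                            break
                    if current is None:
                        continue
                    upto = [t for t in current if t <= cand]
                    if len(upto) >= min_of[a]:
                        sats[a] = upto
                if len(sats) < spec.k_required:
                    continue
                last_t = max(ts[-1] for ts in sats.values())
                if cand < last_t + spec.quantum_s:
                    continue
                # Criteria 1, 2 and 4 hold at this tick; criterion 3 (span)
                # decides between emission and a silent reset.
                start_t = min(ts[0] for ts in sats.values())
                if last_t - start_t <= spec.t_max_s:
                    episode_beats = sorted(
                        (
                            b
                            for a, ts in sats.items()
                            for b in beats_of[a]
                            if b.t in set(ts)
                        ),
                        key=lambda b: (b.t, b.artifact_id),
                    )
                    out.append(
                        ActivityInstance(
                            name=spec.name,
                            start_t=start_t,
                            end_t=last_t,
                            inferred_at=cand,
                            beats=episode_beats,
                            satisfied_artifacts=sorted(sats),
                        )
                    )
                consumed_at = cand
                break
            if consumed_at is None:
                break
            for a in spec.artifact_ids:
                lst = beats_of[a]
                i = pos[a]
                while i < len(lst) and lst[i].t <= consumed_at:
                    i += 1
                pos[a] = i
    out.sort(key=lambda inst: (inst.inferred_at, inst.name))
    return out


# ---------------------------------------------------------------------------
# Instance import/export (JSONL)
# ---------------------------------------------------------------------------

def write_instances(instances: Sequence[ActivityInstance], path) -> None:
    """Write inferred instances to JSONL (one object per instance)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(
                json.dumps(
                    {
                        "name": inst.name,
                        "start_t": inst.start_t,
                        "end_t": inst.end_t,
                        "inferred_at": inst.inferred_at,
                        "satisfied_artifacts": list(inst.satisfied_artifacts),
                        "beats": [
                            {
                                "t": b.t,
                                "artifact_id": b.artifact_id,
                                "direction": b.direction,
                                "technology": b.technology,
                                "frame_index": b.frame_index,
                            }
                            for b in inst.beats
                        ],
                    }
                )
                + "\n"
            )


def read_instances(path) -> list:
    """Read instances written by :func:`write_instances`."""
    path = Path(path)
    out = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            record = json.loads(line)
            out.append(
                ActivityInstance(
                    name=record["name"],
                    start_t=record["start_t"],
                    end_t=record["end_t"],
                    inferred_at=record["inferred_at"],
                    satisfied_artifacts=list(record.get("satisfied_artifacts", [])),
                    beats=[
                        Beat(
                            artifact_id=b["artifact_id"],
                            t=b["t"],
                            direction=b["direction"],
                            technology=b.get("technology"),
                            frame_index=b.get("frame_index"),
                        )
                        for b in record.get("beats", [])
                    ],
                )
            )
    return out
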