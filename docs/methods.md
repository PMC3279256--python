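# Methods

## Signal model

Every artifact is reduced to a binary presence signal: state 1 while it is
recognized on its *base location* (the tools table), state 0 while it is
away being handled.  A *beat* is one transition of that signal, stamped with
the time it occurred.  Time is a real-valued offset in seconds from a
per-run origin; wall-clock origins belong in run metadata, which keeps every
computation and test deterministic.  The initial state is 0 (the artifact
has not yet been placed), so a well-formed episode always opens with a
`to_base` beat.

Technology-specific conversion:

* **RFID** — tag-gain maps to state 1 at the event time, tag-loss to
  state 0.  Consecutive duplicate events are reader re-announcements and
  collapse onto the first occurrence.
* **Accelerometer** — the artifact is at rest while the magnitude sits in a
  rest band (default [0.9, 1.1] g around gravity); a sample above the
  threshold (default 1.3 g) flips it to state 0 at that sample; it returns
  to state 1 once the magnitude has stayed in the rest band for `min_dwell`
  seconds, stamped at re-entry + dwell.  `min_dwell = 0` reproduces the bare
  threshold rule; a positive dwell is offered because a sensitive
  accelerometer otherwise inflates the beat count with chatter.  The initial
  state follows the first sample (in-band ⇒ at rest).  Threshold values are
  configuration, not constants: deployments differ.
* **Vision** — per-frame correlation score ≥ threshold ⇒ state 1.  The
  threshold is a required parameter of the deployment (it depends on the
  filter and the scene) and has no universal default; 0.5 is used for the
  synthetic streams, whose scores are rendered at 0.9/0.2.

## Inference engine

Criteria per activity: an artifact set; per artifact a minimum beat count
("beats established", `min_beats`); a duration window ΔT = [t_min, t_max]
in minutes; a quantum q (default t_min); and a mode — strict (all artifacts)
or flexible (any `k_required` ≥ 2).  `max_beats` is advisory bookkeeping:
the flag is raised at `min_beats` and extra beats before the quantum expires
simply re-arm the quantum (the blood-pressure device sometimes lingers on
the table after the activity, producing a fourth beat).

Each (activity, artifact) pair is a tracker:

* IDLE + beat → COUNTING with count 1; the waiting interval is loaded with
  t_max (the episode cannot stretch its inter-beat gaps beyond the longest
  plausible duration).
* COUNTING + beat within the waiting interval → count it; at `min_beats` the
  flag goes up, the phase becomes SATISFIED and the waiting interval shrinks
  to the quantum.
* COUNTING + silence past the waiting interval → the episode is abandoned
  (the artifact was placed once and forgotten); the tracker resets.
* SATISFIED + beat within the quantum → counted; the quantum restarts.
* A beat past the waiting interval in either phase opens a fresh episode
  with that beat, so a stale satisfied tracker cannot leak its flag into a
  later episode.

The parent coordinator per activity emits an instance at the first clock
tick at least one quantum after the last beat counted by any satisfied
tracker, provided the flag condition holds (all / ≥ k) and the episode span
(last counted beat − first counted beat over satisfied trackers) does not
exceed t_max.  Emission resets all of the activity's trackers, so instances
of one activity never overlap.  Two design points were genuinely open and
are resolved as follows:

* *Whose quantum counts* when several artifacts are satisfied: the artifact
  that produced the most recent counted beat is the emitter, i.e. emission
  happens one quantum after the episode's last qualifying beat.  This is the
  only reading under which the canonical single-artifact (5 min) and
  two-artifact (10 min) examples both come out exactly.
* *Quantum expiry is inclusive* (emission at now ≥ last + q, "once the
  minutes have finished"), while episode abandonment is strict
  (now > last + waiting interval).  With a 1 s tick and integer beat times
  this makes the emission delay exactly q.

ΔT's lower bound needs no explicit check: the quantum equals t_min, so an
instance can never be declared earlier than t_min after its last beat was
due.  The upper bound is enforced at emission time on the episode span.

Concurrency is logical, not operational: the paper-and-pencil picture of one
process per artifact coordinated by a parent is implemented as deterministic
trackers stepped by a single chronological event loop, so results are a pure
function of the time-ordered beat stream.  Beats are non-exclusive across
activities — every activity referencing the artifact receives the beat —
which is what makes interleaved and concurrent activities (medications
inside feeding) fall out for free.  When two activities become inferable at
the same tick, both are emitted, ordered by name.

The default clock tick is 1 s: finer than any configured interval, bounding
the emission-time discretization error at one second.  The engine computes
deadline times analytically and visits only the ticks at which something
happens; this is an optimization with bit-identical results to stepping
every tick.

`oracle_inference` re-derives the same semantics declaratively — each
artifact's beat list is decomposed into chains by the gap rule, candidate
emission ticks are enumerated, and the criteria are applied literally at
each — and is used only as an independent cross-check in tests.

## Vision front end

"Composite correlation filter" is implemented as the average of the
zero-mean, unit-energy reference spectra (an average-spectrum composite of
normalized matched filters).  Nonlinear filter variants from the literature
are deliberately not reproduced; the pipeline role of the filter — a score
per frame, thresholded into beats — only requires a well-defined, testable
linear operator.  Scene scoring is zero-normalized cross-correlation
computed via FFT, valid only where the template fully overlaps the frame;
coordinates are 0-based (row, column) from the top-left.  Windows with
numerically zero variance score 0.  The score is invariant to affine
intensity rescaling of the frame and equals 1.0 exactly at a verbatim copy
of a single-reference template.  Color input is luminance-converted.

## Synthetic scenarios

The generator emulates the evaluated deployment at desk scale: 74 episodes
(hygiene 21, feeding 23, medications 16, blood pressure 14) over a 120-hour
horizon — ten 12-hour days flattened to one continuous timeline, since
nothing in the model depends on absolute wall-clock time.  Medications are
nested inside feeding episodes (pills at breakfast and dinner); hygiene uses
two artifacts about twice as often as three, mirroring the reported 14/7
split; episodes are otherwise separated by 55–65 minutes of quiet, which
exceeds the longest activity span (50 min) and keeps episodes independent.

Per-episode beat counts: tray 2 (place/remove), blood-pressure device 4
(place, take, return, remove), paper towel 6, solution 3, cream 3, pillbox
2 or 4 with equal probability.  Beat times are constructed to satisfy the
tracker semantics by design: gaps within each artifact's counting window,
post-satisfaction gaps within the quantum, total span within t_max, every
scheduled artifact finishing near the episode end, and no quantum-length
silence among already-satisfied artifacts mid-episode — so at zero noise
each true episode produces exactly one inference covering all its
artifacts.  This is a *self-consistency* property of the generator, checked
by tests; passing it shows the engine implements its stated semantics, not
that real caregiving data is this clean.

What the generator does not emulate: camera geometry and occlusion, radio
propagation, caregiver ergonomics, variable activity durations beyond the
configured windows, or correlated sensor failures.  The noise model is
deliberately simple — independent per-event dropout, Poisson spurious
events, Gaussian timing jitter — and all randomness flows from one seed
through numpy's `default_rng` (the scenario uses the seed directly; noise
corruption takes its own seed argument).

Effectiveness is scored by greedy one-to-one matching of inferred instances
to true episodes of the same activity, ranked by temporal overlap measured
as intersection over the shorter span, with a 0.5 minimum.  The matching
rule is this package's convention (the deployment reported only the
headline ratio); both conventions of the rate — correct/recorded and
correct/truth — are exposed in the report.

## Context log

The store is a single-file SQLite database (schema version 1) with JSONL
export; idempotence is enforced by natural-key uniqueness per record kind.
The four context facets are derivable from the store alone: identity is the
artifact or person id, location reads off the beat direction (to-base ⇒ on
the base location, to-mobile ⇒ roaming), time is the beat stamp, and
activity is the stored instance whose episode contains the beat.  Person
events (door RFID) use the same gain/loss convention but never feed activity
criteria.  An activity representation is the ordered list of (beat time,
frame index) pairs under a frame clock — frame index = floor((t − t0) ×
rate), floor because the frame current at the instant of the beat is the one
recorded — optionally plus the frame at the episode's temporal midpoint as
the conventional illustrative mid-activity image.

## Numerical conventions and limitations

* Ticks sit at integer multiples of the tick length; alignment uses a 1e-9
  relative guard against floating-point drift.
* Beat merging breaks time ties lexicographically by artifact id, and
  same-tick emissions order by activity name, purely for determinism.
* Stream readers sort rows per artifact and reject duplicate timestamps
  within one artifact (their relative order would be ambiguous).
* A beat counted by two concurrent instances of the *same* activity is
  impossible by construction (emission resets the activity's trackers);
  sharing across different activities is intended and unrestricted.
* The engine is an online algorithm in spirit but is run here in batch; no
  provision is made for out-of-order sensor delivery beyond rejecting it.
* Recognition robustness is bounded by the linear filter: heavy occlusion
  or small artifacts degrade scores, and recovery is delegated to the other
  technologies rather than solved in-filter.
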