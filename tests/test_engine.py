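"""The tracker state machine, criteria loading, and the inference engine."""

import numpy as np
import pytest

import roambeat as rb
from roambeat.beats import Beat, TO_BASE, TO_MOBILE
from roambeat.engine import (
    COUNTING,
    IDLE,
    SATISFIED,
    ActivitySpec,
    ArtifactCriterion,
    ClockTick,
    ConfigError,
    OrderingError,
    TrackerState,
    oracle_inference,
    run_inference,
    tracker_step,
)

from conftest import make_trace, merge


class TestLoadCriteria:
    def test_packaged_config_has_four_activities_six_artifacts(self, specs):
        assert len(specs) == 4
        artifacts = {c.artifact_id for s in specs for c in s.criteria}
        assert len(artifacts) == 6
        by_name = {s.name: s for s in specs}
        hygiene = by_name["hygiene"]
        assert hygiene.mode == "flexible" and hygiene.k_required == 2
        assert hygiene.criterion_for("paper_towel").min_beats == 6
        assert by_name["feeding"].criterion_for("tray").min_beats == 2
        assert by_name["medications"].quantum == 3

    def test_quantum_defaults_to_minimum_duration(self):
        (spec,) = rb.load_criteria(
            {
                "activities": {
                    "x": {
                        "time_span": [5, 10],
                        "artifacts": {"a": {"min_beats": 1}},
                    }
                }
            }
        )
        assert spec.quantum == spec.t_min == 5

    def test_inverted_time_span_rejected(self):
        with pytest.raises(ConfigError, match="t_min <= t_max"):
            rb.load_criteria(
                {
                    "activities": {
                        "x": {
                            "time_span": [10, 5],
                            "artifacts": {"a": {"min_beats": 1}},
                        }
                    }
                }
            )

    @pytest.mark.parametrize(
        "body, message",
        [
            ({"time_span": [5, 10], "artifacts": {}}, "artifacts"),
            ({"artifacts": {"a": {"min_beats": 1}}}, "time_span"),
            ({"time_span": [5, 10], "artifacts": {"a": {}}}, "min_beats"),
            (
                {
                    "time_span": [5, 10],
                    "mode": "flexible",
                    "artifacts": {"a": {"min_beats": 1}},
                },
                "k_required",
            ),
        ],
    )
    def test_invalid_configs_name_the_field(self, body, message):
        with pytest.raises(ConfigError, match=message):
            rb.load_criteria({"activities": {"x": body}})


def bp_spec(spec_by_name):
    return spec_by_name["blood_pressure"]


class TestTrackerStep:
    def step_beats(self, spec, times):
        state = TrackerState(spec.name, spec.artifact_ids[0])
        notes = []
        for beat in make_trace(spec.artifact_ids[0], times):
            _, emitted = tracker_step(state, spec, beat)
            notes.extend(emitted)
        return state, notes

    def test_first_beat_opens_episode_with_max_duration_window(self, spec_by_name):
        spec = bp_spec(spec_by_name)
        state = TrackerState(spec.name, "blood_pressure_device")
        tracker_step(state, spec, Beat("blood_pressure_device", 0.0, TO_BASE))
        assert state.phase == COUNTING
        assert state.beat_count == 1
        assert state.waiting_interval == spec.t_max_s

    def test_satisfaction_arms_the_quantum(self, spec_by_name):
        spec = bp_spec(spec_by_name)
        state, notes = self.step_beats(spec, [0, 60, 360, 420])
        assert state.phase == SATISFIED and state.flag
        assert state.beat_count == 4
        assert state.waiting_interval == spec.quantum_s
        assert notes.count("satisfied") == 1
        # Quantum elapsed after the 4th beat: tracker reports ready to infer.
        _, emitted = tracker_step(state, spec, ClockTick(720.0))
        assert "ready" in emitted

    def test_single_beat_then_silence_aborts(self, spec_by_name):
        spec = bp_spec(spec_by_name)
        state = TrackerState(spec.name, "blood_pressure_device")
        tracker_step(state, spec, Beat("blood_pressure_device", 0.0, TO_BASE))
        _, emitted = tracker_step(state, spec, ClockTick(spec.t_max_s + 1.0))
        assert "aborted" in emitted
        assert state.phase == IDLE and state.beat_count == 0 and not state.flag

    def test_zero_beats_stays_idle(self, spec_by_name):
        spec = bp_spec(spec_by_name)
        state = TrackerState(spec.name, "blood_pressure_device")
        for t in (100.0, 10_000.0, 1e6):
            _, emitted = tracker_step(state, spec, ClockTick(t))
            assert emitted == []
        assert state.phase == IDLE

    def test_late_beat_restarts_episode(self, spec_by_name):
        spec = bp_spec(spec_by_name)
        state = TrackerState(spec.name, "blood_pressure_device")
        tracker_step(state, spec, Beat("blood_pressure_device", 0.0, TO_BASE))
        _, emitted = tracker_step(
            state, spec, Beat("blood_pressure_device", spec.t_max_s + 100.0, TO_MOBILE)
        )
        assert "restarted" in emitted
        assert state.beat_count == 1
        assert state.first_beat_t == spec.t_max_s + 100.0

    def test_time_regression_rejected(self, spec_by_name):
        spec = bp_spec(spec_by_name)
        state = TrackerState(spec.name, "blood_pressure_device")
        tracker_step(state, spec, Beat("blood_pressure_device", 100.0, TO_BASE))
        with pytest.raises(OrderingError):
            tracker_step(state, spec, Beat("blood_pressure_device", 50.0, TO_MOBILE))


class TestRunInference:
    def test_canonical_blood_pressure(self, specs, blood_pressure_trace):
        instances, _ = run_inference(blood_pressure_trace, specs, tick=1.0)
        assert len(instances) == 1
        inst = instances[0]
        assert inst.name == "blood_pressure"
        assert inst.end_t == 420.0
        assert inst.inferred_at - inst.end_t == pytest.approx(300.0)
        assert len(inst.beats) == 4

    def test_hygiene_with_two_of_three_artifacts(self, specs, hygiene_trace):
        instances, _ = run_inference(hygiene_trace, specs)
        assert len(instances) == 1
        inst = instances[0]
        assert inst.name == "hygiene"
        assert inst.satisfied_artifacts == ["paper_towel", "physiological_solution"]
        assert inst.inferred_at - inst.end_t == pytest.approx(600.0)

    def test_single_satisfied_artifact_never_infers_flexible_activity(self, specs):
        solution_only = make_trace("physiological_solution", [60, 400, 1000])
        instances, _ = run_inference(solution_only, specs)
        assert instances == []

    def test_medications_inferred_before_feeding_finishes(self, specs, interleaved_trace):
        instances, _ = run_inference(interleaved_trace, specs)
        names = [i.name for i in instances]
        assert "medications" in names and "feeding" in names
        assert names.index("medications") < names.index("feeding")
        meds = next(i for i in instances if i.name == "medications")
        feeding = next(i for i in instances if i.name == "feeding")
        assert meds.inferred_at < feeding.inferred_at
        # The pillbox episode sits inside the tray episode.
        assert feeding.start_t < meds.start_t and meds.end_t < feeding.end_t

    def test_emission_timing_equals_quantum_within_one_tick(self, specs, rng):
        for _ in range(20):
            times = np.sort(rng.choice(np.arange(0, 2400), size=4, replace=False))
            trace = make_trace("blood_pressure_device", [float(t) for t in times])
            instances, _ = run_inference(trace, specs, tick=1.0)
            for inst in instances:
                spec = next(s for s in specs if s.name == inst.name)
                delay = inst.inferred_at - inst.end_t
                assert spec.quantum_s <= delay <= spec.quantum_s + 1.0

    def test_strict_mode_requires_every_artifact(self):
        spec = ActivitySpec(
            name="pair",
            criteria=(ArtifactCriterion("a", 2), ArtifactCriterion("b", 2)),
            t_min=2.0,
            t_max=10.0,
        )
        full = merge(make_trace("a", [0, 60]), make_trace("b", [30, 90]))
        instances, _ = run_inference(full, [spec])
        assert len(instances) == 1
        # Removing either artifact's beats prevents inference.
        for keep in ("a", "b"):
            partial = [b for b in full if b.artifact_id == keep]
            instances, _ = run_inference(partial, [spec])
            assert instances == []

    def test_flexible_mode_requires_exactly_k_artifacts(self):
        spec = ActivitySpec(
            name="trio",
            criteria=(
                ArtifactCriterion("a", 2),
                ArtifactCriterion("b", 2),
                ArtifactCriterion("c", 2),
            ),
            t_min=2.0,
            t_max=10.0,
            mode="flexible",
            k_required=2,
        )
        traces = {
            "a": make_trace("a", [0, 60]),
            "b": make_trace("b", [30, 90]),
            "c": make_trace("c", [10, 70]),
        }
        # Every single artifact alone: never infers.
        for name, trace in traces.items():
            instances, _ = run_inference(trace, [spec])
            assert instances == [], name
        # Every pair: infers once.
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            instances, _ = run_inference(merge(traces[x], traces[y]), [spec])
            assert len(instances) == 1
            assert instances[0].satisfied_artifacts == sorted((x, y))

    def test_reset_soundness_after_abort(self, specs):
        # A lone beat dies past t_max; a later complete episode infers once.
        lone = [0.0]
        full = [2000.0, 2060.0, 2300.0, 2360.0]
        trace = make_trace("blood_pressure_device", lone + full)
        instances, _ = run_inference(trace, specs)
        assert len(instances) == 1
        assert instances[0].start_t == 2000.0

    def test_episode_span_beyond_t_max_is_rejected(self):
        spec = ActivitySpec(
            name="short",
            criteria=(ArtifactCriterion("a", 3),),
            t_min=1.0,
            t_max=3.0,
        )
        # Gaps each within t_max but total span 320 s > 180 s.
        trace = make_trace("a", [0, 160, 320])
        instances, log = run_inference(trace, [spec])
        assert instances == []
        assert any(entry["event"] == "span_exceeded" for entry in log)

    def test_beats_for_unknown_artifacts_are_ignored(self, specs, blood_pressure_trace):
        noise = make_trace("wheelchair", [10, 20, 30])
        instances, log = run_inference(merge(blood_pressure_trace, noise), specs)
        assert [i.name for i in instances] == ["blood_pressure"]
        assert sum(1 for e in log if e["event"] == "unknown_artifact") == 3

    def test_out_of_order_stream_rejected(self, specs):
        trace = make_trace("tray", [100, 50])
        trace.sort(key=lambda b: -b.t)
        with pytest.raises(OrderingError):
            run_inference(trace, specs)

    def test_results_are_a_pure_function_of_the_stream(self, specs, hygiene_trace):
        a, _ = run_inference(list(hygiene_trace), specs)
        b, _ = run_inference(list(hygiene_trace), specs)
        assert a == b


def random_specs(rng):
    arts = [f"a{i}" for i in range(int(rng.integers(1, 5)))]
    specs = []
    for k in range(int(rng.integers(1, 3))):
        n_art = int(rng.integers(1, min(3, len(arts)) + 1))
        chosen = [str(a) for a in rng.choice(arts, size=n_art, replace=False)]
        criteria = tuple(
            ArtifactCriterion(a, int(rng.integers(1, 5))) for a in chosen
        )
        t_min = float(rng.integers(1, 4))
        t_max = t_min + float(rng.integers(0, 4))
        mode = "flexible" if (n_art >= 2 and rng.random() < 0.5) else "strict"
        k_required = int(rng.integers(2, n_art + 1)) if mode == "flexible" else None
        specs.append(
            ActivitySpec(
                name=f"act{k}",
                criteria=criteria,
                t_min=t_min,
                t_max=t_max,
                mode=mode,
                k_required=k_required,
            )
        )
    return specs, arts


def random_stream(rng, arts):
    beats = []
    for artifact in arts:
        n = int(rng.integers(0, 15))
        times = np.sort(rng.choice(np.arange(0, 4 * 5400), size=n, replace=False)) / 4.0
        state = 0
        for t in times:
            state ^= 1
            beats.append(
                Beat(artifact, float(t), TO_BASE if state else TO_MOBILE)
            )
    beats.sort(key=lambda b: (b.t, b.artifact_id))
    return beats


def instance_key(inst):
    return (
        inst.name,
        inst.start_t,
        inst.end_t,
        inst.inferred_at,
        tuple(inst.satisfied_artifacts),
        tuple((b.t, b.artifact_id) for b in inst.beats),
    )


class TestOracleEquivalence:
    def test_oracle_on_empty_stream(self, specs):
        assert oracle_inference([], specs) == []

    def test_oracle_matches_engine_on_canonical_traces(
        self, specs, blood_pressure_trace, hygiene_trace, interleaved_trace
    ):
        for trace in (blood_pressure_trace, hygiene_trace, interleaved_trace):
            engine, _ = run_inference(trace, specs)
            assert [instance_key(i) for i in engine] == [
                instance_key(i) for i in oracle_inference(trace, specs)
            ]

    def test_oracle_matches_engine_on_random_scenarios(self):
        rng = np.random.default_rng(4177)
        for _ in range(200):
            specs, arts = random_specs(rng)
            stream = random_stream(rng, arts)
            engine, _ = run_inference(stream, specs)
            engine = sorted(engine, key=lambda i: (i.inferred_at, i.name))
            oracle = oracle_inference(stream, specs)
            assert [instance_key(i) for i in engine] == [
                instance_key(i) for i in oracle
            ]
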