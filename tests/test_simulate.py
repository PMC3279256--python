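"""Scenario generation, noise injection, and effectiveness scoring."""

import numpy as np
import pytest

import roambeat as rb
from roambeat.engine import ConfigError
from roambeat.simulate import (
    DEFAULT_MIX,
    NoiseConfig,
    ScenarioConfig,
    _chain_ok,
)


@pytest.fixture(scope="module")
def specs():
    return rb.load_criteria(rb.default_criteria_path())


def small_cfg(seed=3, **kw):
    defaults = dict(
        duration_hours=8.0,
        activity_mix={"feeding": 2, "blood_pressure": 2, "hygiene": 1, "medications": 1},
        seed=seed,
    )
    defaults.update(kw)
    return ScenarioConfig(**defaults)


class TestGenerateScenario:
    def test_single_blood_pressure_episode_discretizes_to_four_beats(self, specs):
        cfg = ScenarioConfig(
            duration_hours=4.0, activity_mix={"blood_pressure": 1}, seed=11
        )
        streams, truth = rb.generate_scenario(cfg, specs)
        assert len(truth) == 1
        beats = rb.discretize_streams(streams)
        assert len(beats) == 4
        assert [b.artifact_id for b in beats] == ["blood_pressure_device"] * 4

    def test_seed_determinism(self, specs):
        a = rb.generate_scenario(small_cfg(seed=42), specs)
        b = rb.generate_scenario(small_cfg(seed=42), specs)
        assert [s.samples for s in a[0].values()] == [s.samples for s in b[0].values()]
        assert [(ep.activity, ep.beat_times) for ep in a[1]] == [
            (ep.activity, ep.beat_times) for ep in b[1]
        ]
        c = rb.generate_scenario(small_cfg(seed=43), specs)
        assert [s.samples for s in a[0].values()] != [s.samples for s in c[0].values()]

    def test_deployment_mix_produces_74_truth_episodes(self, specs):
        streams, truth = rb.generate_scenario(ScenarioConfig(seed=1), specs)
        assert len(truth) == sum(DEFAULT_MIX.values()) == 74
        counts = {}
        for ep in truth:
            counts[ep.activity] = counts.get(ep.activity, 0) + 1
        assert counts == DEFAULT_MIX

    def test_generator_self_consistency(self, specs):
        """Every generated episode, discretized losslessly, satisfies its
        activity's criteria (chain gaps, counts, span)."""
        _, truth = rb.generate_scenario(small_cfg(seed=9), specs)
        by_name = {s.name: s for s in specs}
        for ep in truth:
            spec = by_name[ep.activity]
            flat = sorted(t for ts in ep.beat_times.values() for t in ts)
            assert flat[-1] - flat[0] <= spec.t_max_s
            satisfied = 0
            for artifact, times in ep.beat_times.items():
                crit = spec.criterion_for(artifact)
                assert len(times) >= crit.min_beats
                assert _chain_ok(sorted(times), crit.min_beats, spec)
                satisfied += 1
            assert satisfied >= spec.k_required

    def test_unknown_activity_rejected(self, specs):
        with pytest.raises(ConfigError, match="unknown activity"):
            rb.generate_scenario(
                ScenarioConfig(activity_mix={"juggling": 1}), specs
            )

    def test_infeasible_mix_rejected(self, specs):
        with pytest.raises(ConfigError, match="does not fit"):
            rb.generate_scenario(
                ScenarioConfig(duration_hours=1.0, activity_mix={"feeding": 10}),
                specs,
            )


class TestCorrupt:
    def test_zero_noise_is_identity(self, specs):
        streams, _ = rb.generate_scenario(small_cfg(), specs)
        out = rb.corrupt(streams, NoiseConfig(), seed=5)
        assert {a: s.samples for a, s in out.items()} == {
            a: s.samples for a, s in streams.items()
        }

    def test_total_dropout_silences_every_stream(self, specs):
        streams, _ = rb.generate_scenario(small_cfg(), specs)
        out = rb.corrupt(streams, NoiseConfig(dropout_prob=1.0), seed=5)
        assert all(len(s.samples) == 0 for s in out.values())
        assert rb.discretize_streams(out) == []

    def test_dropout_rate_matches_probability(self, specs):
        streams, _ = rb.generate_scenario(small_cfg(), specs)
        n_total = sum(len(s.samples) for s in streams.values())
        p = 0.1
        fractions = []
        for seed in range(40):
            out = rb.corrupt(streams, NoiseConfig(dropout_prob=p), seed=seed)
            kept = sum(len(s.samples) for s in out.values())
            fractions.append((n_total - kept) / n_total)
        mean = np.mean(fractions)
        se = np.sqrt(p * (1 - p) / (n_total * len(fractions)))
        assert abs(mean - p) <= 3 * se

    def test_corrupted_streams_remain_parseable(self, specs):
        streams, _ = rb.generate_scenario(small_cfg(), specs)
        noise = NoiseConfig(dropout_prob=0.2, spurious_rate=2.0, jitter_sd=1.5)
        out = rb.corrupt(streams, noise, seed=8)
        beats = rb.discretize_streams(out)
        for a, b in zip(beats, beats[1:]):
            assert a.t <= b.t


class TestEvaluate:
    def test_perfect_inference_scores_100(self, specs):
        streams, truth = rb.generate_scenario(small_cfg(), specs)
        instances, _ = rb.run_inference(rb.discretize_streams(streams), specs)
        report = rb.evaluate(instances, truth)
        assert report.effectiveness == 100.0
        assert report.n_inferred == report.n_truth == len(truth)

    def test_empty_inference_scores_zero(self, specs):
        _, truth = rb.generate_scenario(small_cfg(), specs)
        report = rb.evaluate([], truth)
        assert report.n_inferred == 0 and report.effectiveness == 0.0
        assert report.effectiveness_vs_truth == 0.0

    def test_spurious_extra_inferences_lower_the_recorded_rate(self):
        truth = [
            rb.GroundTruthEpisode("feeding", 1000.0 * i, 1000.0 * i + 600.0, {})
            for i in range(4)
        ]
        matching = [
            rb.ActivityInstance("feeding", 1000.0 * i, 1000.0 * i + 600.0,
                                1000.0 * i + 900.0)
            for i in range(3)
        ]
        spurious = rb.ActivityInstance("feeding", 50_000.0, 50_600.0, 50_900.0)
        report = rb.evaluate(matching + [spurious], truth)
        assert report.n_correct == 3
        assert report.effectiveness == pytest.approx(75.0)
        assert report.effectiveness_vs_truth == pytest.approx(75.0)

    def test_overlap_below_threshold_does_not_match(self):
        truth = [rb.GroundTruthEpisode("feeding", 0.0, 1000.0, {})]
        barely = rb.ActivityInstance("feeding", 900.0, 1900.0, 2200.0)
        assert rb.evaluate([barely], truth, overlap_min=0.5).n_correct == 0
        assert rb.evaluate([barely], truth, overlap_min=0.05).n_correct == 1

    def test_effectiveness_not_increasing_with_dropout(self, specs):
        """Monte-Carlo trend: heavier event dropout cannot help inference."""
        cfg = small_cfg(seed=21)
        streams, truth = rb.generate_scenario(cfg, specs)
        means = []
        for p in (0.0, 0.4):
            scores = []
            for seed in range(5):
                noisy = rb.corrupt(streams, NoiseConfig(dropout_prob=p), seed=seed)
                instances, _ = rb.run_inference(rb.discretize_streams(noisy), specs)
                scores.append(rb.evaluate(instances, truth).effectiveness_vs_truth)
            means.append(np.mean(scores))
        assert means[1] <= means[0]


class TestTruthIO:
    def test_round_trip(self, tmp_path, specs):
        _, truth = rb.generate_scenario(small_cfg(), specs)
        from roambeat.simulate import read_truth, write_truth

        path = tmp_path / "truth.jsonl"
        write_truth(truth, path)
        back = read_truth(path)
        assert [(ep.activity, ep.start_t, ep.end_t, ep.beat_times) for ep in back] == [
            (ep.activity, ep.start_t, ep.end_t, ep.beat_times) for ep in truth
        ]
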