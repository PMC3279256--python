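"""Shared fixtures: packaged criteria, canonical traces, random generators."""

import logging

import numpy as np
import pytest

import roambeat as rb
from roambeat.beats import Beat, TO_BASE, TO_MOBILE

# The engine logs every ignored beat; random streams produce many.
logging.getLogger("roambeat.engine").setLevel(logging.ERROR)


def make_trace(artifact_id, times, technology=None, start_state=0):
    """Alternating beat sequence for one artifact from raw beat times."""
    beats = []
    state = start_state
    for t in times:
        state ^= 1
        beats.append(
            Beat(
                artifact_id=artifact_id,
                t=float(t),
                direction=TO_BASE if state else TO_MOBILE,
                technology=technology,
            )
        )
    return beats


def merge(*traces):
    out = [b for tr in traces for b in tr]
    out.sort(key=lambda b: (b.t, b.artifact_id))
    return out


@pytest.fixture(scope="session")
def specs():
    """The packaged nursing-home criteria (4 activities, 6 artifacts)."""
    return rb.load_criteria(rb.default_criteria_path())


@pytest.fixture(scope="session")
def spec_by_name(specs):
    return {s.name: s for s in specs}


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def blood_pressure_trace():
    """Canonical simple activity: place, take, return, remove over 7 minutes."""
    return make_trace("blood_pressure_device", [0, 60, 360, 420])


@pytest.fixture
def hygiene_trace():
    """Canonical composite activity: paper towel 6 beats + solution 3 beats
    inside a 20-minute window; cream silent."""
    towel = make_trace("paper_towel", [0, 120, 300, 500, 700, 900])
    solution = make_trace("physiological_solution", [60, 400, 1000])
    return merge(towel, solution)


@pytest.fixture
def feeding_trace():
    """Tray placed at breakfast, removed 30 minutes later."""
    return make_trace("tray", [0, 1800])


@pytest.fixture
def interleaved_trace(feeding_trace):
    """Medications handed out while the feeding tray sits on the base."""
    pillbox = make_trace("pillbox", [120, 180, 900, 960])
    return merge(feeding_trace, pillbox)
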