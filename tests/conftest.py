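from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from passnet.events import GoalEvent, MatchRecord, PassEvent, SubstitutionEvent
from passnet.simulate import (SimulationConfig, TeamProfile, default_subs,
                              generate_match)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

FCB = "F.C. Barcelona"


@pytest.fixture
def table1_passes() -> list[PassEvent]:
    """The three example passes printed in the source dataset layout."""
    return [
        PassEvent(355.0, FCB, "Busquets", (32.35, 58.35), "Xavi", (41.20, 61.90)),
        PassEvent(359.0, FCB, "Xavi", (50.35, 62.35), "Messi", (60.70, 64.80)),
        PassEvent(363.0, FCB, "Messi", (70.35, 60.55), "Henry", (82.70, 56.50)),
    ]


@pytest.fixture
def table1_match(table1_passes) -> MatchRecord:
    return MatchRecord(match_id="t1", team_a=FCB, team_b=None,
                       passes=tuple(table1_passes))


def two_team_match(seed: int = 42, duration_s: float = 5400.0,
                   subs: bool = True, **a_overrides) -> MatchRecord:
    prof_a = TeamProfile(name="A",
                         sub_schedule=default_subs("A") if subs else (),
                         **a_overrides)
    prof_b = TeamProfile(name="B", retain_prob=2 / 3)
    cfg = SimulationConfig(team_a=prof_a, team_b=prof_b,
                           duration_s=duration_s)
    return generate_match(cfg, seed)


@pytest.fixture(scope="session")
def synthetic_match() -> MatchRecord:
    """One full-length match with substitutions, reused across tests."""
    return two_team_match(seed=42)


@pytest.fixture(scope="session")
def short_match() -> MatchRecord:
    """A 15-minute match: enough passes for a handful of 50-pass windows."""
    return two_team_match(seed=7, duration_s=900.0, subs=False)


def simple_passes(pairs, team="A", t0=0.0, dt=5.0):
    """Hand-build a pass list from (sender, origin, receiver, dest) tuples."""
    out = []
    for k, (s, o, r, d) in enumerate(pairs):
        out.append(PassEvent(t0 + k * dt, team, s, o, r, d))
    return out
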