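"""Synthetic match-event generator.

Emulates the structure of league pass-event data — two teams per match,
asymmetric possession, ~90-minute matches, 11 simultaneous players with
substitutions, spatially embedded passes and sparse goals — with fully
controllable statistical structure, so every pipeline stage can be
exercised and calibrated without proprietary data.

Model
-----
Possession strictly alternates between the two teams.  A possession is a
chain of completed passes whose length is geometric: after every pass the
chain continues with probability ``retain_prob`` (mean chain length
1/(1 − retain_prob)).  Consecutive passes of a team are separated by
exponential waiting times with mean ``60 / pass_rate`` seconds; a fixed
exponential turnover gap separates possessions.  Under this model the
expected share of passes of team A is E[chain_A] / (E[chain_A] +
E[chain_B]).

Each player owns a formation anchor on the pitch.  Pass origins are the
sender's anchor plus isotropic Gaussian noise; the receiver is drawn from
the sender's row of ``receiver_affinity``.  The destination keeps the
receiver-anchor lateral coordinate while the goalward component of the
displacement is scaled so that |Δx| = |Δy| / advance_bias pass by pass;
at a field boundary the whole displacement is shrunk toward the origin,
preserving that ratio, so the match advance ratio equals
``advance_bias`` exactly up to floating-point rounding.  Pass origins
are still clipped at the boundary, which pulls boundary-adjacent
position means slightly inward.  After each pass the passing team scores with
probability ``goal_hazard_scale · (x2/100)²``: a monotone hazard in the
destination coordinate, so teams are playing more advanced just before
they score.  Turnovers are implicit (a chain simply ends); only completed
passes are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .events import GoalEvent, MatchRecord, PassEvent, SubstitutionEvent

#: default 1-4-4-2 formation anchors, own-attack frame (x toward opponent goal)
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = (
    (10.0, 50.0),
    (25.0, 12.0), (25.0, 37.0), (25.0, 63.0), (25.0, 88.0),
    (50.0, 15.0), (50.0, 40.0), (50.0, 60.0), (50.0, 85.0),
    (75.0, 35.0), (75.0, 65.0),
)


class ConfigError(ValueError):
    """An infeasible simulation configuration."""


def uniform_affinity() -> np.ndarray:
    """Every teammate equally likely to receive; zero diagonal."""
    a = np.ones((11, 11))
    np.fill_diagonal(a, 0.0)
    return a


def hub_affinity(hub: int = 6, strength: float = 6.0) -> np.ndarray:
    """One player (default the central midfielder) involved in most play."""
    a = uniform_affinity()
    a[:, hub] *= strength
    a[hub, :] *= strength
    np.fill_diagonal(a, 0.0)
    return a


@dataclass(frozen=True)
class TeamProfile:
    """Generating parameters of one team.

    pass_rate
        Expected completed passes per minute of own possession.
    retain_prob
        Probability each pass is followed by another in the same chain.
    formation_anchors
        11 mean player positions, field units, own attacking frame.
    position_sd
        Isotropic Gaussian spread around the anchors, field units.
    receiver_affinity
        11×11 non-negative receiver preference weights, zero diagonal.
    advance_bias
        Target ratio of lateral to goalward displacement (the advance
        ratio the team's passes realise in expectation).
    sub_schedule
        (time_s, out_index, incoming_name) triples; out_index refers to
        the formation slot 0..10.
    goal_hazard_scale
        Scale of the per-pass scoring probability hazard·(x2/100)².
    """

    name: str
    pass_rate: float = 12.0
    retain_prob: float = 0.8
    formation_anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
    position_sd: float = 8.0
    receiver_affinity: np.ndarray = field(default_factory=uniform_affinity)
    advance_bias: float = 1.0
    sub_schedule: tuple[tuple[float, int, str], ...] = ()
    goal_hazard_scale: float = 0.015

    def __post_init__(self):
        if not (0.0 <= self.retain_prob < 1.0):
            raise ConfigError("retain_prob must lie in [0, 1)")
        if self.pass_rate <= 0:
            raise ConfigError("pass_rate must be positive")
        if len(self.formation_anchors) != 11:
            raise ConfigError("exactly 11 formation anchors required")
        for x, y in self.formation_anchors:
            if not (0 <= x <= 100 and 0 <= y <= 100):
                raise ConfigError(f"anchor ({x}, {y}) outside the field")
        aff = np.asarray(self.receiver_affinity, dtype=float)
        if aff.shape != (11, 11) or (aff < 0).any() or np.diag(aff).any():
            raise ConfigError("receiver_affinity must be 11x11, non-negative, "
                              "zero diagonal")
        if not (0.0 <= self.goal_hazard_scale <= 1.0):
            raise ConfigError("goal_hazard_scale must lie in [0, 1]")
        if self.advance_bias < 0:
            raise ConfigError("advance_bias must be non-negative")

    def players(self) -> list[str]:
        return [f"{self.name}_P{i + 1:02d}" for i in range(11)]


def default_subs(profile_name: str) -> tuple[tuple[float, int, str], ...]:
    """A realistic three-substitution schedule (minutes 55, 70, 82)."""
    return ((55 * 60.0, 8, f"{profile_name}_P12"),
            (70 * 60.0, 9, f"{profile_name}_P13"),
            (82 * 60.0, 5, f"{profile_name}_P14"))


@dataclass(frozen=True)
class SimulationConfig:
    team_a: TeamProfile
    team_b: TeamProfile
    duration_s: float = 5400.0
    turnover_s: float = 5.0      # mean dead time between possessions
    n_matches: int = 1

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.team_a.name == self.team_b.name:
            raise ConfigError("the two teams must have distinct names")


def expected_possession_share(config: SimulationConfig) -> float:
    """Expected share of team_a passes under strict possession alternation."""
    ca = 1.0 / (1.0 - config.team_a.retain_prob)
    cb = 1.0 / (1.0 - config.team_b.retain_prob)
    return ca / (ca + cb)


class _TeamState:
    def __init__(self, profile: TeamProfile):
        self.profile = profile
        self.active = profile.players()          # index = formation slot
        self.pending = sorted(profile.sub_schedule)
        self.aff = np.asarray(profile.receiver_affinity, dtype=float)

    def apply_subs(self, t: float, subs_out: list[SubstitutionEvent]) -> None:
        while self.pending and self.pending[0][0] <= t:
            sched_t, out_idx, incoming = self.pending.pop(0)
            outgoing = self.active[out_idx]
            # event stamped when applied so the outgoing player has
            # provably made no pass after it
            subs_out.append(SubstitutionEvent(
                time_s=max(sched_t, t), team=self.profile.name,
                player_out=outgoing, player_in=incoming))
            self.active[out_idx] = incoming


def _clip(v: float) -> float:
    return min(100.0, max(0.0, v))


def generate_match(config: SimulationConfig,
                   seed: int | np.random.SeedSequence | np.random.Generator,
                   match_id: str | None = None) -> MatchRecord:
    """Simulate one match; byte-identical output for equal seeds."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    a, b = _TeamState(config.team_a), _TeamState(config.team_b)
    passes: list[PassEvent] = []
    goals: list[GoalEvent] = []
    subs: list[SubstitutionEvent] = []

    t = 0.0
    attacking, defending = a, b
    while t < config.duration_s:
        state = attacking
        prof = state.profile
        state.apply_subs(t, subs)
        anchors = np.asarray(prof.formation_anchors, dtype=float)
        sender = int(rng.integers(11))
        while True:
            t += rng.exponential(60.0 / prof.pass_rate)
            if t >= config.duration_s:
                break
            w = state.aff[sender].copy()
            w[sender] = 0.0
            receiver = int(rng.choice(11, p=w / w.sum()))
            ox = _clip(anchors[sender, 0] + rng.normal(0.0, prof.position_sd))
            oy = _clip(anchors[sender, 1] + rng.normal(0.0, prof.position_sd))
            raw_dx = (anchors[receiver, 0]
                      + rng.normal(0.0, prof.position_sd)) - ox
            dy = _clip(anchors[receiver, 1]
                       + rng.normal(0.0, prof.position_sd)) - oy
            if prof.advance_bias > 0:
                dx_mag = abs(dy) / prof.advance_bias
            else:
                dx_mag = abs(raw_dx)
            sign = 1.0 if raw_dx >= 0 else -1.0
            # shrink the whole displacement at the field boundary so the
            # lateral/goalward ratio of every pass is preserved exactly
            shrink = 1.0
            if dx_mag > 1e-12:
                allowed = (100.0 - ox) if sign > 0 else ox
                shrink = min(shrink, allowed / dx_mag)
            if abs(dy) > 1e-12:
                allowed = (100.0 - oy) if dy > 0 else oy
                shrink = min(shrink, allowed / abs(dy))
            shrink = max(shrink, 0.0)
            x2 = _clip(ox + sign * dx_mag * shrink)
            y2 = _clip(oy + dy * shrink)
            passes.append(PassEvent(
                time_s=t, team=prof.name, sender=state.active[sender],
                origin=(ox, oy), receiver=state.active[receiver],
                destination=(x2, y2)))
            if rng.random() < prof.goal_hazard_scale * (x2 / 100.0) ** 2:
                goals.append(GoalEvent(time_s=t, scoring_team=prof.name))
                break
            if rng.random() >= prof.retain_prob:
                break
            sender = receiver
        t += rng.exponential(config.turnover_s)
        attacking, defending = defending, attacking

    return MatchRecord(
        match_id=match_id or f"{config.team_a.name}-vs-{config.team_b.name}",
        team_a=config.team_a.name, team_b=config.team_b.name,
        passes=tuple(passes), goals=tuple(goals),
        substitutions=tuple(sorted(subs, key=lambda s: s.time_s)),
        duration_s=config.duration_s)


def round_robin_fixtures(teams: Sequence[str]) -> list[tuple[str, str]]:
    """Double round-robin: every ordered pair plays once (n(n−1) matches)."""
    return [(h, w) for h in teams for w in teams if h != w]


def generate_season(profiles: Sequence[TeamProfile], seed: int,
                    duration_s: float = 5400.0,
                    turnover_s: float = 5.0) -> list[MatchRecord]:
    """A double-round-robin season: one match per ordered team pair.

    With n teams this is n(n−1) matches, n−1 home and n−1 away per team
    (20 teams → 380 matches, 38 per team).  Per-match seeds derive
    deterministically from the season seed.
    """
    if len(profiles) < 2:
        raise ConfigError("a season needs at least 2 teams")
    if len(profiles) % 2 != 0:
        raise ConfigError("team count must be even")
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ConfigError("team names must be unique")
    by_name = {p.name: p for p in profiles}
    fixtures = round_robin_fixtures(names)
    children = np.random.SeedSequence(seed).spawn(len(fixtures))
    matches = []
    for (home, away), child in zip(fixtures, children):
        cfg = SimulationConfig(team_a=by_name[home], team_b=by_name[away],
                               duration_s=duration_s, turnover_s=turnover_s)
        matches.append(generate_match(cfg, child,
                                      match_id=f"{home}-vs-{away}"))
    return matches
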