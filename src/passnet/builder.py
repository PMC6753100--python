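"""Construction of passing networks.

A passing network has exactly eleven nodes ("slots").  Each titular player
owns one slot; when a player is substituted, the incoming player inherits
the outgoing player's slot (transitively for chained substitutions), so
every network of the match — the match-average network and every sliding
l-pass network — has the same eleven nodes.

Links are directed and weighted by pass counts: ``W[i, j]`` is the number
of passes sent from slot i to slot j inside the network's pass window.
Node positions are the mean origin coordinate of the passes each slot
sent inside the window (receiving a pass never moves a node).
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .events import MatchRecord, PassEvent

log = logging.getLogger(__name__)

N_SLOTS = 11


class RosterError(ValueError):
    """More than eleven titular players for one team."""


class MappingError(ValueError):
    """A substitution references a player who is not currently active."""


class EmptyNetworkError(ValueError):
    """No passes available to build a network from."""


@dataclass(frozen=True)
class PassingNetwork:
    """Directed weighted 11-node network over one window of passes."""

    team: str
    player_slot: dict[str, int]          # every mapped player -> slot 0..10
    slot_chains: tuple[tuple[str, ...], ...]   # per slot: titular, then subs
    W: np.ndarray                        # (11, 11) int pass counts, zero diag
    window: tuple[PassEvent, ...]
    t_first: float
    t_last: float
    mean_origin: np.ndarray              # (11, 2); NaN for slots that sent none

    @property
    def n_passes(self) -> int:
        return len(self.window)

    def symmetrized(self) -> np.ndarray:
        """Total passes exchanged per pair, either direction: W + Wᵀ."""
        return self.W + self.W.T


def assign_slots(match: MatchRecord, team: str) -> dict[str, int]:
    """Map every player of ``team`` to one of the 11 node slots.

    Titular players (those never introduced by a substitution) take slots
    0–10 in order of first appearance; each substitute inherits the slot
    of the player replaced, transitively for chained substitutions.
    """
    if team not in match.teams:
        raise ValueError(f"team {team!r} does not play in match {match.match_id}")
    subs = sorted((s for s in match.substitutions if s.team == team),
                  key=lambda s: s.time_s)
    incoming = {s.player_in for s in subs}

    slot_of: dict[str, int] = {}
    active: dict[int, str] = {}          # slot -> currently active player
    next_slot = 0

    def new_slot(player: str) -> None:
        nonlocal next_slot
        if next_slot >= N_SLOTS:
            raise RosterError(
                f"{team}: more than {N_SLOTS} titular players "
                f"(while assigning {player!r})")
        slot_of[player] = next_slot
        active[next_slot] = player
        next_slot += 1

    # merge passes and subs chronologically; subs at time t apply before
    # any pass at a strictly later time
    events: list[tuple[float, int, object]] = []
    for p in match.passes:
        if p.team == team:
            events.append((p.time_s, 1, p))
    for s in subs:
        events.append((s.time_s, 0, s))
    events.sort(key=lambda e: (e[0], e[1]))

    for _, kind, ev in events:
        if kind == 0:                      # substitution
            s = ev
            if s.player_out not in slot_of and s.player_out not in incoming:
                new_slot(s.player_out)     # titular who never touched the ball
            slot = slot_of.get(s.player_out)
            if slot is None or active.get(slot) != s.player_out:
                raise MappingError(
                    f"{team}: substitution brings {s.player_in!r} on for "
                    f"{s.player_out!r}, who is not currently active")
            slot_of[s.player_in] = slot
            active[slot] = s.player_in
        else:                              # pass
            for player in (ev.sender, ev.receiver):
                if player not in slot_of:
                    if player in incoming:
                        raise MappingError(
                            f"{team}: {player!r} passes before their "
                            f"substitution record")
                    new_slot(player)
    return slot_of


def slot_chains(slot_of: dict[str, int]) -> tuple[tuple[str, ...], ...]:
    """Per slot, the chain of players who occupied it, in order."""
    chains: list[list[str]] = [[] for _ in range(N_SLOTS)]
    for player, slot in slot_of.items():   # dict preserves assignment order
        chains[slot].append(player)
    return tuple(tuple(c) for c in chains)


def _network(team: str, slot_of: dict[str, int],
             chains: tuple[tuple[str, ...], ...],
             window: Sequence[PassEvent]) -> PassingNetwork:
    W = np.zeros((N_SLOTS, N_SLOTS), dtype=np.int64)
    sums = np.zeros((N_SLOTS, 2))
    counts = np.zeros(N_SLOTS, dtype=np.int64)
    for p in window:
        i, j = slot_of[p.sender], slot_of[p.receiver]
        W[i, j] += 1
        sums[i] += p.origin
        counts[i] += 1
    mean_origin = np.full((N_SLOTS, 2), np.nan)
    sent = counts > 0
    mean_origin[sent] = sums[sent] / counts[sent, None]
    return PassingNetwork(
        team=team, player_slot=slot_of, slot_chains=chains, W=W,
        window=tuple(window), t_first=window[0].time_s,
        t_last=window[-1].time_s, mean_origin=mean_origin)


def build_average_network(match: MatchRecord, team: str) -> PassingNetwork:
    """The match-average network: every pass of ``team`` in one window."""
    passes = match.team_passes(team)
    if not passes:
        raise EmptyNetworkError(f"{team} has no passes in {match.match_id}")
    slot_of = assign_slots(match, team)
    return _network(team, slot_of, slot_chains(slot_of), passes)


def sliding_networks(match: MatchRecord, team: str,
                     l: int = 50) -> list[PassingNetwork]:
    """All l-pass sliding windows, advancing one pass at a time.

    With L completed passes this yields exactly ``L - l + 1`` networks,
    window k covering passes k..k+l-1 and stamped with the time of its
    last pass.  Weights are maintained incrementally; a from-scratch
    rebuild gives identical results (tested).
    """
    if l < 2:
        raise ValueError(f"window length l must be >= 2, got {l}")
    passes = match.team_passes(team)
    L = len(passes)
    if L < l:
        log.info("%s/%s: only %d passes, fewer than l=%d; no windows",
                 match.match_id, team, L, l)
        return []
    slot_of = assign_slots(match, team)
    chains = slot_chains(slot_of)

    W = np.zeros((N_SLOTS, N_SLOTS), dtype=np.int64)
    sums = np.zeros((N_SLOTS, 2))
    counts = np.zeros(N_SLOTS, dtype=np.int64)

    def add(p: PassEvent, sign: int) -> None:
        i, j = slot_of[p.sender], slot_of[p.receiver]
        W[i, j] += sign
        sums[i] += np.multiply(sign, p.origin)
        counts[i] += sign

    for p in passes[:l]:
        add(p, +1)
    out: list[PassingNetwork] = []
    for k in range(L - l + 1):
        window = passes[k:k + l]
        mean_origin = np.full((N_SLOTS, 2), np.nan)
        sent = counts > 0
        mean_origin[sent] = sums[sent] / counts[sent, None]
        out.append(PassingNetwork(
            team=team, player_slot=slot_of, slot_chains=chains,
            W=W.copy(), window=window, t_first=window[0].time_s,
            t_last=window[-1].time_s, mean_origin=mean_origin))
        if k + l < L:
            add(passes[k], -1)
            add(passes[k + l], +1)
    return out


def network_before_time(networks: Sequence[PassingNetwork],
                        t: float) -> PassingNetwork | None:
    """The network with the largest ``t_last`` strictly before ``t``.

    ``networks`` must be ordered by ``t_last`` (as produced by
    :func:`sliding_networks`).  Returns None when no window completes
    before ``t``.
    """
    stamps = [n.t_last for n in networks]
    idx = bisect_left(stamps, t) - 1
    return networks[idx] if idx >= 0 else None
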