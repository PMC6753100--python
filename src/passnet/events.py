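"""Reading, validating and writing pass-event streams.

The on-disk dialect is one CSV per match with a leading record-type column
(``PASS``/``GOAL``/``SUB``) so passes, goals and substitutions live in a
single file.  A strict "passes-only" reader accepts the bare layout without
the record column (time, team, sender, origin, receiver, destination).

Coordinates are field units: both axes bounded in [0, 100], with x
increasing toward the opponent's goal for each team, so [100, 50] is the
centre of the opponent's goal.  Times are seconds from kickoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: canonical column order for the event dialect
EVENT_COLUMNS = ("record", "time_s", "team", "player1", "x1", "y1",
                 "player2", "x2", "y2")
#: bare passes-only layout
PASS_COLUMNS = EVENT_COLUMNS[1:]


class FormatError(ValueError):
    """A structural problem with an input file (missing column, bad type)."""


class MatchValidationError(ValueError):
    """An event violates a hard invariant (e.g. coordinate out of bounds)."""


@dataclass(frozen=True)
class PassEvent:
    """One completed pass.

    ``origin``/``destination`` are (x, y) positions of the sender at the
    moment the pass is made and of the receiver at reception.
    """

    time_s: float
    team: str
    sender: str
    origin: tuple[float, float]
    receiver: str
    destination: tuple[float, float]


@dataclass(frozen=True)
class GoalEvent:
    time_s: float
    scoring_team: str


@dataclass(frozen=True)
class SubstitutionEvent:
    time_s: float
    team: str
    player_out: str
    player_in: str


@dataclass(frozen=True)
class MatchRecord:
    """All events of one match: time-ordered passes, goals, substitutions."""

    match_id: str
    team_a: str
    team_b: str | None
    passes: tuple[PassEvent, ...]
    goals: tuple[GoalEvent, ...] = ()
    substitutions: tuple[SubstitutionEvent, ...] = ()
    duration_s: float | None = None

    @property
    def teams(self) -> tuple[str, ...]:
        return (self.team_a,) if self.team_b is None else (self.team_a, self.team_b)

    def duration(self) -> float:
        """Match length; defaults to the time of the last recorded event."""
        if self.duration_s is not None:
            return self.duration_s
        times = [e.time_s for e in self.passes]
        times += [g.time_s for g in self.goals]
        times += [s.time_s for s in self.substitutions]
        return max(times) if times else 0.0

    def team_passes(self, team: str) -> tuple[PassEvent, ...]:
        return tuple(p for p in self.passes if p.team == team)

    def team_goals(self, team: str) -> tuple[GoalEvent, ...]:
        return tuple(g for g in self.goals if g.scoring_team == team)


@dataclass(frozen=True)
class Finding:
    """One validation finding: never an exception, always reportable."""

    severity: str           # "error" | "warning"
    code: str
    row: int | None         # index into the relevant event sequence
    message: str


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def _as_time(value, row: int, path: Path) -> float:
    try:
        t = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"{path}: non-numeric time {value!r} at row {row}") from None
    return t


def _as_coord(value, name: str, row: int, path: Path) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"{path}: non-numeric {name}={value!r} at row {row}") from None
    if not (0.0 <= v <= 100.0):
        raise MatchValidationError(
            f"{path}: {name}={v} outside [0, 100] at row {row}")
    return v


def read_match(path: str | Path, dialect: str = "events",
               match_id: str | None = None) -> MatchRecord:
    """Read one match file.

    Parameters
    ----------
    path
        CSV file, UTF-8, with a header row.
    dialect
        ``"events"`` for the canonical PASS/GOAL/SUB layout, ``"passes"``
        for the bare passes-only layout.
    """
    path = Path(path)
    if dialect not in ("events", "passes"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    expected = EVENT_COLUMNS if dialect == "events" else PASS_COLUMNS
    _require_columns(df, expected, path)

    passes: list[PassEvent] = []
    goals: list[GoalEvent] = []
    subs: list[SubstitutionEvent] = []
    for row, rec in enumerate(df.itertuples(index=False)):
        kind = getattr(rec, "record", "PASS").strip().upper() or "PASS"
        t = _as_time(rec.time_s, row, path)
        if kind == "PASS":
            passes.append(PassEvent(
                time_s=t, team=rec.team, sender=rec.player1,
                origin=(_as_coord(rec.x1, "x1", row, path),
                        _as_coord(rec.y1, "y1", row, path)),
                receiver=rec.player2,
                destination=(_as_coord(rec.x2, "x2", row, path),
                             _as_coord(rec.y2, "y2", row, path))))
        elif kind == "GOAL":
            goals.append(GoalEvent(time_s=t, scoring_team=rec.team))
        elif kind == "SUB":
            subs.append(SubstitutionEvent(time_s=t, team=rec.team,
                                          player_out=rec.player1,
                                          player_in=rec.player2))
        else:
            raise FormatError(f"{path}: unknown record type {kind!r} at row {row}")

    times = [p.time_s for p in passes]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        log.warning("%s: pass events out of time order; re-sorting", path)
        passes.sort(key=lambda p: p.time_s)   # stable: file order breaks ties
    goals.sort(key=lambda g: g.time_s)
    subs.sort(key=lambda s: s.time_s)
    if not passes:
        log.warning("%s: no pass events", path)

    seen: list[str] = []
    for ev in passes + goals + subs:  # type: ignore[operator]
        team = ev.scoring_team if isinstance(ev, GoalEvent) else ev.team
        if team not in seen:
            seen.append(team)
    team_a = seen[0] if seen else "unknown"
    team_b = seen[1] if len(seen) > 1 else None

    return MatchRecord(
        match_id=match_id or path.stem, team_a=team_a, team_b=team_b,
        passes=tuple(passes), goals=tuple(goals), substitutions=tuple(subs))


def write_match(match: MatchRecord, path: str | Path) -> None:
    """Write a match in the canonical PASS/GOAL/SUB dialect.

    Floats are written with ``repr`` precision so a read-back round-trips
    field-for-field.
    """
    rows = []
    for p in match.passes:
        rows.append(("PASS", p.time_s, p.team, p.sender, p.origin[0],
                     p.origin[1], p.receiver, p.destination[0], p.destination[1]))
    for g in match.goals:
        rows.append(("GOAL", g.time_s, g.scoring_team, "", "", "", "", "", ""))
    for s in match.substitutions:
        rows.append(("SUB", s.time_s, s.team, s.player_out, "", "",
                     s.player_in, "", ""))
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    # stable sort keeps the original within-second pass order
    df = df.sort_values("time_s", kind="stable")
    df.to_csv(path, index=False)


def _titulars(match: MatchRecord, team: str) -> list[str]:
    """Players active at kickoff: everyone not introduced by a SUB, in
    order of first appearance in the pass stream."""
    incoming = {s.player_in for s in match.substitutions if s.team == team}
    order: list[str] = []
    for p in match.passes:
        if p.team != team:
            continue
        for player in (p.sender, p.receiver):
            if player not in incoming and player not in order:
                order.append(player)
    for s in match.substitutions:
        if s.team == team and s.player_out not in incoming and s.player_out not in order:
            order.append(s.player_out)
    return order


def validate_match(match: MatchRecord) -> list[Finding]:
    """Check every type invariant; returns findings instead of raising.

    An empty list means the record is fully consistent.
    """
    findings: list[Finding] = []
    teams = set(match.teams)

    prev_t = -float("inf")
    for i, p in enumerate(match.passes):
        if p.time_s < 0:
            findings.append(Finding("error", "negative-time", i,
                                    f"pass at t={p.time_s} < 0"))
        if p.time_s < prev_t:
            findings.append(Finding("error", "unsorted", i,
                                    "passes not in time order"))
        prev_t = p.time_s
        for name, v in (("x1", p.origin[0]), ("y1", p.origin[1]),
                        ("x2", p.destination[0]), ("y2", p.destination[1])):
            if not (0.0 <= v <= 100.0):
                findings.append(Finding("error", "bounds", i,
                                        f"{name}={v} outside [0, 100]"))
        if p.sender == p.receiver:
            findings.append(Finding("error", "self-pass", i,
                                    f"sender equals receiver ({p.sender})"))
        if p.team not in teams:
            findings.append(Finding("error", "unknown-team", i,
                                    f"team {p.team!r} not in match"))

    for i, g in enumerate(match.goals):
        if g.time_s < 0:
            findings.append(Finding("error", "negative-time", i,
                                    f"goal at t={g.time_s} < 0"))
        if g.scoring_team not in teams:
            findings.append(Finding("error", "unknown-team", i,
                                    f"scoring team {g.scoring_team!r} not in match"))

    for i, s in enumerate(match.substitutions):
        if s.player_out == s.player_in:
            findings.append(Finding("error", "sub-self", i,
                                    f"player substituted for themselves ({s.player_out})"))
        for p in match.passes:
            if p.team != s.team:
                continue
            if p.time_s > s.time_s and s.player_out in (p.sender, p.receiver):
                findings.append(Finding("error", "sub-after", i,
                                        f"{s.player_out} active after being "
                                        f"substituted out at t={s.time_s}"))
                break
        for p in match.passes:
            if p.team != s.team:
                continue
            if p.time_s < s.time_s and s.player_in in (p.sender, p.receiver):
                findings.append(Finding("error", "sub-before", i,
                                        f"{s.player_in} active before coming "
                                        f"on at t={s.time_s}"))
                break

    for team in teams:
        titulars = _titulars(match, team)
        if len(titulars) > 11:
            findings.append(Finding(
                "error", "roster-overflow", None,
                f"{team}: {len(titulars)} distinct players with no "
                f"substitution record"))

    if not match.passes:
        findings.append(Finding("warning", "no-events", None, "no pass events"))
    return findings
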