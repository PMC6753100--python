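"""Temporal and season-level analysis.

Three layers:

* per match: one metric vector per sliding l-pass window (a metric time
  series with the timestamp of each window's last pass);
* goal-anchored: the last complete window strictly before each goal,
  classified by whether the team scored or conceded, averaged over a
  season;
* season: match-average-network metrics per match for a focal team and
  the pooled group of its opponents, plus classical tallies (passes,
  goals, league points under 3/1/0 scoring).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .builder import (EmptyNetworkError, PassingNetwork, build_average_network,
                      network_before_time, sliding_networks)
from .events import MatchRecord
from .spatial import compute_spatial
from .topology import compute_topology

#: scalar metric names carried by a MetricVector, in reporting order
METRIC_NAMES = ("X_mean", "Y_mean", "centroid_dispersion", "advance_ratio",
                "t_net", "C", "d", "reachable_fraction", "lambda1",
                "lambda2_alg", "EC_max", "EC_disp")


@dataclass(frozen=True)
class MetricVector:
    """The full metric suite for one network/window.

    Metrics that are undefined on the window (e.g. advance ratio of a
    purely lateral window) are NaN — explicitly missing, never zero.
    ``L`` is the number of passes in scope.
    """

    L: int
    X_mean: float
    Y_mean: float
    centroid_dispersion: float
    advance_ratio: float
    t_net: float
    C: float
    d: float
    reachable_fraction: float
    lambda1: float
    lambda2_alg: float
    EC_max: float
    EC_disp: float

    def as_dict(self) -> dict[str, float]:
        return {"L": self.L, **{m: getattr(self, m) for m in METRIC_NAMES}}


def evaluate_network(net: PassingNetwork, **variant_flags) -> MetricVector:
    """Spatial metrics on the window's passes, topology on its network."""
    sp = compute_spatial(net.window,
                         per_pass_dispersion=variant_flags.get(
                             "per_pass_dispersion", False),
                         signed_advance=variant_flags.get("signed_advance", False))
    tp = compute_topology(net, rescale_clustering=variant_flags.get(
        "rescale_clustering", True))
    return MetricVector(
        L=net.n_passes, X_mean=sp.X_mean, Y_mean=sp.Y_mean,
        centroid_dispersion=sp.centroid_dispersion,
        advance_ratio=sp.advance_ratio, t_net=sp.t_net,
        C=tp.C, d=tp.d, reachable_fraction=tp.reachable_fraction,
        lambda1=tp.lambda1, lambda2_alg=tp.lambda2_alg,
        EC_max=tp.EC_max, EC_disp=tp.EC_disp)


@dataclass(frozen=True)
class MetricSeries:
    """Metric evolution of one team along one match."""

    match_id: str
    team: str
    l: int
    samples: tuple[tuple[float, MetricVector], ...]   # (t of last pass, metrics)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"t": t, **mv.as_dict()} for t, mv in self.samples]
        return pd.DataFrame(rows, columns=["t", "L", *METRIC_NAMES])


def metric_timeseries(match: MatchRecord, team: str, l: int = 50,
                      **variant_flags) -> MetricSeries:
    """One MetricVector per sliding l-pass window of ``team``.

    Empty series when the team never completes l passes.
    """
    nets = sliding_networks(match, team, l)
    samples = tuple((n.t_last, evaluate_network(n, **variant_flags))
                    for n in nets)
    return MetricSeries(match_id=match.match_id, team=team, l=l,
                        samples=samples)


@dataclass(frozen=True)
class GoalAnchoredSummary:
    """Season means of each metric just before scored vs conceded goals."""

    team: str
    mean_before_scored: dict[str, float]
    mean_before_conceded: dict[str, float]
    n_scored: int
    n_conceded: int
    n_skipped: int        # goals with no complete window before them

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"before_scored": self.mean_before_scored,
             "before_conceded": self.mean_before_conceded})


def goal_anchored(matches: Iterable[MatchRecord], team: str,
                  l: int = 50, **variant_flags) -> GoalAnchoredSummary:
    """Network state just before every goal involving ``team``.

    For each goal in each match the team plays, the team's last complete
    l-pass window strictly before the goal time is evaluated; the vector
    joins the "scored" class if the team scored, "conceded" otherwise.
    Goals falling before the team's first complete window are skipped and
    counted.
    """
    scored: list[MetricVector] = []
    conceded: list[MetricVector] = []
    skipped = 0
    for match in matches:
        if team not in match.teams:
            continue
        nets = sliding_networks(match, team, l)
        for goal in match.goals:
            net = network_before_time(nets, goal.time_s)
            if net is None:
                skipped += 1
                continue
            mv = evaluate_network(net, **variant_flags)
            (scored if goal.scoring_team == team else conceded).append(mv)

    def _means(vectors: Sequence[MetricVector]) -> dict[str, float]:
        if not vectors:
            return {m: float("nan") for m in METRIC_NAMES}
        arr = {m: np.array([getattr(v, m) for v in vectors]) for m in METRIC_NAMES}
        with np.errstate(invalid="ignore"):
            return {m: float(np.nanmean(a)) if not np.all(np.isnan(a))
                    else float("nan") for m, a in arr.items()}

    return GoalAnchoredSummary(
        team=team, mean_before_scored=_means(scored),
        mean_before_conceded=_means(conceded),
        n_scored=len(scored), n_conceded=len(conceded), n_skipped=skipped)


def points_for(match: MatchRecord, team: str) -> int:
    """League points from this match under 3/1/0 scoring."""
    if team not in match.teams:
        raise ValueError(f"{team!r} does not play in {match.match_id}")
    own = len(match.team_goals(team))
    other = len(match.goals) - own
    return 3 if own > other else (1 if own == other else 0)


@dataclass(frozen=True)
class SeasonSummary:
    """Per-match average-network metrics for a focal team and its rivals.

    ``per_match`` has one row per (match, team) with a ``group`` column
    ("focal"/"rival"); the focal team is averaged with itself while all
    opponents pool into one group, matching a focal-team season design.
    """

    focal_team: str
    per_match: pd.DataFrame
    group_stats: pd.DataFrame       # mean/sd per group per metric
    season_points: dict[str, int]

    @property
    def metrics(self) -> list[str]:
        skip = {"match_id", "team", "group"}
        return [c for c in self.per_match.columns if c not in skip]

    def group_values(self, metric: str) -> tuple[np.ndarray, np.ndarray]:
        """(focal, rival) per-match value arrays for one metric."""
        if metric not in self.per_match.columns:
            raise KeyError(f"metric {metric!r} not in season summary")
        df = self.per_match
        a = df.loc[df["group"] == "focal", metric].to_numpy(dtype=float)
        b = df.loc[df["group"] == "rival", metric].to_numpy(dtype=float)
        return a, b


def season_summary(matches: Sequence[MatchRecord], focal_team: str,
                   shots: Mapping[tuple[str, str], int] | None = None,
                   **variant_flags) -> SeasonSummary:
    """Average-network metrics for every match of a focal-team season.

    Every match must involve ``focal_team``.  ``shots`` optionally maps
    (match_id, team) to a shot count; shots are external metadata, not
    derivable from pass events.
    """
    rows = []
    season_points: dict[str, int] = {}
    for match in matches:
        if focal_team not in match.teams:
            raise ValueError(
                f"match {match.match_id} does not involve {focal_team!r}")
        for team in match.teams:
            try:
                net = build_average_network(match, team)
                mv = evaluate_network(net, **variant_flags).as_dict()
            except EmptyNetworkError:
                mv = {"L": 0, **{m: float("nan") for m in METRIC_NAMES}}
            row = {"match_id": match.match_id, "team": team,
                   "group": "focal" if team == focal_team else "rival",
                   "n_passes": mv.pop("L"), **mv,
                   "goals": len(match.team_goals(team)),
                   "points": points_for(match, team)}
            if shots is not None:
                row["shots"] = shots.get((match.match_id, team), np.nan)
            rows.append(row)
            season_points[team] = season_points.get(team, 0) + row["points"]

    per_match = pd.DataFrame(rows)
    numeric = per_match.drop(columns=["match_id", "team"])
    group_stats = numeric.groupby("group").agg(["mean", "std"])
    return SeasonSummary(focal_team=focal_team, per_match=per_match,
                         group_stats=group_stats, season_points=season_points)
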