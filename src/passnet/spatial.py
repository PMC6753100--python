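"""Spatial metrics of a pass window.

All operate directly on the sequence of passes (not the graph): centroid
coordinates ⟨X⟩, ⟨Y⟩, dispersion of the players around the centroid,
advance ratio ⟨Δy⟩/⟨Δx⟩, and the window construction time.

Only the origin of each pass contributes to positions: the team's shape is
summarised by where passes are sent from.  The advance ratio divides the
total lateral displacement Σ|y2 − y1| by the total goalward displacement
Σ|x2 − x1|; high values mean the ball moves parallel to the opponent's
goal rather than toward it.  Displacements are summed unsigned — a signed
sum would cancel forward and backward passes and could not represent a
travelled length (a signed variant is available for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .events import PassEvent


class UndefinedMetricError(ValueError):
    """The metric is not defined for this window (reported as missing)."""


@dataclass(frozen=True)
class SpatialMetrics:
    X_mean: float
    Y_mean: float
    centroid_dispersion: float
    advance_ratio: float      # NaN when Σ|Δx| = 0
    t_net: float              # seconds to construct the window


def _origins(window: Sequence[PassEvent]) -> np.ndarray:
    return np.array([p.origin for p in window], dtype=float)


def centroid(window: Sequence[PassEvent]) -> tuple[float, float]:
    """Mean origin coordinate of all passes in the window."""
    if not window:
        raise UndefinedMetricError("centroid of an empty window")
    x, y = _origins(window).mean(axis=0)
    return float(x), float(y)


def centroid_dispersion(window: Sequence[PassEvent],
                        per_pass: bool = False) -> float:
    """SD of players' distances to the window centroid.

    Each sending player is represented by the mean origin of their sent
    passes; the metric is the population standard deviation of those
    players' Euclidean distances to the centroid.  ``per_pass=True``
    switches to the per-pass-origin variant (every pass contributes its
    own distance) for sensitivity analysis.
    """
    if not window:
        raise UndefinedMetricError("dispersion of an empty window")
    cx, cy = centroid(window)
    if per_pass:
        pts = _origins(window)
    else:
        by_player: dict[str, list[tuple[float, float]]] = {}
        for p in window:
            by_player.setdefault(p.sender, []).append(p.origin)
        if len(by_player) < 2:
            raise UndefinedMetricError(
                "dispersion needs at least 2 distinct sending players")
        pts = np.array([np.mean(v, axis=0) for v in by_player.values()])
    dist = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    return float(dist.std(ddof=0))


def advance_ratio(window: Sequence[PassEvent], signed: bool = False) -> float:
    """⟨Δy⟩/⟨Δx⟩: total lateral over total goalward pass displacement."""
    if not window:
        raise UndefinedMetricError("advance ratio of an empty window")
    dx = np.array([p.destination[0] - p.origin[0] for p in window])
    dy = np.array([p.destination[1] - p.origin[1] for p in window])
    if not signed:
        dx, dy = np.abs(dx), np.abs(dy)
    denom = dx.sum()
    if denom == 0:
        raise UndefinedMetricError("advance ratio undefined: total Δx is zero")
    return float(dy.sum() / denom)


def window_time(window: Sequence[PassEvent]) -> float:
    """Seconds from the first to the last pass of the window."""
    if not window:
        raise UndefinedMetricError("window time of an empty window")
    return float(window[-1].time_s - window[0].time_s)


def compute_spatial(window: Sequence[PassEvent],
                    per_pass_dispersion: bool = False,
                    signed_advance: bool = False) -> SpatialMetrics:
    """All spatial metrics; undefined ones come back as NaN."""
    x, y = centroid(window)

    def _try(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except UndefinedMetricError:
            return float("nan")

    return SpatialMetrics(
        X_mean=x, Y_mean=y,
        centroid_dispersion=_try(centroid_dispersion, window,
                                 per_pass=per_pass_dispersion),
        advance_ratio=_try(advance_ratio, window, signed=signed_advance),
        t_net=window_time(window))
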