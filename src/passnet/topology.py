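"""Graph-theoretic metrics of a passing network.

Spectral quantities — weighted clustering, largest adjacency eigenvalue
λ1, algebraic connectivity λ̃2 and eigenvector centrality — presuppose a
symmetric operator, so they act on the symmetrized weight matrix
``W + Wᵀ`` (total passes exchanged per pair in either direction).  The
shortest-path length alone honours pass direction, because it is the ball
that travels the directed links.

Weighted clustering follows the Zhang–Horvath convention:

    C_w(i) = Σ_{j≠k} w_ij w_jk w_ik / Σ_{j≠k} w_ij w_ik,

with weights rescaled by the maximum entry so every w ≤ 1 and C ∈ [0, 1];
the team value C averages C_w(i) over the 11 nodes.  On a binary graph
this reduces to the classical unweighted clustering coefficient.

Link lengths for shortest paths are inverse weights, l_ij = 1/w_ij: the
more passes between two players, the topologically closer they are.  The
average shortest path d divides by the number of *reachable* ordered
pairs; ``reachable_fraction`` reports coverage so the substitution is
visible whenever a sliding window is not strongly connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, dijkstra

from .builder import N_SLOTS, PassingNetwork
from .spatial import UndefinedMetricError


@dataclass(frozen=True)
class TopologyMetrics:
    C: float
    d: float
    reachable_fraction: float
    lambda1: float
    lambda2_alg: float
    ec: np.ndarray = field(repr=False)   # (11,) non-negative, unit 2-norm
    EC_max: float = float("nan")
    EC_disp: float = float("nan")


def _weights(net: PassingNetwork | np.ndarray) -> np.ndarray:
    W = net.W if isinstance(net, PassingNetwork) else np.asarray(net, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    return np.asarray(W, dtype=float)


def symmetrized_weights(net: PassingNetwork | np.ndarray) -> np.ndarray:
    """W + Wᵀ: passes exchanged between each pair, either direction."""
    W = _weights(net)
    return W + W.T


def weighted_clustering(net: PassingNetwork | np.ndarray,
                        rescale: bool = True) -> float:
    """Zhang–Horvath weighted clustering coefficient, averaged over nodes.

    Nodes with fewer than two weighted neighbours contribute 0.  With
    ``rescale=False`` the raw symmetrized counts are used (C is then not
    bounded by 1).
    """
    A = symmetrized_weights(net)
    np.fill_diagonal(A, 0.0)
    if rescale and A.max() > 0:
        A = A / A.max()
    # ordered pairs j != k, both != i; diagonal is zero so the j == k
    # term of the numerator vanishes on its own
    num = np.diag(A @ A @ A)
    row = A.sum(axis=1)
    den = row ** 2 - (A ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(ci.mean())


def average_shortest_path(
        net: PassingNetwork | np.ndarray) -> tuple[float, float]:
    """(d, reachable_fraction) via Dijkstra on inverse-weight lengths.

    d averages the shortest topological distance p_ij over all reachable
    ordered pairs i ≠ j of the *directed* network.
    """
    W = _weights(net)
    n = W.shape[0]
    if not W.any():
        raise UndefinedMetricError("shortest path undefined: no links")
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    dist = dijkstra(lengths, directed=True)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    reachable_fraction = finite.sum() / (n * (n - 1))
    d = float(dist[finite].mean())
    return d, float(reachable_fraction)


def largest_eigenvalue(net: PassingNetwork | np.ndarray) -> float:
    """λ1 of the symmetrized weight matrix — the network strength.

    For integer pass counts it satisfies s_max ≥ λ1 ≥ max(⟨S⟩, √s_max),
    where the strength s_i is the total passes player i exchanged, ⟨S⟩
    the mean strength and s_max the largest.
    """
    A = symmetrized_weights(net)
    lam = float(np.linalg.eigvalsh(A)[-1])
    return max(lam, 0.0)


def algebraic_connectivity(net: PassingNetwork | np.ndarray) -> float:
    """λ̃2: second-smallest eigenvalue of the Laplacian L̃ = S − A.

    A is the symmetrized weight matrix and S the diagonal of its row
    sums.  Zero exactly when the (symmetrized) network splits into
    disconnected groups; larger values mean a more cohesive team.
    """
    A = symmetrized_weights(net)
    L = np.diag(A.sum(axis=1)) - A
    lam2 = float(np.linalg.eigvalsh(L)[1])
    return max(lam2, 0.0)


def is_connected(net: PassingNetwork | np.ndarray) -> bool:
    A = symmetrized_weights(net)
    ncomp, _ = connected_components(A > 0, directed=False)
    return ncomp == 1


def eigenvector_centrality(
        net: PassingNetwork | np.ndarray) -> tuple[np.ndarray, float, float]:
    """(ec, EC_max, EC_disp) from the leading eigenvector of W + Wᵀ.

    The Perron vector is taken with non-negative entries and unit
    Euclidean norm; a uniform complete team therefore sits at the
    reference point EC_max = 1/√11.  EC_disp is the population SD over
    all 11 slots, zero-centrality slots included.  On a disconnected
    network the vector is supported on the component with the larger λ1.
    """
    A = symmetrized_weights(net)
    if not A.any():
        raise UndefinedMetricError("eigenvector centrality undefined: no links")
    vals, vecs = np.linalg.eigh(A)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)           # Perron vector: numerical negatives -> 0
    v = v / np.linalg.norm(v)
    return v, float(v.max()), float(v.std(ddof=0))


def compute_topology(net: PassingNetwork | np.ndarray,
                     rescale_clustering: bool = True) -> TopologyMetrics:
    """All topology metrics; undefined ones come back as NaN."""
    W = _weights(net)
    C = weighted_clustering(W, rescale=rescale_clustering)
    try:
        d, rf = average_shortest_path(W)
    except UndefinedMetricError:
        d, rf = float("nan"), 0.0
    lam1 = largest_eigenvalue(W)
    lam2 = algebraic_connectivity(W)
    try:
        ec, ec_max, ec_disp = eigenvector_centrality(W)
    except UndefinedMetricError:
        ec = np.full(W.shape[0], np.nan)
        ec_max = ec_disp = float("nan")
    return TopologyMetrics(C=C, d=d, reachable_fraction=rf, lambda1=lam1,
                           lambda2_alg=lam2, ec=ec, EC_max=ec_max,
                           EC_disp=ec_disp)
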