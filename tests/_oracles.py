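"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: triple loops, exhaustive path enumeration, power
iteration.  They share no code with the package paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def clustering_triple_loop(A: np.ndarray, rescale: bool = True) -> float:
    """Weighted clustering by literal evaluation of the per-node formula
    over all ordered (j, k) pairs, averaged over nodes."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if rescale and A.max() > 0:
        A = A / A.max()
    total = 0.0
    for i in range(n):
        num = den = 0.0
        for j in range(n):
            for k in range(n):
                if j == k or j == i or k == i:
                    continue
                num += A[i, j] * A[j, k] * A[i, k]
                den += A[i, j] * A[i, k]
        total += num / den if den > 0 else 0.0
    return total / n


def shortest_paths_enumeration(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest directed path lengths (l_ij = 1/w_ij) by
    exhaustive enumeration of simple paths."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    best = np.full((n, n), np.inf)
    np.fill_diagonal(best, 0.0)

    def explore(node: int, start: int, visited: set, length: float) -> None:
        for nxt in range(n):
            if nxt in visited or W[node, nxt] <= 0:
                continue
            cand = length + 1.0 / W[node, nxt]
            if cand < best[start, nxt]:
                best[start, nxt] = cand
            explore(nxt, start, visited | {nxt}, cand)

    for s in range(n):
        explore(s, s, {s}, 0.0)
    return best


def average_path_enumeration(W: np.ndarray) -> tuple[float, float]:
    n = W.shape[0]
    p = shortest_paths_enumeration(W)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(p) & off
    return float(p[finite].mean()), finite.sum() / (n * (n - 1))


def power_iteration(A: np.ndarray, iters: int = 5000,
                    tol: float = 1e-13) -> tuple[float, np.ndarray]:
    """Leading eigenpair of a symmetric non-negative matrix.

    A positive diagonal shift makes the dominant eigenvalue strictly
    largest in modulus (a star graph has lambda_min = -lambda_max, which
    would otherwise make the iteration oscillate).
    """
    A = np.asarray(A, dtype=float)
    shift = 1.0 + A.sum(axis=1).max()
    M = A + shift * np.eye(A.shape[0])
    v = np.ones(A.shape[0]) / np.sqrt(A.shape[0])
    lam = 0.0
    for _ in range(iters):
        w = M @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0, v
        w /= norm
        if np.linalg.norm(w - v) < tol:
            v = w
            break
        v = w
    lam = float(v @ A @ v)
    return lam, np.abs(v)


def connected_union_find(A: np.ndarray) -> bool:
    """Connectivity of the symmetrized support via union-find."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(n):
            if A[i, j] > 0 or A[j, i] > 0:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)}) == 1


def step_up_fdr(p: np.ndarray, alpha: float) -> np.ndarray:
    """Direct evaluation of the Benjamini–Hochberg step-up rule."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def exact_ranksum_p(a, b) -> float:
    """Two-sided exact rank-sum p-value by full enumeration of the
    label assignments (tie-free samples only)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(a)
    w_obs = sum(ranks[v] for v in a)
    mid = n_a * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n_a):
        w = sum(combo)
        total += 1
        if abs(w - mid) >= abs(w_obs - mid) - 1e-12:
            count += 1
    return count / total
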