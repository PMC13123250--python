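"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with gcfkit's algorithms: exhaustive
matching for copy-level similarity, breadth-first search for connected
components, and a dense grid search for the power-law MLE.
"""
from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy import special

from gcfkit.similarity import _copy_similarity


def dss_bruteforce(a, b) -> float:
    """Exhaustive optimal copy matching over every shared domain type."""
    by_type_a: dict[str, list] = {}
    by_type_b: dict[str, list] = {}
    for c in a:
        by_type_a.setdefault(c.domain_type, []).append(c)
    for c in b:
        by_type_b.setdefault(c.domain_type, []).append(c)
    shared = set(by_type_a) & set(by_type_b)
    total, n_matched, n_unmatched = 0.0, 0, 0
    for dtype in shared:
        ca, cb = by_type_a[dtype], by_type_b[dtype]
        if len(ca) > len(cb):
            ca, cb = cb, ca
        best = 0.0
        for perm in itertools.permutations(range(len(cb)), len(ca)):
            best = max(
                best, sum(_copy_similarity(x, cb[j]) for x, j in zip(ca, perm))
            )
        total += best
        n_matched += len(ca)
        n_unmatched += len(cb) - len(ca)
    for dtype in set(by_type_a) - shared:
        n_unmatched += len(by_type_a[dtype])
    for dtype in set(by_type_b) - shared:
        n_unmatched += len(by_type_b[dtype])
    denom = n_matched + n_unmatched
    return total / denom if denom else 0.0


def components_bfs(nodes, edges) -> list[frozenset]:
    """Connected components by breadth-first search on an adjacency map."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set[str] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        queue = deque([start])
        comp = set()
        while queue:
            node = queue.popleft()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def powerlaw_alpha_grid(sizes, xmin: int = 1, step: float = 1e-3) -> float:
    """Dense grid-search MLE for the discrete power-law exponent."""
    tail = np.asarray([s for s in sizes if s >= xmin], dtype=float)
    slog = np.sum(np.log(tail))
    grid = np.arange(1.0 + step, 20.0, step)
    loglik = -grid * slog - tail.size * np.log(special.zeta(grid, xmin))
    return float(grid[np.argmax(loglik)])


def knee_chord_exhaustive(x, y) -> float:
    """Exhaustive perpendicular-chord-distance knee on normalised axes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xn = (x - x[0]) / (x[-1] - x[0])
    span = y[-1] - y[0]
    yn = (y - y[0]) / span if span else np.zeros_like(y)
    best_d, best_x = -1.0, x[0]
    for xi, yi in zip(xn, yn):
        # distance from (xi, yi) to the line through (0, yn[0]) and (1, yn[-1])
        d = abs((yn[-1] - yn[0]) * xi - (1 - 0) * (yi - yn[0])) / np.hypot(
            1.0, yn[-1] - yn[0]
        )
        if d > best_d + 1e-12:
            best_d, best_x = d, xi
    return float(x[0] + best_x * (x[-1] - x[0]))
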