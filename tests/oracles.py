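"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive enumeration and
bisection — and shares no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations


def all_simple_paths(edges: set[tuple[str, str]], source: str, target: str,
                     vertices: set[str]) -> list[tuple[str, ...]]:
    """Every simple source->target path by depth-first enumeration."""
    adjacency: dict[str, list[str]] = {v: [] for v in vertices}
    for u, v in edges:
        adjacency[u].append(v)
    out: list[tuple[str, ...]] = []

    def walk(path: list[str]) -> None:
        node = path[-1]
        if node == target:
            out.append(tuple(path))
            return
        for succ in adjacency[node]:
            if succ not in path:
                walk(path + [succ])

    if source in vertices and target in vertices:
        walk([source])
    return out


def ksp_oracle(edges: set[tuple[str, str]], source: str, target: str,
               vertices: set[str], k: int | None = None
               ) -> list[tuple[str, ...]]:
    """All simple paths sorted by (hop count, lexicographic sequence)."""
    paths = sorted(all_simple_paths(edges, source, target, vertices),
                   key=lambda p: (len(p), p))
    return paths if k is None else paths[:k]


def betweenness_oracle(edges: set[tuple[str, str]],
                       vertices: set[str]) -> dict[str, float]:
    """Scaled betweenness by explicit all-pairs shortest-path counting.

    Works on the undirected view; pairs with no connecting path contribute
    zero; scaling is 2/((n-1)(n-2)).
    """
    undirected = {frozenset(e) for e in edges if e[0] != e[1]}
    und_edges = {(u, v) for e in undirected for u, v in (tuple(e), tuple(e)[::-1])}
    n = len(vertices)
    raw = {v: 0.0 for v in vertices}
    for s, t in combinations(sorted(vertices), 2):
        paths = all_simple_paths(und_edges, s, t, vertices)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for i in vertices:
            if i in (s, t):
                continue
            through = sum(1 for p in geodesics if i in p)
            raw[i] += through / len(geodesics)
    if n < 3:
        return {v: 0.0 for v in vertices}
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: raw[v] * scale for v in vertices}


def degree_oracle(edges: set[tuple[str, str]],
                  vertices: set[str]) -> dict[str, float]:
    """deg(i)/(n-1) on the undirected simple view, by direct counting."""
    undirected = {frozenset(e) for e in edges if e[0] != e[1]}
    n = len(vertices)
    degree = {v: sum(1 for e in undirected if v in e) for v in vertices}
    return {v: degree[v] / (n - 1) for v in vertices}


def line_graph_edge_count(undirected_edges: set[frozenset]) -> int:
    """Sum over vertices of C(deg, 2) — the line-graph edge count law."""
    degree: dict[str, int] = {}
    for edge in undirected_edges:
        for v in edge:
            degree[v] = degree.get(v, 0) + 1
    return sum(d * (d - 1) // 2 for d in degree.values())


def _std_normal_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def inverse_survival_bisect(p: float, tol: float = 1e-12) -> float:
    """Solve 1 - Phi(z) = p by bisection on the standard normal CDF."""
    lo, hi = -40.0, 40.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if 1.0 - _std_normal_cdf(mid) > p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def reachable(edges: set[tuple[str, str]], source: str,
              vertices: set[str]) -> set[str]:
    """Transitive closure from one vertex by naive expansion."""
    seen = {source}
    changed = True
    while changed:
        changed = False
        for u, v in edges:
            if u in seen and v not in seen:
                seen.add(v)
                changed = True
    return seen
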