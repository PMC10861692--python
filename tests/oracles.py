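"""Independent brute-force oracles used to cross-check graph algorithms.

Deliberately naive: plain recursive DFS over raw successor dicts, no
networkx algorithm calls, so that agreement with the implementation is a
genuine dual-route check.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx


def successors(g: nx.DiGraph) -> dict[str, list[str]]:
    return {v: sorted(g.successors(v)) for v in g.nodes}


def brute_simple_paths(
    g: nx.DiGraph, sources: Iterable[str], targets: Iterable[str]
) -> list[tuple[str, ...]]:
    """All simple source-to-target paths of length >= 1, by recursive DFS."""
    succ = successors(g)
    targets = set(targets)
    out: list[tuple[str, ...]] = []

    def dfs(path: list[str]) -> None:
        tail = path[-1]
        if tail in targets and len(path) > 1:
            out.append(tuple(path))
        for nxt in succ[tail]:
            if nxt not in path:
                dfs(path + [nxt])

    for s in sorted(set(sources)):
        if s in succ:
            dfs([s])
    return sorted(out)


def brute_betweenness(g: nx.DiGraph) -> dict[str, float]:
    """Directed betweenness by exhaustive shortest-path enumeration.

    For every ordered pair (s, t), all simple paths are enumerated, the
    shortest kept, and each interior node credited with its share of them;
    totals are rescaled by 1 / ((n-1)(n-2)) for n > 2.
    """
    nodes = list(g.nodes)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = brute_simple_paths(g, [s], [t])
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            short_paths = [p for p in paths if len(p) == shortest]
            for v in nodes:
                if v in (s, t):
                    continue
                on = sum(1 for p in short_paths if v in p)
                score[v] += on / len(short_paths)
    if n > 2:
        scale = 1.0 / ((n - 1) * (n - 2))
        score = {v: x * scale for v, x in score.items()}
    return score


def all_digraphs(n: int):
    """Yield every labelled simple digraph on nodes '0'..'n-1' (no self-loops)."""
    names = [str(i) for i in range(n)]
    pairs = [(a, b) for a in names for b in names if a != b]
    for mask in range(1 << len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(names)
        for bit, (a, b) in enumerate(pairs):
            if mask >> bit & 1:
                g.add_edge(a, b)
        yield g


def random_digraph(n: int, p: float, rng) -> nx.DiGraph:
    names = [str(i) for i in range(n)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for a in names:
        for b in names:
            if a != b and rng.random() < p:
                g.add_edge(a, b)
    return g
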