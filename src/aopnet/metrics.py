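"""Node-level statistics of a merged AOP network.

All metrics run on the collapsed simple directed graph (one edge per
ordered node pair); per-AOP multiplicity stays in edge provenance. The
statistics computed here are the ones used to rank key events by network
centrality:

degree / in-degree / out-degree
    Connectivity counts; the in/out imbalance classifies nodes as
    convergence points (more upstream neighbours) or divergence points
    (more downstream neighbours).
directed eccentricity
    Longest shortest-path distance over the chosen orientation. With the
    default *incoming* orientation, ecc(v) is the maximum number of hops
    from any ancestor of v, so initiating events score 0 and terminal
    outcomes score high; nodes band as net-upstream (< 3), middle (3-6)
    or net-downstream (> 6). Unreachable pairs are ignored.
betweenness centrality
    Standard directed shortest-path betweenness, normalised by
    (n-1)(n-2), endpoints excluded.
simple path occurrence (normalised)
    The fraction of all simple MIE-to-AO paths that pass through a node —
    an adaptation of betweenness restricted to routes joining initiating
    events to adverse outcomes, which is the more informative centrality
    on this kind of network. Enumeration is cycle-safe because simple
    paths forbid node revisits.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx

from .build import AOPNetwork, sources_and_sinks
from .model import AopnetError, PathExplosionError, Woe

DEFAULT_MAX_PATHS = 1_000_000


class DegreeTriple(NamedTuple):
    in_degree: int
    out_degree: int
    degree: int


class ConvergenceClass(str, Enum):
    CONVERGENT = "convergent"
    DIVERGENT = "divergent"
    BALANCED = "balanced"


class EccentricityBand(str, Enum):
    UPSTREAM = "upstream"
    MIDDLE = "middle"
    DOWNSTREAM = "downstream"


class Orientation(str, Enum):
    """Edge direction along which eccentricity distances are measured."""

    INCOMING = "incoming"
    OUTGOING = "outgoing"


def _graph(network: AOPNetwork | nx.DiGraph) -> nx.DiGraph:
    return network.graph if isinstance(network, AOPNetwork) else network


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (so 57.78 -> 58, 2.5 -> 3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def degrees(network: AOPNetwork | nx.DiGraph) -> dict[str, DegreeTriple]:
    """Per-node (in, out, total) degree over the collapsed edge set."""
    g = _graph(network)
    return {
        v: DegreeTriple(g.in_degree(v), g.out_degree(v), g.in_degree(v) + g.out_degree(v))
        for v in g.nodes
    }


def classify_convergence(
    degs: Mapping[str, DegreeTriple],
) -> dict[str, ConvergenceClass]:
    """Convergent iff in > out; divergent iff out > in; balanced otherwise.

    Isolated nodes (0, 0) are balanced, so the three classes partition the
    node set.
    """
    out: dict[str, ConvergenceClass] = {}
    for node, d in degs.items():
        if d.in_degree > d.out_degree:
            out[node] = ConvergenceClass.CONVERGENT
        elif d.out_degree > d.in_degree:
            out[node] = ConvergenceClass.DIVERGENT
        else:
            out[node] = ConvergenceClass.BALANCED
    return out


def directed_eccentricity(
    network: AOPNetwork | nx.DiGraph,
    orientation: Orientation | str = Orientation.INCOMING,
) -> dict[str, int]:
    """Maximum finite shortest-path distance per node, directionally.

    incoming (default)
        ecc(v) = max over ancestors u of d(u, v); nodes with no ancestors
        score 0. Low values sit near the top of the event cascade.
    outgoing
        ecc(v) = max over descendants w of d(v, w); sinks score 0.

    Unreachable pairs contribute nothing (the maximum runs over finite
    distances only), so disconnected networks still get finite scores.
    """
    g = _graph(network)
    orientation = Orientation(orientation)
    search = g.reverse(copy=False) if orientation is Orientation.INCOMING else g
    ecc: dict[str, int] = {}
    for v in g.nodes:
        lengths = nx.single_source_shortest_path_length(search, v)
        ecc[v] = max(lengths.values(), default=0)
    return ecc


def band_eccentricity(ecc: Mapping[str, int]) -> dict[str, EccentricityBand]:
    """Band nodes as net-upstream (ecc < 3), middle (3-6) or net-downstream (> 6)."""
    out: dict[str, EccentricityBand] = {}
    for node, e in ecc.items():
        if e < 3:
            out[node] = EccentricityBand.UPSTREAM
        elif e > 6:
            out[node] = EccentricityBand.DOWNSTREAM
        else:
            out[node] = EccentricityBand.MIDDLE
    return out


def betweenness(network: AOPNetwork | nx.DiGraph) -> dict[str, float]:
    """Directed shortest-path betweenness, normalised by (n-1)(n-2)."""
    g = _graph(network)
    return nx.betweenness_centrality(g, normalized=True)


def simple_paths_between(
    graph: nx.DiGraph,
    sources: Iterable[str],
    targets: Iterable[str],
    max_paths: int = DEFAULT_MAX_PATHS,
) -> list[tuple[str, ...]]:
    """All simple directed paths from any source to any target.

    Node revisits are forbidden, so enumeration terminates on cyclic
    graphs. Zero-length (single-node) paths are never emitted: a node that
    is both a source and a target contributes no trivial path, because a
    path with no relationship carries no information. Output order is
    lexicographic and deterministic. Raises :class:`PathExplosionError`
    once more than ``max_paths`` paths are found.
    """
    source_set = sorted(set(sources) & set(graph.nodes))
    target_set = set(targets) & set(graph.nodes)
    paths: list[tuple[str, ...]] = []
    for src in source_set:
        reachable_targets = target_set - {src}
        if not reachable_targets:
            continue
        for path in nx.all_simple_paths(graph, src, reachable_targets):
            paths.append(tuple(path))
            if len(paths) > max_paths:
                raise PathExplosionError(
                    f"more than {max_paths} simple paths; raise the max_paths guard "
                    "if enumeration at this scale is intended"
                )
    paths.sort()
    return paths


def enumerate_mie_ao_paths(
    network: AOPNetwork,
    mie_set: Iterable[str] | None = None,
    ao_set: Iterable[str] | None = None,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> list[tuple[str, ...]]:
    """All simple MIE-to-AO paths of the network.

    Endpoint sets default to the annotation-driven MIE and AO sets of the
    network (per-AOP roles), never to degree-based guesses; an initiating
    event with incoming edges is still a valid path start.
    """
    if mie_set is None or ao_set is None:
        auto_mie, auto_ao = sources_and_sinks(network)
        mie_set = auto_mie if mie_set is None else mie_set
        ao_set = auto_ao if ao_set is None else ao_set
    mie_set, ao_set = set(mie_set), set(ao_set)
    if not mie_set or not ao_set:
        raise AopnetError("path enumeration requires non-empty MIE and AO sets")
    return simple_paths_between(network.graph, mie_set, ao_set, max_paths=max_paths)


def path_occurrence(
    paths: Sequence[tuple[str, ...]], nodes: Iterable[str]
) -> dict[str, float]:
    """Fraction of enumerated paths containing each node.

    Endpoints count as contained. A node on every path scores exactly 1;
    nodes on no path score 0. Raises on an empty path list (the
    normalisation would be undefined).
    """
    if not paths:
        raise AopnetError("path occurrence is undefined for an empty path list")
    counts: Counter[str] = Counter()
    for path in paths:
        counts.update(set(path))
    total = len(paths)
    return {v: counts.get(v, 0) / total for v in nodes}


def ke_sharing(network: AOPNetwork) -> tuple[dict[str, int], dict[int, int]]:
    """Per-node AOP membership count and its histogram."""
    share = {
        t: len(network.key_events[t].aop_ids)
        for t in network.graph.nodes
    }
    histogram = dict(sorted(Counter(share.values()).items()))
    return share, histogram


def woe_counts(network: AOPNetwork) -> dict[Woe, int]:
    counts = Counter(data["woe"] for _, _, data in network.graph.edges(data=True))
    return {w: counts.get(w, 0) for w in Woe}


def woe_distribution(network: AOPNetwork) -> dict[Woe, int]:
    """Percentage of collapsed edges per evidence level (integer percent).

    Rounding is half away from zero; the percentages may therefore sum to
    slightly off 100 — the summary flags that case and always carries the
    raw fractions.
    """
    counts = woe_counts(network)
    n_edges = sum(counts.values())
    if n_edges == 0:
        return {w: 0 for w in Woe}
    return {w: round_half_away(100.0 * c / n_edges) for w, c in counts.items()}


@dataclass
class MetricsRecord:
    """All node-level statistics for one key event."""

    node: str
    in_degree: int
    out_degree: int
    degree: int
    eccentricity: int
    eccentricity_band: EccentricityBand
    betweenness: float
    path_occurrence: float
    convergence_class: ConvergenceClass
    aop_share_count: int

    def as_dict(self) -> dict:
        return {
            "node": self.node,
            "in_degree": self.in_degree,
            "out_degree": self.out_degree,
            "degree": self.degree,
            "eccentricity": self.eccentricity,
            "eccentricity_band": self.eccentricity_band.value,
            "betweenness": self.betweenness,
            "path_occurrence": self.path_occurrence,
            "convergence_class": self.convergence_class.value,
            "aop_share_count": self.aop_share_count,
        }


@dataclass
class NetworkSummary:
    """Whole-network statistics backing the distribution figures."""

    n_nodes: int
    n_edges: int
    n_paths: int
    n_convergent: int
    n_divergent: int
    n_balanced: int
    share_histogram: dict[int, int]
    single_aop_pct: int
    ecc_band_fractions: dict[str, int]
    ecc_band_fractions_raw: dict[str, float]
    indegree_histogram: dict[int, int]
    outdegree_histogram: dict[int, int]
    indegree_pct_all: dict[int, int]
    indegree_pct_nonzero: dict[int, int]
    outdegree_pct_all: dict[int, int]
    outdegree_pct_nonzero: dict[int, int]
    woe_counts: dict[str, int]
    woe_distribution: dict[str, int]
    woe_fractions_raw: dict[str, float]
    rounding_notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_paths": self.n_paths,
            "n_convergent": self.n_convergent,
            "n_divergent": self.n_divergent,
            "n_balanced": self.n_balanced,
            "share_histogram": self.share_histogram,
            "single_aop_pct": self.single_aop_pct,
            "ecc_band_fractions": self.ecc_band_fractions,
            "ecc_band_fractions_raw": self.ecc_band_fractions_raw,
            "indegree_histogram": self.indegree_histogram,
            "outdegree_histogram": self.outdegree_histogram,
            "indegree_pct_all": self.indegree_pct_all,
            "indegree_pct_nonzero": self.indegree_pct_nonzero,
            "outdegree_pct_all": self.outdegree_pct_all,
            "outdegree_pct_nonzero": self.outdegree_pct_nonzero,
            "woe_counts": self.woe_counts,
            "woe_distribution": self.woe_distribution,
            "woe_fractions_raw": self.woe_fractions_raw,
            "rounding_notes": self.rounding_notes,
        }


def _pct_histograms(
    hist: dict[int, int], n_all: int
) -> tuple[dict[int, int], dict[int, int]]:
    """Percentage views of a degree histogram under both denominators.

    The population for the "nonzero" view is nodes with the respective
    degree >= 1; both views are emitted because either denominator is a
    defensible reading of per-degree percentages.
    """
    n_nonzero = sum(c for d, c in hist.items() if d >= 1)
    pct_all = {d: round_half_away(100.0 * c / n_all) for d, c in hist.items()} if n_all else {}
    pct_nonzero = (
        {d: round_half_away(100.0 * c / n_nonzero) for d, c in hist.items() if d >= 1}
        if n_nonzero
        else {}
    )
    return pct_all, pct_nonzero


def summarise(
    network: AOPNetwork,
    orientation: Orientation | str = Orientation.INCOMING,
    max_paths: int = DEFAULT_MAX_PATHS,
) -> tuple[NetworkSummary, list[MetricsRecord]]:
    """Compute every node statistic and the whole-network distributions.

    Returns the summary plus one :class:`MetricsRecord` per node, ranked by
    (path occurrence desc, degree desc, title asc).
    """
    g = network.graph
    degs = degrees(network)
    conv = classify_convergence(degs)
    ecc = directed_eccentricity(network, orientation)
    bands = band_eccentricity(ecc)
    btw = betweenness(network)
    share, share_hist = ke_sharing(network)

    paths = enumerate_mie_ao_paths(network, max_paths=max_paths)
    occ = path_occurrence(paths, g.nodes) if paths else {v: 0.0 for v in g.nodes}

    records = [
        MetricsRecord(
            node=v,
            in_degree=degs[v].in_degree,
            out_degree=degs[v].out_degree,
            degree=degs[v].degree,
            eccentricity=ecc[v],
            eccentricity_band=bands[v],
            betweenness=btw[v],
            path_occurrence=occ[v],
            convergence_class=conv[v],
            aop_share_count=share[v],
        )
        for v in g.nodes
    ]
    records.sort(key=lambda r: (-r.path_occurrence, -r.degree, r.node))

    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    class_counts = Counter(conv.values())
    band_counts = Counter(bands.values())
    band_raw = {
        b.value: (100.0 * band_counts.get(b, 0) / n_nodes if n_nodes else 0.0)
        for b in EccentricityBand
    }
    band_pct = {b: round_half_away(x) for b, x in band_raw.items()}

    in_hist = dict(sorted(Counter(d.in_degree for d in degs.values()).items()))
    out_hist = dict(sorted(Counter(d.out_degree for d in degs.values()).items()))
    in_pct_all, in_pct_nz = _pct_histograms(in_hist, n_nodes)
    out_pct_all, out_pct_nz = _pct_histograms(out_hist, n_nodes)

    wcounts = woe_counts(network)
    wdist = woe_distribution(network)
    wraw = {
        w.value: (100.0 * c / n_edges if n_edges else 0.0) for w, c in wcounts.items()
    }

    single = sum(1 for c in share.values() if c == 1)
    single_pct = round_half_away(100.0 * single / n_nodes) if n_nodes else 0

    notes: list[str] = []
    if sum(wdist.values()) != 100 and n_edges:
        notes.append(f"WoE percentages sum to {sum(wdist.values())}, not 100")
    if sum(band_pct.values()) != 100 and n_nodes:
        notes.append(f"eccentricity band percentages sum to {sum(band_pct.values())}, not 100")

    summary = NetworkSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_paths=len(paths),
        n_convergent=class_counts.get(ConvergenceClass.CONVERGENT, 0),
        n_divergent=class_counts.get(ConvergenceClass.DIVERGENT, 0),
        n_balanced=class_counts.get(ConvergenceClass.BALANCED, 0),
        share_histogram=share_hist,
        single_aop_pct=single_pct,
        ecc_band_fractions=band_pct,
        ecc_band_fractions_raw=band_raw,
        indegree_histogram=in_hist,
        outdegree_histogram=out_hist,
        indegree_pct_all=in_pct_all,
        indegree_pct_nonzero=in_pct_nz,
        outdegree_pct_all=out_pct_all,
        outdegree_pct_nonzero=out_pct_nz,
        woe_counts={w.value: c for w, c in wcounts.items()},
        woe_distribution={w.value: p for w, p in wdist.items()},
        woe_fractions_raw=wraw,
        rounding_notes=notes,
    )
    return summary, records


# ---------------------------------------------------------------------------
# serialisation

def metrics_to_tsv(records: Sequence[MetricsRecord], path: str | Path) -> None:
    """One row per node; occurrence and betweenness printed at 3 decimals."""
    header = [
        "node",
        "in_degree",
        "out_degree",
        "degree",
        "eccentricity",
        "eccentricity_band",
        "betweenness",
        "path_occurrence",
        "convergence_class",
        "aop_share_count",
    ]
    with Path(path).open("w", encoding="utf-8") as handle:
        handle.write("\t".join(header) + "\n")
        for r in records:
            handle.write(
                "\t".join(
                    [
                        r.node,
                        str(r.in_degree),
                        str(r.out_degree),
                        str(r.degree),
                        str(r.eccentricity),
                        r.eccentricity_band.value,
                        f"{r.betweenness:.3f}",
                        f"{r.path_occurrence:.3f}",
                        r.convergence_class.value,
                        str(r.aop_share_count),
                    ]
                )
                + "\n"
            )


def summary_to_json(summary: NetworkSummary, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(summary.as_dict(), indent=2, ensure_ascii=False), encoding="utf-8"
    )


def convergence_markdown(records: Sequence[MetricsRecord]) -> str:
    """Markdown table of convergent and divergent key events."""
    convergent = sorted(
        (r for r in records if r.convergence_class is ConvergenceClass.CONVERGENT),
        key=lambda r: (-r.in_degree, r.node),
    )
    divergent = sorted(
        (r for r in records if r.convergence_class is ConvergenceClass.DIVERGENT),
        key=lambda r: (-r.out_degree, r.node),
    )
    lines = [
        f"## Convergent key events ({len(convergent)})",
        "",
        "| Key event | in-degree | out-degree |",
        "| --- | --- | --- |",
    ]
    lines += [f"| {r.node} | {r.in_degree} | {r.out_degree} |" for r in convergent]
    lines += [
        "",
        f"## Divergent key events ({len(divergent)})",
        "",
        "| Key event | in-degree | out-degree |",
        "| --- | --- | --- |",
    ]
    lines += [f"| {r.node} | {r.in_degree} | {r.out_degree} |" for r in divergent]
    return "\n".join(lines) + "\n"
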