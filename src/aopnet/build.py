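"""Merging curated AOP records into a single directed network.

Pathways are merged on shared key events. Parallel reports of the same
ordered node pair collapse onto one edge whose provenance records every
contributing AOP; the collapsed edge keeps the highest weight of evidence
among contributors (the per-AOP labels stay available on the edge). A KER
flagged nonadjacent in one pathway but adjacent in another is, under the
default policy, stored as adjacent. Placeholder nodes (by default the
"Unknown, MIE" stub used by pathways whose initiating event is not
characterised) are dropped after construction, with every action recorded
in the build log so the final graph is auditable row-by-row against the
curated table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx

from .io import validate_collection
from .model import (
    Adjacency,
    AOPCollection,
    BuildError,
    KeyEvent,
    Role,
    WOE_RANK,
    Woe,
)

#: Node removed after a default build; it is a curation placeholder, not a
#: biological event, and contributes nothing to the sequence of events.
DEFAULT_DROP_TITLES: frozenset[str] = frozenset({"Unknown, MIE"})


class NonadjacentPolicy(str, Enum):
    """How to treat KERs flagged nonadjacent when collapsing edges.

    reconcile
        An edge is adjacent if any contributing AOP reports it adjacent
        (an indirect link in one pathway described directly in another is
        treated as bridged). Default.
    keep_flagged
        An edge keeps the nonadjacent flag if any contributor used it.
    exclude
        Nonadjacent reports are discarded before collapsing; an edge
        survives only through its adjacent contributors.
    """

    RECONCILE = "reconcile"
    KEEP_FLAGGED = "keep_flagged"
    EXCLUDE = "exclude"


@dataclass
class AOPNetwork:
    """The merged directed network with node and edge annotations.

    ``graph`` is a simple :class:`networkx.DiGraph` keyed by canonical
    title. Edge attributes: ``adjacency``, ``woe`` (merged), ``aop_ids``
    (sorted tuple of contributing AOPs), ``woe_by_aop`` and
    ``adjacency_by_aop`` (per-contributor labels). Per-AOP multiplicity is
    therefore never lost even though metrics run on the collapsed graph.
    """

    graph: nx.DiGraph
    key_events: dict[str, KeyEvent]
    dropped_nodes: set[str] = field(default_factory=set)
    build_log: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    @property
    def provenance(self) -> dict[tuple[str, str], tuple[int, ...]]:
        return {
            (u, v): tuple(data["aop_ids"]) for u, v, data in self.graph.edges(data=True)
        }

    @property
    def aop_ids(self) -> set[int]:
        out: set[int] = set()
        for ke in self.key_events.values():
            out |= ke.aop_ids
        return out

    def __eq__(self, other: object) -> bool:  # build_log intentionally ignored
        if not isinstance(other, AOPNetwork):
            return NotImplemented
        if set(self.graph.nodes) != set(other.graph.nodes):
            return False
        if set(self.graph.edges) != set(other.graph.edges):
            return False
        for u, v in self.graph.edges:
            a, b = self.graph.edges[u, v], other.graph.edges[u, v]
            if (
                a["adjacency"] != b["adjacency"]
                or a["woe"] != b["woe"]
                or tuple(a["aop_ids"]) != tuple(b["aop_ids"])
            ):
                return False
        return (
            self.key_events == other.key_events
            and self.dropped_nodes == other.dropped_nodes
        )


def build_network(
    collection: AOPCollection,
    drop_titles: frozenset[str] | set[str] = DEFAULT_DROP_TITLES,
    nonadjacent_policy: NonadjacentPolicy | str = NonadjacentPolicy.RECONCILE,
) -> AOPNetwork:
    """Merge validated AOP records into one directed network.

    Raises :class:`BuildError` on an empty collection, on any validation
    finding, or on a self-loop KER.
    """
    policy = NonadjacentPolicy(nonadjacent_policy)
    if not collection.records:
        raise BuildError("cannot build a network from an empty collection")
    report = validate_collection(collection)
    if not report.is_empty:
        raise BuildError("collection failed validation:\n" + report.to_text())

    log: list[str] = [f"build: {len(collection.records)} AOPs, policy={policy.value}"]

    # gather per-pair contributions
    contributions: dict[tuple[str, str], list[tuple[int, Adjacency, Woe]]] = {}
    for record in collection.records:
        for ker in record.kers:
            if ker.upstream == ker.downstream:
                raise BuildError(
                    f"self-loop on {ker.upstream!r} in AOP {record.aop_id}"
                )
            if policy is NonadjacentPolicy.EXCLUDE and ker.adjacency is Adjacency.NONADJACENT:
                log.append(
                    f"excluded nonadjacent KER {ker.upstream!r} -> {ker.downstream!r} "
                    f"(AOP {record.aop_id})"
                )
                continue
            contributions.setdefault(ker.pair, []).append(
                (record.aop_id, ker.adjacency, ker.woe)
            )

    graph = nx.DiGraph()
    for title in sorted(collection.key_events):
        graph.add_node(title)

    for (up, down) in sorted(contributions):
        contribs = contributions[(up, down)]
        aop_ids = tuple(sorted({c[0] for c in contribs}))
        adjacencies = {c[1] for c in contribs}
        woes = [c[2] for c in contribs]
        merged_woe = max(woes, key=lambda w: WOE_RANK[w])
        if len(set(woes)) > 1:
            log.append(
                f"merged WoE on {up!r} -> {down!r}: "
                f"{sorted(w.value for w in set(woes))} -> {merged_woe.value}"
            )
        if policy is NonadjacentPolicy.KEEP_FLAGGED:
            adjacency = (
                Adjacency.NONADJACENT
                if Adjacency.NONADJACENT in adjacencies
                else Adjacency.ADJACENT
            )
        else:  # reconcile / exclude: adjacent wins when any contributor says so
            adjacency = (
                Adjacency.ADJACENT
                if Adjacency.ADJACENT in adjacencies
                else Adjacency.NONADJACENT
            )
        if len(adjacencies) > 1:
            log.append(
                f"reconciled adjacency on {up!r} -> {down!r} to {adjacency.value} "
                f"(AOPs {aop_ids})"
            )
        graph.add_edge(
            up,
            down,
            adjacency=adjacency,
            woe=merged_woe,
            aop_ids=aop_ids,
            woe_by_aop={c[0]: c[2] for c in contribs},
            adjacency_by_aop={c[0]: c[1] for c in contribs},
        )

    dropped: set[str] = set()
    for title in sorted(drop_titles):
        if title in graph:
            graph.remove_node(title)
            dropped.add(title)
            log.append(f"dropped node {title!r} with incident edges")

    key_events = {
        t: ke for t, ke in collection.key_events.items() if t not in dropped
    }
    for title in sorted(graph.nodes):
        if graph.degree(title) == 0:
            log.append(f"retained isolated node {title!r}")

    return AOPNetwork(
        graph=graph, key_events=key_events, dropped_nodes=dropped, build_log=log
    )


def subnetwork_for_aop(network: AOPNetwork, aop_id: int) -> AOPNetwork:
    """Induced subgraph of the edges (and member nodes) of one source AOP."""
    if aop_id not in network.aop_ids:
        raise LookupError(f"AOP {aop_id} not present in network provenance")
    sub = nx.DiGraph()
    for title, ke in network.key_events.items():
        if aop_id in ke.aop_ids and title in network.graph:
            sub.add_node(title)
    for u, v, data in network.graph.edges(data=True):
        if aop_id in data["aop_ids"]:
            sub.add_edge(u, v, **data)
    key_events = {t: network.key_events[t] for t in sub.nodes}
    return AOPNetwork(
        graph=sub,
        key_events=key_events,
        dropped_nodes=set(network.dropped_nodes),
        build_log=[f"subnetwork for AOP {aop_id}"],
    )


def sources_and_sinks(network: AOPNetwork) -> tuple[set[str], set[str]]:
    """Annotation-driven MIE and AO sets of the built network.

    Membership comes from the per-AOP role profile, never from degree: an
    MIE may have incoming edges (it is an interior event of other
    pathways) and an AO may have outgoing ones. The sets may overlap.
    """
    mie_set = {
        t
        for t, ke in network.key_events.items()
        if t in network.graph and Role.MIE in ke.roles
    }
    ao_set = {
        t
        for t, ke in network.key_events.items()
        if t in network.graph and Role.AO in ke.roles
    }
    if not mie_set or not ao_set:
        raise BuildError("network has no annotated MIE or no annotated AO")
    return mie_set, ao_set


# ---------------------------------------------------------------------------
# export / import

def _roles_to_str(profile: dict[int, Role]) -> str:
    return json.dumps({str(k): v.value for k, v in sorted(profile.items())})


def to_graphml(network: AOPNetwork, path: str | Path) -> None:
    """Write a Cytoscape-importable GraphML file.

    Container-valued annotations (aliases, role profiles, provenance) are
    serialised as JSON strings because GraphML attributes are scalar.
    """
    out = nx.DiGraph()
    out.graph["dropped_nodes"] = json.dumps(sorted(network.dropped_nodes))
    for title in sorted(network.graph.nodes):
        ke = network.key_events[title]
        out.add_node(
            title,
            canonical_title=title,
            roles=_roles_to_str(ke.type_profile),
            aliases=json.dumps(sorted(ke.aliases)),
            wiki_ids=json.dumps(sorted(ke.wiki_ids)),
            aop_count=len(ke.aop_ids),
            aop_ids=",".join(str(i) for i in sorted(ke.aop_ids)),
        )
    for u, v in sorted(network.graph.edges):
        data = network.graph.edges[u, v]
        out.add_edge(
            u,
            v,
            woe=data["woe"].value,
            adjacency=data["adjacency"].value,
            aop_ids=",".join(str(i) for i in data["aop_ids"]),
            woe_by_aop=json.dumps(
                {str(k): w.value for k, w in sorted(data["woe_by_aop"].items())}
            ),
            adjacency_by_aop=json.dumps(
                {str(k): a.value for k, a in sorted(data["adjacency_by_aop"].items())}
            ),
        )
    nx.write_graphml(out, str(path))


def network_from_graphml(path: str | Path) -> AOPNetwork:
    """Re-import a network written by :func:`to_graphml`."""
    raw = nx.read_graphml(str(path))
    graph = nx.DiGraph()
    key_events: dict[str, KeyEvent] = {}
    for node, data in raw.nodes(data=True):
        graph.add_node(node)
        key_events[node] = KeyEvent(
            canonical_title=node,
            aliases=set(json.loads(data.get("aliases", "[]"))),
            wiki_ids=set(json.loads(data.get("wiki_ids", "[]"))),
            type_profile={
                int(k): Role(v) for k, v in json.loads(data.get("roles", "{}")).items()
            },
        )
    for u, v, data in raw.edges(data=True):
        graph.add_edge(
            u,
            v,
            adjacency=Adjacency(data["adjacency"]),
            woe=Woe(data["woe"]),
            aop_ids=tuple(int(x) for x in data["aop_ids"].split(",") if x),
            woe_by_aop={
                int(k): Woe(w) for k, w in json.loads(data.get("woe_by_aop", "{}")).items()
            },
            adjacency_by_aop={
                int(k): Adjacency(a)
                for k, a in json.loads(data.get("adjacency_by_aop", "{}")).items()
            },
        )
    dropped = set(json.loads(raw.graph.get("dropped_nodes", "[]")))
    return AOPNetwork(
        graph=graph,
        key_events=key_events,
        dropped_nodes=dropped,
        build_log=[f"imported from {path}"],
    )


def to_sif(network: AOPNetwork, path: str | Path) -> None:
    """Write the three-column SIF edge list (upstream, "KER", downstream)."""
    with Path(path).open("w", encoding="utf-8") as handle:
        for u, v in sorted(network.graph.edges):
            handle.write(f"{u}\tKER\t{v}\n")


def network_to_dict(network: AOPNetwork) -> dict:
    return {
        "nodes": [
            {
                "canonical_title": t,
                "aliases": sorted(ke.aliases),
                "wiki_ids": sorted(ke.wiki_ids),
                "type_profile": {str(k): v.value for k, v in sorted(ke.type_profile.items())},
            }
            for t, ke in sorted(network.key_events.items())
            if t in network.graph
        ],
        "edges": [
            {
                "upstream": u,
                "downstream": v,
                "adjacency": network.graph.edges[u, v]["adjacency"].value,
                "woe": network.graph.edges[u, v]["woe"].value,
                "aop_ids": list(network.graph.edges[u, v]["aop_ids"]),
                "woe_by_aop": {
                    str(k): w.value
                    for k, w in sorted(network.graph.edges[u, v]["woe_by_aop"].items())
                },
                "adjacency_by_aop": {
                    str(k): a.value
                    for k, a in sorted(
                        network.graph.edges[u, v]["adjacency_by_aop"].items()
                    )
                },
            }
            for u, v in sorted(network.graph.edges)
        ],
        "dropped_nodes": sorted(network.dropped_nodes),
        "build_log": list(network.build_log),
    }


def to_json(network: AOPNetwork, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(network_to_dict(network), indent=2, ensure_ascii=False),
        encoding="utf-8",
    )


def network_from_json(path: str | Path) -> AOPNetwork:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    graph = nx.DiGraph()
    key_events: dict[str, KeyEvent] = {}
    for node in data["nodes"]:
        title = node["canonical_title"]
        graph.add_node(title)
        key_events[title] = KeyEvent(
            canonical_title=title,
            aliases=set(node["aliases"]),
            wiki_ids=set(node["wiki_ids"]),
            type_profile={int(k): Role(v) for k, v in node["type_profile"].items()},
        )
    for edge in data["edges"]:
        graph.add_edge(
            edge["upstream"],
            edge["downstream"],
            adjacency=Adjacency(edge["adjacency"]),
            woe=Woe(edge["woe"]),
            aop_ids=tuple(edge["aop_ids"]),
            woe_by_aop={int(k): Woe(w) for k, w in edge["woe_by_aop"].items()},
            adjacency_by_aop={
                int(k): Adjacency(a) for k, a in edge["adjacency_by_aop"].items()
            },
        )
    return AOPNetwork(
        graph=graph,
        key_events=key_events,
        dropped_nodes=set(data["dropped_nodes"]),
        build_log=list(data.get("build_log", [])),
    )
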