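"""Host-sharing network built from shared recombinase families.

Hosts are grouped at the genus level (first binomial token, skipping a
"Candidatus" prefix) unless a genus has a single representative, which
then keeps its full species/strain label.  Two host nodes are linked by
an edge weighted by the number of families present in both; singleton
families cannot be shared and are excluded by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from tbssr.mcl import FamintPartition
from tbssr.records import ProteinRecord


@dataclass
class HostNode:
    label: str
    members: list[str]
    taxon_class: str | None = None


def _genus(host: str) -> str | None:
    tokens = host.split()
    if tokens and tokens[0].lower() == "candidatus":
        tokens = tokens[1:]
    return tokens[0] if tokens else None


def group_hosts(proteins: list[ProteinRecord]) -> list[HostNode]:
    """Collapse host strings to genus nodes, keeping lone hosts verbatim."""
    by_genus: dict[str, set[str]] = {}
    unparseable: list[str] = []
    for p in proteins:
        g = _genus(p.host)
        if g is None:
            if p.host not in unparseable:
                warnings.warn(
                    f"unparseable host string {p.host!r}; kept as its own node",
                    stacklevel=2,
                )
                unparseable.append(p.host)
            continue
        by_genus.setdefault(g, set()).add(p.host)
    nodes: list[HostNode] = []
    for g in sorted(by_genus):
        hosts = sorted(by_genus[g])
        if len(hosts) >= 2:
            nodes.append(HostNode(label=g, members=hosts))
        else:
            nodes.append(HostNode(label=hosts[0], members=hosts))
    for h in unparseable:
        nodes.append(HostNode(label=h, members=[h]))
    return nodes


@dataclass
class HostGraph:
    nodes: list[HostNode]
    edges: dict[tuple[str, str], int]
    components: list[list[str]] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(n.label for n in self.nodes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


def shared_family_graph(
    partition: FamintPartition,
    proteins: list[ProteinRecord],
    nodes: list[HostNode] | None = None,
    min_family_size: int = 2,
) -> HostGraph:
    """Weight each host pair by the number of families both carry.

    A family is present in a node when any member's host maps to it;
    families below ``min_family_size`` are ignored (a singleton family
    cannot be shared).
    """
    nodes = nodes if nodes is not None else group_hosts(proteins)
    host_to_node: dict[str, str] = {}
    for n in nodes:
        for h in n.members:
            host_to_node[h] = n.label
    by_id = {p.id: p for p in proteins}
    fam_nodes: dict[int, set[str]] = {}
    for pid, fam in partition.assignment.items():
        if partition.family_sizes[fam] < min_family_size:
            continue
        host = by_id[pid].host
        label = host_to_node.get(host)
        if label is not None:
            fam_nodes.setdefault(fam, set()).add(label)
    edges: dict[tuple[str, str], int] = {}
    for labels in fam_nodes.values():
        ordered = sorted(labels)
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                key = (ordered[i], ordered[j])
                edges[key] = edges.get(key, 0) + 1
    graph = HostGraph(nodes=nodes, edges=edges)
    graph.components = connected_components(graph)
    return graph


def connected_components(graph: HostGraph) -> list[list[str]]:
    """Components ordered by (size desc, smallest label), labels sorted."""
    g = graph.to_networkx()
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def hub_impact(
    graph: HostGraph, remove: list[str]
) -> tuple[list[list[str]], list[list[str]]]:
    """Components before and after deleting the named nodes."""
    labels = {n.label for n in graph.nodes}
    missing = [r for r in remove if r not in labels]
    if missing:
        raise ValueError(f"unknown node labels: {missing}")
    before = connected_components(graph)
    g = graph.to_networkx()
    g.remove_nodes_from(remove)
    comps = [sorted(c) for c in nx.connected_components(g)]
    after = sorted(comps, key=lambda c: (-len(c), c[0]))
    return before, after
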