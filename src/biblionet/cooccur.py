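"""Entity co-occurrence networks: construction, Jaccard normalization,
community detection, and graph export.

A co-occurrence network over one kind of entity (terms, institutions) has
node frequencies F(i) = number of documents mentioning entity i and edge
co-frequencies CF(i,j) = number of documents mentioning both. Edge weights
are either the raw CF or the Jaccard coefficient

    J(i,j) = CF(i,j) / (F(i) + F(j) - CF(i,j)),

the overlap of the two entities' document sets, which corrects for the
scale difference between frequent and rare entities. Communities are found
by greedy local-moving modularity optimization (Louvain) on the chosen
weights.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx

__all__ = [
    "CooccurrenceNetwork",
    "build_network",
    "jaccard_normalize",
    "node_strength",
    "detect_communities",
    "modularity",
    "export_graph",
    "load_graphml",
]


@dataclass
class CooccurrenceNetwork:
    """Undirected weighted co-occurrence graph.

    Node attribute ``freq`` holds F(i); edge attributes ``cf`` (raw
    co-frequency) and ``weight`` (the analysis weight: raw CF until
    normalization, Jaccard coefficient after). ``community`` maps nodes to
    contiguous integer labels once detected.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    normalized: bool = False
    community: dict[Hashable, int] = field(default_factory=dict)

    def freq(self, node: Hashable) -> int:
        return self.graph.nodes[node]["freq"]

    def cf(self, i: Hashable, j: Hashable) -> int:
        return self.graph.edges[i, j]["cf"]

    def weight(self, i: Hashable, j: Hashable) -> float:
        return self.graph.edges[i, j]["weight"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(doc_entity_sets: Iterable[Iterable[Hashable]],
                  ) -> CooccurrenceNetwork:
    """Build the co-occurrence network from per-document entity sets.

    F(i) counts documents containing i; CF(i,j) counts documents containing
    both; an edge exists iff CF >= 1. Duplicate mentions within a document
    are collapsed (sets).
    """
    g = nx.Graph()
    for entities in doc_entity_sets:
        uniq = sorted(set(entities))
        for e in uniq:
            if g.has_node(e):
                g.nodes[e]["freq"] += 1
            else:
                g.add_node(e, freq=1)
        for i, j in combinations(uniq, 2):
            if g.has_edge(i, j):
                g.edges[i, j]["cf"] += 1
            else:
                g.add_edge(i, j, cf=1)
    for i, j, data in g.edges(data=True):
        data["weight"] = float(data["cf"])
        assert data["cf"] <= min(g.nodes[i]["freq"], g.nodes[j]["freq"])
    return CooccurrenceNetwork(graph=g)


def jaccard_normalize(network: CooccurrenceNetwork) -> CooccurrenceNetwork:
    """Replace edge weights by the Jaccard coefficient of the endpoints.

    Raw CF is retained in the ``cf`` edge attribute. The denominator
    F(i)+F(j)-CF is the size of the union of the two document sets and is
    positive whenever an edge exists; a nonpositive value signals corrupted
    frequencies and trips an assertion.
    """
    g = network.graph.copy()
    for i, j, data in g.edges(data=True):
        denom = g.nodes[i]["freq"] + g.nodes[j]["freq"] - data["cf"]
        assert denom > 0, f"corrupted frequencies on edge ({i!r},{j!r})"
        data["weight"] = data["cf"] / denom
    return CooccurrenceNetwork(graph=g, normalized=True,
                               community=dict(network.community))


def node_strength(network: CooccurrenceNetwork, node: Hashable) -> float:
    """Sum of weights over the node's incident edges (0 for isolates)."""
    if node not in network.graph:
        raise KeyError(f"unknown entity: {node!r}")
    return float(network.graph.degree(node, weight="weight"))


def detect_communities(
    network: CooccurrenceNetwork,
    resolution: float = 1.0,
    seed: int = 0,
    min_size: int = 1,
) -> dict[Hashable, int]:
    """Louvain-style local-moving modularity communities.

    Deterministic for a given seed. Labels are contiguous integers from 0,
    ordered by decreasing community size (ties by smallest node name).
    Communities smaller than ``min_size`` are merged into the neighboring
    community with the largest total connecting weight; isolated small
    communities stay as they are.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot detect communities on an empty network")
    g = network.graph
    comms = [set(c) for c in nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed)]

    if min_size > 1:
        comms = _merge_small(g, comms, min_size)

    comms.sort(key=lambda c: (-len(c), str(min(c, key=str))))
    labels = {node: idx for idx, c in enumerate(comms) for node in c}
    network.community = labels
    return labels


def _merge_small(g: nx.Graph, comms: list[set], min_size: int) -> list[set]:
    comms = [set(c) for c in comms]
    changed = True
    while changed:
        changed = False
        comms.sort(key=len)
        for idx, small in enumerate(comms):
            if len(small) >= min_size or len(comms) == 1:
                continue
            best, best_w = None, 0.0
            for jdx, other in enumerate(comms):
                if jdx == idx:
                    continue
                w = sum(d.get("weight", 1.0)
                        for u in small
                        for _, v, d in g.edges(u, data=True) if v in other)
                if w > best_w:
                    best, best_w = jdx, w
            if best is not None:
                comms[best] |= small
                del comms[idx]
                changed = True
                break
    return comms


def modularity(network: CooccurrenceNetwork,
               labels: Mapping[Hashable, int] | None = None,
               resolution: float = 1.0) -> float:
    """Weighted Newman modularity of a partition (default: the stored one)."""
    labels = labels if labels is not None else network.community
    groups: dict[int, set] = {}
    for node, lab in labels.items():
        groups.setdefault(lab, set()).add(node)
    return nx.community.modularity(network.graph, groups.values(),
                                   weight="weight", resolution=resolution)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_graph(network: CooccurrenceNetwork, path: str | Path,
                 format: str = "graphml") -> None:
    """Write the network to ``graphml``, ``pajek`` or ``edge-csv``.

    All formats carry node frequency, raw CF, weight and (if present)
    community labels; Pajek labels go to a parallel ``.clu`` file.
    """
    path = Path(path)
    g = network.graph.copy()
    for node in g.nodes:
        if network.community:
            g.nodes[node]["community"] = int(network.community.get(node, -1))
    if format == "graphml":
        g.graph["normalized"] = network.normalized
        nx.write_graphml(g, path)
    elif format == "pajek":
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        for i, j, d in g.edges(data=True):
            h.add_edge(i, j, weight=d["weight"])
        nx.write_pajek(h, path)
        if network.community:
            nodes = list(h.nodes)
            clu = path.with_suffix(".clu")
            with open(clu, "w", encoding="utf-8") as handle:
                handle.write(f"*Vertices {len(nodes)}\n")
                for node in nodes:
                    handle.write(f"{network.community.get(node, -1)}\n")
    elif format == "edge-csv":
        with open(path, "w", newline="", encoding="utf-8") as handle:
            w = csv.writer(handle)
            w.writerow(["source", "target", "cf", "weight"])
            for i, j, d in sorted(g.edges(data=True),
                                  key=lambda e: (str(e[0]), str(e[1]))):
                w.writerow([i, j, d["cf"], d["weight"]])
    else:
        raise ValueError(f"unknown export format: {format!r}")


def load_graphml(path: str | Path) -> CooccurrenceNetwork:
    """Read back a network written by :func:`export_graph` (graphml)."""
    g = nx.read_graphml(path)
    g = nx.Graph(g)
    community = {}
    for node, data in g.nodes(data=True):
        data["freq"] = int(data["freq"])
        if "community" in data:
            community[node] = int(data.pop("community"))
    for _, _, data in g.edges(data=True):
        data["cf"] = int(data["cf"])
        data["weight"] = float(data["weight"])
    return CooccurrenceNetwork(
        graph=g, normalized=bool(g.graph.get("normalized", False)),
        community=community)
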