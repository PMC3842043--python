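"""Confidence-filtered interaction networks, hub calling, family modules.

Edges carry an interaction confidence in [0, 1] (or the 0-1000 integer scale
used by STRING-style exports, selected explicitly - the scale is never
auto-detected).  After filtering at the confidence threshold (default 0.15),
hubs are nodes with at least five distinct interaction partners, and a
family module is a connected component of at least two nodes within the
subgraph induced by one family label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "InteractionNetwork",
    "load_network",
    "network_from_edges",
    "find_hubs",
    "family_modules",
    "network_summary",
    "DEFAULT_MIN_CONFIDENCE",
    "DEFAULT_HUB_THRESHOLD",
]

DEFAULT_MIN_CONFIDENCE = 0.15
DEFAULT_HUB_THRESHOLD = 5


@dataclass
class InteractionNetwork:
    """Undirected confidence-weighted graph plus derived annotations."""

    graph: nx.Graph
    hub_threshold: int = DEFAULT_HUB_THRESHOLD
    family_labels: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def degrees(self) -> dict:
        return dict(self.graph.degree)

    def is_hub(self, node) -> bool:
        return self.graph.degree(node) >= self.hub_threshold

    def set_labels(self, labels: dict) -> None:
        self.family_labels = dict(labels)


def network_from_edges(edges, min_confidence: float = DEFAULT_MIN_CONFIDENCE, *,
                       string_scale: bool = False,
                       hub_threshold: int = DEFAULT_HUB_THRESHOLD) -> InteractionNetwork:
    """Build a network from (node_a, node_b, confidence) triples.

    Confidences must lie in [0, 1] (or [0, 1000] with ``string_scale``, then
    divided by 1000).  Duplicate edges collapse to the maximum confidence,
    self-loops are dropped with a warning, then edges below
    ``min_confidence`` are removed.
    """
    g = nx.Graph()
    n_self = 0
    for a, b, conf in edges:
        conf = float(conf)
        if string_scale:
            if not 0 <= conf <= 1000:
                raise ValueError(f"confidence {conf} outside [0, 1000]")
            conf /= 1000.0
        elif not 0.0 <= conf <= 1.0:
            raise ValueError(f"confidence {conf} outside [0, 1]")
        a, b = str(a), str(b)
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop(s)", stacklevel=2)
    drop = [(a, b) for a, b, c in g.edges(data="confidence") if c < min_confidence]
    g.remove_edges_from(drop)
    g.remove_nodes_from([n for n in list(g.nodes) if g.degree(n) == 0])
    return InteractionNetwork(graph=g, hub_threshold=hub_threshold)


def load_network(edge_file, min_confidence: float = DEFAULT_MIN_CONFIDENCE, *,
                 string_scale: bool = False,
                 hub_threshold: int = DEFAULT_HUB_THRESHOLD) -> InteractionNetwork:
    """Load a three-column edge-list TSV ``node_a  node_b  confidence``."""
    df = pd.read_csv(edge_file, sep="\t", header=0, dtype=str)
    if df.shape[1] < 3:
        raise ValueError("edge file needs three columns: node_a, node_b, confidence")
    triples = [(r.iloc[0], r.iloc[1], float(r.iloc[2])) for _, r in df.iterrows()]
    return network_from_edges(triples, min_confidence,
                              string_scale=string_scale,
                              hub_threshold=hub_threshold)


def find_hubs(net: InteractionNetwork, hub_threshold: int | None = None) -> list:
    """Nodes with at least ``hub_threshold`` distinct neighbours, sorted by
    descending degree then id."""
    threshold = net.hub_threshold if hub_threshold is None else hub_threshold
    hubs = [(n, d) for n, d in net.graph.degree if d >= threshold]
    hubs.sort(key=lambda nd: (-nd[1], nd[0]))
    return [n for n, _ in hubs]


def family_modules(net: InteractionNetwork, family_labels: dict | None = None) -> list:
    """Connected >=2-node components of each family's induced subgraph.

    Returns ``(family, sorted-node-list)`` pairs, deterministically ordered.
    """
    labels = net.family_labels if family_labels is None else family_labels
    if not labels:
        return []
    by_family = {}
    for node, fam in labels.items():
        if node in net.graph:
            by_family.setdefault(fam, []).append(node)
    modules = []
    for fam in sorted(by_family):
        sub = net.graph.subgraph(by_family[fam])
        for comp in nx.connected_components(sub):
            if len(comp) >= 2:
                modules.append((fam, sorted(comp)))
    modules.sort(key=lambda m: (m[0], m[1]))
    return modules


def network_summary(net: InteractionNetwork) -> dict:
    """Deterministic counts: nodes, edges, hubs, modules, degree histogram."""
    degs = [d for _, d in net.graph.degree]
    hist = {}
    for d in degs:
        hist[d] = hist.get(d, 0) + 1
    return {
        "nodes": net.graph.number_of_nodes(),
        "edges": net.graph.number_of_edges(),
        "hubs": len(find_hubs(net)),
        "modules": len(family_modules(net)),
        "degree_histogram": dict(sorted(hist.items())),
    }


def write_hub_table(net: InteractionNetwork, path) -> None:
    hubs = find_hubs(net)
    df = pd.DataFrame(
        [(h, net.graph.degree(h)) for h in hubs], columns=["protein", "degree"])
    df.to_csv(path, sep="\t", index=False)


def write_module_table(net: InteractionNetwork, path) -> None:
    rows = [(fam, len(nodes), ";".join(nodes))
            for fam, nodes in family_modules(net)]
    pd.DataFrame(rows, columns=["family", "size", "members"]).to_csv(
        path, sep="\t", index=False)


def export_graphml(net: InteractionNetwork, path) -> None:
    g = net.graph.copy()
    for node in g.nodes:
        if node in net.family_labels:
            g.nodes[node]["family"] = net.family_labels[node]
        g.nodes[node]["hub"] = net.is_hub(node)
    nx.write_graphml(g, path)
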