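"""Presence/absence comparison of two or more tissue networks.

Networks built for different tissues are superimposed node by node: the
presence matrix records, for every protein seen in any network, which
networks contain it.  From this follow the common core (present in all),
the differential set (absent from at least one), a per-node rewiring score
and a merged reference network whose nodes and edges carry presence counts.

The rewiring score is purely presence/absence based:

    rewiring(v) = 1 - (#networks containing v) / (#networks)

so a protein in every network scores 0 and a protein in a single network
out of five scores 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .interactome import PPINetwork


def _labels(networks: list[PPINetwork]) -> list[str]:
    labels = [n.tissue for n in networks]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate network labels: {labels}")
    return labels


def _require_multiple(networks: list[PPINetwork]) -> None:
    if len(networks) < 2:
        raise ValueError("comparison needs at least two networks")


def presence_matrix(networks: list[PPINetwork]) -> pd.DataFrame:
    """Node x network boolean matrix over the union of node sets."""
    _require_multiple(networks)
    labels = _labels(networks)
    union = sorted(set().union(*(n.nodes for n in networks)))
    data = {lab: [v in net.nodes for v in union]
            for lab, net in zip(labels, networks)}
    return pd.DataFrame(data, index=union, columns=labels)


def common_core(networks: list[PPINetwork]) -> set[str]:
    """Nodes present in every network."""
    _require_multiple(networks)
    core = set(networks[0].nodes)
    for net in networks[1:]:
        core &= net.nodes
    return core


def differential_nodes(networks: list[PPINetwork]) -> set[str]:
    """Nodes absent from at least one network (union minus intersection)."""
    _require_multiple(networks)
    union = set().union(*(n.nodes for n in networks))
    return union - common_core(networks)


def rewiring_score(node: str, networks: list[PPINetwork]) -> float:
    """Fraction of networks the node is missing from, in [0, 1)."""
    _require_multiple(networks)
    count = sum(node in net.nodes for net in networks)
    if count == 0:
        raise ValueError(f"node {node!r} appears in none of the networks")
    return 1.0 - count / len(networks)


def rewiring_ranking(networks: list[PPINetwork]) -> list[tuple[str, float]]:
    """All nodes ranked most-rewired first; ties broken alphabetically."""
    union = sorted(set().union(*(n.nodes for n in networks)))
    scored = [(v, rewiring_score(v, networks)) for v in union]
    return sorted(scored, key=lambda vs: (-vs[1], vs[0]))


def merge_reference(networks: list[PPINetwork]) -> PPINetwork:
    """Union network with per-node and per-edge presence counts.

    Edge confidence in the merged network is the maximum over the input
    networks carrying the edge.
    """
    _require_multiple(networks)
    _labels(networks)
    graph = nx.Graph()
    for net in networks:
        for v in net.nodes:
            if v in graph:
                graph.nodes[v]["presence_count"] += 1
            else:
                graph.add_node(v, presence_count=1)
        for a, b in net.edges():
            conf = net.edge_confidence(a, b)
            types = set(net.graph.edges[a, b].get("interaction_types", set()))
            if graph.has_edge(a, b):
                d = graph.edges[a, b]
                d["presence_count"] += 1
                d["confidence"] = max(d["confidence"], conf)
                d["interaction_types"] |= types
            else:
                graph.add_edge(a, b, presence_count=1, confidence=conf,
                               interaction_types=types)
    seed = networks[0].seed
    return PPINetwork(seed=seed, tissue="merged", graph=graph)


@dataclass
class ComparisonResult:
    """Bundle of every presence/absence comparison output."""

    network_labels: list[str]
    presence: pd.DataFrame
    core: set[str]
    differential: set[str]
    rewiring: dict[str, float]
    merged: PPINetwork

    @property
    def ranking(self) -> list[tuple[str, float]]:
        return sorted(self.rewiring.items(), key=lambda vs: (-vs[1], vs[0]))


def compare_networks(networks: list[PPINetwork]) -> ComparisonResult:
    """Run the full comparison over >= 2 tissue networks."""
    _require_multiple(networks)
    presence = presence_matrix(networks)
    core = common_core(networks)
    return ComparisonResult(
        network_labels=_labels(networks),
        presence=presence,
        core=core,
        differential=differential_nodes(networks),
        rewiring={v: rewiring_score(v, networks) for v in presence.index},
        merged=merge_reference(networks),
    )
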