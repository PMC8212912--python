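"""Seed-centred tissue-specific interactome construction.

Three filters are applied to a scored interaction table to obtain the
direct interactome of a seed protein in one tissue:

1. confidence: keep interactions whose reliability score exceeds a
   threshold (default strictly > 0.72);
2. interaction type: keep interactions whose PSI-MI type-code set
   intersects an allowed set (default direct interaction, MI:0407);
3. tissue expression: drop partner genes not expressed in the tissue
   (NX below a cutoff, default 1.0, or missing from the matrix).

The network is a depth-1 ego network: the seed plus its direct partners,
with seed-partner edges only.  The seed itself is exempt from the
expression filter so a tissue network is always anchored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .io_formats import ExpressionMatrix, InteractionRecord

logger = logging.getLogger(__name__)

#: PSI-MI controlled-vocabulary codes for the four interaction categories.
DIRECT_INTERACTION = "MI:0407"
PHYSICAL_ASSOCIATION = "MI:0915"
ASSOCIATION = "MI:0914"
COLOCALIZATION = "MI:0403"
BROAD_TYPES = frozenset(
    {DIRECT_INTERACTION, PHYSICAL_ASSOCIATION, ASSOCIATION, COLOCALIZATION}
)


@dataclass(frozen=True)
class FilterConfig:
    """Parameters of the three-filter cascade.

    ``min_confidence`` is compared strictly (score > cutoff) by default;
    set ``strict_greater=False`` for >=.  ``nx_min`` is the NX value at or
    above which a gene counts as expressed in a tissue.
    """

    min_confidence: float = 0.72
    allowed_interaction_types: frozenset[str] = frozenset({DIRECT_INTERACTION})
    broad_interaction_types: frozenset[str] = BROAD_TYPES
    nx_min: float = 1.0
    strict_greater: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_confidence <= 1.0:
            raise ValueError("min_confidence must lie in [0, 1]")
        if self.nx_min < 0:
            raise ValueError("nx_min must be >= 0")
        object.__setattr__(self, "allowed_interaction_types",
                           frozenset(self.allowed_interaction_types))
        object.__setattr__(self, "broad_interaction_types",
                           frozenset(self.broad_interaction_types))
        if not self.allowed_interaction_types <= self.broad_interaction_types:
            raise ValueError(
                "allowed_interaction_types must be a subset of broad_interaction_types"
            )


class PPINetwork:
    """A tissue-labelled undirected network of proteins around a seed.

    Edges carry ``confidence`` and ``interaction_types`` attributes.  Two
    networks are equal when node sets, edge sets and edge confidences
    coincide (labels are not compared).
    """

    def __init__(self, seed: str, tissue: str = "all",
                 graph: nx.Graph | None = None):
        self.seed = seed.upper() if seed else seed
        self.tissue = tissue
        self.graph = graph if graph is not None else nx.Graph()
        for a, b in self.graph.edges:
            if a == b:
                raise ValueError(f"self-loop on {a} is not allowed")

    @classmethod
    def from_records(cls, records: list[InteractionRecord], seed: str,
                     tissue: str = "all") -> "PPINetwork":
        seed = seed.upper()
        graph = nx.Graph()
        graph.add_node(seed)
        for rec in records:
            graph.add_edge(rec.id_a, rec.id_b, confidence=rec.confidence,
                           interaction_types=set(rec.interaction_types))
        return cls(seed=seed, tissue=tissue, graph=graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def interactors(self) -> set[str]:
        return self.nodes - {self.seed}

    @property
    def n_interactors(self) -> int:
        return len(self.interactors)

    def edges(self) -> set[tuple[str, str]]:
        return {(min(a, b), max(a, b)) for a, b in self.graph.edges}

    def edge_confidence(self, a: str, b: str) -> float:
        return float(self.graph.edges[a, b]["confidence"])

    def copy(self, tissue: str | None = None) -> "PPINetwork":
        return PPINetwork(seed=self.seed,
                          tissue=self.tissue if tissue is None else tissue,
                          graph=self.graph.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        if self.nodes != other.nodes or self.edges() != other.edges():
            return False
        return all(
            self.edge_confidence(a, b) == other.edge_confidence(a, b)
            for a, b in self.edges()
        )

    def __repr__(self) -> str:
        return (f"PPINetwork(seed={self.seed!r}, tissue={self.tissue!r}, "
                f"{len(self.nodes)} nodes, {self.graph.number_of_edges()} edges)")


def filter_confidence(records: list[InteractionRecord],
                      config: FilterConfig) -> list[InteractionRecord]:
    """Filter #1: keep records whose confidence clears the threshold."""
    if config.strict_greater:
        kept = [r for r in records if r.confidence > config.min_confidence]
    else:
        kept = [r for r in records if r.confidence >= config.min_confidence]
    logger.info("confidence filter (%s %.3f): %d -> %d records",
                ">" if config.strict_greater else ">=",
                config.min_confidence, len(records), len(kept))
    return kept


def filter_interaction_type(
    records: list[InteractionRecord],
    allowed_types: frozenset[str] | set[str],
) -> list[InteractionRecord]:
    """Filter #2: keep records typed with at least one allowed CV code.

    Records with an empty type set cannot match and are excluded; their
    count is logged so the cascade stays auditable.
    """
    allowed = frozenset(allowed_types)
    untyped = sum(1 for r in records if not r.interaction_types)
    kept = [r for r in records if r.interaction_types & allowed]
    if untyped:
        logger.info("type filter: %d untyped records excluded", untyped)
    logger.info("type filter (%s): %d -> %d records",
                ",".join(sorted(allowed)), len(records), len(kept))
    return kept


def build_ego_network(records: list[InteractionRecord], seed: str,
                      tissue_label: str = "all") -> PPINetwork:
    """Depth-1 ego network: the seed, its partners, and seed-partner edges.

    Partner-partner edges in the input are ignored.  If the seed appears in
    no record the result is the single-node network {seed} with a warning.
    """
    seed = seed.upper()
    graph = nx.Graph()
    graph.add_node(seed)
    for rec in records:
        partner = rec.partner_of(seed)
        if partner is None:
            continue
        graph.add_edge(seed, partner, confidence=rec.confidence,
                       interaction_types=set(rec.interaction_types))
    if graph.number_of_edges() == 0:
        logger.warning("seed %s not found in any record; ego network is {%s}",
                       seed, seed)
    return PPINetwork(seed=seed, tissue=tissue_label, graph=graph)


def tissue_subnetwork(network: PPINetwork, expression: ExpressionMatrix,
                      tissue: str, config: FilterConfig) -> PPINetwork:
    """Filter #3: drop non-seed nodes not expressed in the tissue.

    A node survives when its NX in ``tissue`` is >= ``config.nx_min``.
    Genes absent from the expression matrix are treated as not expressed
    and dropped, with the dropped list logged.  The seed is always kept.
    """
    if tissue not in expression.tissues:
        raise KeyError(
            f"tissue {tissue!r} not in expression matrix; available: "
            f"{', '.join(expression.tissues)}"
        )
    missing = sorted(g for g in network.interactors if g not in expression)
    if missing:
        logger.info("tissue %s: %d genes missing from expression matrix, "
                    "treated as not expressed: %s",
                    tissue, len(missing), ", ".join(missing))
    keep = {network.seed} | {
        g for g in network.interactors
        if expression.is_expressed(g, tissue, config.nx_min)
    }
    graph = network.graph.subgraph(keep).copy()
    graph.add_node(network.seed)
    logger.info("expression filter (%s, NX >= %g): %d -> %d interactors",
                tissue, config.nx_min, network.n_interactors, len(keep) - 1)
    return PPINetwork(seed=network.seed, tissue=tissue, graph=graph)


def build_tissue_interactomes(
    records: list[InteractionRecord],
    seed: str,
    expression: ExpressionMatrix,
    tissues: list[str],
    config: FilterConfig | None = None,
) -> dict[str, PPINetwork]:
    """Run the full cascade and return one direct interactome per tissue."""
    config = config or FilterConfig()
    confident = filter_confidence(records, config)
    direct = filter_interaction_type(confident, config.allowed_interaction_types)
    ego = build_ego_network(direct, seed)
    return {
        t: tissue_subnetwork(ego, expression, t, config) for t in tissues
    }
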