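"""End-to-end orchestration: inputs -> per-tissue interactomes -> comparison,
profiling and enrichment -> a report bundle of TSV/GraphML files.

Every run writes a ``run_log.yaml`` recording the resolved configuration,
record counts in and out of each filter, and per-tissue node counts, so the
filter cascade is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .compare import ComparisonResult, compare_networks
from .enrichment import run_enrichment
from .interactome import (
    FilterConfig,
    PPINetwork,
    build_ego_network,
    filter_confidence,
    filter_interaction_type,
    tissue_subnetwork,
)
from .io_formats import (
    EDGE_LIST,
    GRAPHML,
    MitabDialect,
    parse_annotations,
    parse_expression,
    parse_mitab,
    write_network,
)
from .profiles import profile_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    mitab: str
    expression: str
    annotations: str
    terms: str
    out_dir: str
    seed_gene: str
    tissues: list[str]
    universe: str | None = None
    min_confidence: float = 0.72
    strict_greater: bool = True
    nx_min: float = 1.0
    alpha: float = 0.05
    top_k: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.tissues:
            raise ValueError("tissues must be non-empty")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue labels must be unique")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(min_confidence=self.min_confidence,
                            strict_greater=self.strict_greater,
                            nx_min=self.nx_min)


@dataclass
class PipelineReport:
    """In-memory handles on everything a run wrote."""

    config: PipelineConfig
    networks: dict[str, PPINetwork]
    comparison: ComparisonResult
    counts: dict[str, int] = field(default_factory=dict)
    out_dir: Path = Path(".")


def _write_gene_list(genes, path: Path) -> None:
    path.write_text("".join(f"{g}\n" for g in sorted(genes)), encoding="utf-8")


def _write_enrichment(results, path: Path) -> None:
    lines = ["term\tnamespace\tname\tk\tK\tn\tN\tp\tpadj\tsignificant"
             "\tfraction\thits"]
    for r in results:
        lines.append("\t".join([
            r.term, r.namespace, r.name, str(r.k), str(r.K), str(r.n),
            str(r.N), f"{r.p:.6g}", f"{r.padj:.6g}",
            str(int(r.significant)), f"{r.fraction:.4f}",
            ",".join(sorted(r.hits)),
        ]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig,
                 dialect: MitabDialect | None = None) -> PipelineReport:
    """Run parse -> filter cascade -> per-tissue networks -> comparison,
    profiles and enrichment, writing the report bundle under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fc = config.filter_config()

    records = parse_mitab(config.mitab, dialect)
    expression = parse_expression(config.expression)
    annotations = parse_annotations(config.annotations, config.terms)
    universe = None
    if config.universe:
        universe = [g.strip() for g in
                    Path(config.universe).read_text().splitlines()
                    if g.strip()]

    counts = {"records_parsed": len(records)}
    confident = filter_confidence(records, fc)
    counts["records_confident"] = len(confident)
    direct = filter_interaction_type(confident, fc.allowed_interaction_types)
    counts["records_direct"] = len(direct)
    ego = build_ego_network(direct, config.seed_gene)
    counts["direct_interactors"] = ego.n_interactors

    networks: dict[str, PPINetwork] = {}
    for tissue in config.tissues:
        net = tissue_subnetwork(ego, expression, tissue, fc)
        networks[tissue] = net
        counts[f"interactors_{tissue}"] = net.n_interactors
        write_network(net, out / f"network_{tissue}.tsv", EDGE_LIST)
        _write_gene_list(net.interactors, out / f"nodes_{tissue}.txt")

    comparison = compare_networks(list(networks.values()))
    comparison.presence.to_csv(out / "presence_matrix.tsv", sep="\t")
    _write_gene_list(comparison.core, out / "core.txt")
    _write_gene_list(comparison.differential, out / "differential.txt")
    with open(out / "rewiring.tsv", "wt", encoding="utf-8") as fh:
        fh.write("node\trewiring\n")
        for node, score in comparison.ranking:
            fh.write(f"{node}\t{score:.6f}\n")
    write_network(comparison.merged, out / "merged.graphml", GRAPHML)

    all_interactors = sorted(set().union(*(n.interactors
                                           for n in networks.values())))
    known = [g for g in all_interactors if g in expression]
    if known:
        profile_table(known, expression, config.tissues).to_csv(
            out / "profile_all.tsv", sep="\t")
    diff_known = [g for g in sorted(comparison.differential)
                  if g in expression]
    if diff_known:
        profile_table(diff_known, expression, config.tissues).to_csv(
            out / "profile_differential.tsv", sep="\t")

    union_results = run_enrichment(all_interactors, annotations,
                                   universe=universe, alpha=config.alpha)
    _write_enrichment(union_results, out / "enrichment_union.tsv")
    for tissue, net in networks.items():
        res = run_enrichment(sorted(net.interactors), annotations,
                             universe=universe, alpha=config.alpha)
        _write_enrichment(res, out / f"enrichment_{tissue}.tsv")

    run_log = {
        "version": __version__,
        "config": asdict(config),
        "counts": counts,
        "universe_size": len(universe) if universe else len(annotations.genes),
    }
    with open(out / "run_log.yaml", "wt", encoding="utf-8") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)

    return PipelineReport(config=config, networks=networks,
                          comparison=comparison, counts=counts, out_dir=out)
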