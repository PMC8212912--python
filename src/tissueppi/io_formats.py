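"""Readers and writers for the standard formats the pipeline touches.

Interaction tables arrive in the PSI-MI 2.5 TAB (MITAB) dialect: one binary
interaction per line, tab-separated, with controlled-vocabulary ``MI:xxxx``
codes for detection methods and interaction types and a confidence score in
[0, 1].  Because public resources export MITAB with varying column orders,
the column layout is configurable (:class:`MitabDialect`).

Expression arrives as a gene x tissue TSV of consensus normalized expression
(NX) values; gene->GO annotations as a GAF-like two-column TSV plus a term
metadata table.  Networks are written as edge-list TSV or GraphML and both
formats round-trip exactly.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

_MI_CODE = re.compile(r"MI:\d{4}")
_FLOAT = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")

#: GAF aspect letters accepted as namespace synonyms.
_NAMESPACE_ALIASES = {
    "BP": "BP", "P": "BP", "BIOLOGICAL_PROCESS": "BP",
    "MF": "MF", "F": "MF", "MOLECULAR_FUNCTION": "MF",
    "CC": "CC", "C": "CC", "CELLULAR_COMPONENT": "CC",
}


class MitabParseError(ValueError):
    """Raised for malformed MITAB input in strict mode."""


@dataclass
class InteractionRecord:
    """One scored, typed, undirected binary protein-protein interaction.

    Identifiers are uppercase gene symbols; ``(id_a, id_b)`` is stored in
    canonical (lexicographic) order so that an interaction reported as
    (A, B) equals the same interaction reported as (B, A).
    """

    id_a: str
    id_b: str
    confidence: float
    uniprot_a: str | None = None
    uniprot_b: str | None = None
    detection_methods: set[str] = field(default_factory=set)
    interaction_types: set[str] = field(default_factory=set)
    provenance: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("interaction identifiers must be non-empty")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"confidence {self.confidence} outside [0, 1] for "
                f"({self.id_a}, {self.id_b})"
            )
        self.id_a = self.id_a.upper()
        self.id_b = self.id_b.upper()
        if self.id_a > self.id_b:
            self.id_a, self.id_b = self.id_b, self.id_a
            self.uniprot_a, self.uniprot_b = self.uniprot_b, self.uniprot_a

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)

    def partner_of(self, gene: str) -> str | None:
        gene = gene.upper()
        if gene == self.id_a:
            return self.id_b
        if gene == self.id_b:
            return self.id_a
        return None


@dataclass(frozen=True)
class MitabDialect:
    """Column layout of a MITAB-like export (0-based indices).

    The default layout is the one written by
    :func:`tissueppi.synthetic.generate_dataset`: gene symbols in the first
    two columns, then UniProt accessions, detection methods, interaction
    types, publications and the confidence score.
    """

    id_a: int = 0
    id_b: int = 1
    uniprot_a: int | None = 2
    uniprot_b: int | None = 3
    detection_methods: int | None = 4
    interaction_types: int | None = 5
    publications: int | None = 6
    confidence: int = 7

    def min_columns(self) -> int:
        cols = [self.id_a, self.id_b, self.confidence]
        cols += [c for c in (self.uniprot_a, self.uniprot_b, self.detection_methods,
                             self.interaction_types, self.publications) if c is not None]
        return max(cols) + 1


def _clean_identifier(raw: str) -> str:
    """Extract a bare symbol from a possibly db-prefixed MITAB field.

    ``"uniprotkb:LRRK2"`` and ``"entrez gene:120892|symbol:LRRK2"`` style
    fields reduce to the value of their first element after the prefix.
    """
    first = raw.split("|")[0].strip()
    if ":" in first:
        first = first.split(":", 1)[1]
    return first.strip().strip('"')


def _mi_codes(raw: str) -> set[str]:
    return set(_MI_CODE.findall(raw))


def parse_mitab(
    stream: IO[str] | str | Path,
    dialect: MitabDialect | None = None,
    strict: bool = False,
) -> list[InteractionRecord]:
    """Parse a MITAB interaction table into merged interaction records.

    Duplicate (a, b) pairs are merged keeping the maximum confidence and
    the union of method, type and provenance sets.  Self-loops are dropped
    with a warning.  Malformed lines and out-of-range confidences are
    skipped with a logged reason, or raise :class:`MitabParseError` when
    ``strict`` is true.
    """
    dialect = dialect or MitabDialect()
    close = False
    if isinstance(stream, (str, Path)):
        stream = open(stream, "rt", encoding="utf-8")
        close = True
    try:
        by_pair: dict[tuple[str, str], InteractionRecord] = {}
        min_cols = dialect.min_columns()
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                msg = (f"line {lineno}: expected >= {min_cols} columns, "
                       f"got {len(fields)}")
                if strict:
                    raise MitabParseError(msg)
                logger.warning("skipping malformed MITAB %s", msg)
                continue
            conf_match = _FLOAT.search(fields[dialect.confidence])
            if conf_match is None:
                msg = f"line {lineno}: unparseable confidence {fields[dialect.confidence]!r}"
                if strict:
                    raise MitabParseError(msg)
                logger.warning("rejecting record, %s", msg)
                continue
            confidence = float(conf_match.group())
            if not 0.0 <= confidence <= 1.0:
                msg = f"line {lineno}: confidence {confidence} outside [0, 1]"
                if strict:
                    raise MitabParseError(msg)
                logger.warning("rejecting record, %s", msg)
                continue
            id_a = _clean_identifier(fields[dialect.id_a]).upper()
            id_b = _clean_identifier(fields[dialect.id_b]).upper()
            if not id_a or not id_b:
                msg = f"line {lineno}: empty interactor identifier"
                if strict:
                    raise MitabParseError(msg)
                logger.warning("rejecting record, %s", msg)
                continue
            if id_a == id_b:
                logger.warning("line %d: dropping self-loop on %s", lineno, id_a)
                continue

            def _opt(idx: int | None) -> str | None:
                if idx is None or idx >= len(fields):
                    return None
                val = _clean_identifier(fields[idx])
                return val or None

            rec = InteractionRecord(
                id_a=id_a,
                id_b=id_b,
                confidence=confidence,
                uniprot_a=_opt(dialect.uniprot_a),
                uniprot_b=_opt(dialect.uniprot_b),
                detection_methods=(
                    _mi_codes(fields[dialect.detection_methods])
                    if dialect.detection_methods is not None else set()
                ),
                interaction_types=(
                    _mi_codes(fields[dialect.interaction_types])
                    if dialect.interaction_types is not None else set()
                ),
                provenance=(
                    {p.strip() for p in fields[dialect.publications].split("|") if p.strip()}
                    if dialect.publications is not None
                    and dialect.publications < len(fields) else set()
                ),
            )
            prev = by_pair.get(rec.pair)
            if prev is None:
                by_pair[rec.pair] = rec
            else:
                prev.confidence = max(prev.confidence, rec.confidence)
                prev.detection_methods |= rec.detection_methods
                prev.interaction_types |= rec.interaction_types
                prev.provenance |= rec.provenance
                prev.uniprot_a = prev.uniprot_a or rec.uniprot_a
                prev.uniprot_b = prev.uniprot_b or rec.uniprot_b
        return list(by_pair.values())
    finally:
        if close:
            stream.close()


class ExpressionMatrix:
    """Gene x tissue matrix of consensus normalized expression (NX) values.

    Missing cells are tracked as absent (NaN), distinct from an NX of 0:
    absence means the resource reported nothing for that gene/tissue, and
    downstream filters choose their own policy for it.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame.index = frame.index.astype(str).str.upper()
        if frame.index.has_duplicates:
            dupes = sorted(frame.index[frame.index.duplicated()].unique())
            raise ValueError(f"duplicate gene rows: {', '.join(dupes)}")
        if len(set(frame.columns)) != len(frame.columns):
            raise ValueError("duplicate tissue columns")
        if (frame.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative NX values are not allowed")
        self._frame = frame.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self._frame.index)

    @property
    def tissues(self) -> list[str]:
        return list(self._frame.columns)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self._frame.index

    def value(self, gene: str, tissue: str) -> float | None:
        """NX value, or None if the cell is absent or the gene is unknown."""
        gene = gene.upper()
        if gene not in self._frame.index:
            return None
        if tissue not in self._frame.columns:
            raise KeyError(
                f"unknown tissue {tissue!r}; available: {', '.join(self.tissues)}"
            )
        v = self._frame.at[gene, tissue]
        return None if pd.isna(v) else float(v)

    def is_expressed(self, gene: str, tissue: str, nx_min: float = 1.0) -> bool:
        v = self.value(gene, tissue)
        return v is not None and v >= nx_min

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()


def parse_expression(stream: IO[str] | str | Path) -> ExpressionMatrix:
    """Read a TSV with a gene column followed by one NX column per tissue."""
    frame = pd.read_csv(stream, sep="\t", index_col=0)
    return ExpressionMatrix(frame)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     gene_column: str = "gene") -> None:
    frame = matrix.to_frame()
    frame.index.name = gene_column
    frame.to_csv(path, sep="\t")


@dataclass
class AnnotationTable:
    """Flat gene -> GO-term annotations plus per-term metadata.

    No ontology graph is consulted: a gene counts for a term only if the
    input table annotates it directly.
    """

    gene_terms: dict[str, set[str]]
    term_meta: dict[str, tuple[str, str]]  # term -> (namespace, name)

    def __post_init__(self) -> None:
        orphans = sorted(
            {t for terms in self.gene_terms.values() for t in terms}
            - set(self.term_meta)
        )
        if orphans:
            raise ValueError(
                f"terms without metadata: {', '.join(orphans)}"
            )
        for term, (ns, _name) in self.term_meta.items():
            if ns not in {"BP", "MF", "CC"}:
                raise ValueError(f"{term}: namespace {ns!r} not one of BP/MF/CC")

    @property
    def genes(self) -> set[str]:
        return set(self.gene_terms)

    def annotated_genes(self, term: str) -> set[str]:
        return {g for g, terms in self.gene_terms.items() if term in terms}

    def terms_in_namespace(self, namespace: str) -> set[str]:
        return {t for t, (ns, _) in self.term_meta.items() if ns == namespace}


def parse_annotations(
    gaf_stream: IO[str] | str | Path,
    term_stream: IO[str] | str | Path,
) -> AnnotationTable:
    """Read (gene, term) pairs and (term, namespace, name) metadata.

    Gene symbols are uppercased and duplicate pairs deduplicated.  A term
    used in the annotation stream but missing from the metadata stream is
    an error listing the orphans.
    """

    def _rows(src: IO[str] | str | Path) -> Iterable[list[str]]:
        close = False
        if isinstance(src, (str, Path)):
            src = open(src, "rt", encoding="utf-8")
            close = True
        try:
            for line in src:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "!")):
                    continue
                yield line.split("\t")
        finally:
            if close:
                src.close()

    term_meta: dict[str, tuple[str, str]] = {}
    for row in _rows(term_stream):
        if len(row) < 3:
            raise ValueError(f"term metadata row needs 3 columns: {row!r}")
        term, ns_raw, name = row[0].strip(), row[1].strip().upper(), row[2].strip()
        ns = _NAMESPACE_ALIASES.get(ns_raw)
        if ns is None:
            raise ValueError(f"{term}: unknown GO namespace {ns_raw!r}")
        term_meta[term] = (ns, name)

    gene_terms: dict[str, set[str]] = {}
    for row in _rows(gaf_stream):
        if len(row) < 2:
            raise ValueError(f"annotation row needs 2 columns: {row!r}")
        gene, term = row[0].strip().upper(), row[1].strip()
        gene_terms.setdefault(gene, set()).add(term)

    return AnnotationTable(gene_terms=gene_terms, term_meta=term_meta)


# ---------------------------------------------------------------------------
# network export / import

EDGE_LIST = "edge-list"
GRAPHML = "graphml"
_FORMATS = (EDGE_LIST, GRAPHML)


def write_network(network, path: str | Path, format: str = EDGE_LIST) -> None:
    """Write a seed network so that :func:`read_network` round-trips it.

    Edge-list TSV carries seed/tissue in comment headers and emits isolated
    nodes as rows with an empty partner column; GraphML goes through
    networkx with seed/tissue as graph attributes.
    """
    from .interactome import PPINetwork  # local import to avoid a cycle

    if format not in _FORMATS:
        raise ValueError(f"unknown network format {format!r}; use one of {_FORMATS}")
    path = Path(path)
    if format == EDGE_LIST:
        lines = [f"# seed={network.seed}", f"# tissue={network.tissue}",
                 "source\ttarget\tconfidence\tinteraction_types"]
        covered: set[str] = set()
        for a, b, data in sorted(network.graph.edges(data=True)):
            a, b = min(a, b), max(a, b)
            covered.update((a, b))
            types = "|".join(sorted(data.get("interaction_types", set())))
            lines.append(f"{a}\t{b}\t{data['confidence']!r}\t{types}")
        for node in sorted(set(network.graph.nodes) - covered):
            lines.append(f"{node}\t\t\t")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        g = nx.Graph()
        g.graph["seed"] = network.seed
        g.graph["tissue"] = network.tissue
        for node in network.graph.nodes:
            g.add_node(node)
        for a, b, data in network.graph.edges(data=True):
            g.add_edge(a, b, confidence=repr(float(data["confidence"])),
                       interaction_types="|".join(sorted(data.get("interaction_types", set()))))
        nx.write_graphml(g, path)


def read_network(path: str | Path, format: str = EDGE_LIST):
    """Inverse of :func:`write_network`."""
    from .interactome import PPINetwork

    if format not in _FORMATS:
        raise ValueError(f"unknown network format {format!r}; use one of {_FORMATS}")
    path = Path(path)
    if format == EDGE_LIST:
        seed, tissue = "", "all"
        graph = nx.Graph()
        for line in path.read_text(encoding="utf-8").splitlines():
            if line.startswith("# seed="):
                seed = line.split("=", 1)[1]
            elif line.startswith("# tissue="):
                tissue = line.split("=", 1)[1]
            elif line.startswith("#") or line.startswith("source\t") or not line.strip():
                continue
            else:
                a, b, conf, types = (line.split("\t") + ["", "", ""])[:4]
                if b:
                    graph.add_edge(a, b, confidence=float(conf),
                                   interaction_types=set(types.split("|")) - {""})
                else:
                    graph.add_node(a)
        return PPINetwork(seed=seed, tissue=tissue, graph=graph)
    g = nx.read_graphml(path)
    graph = nx.Graph()
    graph.add_nodes_from(g.nodes)
    for a, b, data in g.edges(data=True):
        graph.add_edge(a, b, confidence=float(data["confidence"]),
                       interaction_types=set(str(data.get("interaction_types", "")).split("|")) - {""})
    return PPINetwork(seed=g.graph.get("seed", ""), tissue=g.graph.get("tissue", "all"),
                      graph=graph)
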