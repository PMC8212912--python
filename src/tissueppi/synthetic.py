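"""Synthetic inputs with known ground truth, and the in-paper fixture.

Two generators live here:

* :func:`generate_dataset` emulates the statistical shape of a public
  interactome query around one hub protein: ~120 scored partners with
  Beta-mixture confidences straddling the 0.72 cutoff, multinomial
  interaction types over the four PSI-MI categories, log-normal tissue NX
  values with planted per-tissue dropout that defines tissue membership,
  and GO annotations with planted over-represented terms among the direct
  interactors.  The returned :class:`SyntheticTruth` records exactly which
  genes survive each filter, so pipeline recovery can be checked without
  re-deriving anything.

* :func:`encode_paper_fixture` deterministically encodes the published
  LRRK2 tissue-membership statements for seven tissues (five brain
  regions, kidney, lung): a 38-node five-brain common core and seven named
  differential interactors, padded with placeholder genes PLC001..PLC034
  so per-region interactor counts are 39/40/40/40/39 and kidney/lung have
  39/36.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import (
    ASSOCIATION,
    COLOCALIZATION,
    DIRECT_INTERACTION,
    PHYSICAL_ASSOCIATION,
    FilterConfig,
    PPINetwork,
)
from .io_formats import ExpressionMatrix

#: The seven tissues of the published comparison, brain regions first.
BRAIN_REGIONS = (
    "substantia_nigra",
    "basal_ganglia",
    "frontal_cortex",
    "anterior_cingulate",
    "cerebellum",
)
FIXTURE_TISSUES = BRAIN_REGIONS + ("kidney", "lung")

#: Published differential interactors (Table 1) and their tissue memberships.
FIXTURE_MEMBERSHIP: dict[str, frozenset[str]] = {
    "MAPT": frozenset(BRAIN_REGIONS) | {"kidney"},
    "CHGB": frozenset(BRAIN_REGIONS) | {"kidney"},
    "PAK6": frozenset(BRAIN_REGIONS) | {"kidney"},
    "SH3GL2": frozenset(BRAIN_REGIONS) | {"kidney"},
    "MATK": frozenset({"substantia_nigra", "basal_ganglia", "frontal_cortex",
                       "anterior_cingulate", "lung"}),
    "MAP2K6": frozenset({"cerebellum"}),
    "CDC42EP3": frozenset({"basal_ganglia", "frontal_cortex",
                           "anterior_cingulate", "kidney", "lung"}),
}
_N_PLACEHOLDERS = 34  # 38-node five-brain core minus the 4 named core genes


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic hub-interactome generator.

    Defaults emulate the published study conditions: ~120 scored partners
    around one hub, seven tissues, a ~1,000-gene annotation universe, a
    confidence mixture with the high component centred near 0.85 and the
    low near 0.45 (so the 0.72 threshold is exercised on both sides), 15%
    per-tissue expression dropout, and two GO terms planted at 10-fold
    annotation excess among direct interactors.
    """

    seed_gene: str = "HUB1"
    n_partners: int = 120
    tissues: tuple[str, ...] = FIXTURE_TISSUES
    n_universe: int = 1000
    high_frac: float = 0.55
    beta_high: tuple[float, float] = (17.0, 3.0)
    beta_low: tuple[float, float] = (9.0, 11.0)
    type_probs: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1)
    dropout_rate: float = 0.15
    nx_log_mean: float = 1.0
    nx_log_sigma: float = 0.8
    n_background_terms: int = 30
    baseline_annotation_prob: float = 0.05
    planted_terms: tuple[tuple[str, float], ...] = (
        ("GO:9000001", 10.0),
        ("GO:9000002", 10.0),
    )

    def __post_init__(self) -> None:
        if self.n_partners < 0 or self.n_universe < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if not 0 <= self.high_frac <= 1:
            raise ValueError("high_frac must lie in [0, 1]")
        if not math.isclose(sum(self.type_probs), 1.0, abs_tol=1e-9):
            raise ValueError("type_probs must sum to 1")
        for t, excess in self.planted_terms:
            if excess <= 0:
                raise ValueError(f"planted excess for {t} must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a synthetic dataset."""

    seed_gene: str
    rng_seed: int
    direct_interactors: set[str]
    interactors_by_tissue: dict[str, set[str]]
    confidence_by_edge: dict[tuple[str, str], float]
    planted_terms: dict[str, float]

    @property
    def differential(self) -> set[str]:
        """Planted differential set: direct interactors missing somewhere."""
        if not self.interactors_by_tissue:
            return set()
        union: set[str] = set().union(*self.interactors_by_tissue.values())
        inter = set.intersection(*map(set, self.interactors_by_tissue.values()))
        return union - inter


@dataclass
class SyntheticDataset:
    """Paths of the generated files plus the recorded truth."""

    mitab: Path
    expression: Path
    annotations: Path
    terms: Path
    universe: Path
    truth_manifest: Path
    truth: SyntheticTruth


_TYPE_CODES = (DIRECT_INTERACTION, PHYSICAL_ASSOCIATION, ASSOCIATION,
               COLOCALIZATION)


def generate_dataset(
    out_dir: str | Path,
    params: SyntheticParams | None = None,
    rng_seed: int = 0,
) -> SyntheticDataset:
    """Write a complete synthetic input bundle and return its truth.

    Identical ``rng_seed`` and params yield byte-identical files.  Tissue
    membership truth applies the default :class:`FilterConfig` semantics
    (confidence strictly > 0.72, direct type, NX >= 1.0) to the generated
    values, so it is exact by construction.
    """
    params = params or SyntheticParams()
    config = FilterConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)

    seed = params.seed_gene.upper()
    partners = [f"INT{i + 1:03d}" for i in range(params.n_partners)]

    # --- interactions -----------------------------------------------------
    is_high = rng.random(params.n_partners) < params.high_frac
    conf_high = rng.beta(*params.beta_high, size=params.n_partners)
    conf_low = rng.beta(*params.beta_low, size=params.n_partners)
    confidence = np.round(np.where(is_high, conf_high, conf_low), 4)
    type_idx = rng.choice(len(_TYPE_CODES), size=params.n_partners,
                          p=params.type_probs)

    mitab_path = out_dir / "interactions.mitab.tsv"
    lines = []
    truth_conf: dict[tuple[str, str], float] = {}
    direct: set[str] = set()
    for i, gene in enumerate(partners):
        code = _TYPE_CODES[type_idx[i]]
        conf = float(confidence[i])
        pair = tuple(sorted((seed, gene)))
        truth_conf[pair] = conf
        passes_conf = (conf > config.min_confidence if config.strict_greater
                       else conf >= config.min_confidence)
        if passes_conf and code == DIRECT_INTERACTION:
            direct.add(gene)
        lines.append("\t".join([
            seed, gene, f"UP{0:05d}", f"UP{i + 1:05d}",
            "MI:0004", code, f"pubmed:{10000 + i}", f"{conf:.4f}",
        ]))
    mitab_path.write_text("\n".join(lines) + ("\n" if lines else ""),
                          encoding="utf-8")

    # --- expression -------------------------------------------------------
    tissues = list(params.tissues)
    nx_values = pd.DataFrame(index=[seed] + partners, columns=tissues,
                             dtype=float)
    # the hub is well expressed everywhere so every tissue network is anchored
    nx_values.loc[seed] = np.round(
        1.0 + rng.lognormal(params.nx_log_mean + 1.0, 0.3, size=len(tissues)), 2)
    membership: dict[str, set[str]] = {t: set() for t in tissues}
    for gene in partners:
        dropped = rng.random(len(tissues)) < params.dropout_rate
        expressed = np.round(
            1.0 + rng.lognormal(params.nx_log_mean, params.nx_log_sigma,
                                size=len(tissues)), 2)
        low = np.round(rng.uniform(0.0, 0.99, size=len(tissues)), 2)
        row = np.where(dropped, low, expressed)
        nx_values.loc[gene] = row
        if gene in direct:
            for t, v in zip(tissues, row):
                if v >= config.nx_min:
                    membership[t].add(gene)
    expr_path = out_dir / "expression.tsv"
    nx_values.index.name = "gene"
    nx_values.to_csv(expr_path, sep="\t", float_format="%.2f")

    # --- annotations ------------------------------------------------------
    n_filler = max(0, params.n_universe - len(partners) - 1)
    universe = [seed] + partners + [f"GEN{i + 1:04d}" for i in range(n_filler)]
    ns_cycle = ("BP", "MF", "CC")
    term_rows: list[tuple[str, str, str]] = []
    anno_rows: list[tuple[str, str]] = []
    for j in range(params.n_background_terms):
        term = f"GO:{8000001 + j:07d}"
        term_rows.append((term, ns_cycle[j % 3], f"background process {j + 1}"))
        mask = rng.random(len(universe)) < params.baseline_annotation_prob
        anno_rows.extend((g, term) for g, m in zip(universe, mask) if m)
    planted: dict[str, float] = {}
    for j, (term, excess) in enumerate(params.planted_terms):
        planted[term] = excess
        term_rows.append((term, ns_cycle[j % 3], f"planted process {j + 1}"))
        p_base = params.baseline_annotation_prob
        p_study = min(1.0, excess * p_base)
        for g in universe:
            p = p_study if g in direct else p_base
            if rng.random() < p:
                anno_rows.append((g, term))
    anno_path = out_dir / "annotations.tsv"
    anno_path.write_text(
        "".join(f"{g}\t{t}\n" for g, t in sorted(anno_rows)), encoding="utf-8")
    terms_path = out_dir / "terms.tsv"
    terms_path.write_text(
        "".join(f"{t}\t{ns}\t{name}\n" for t, ns, name in sorted(term_rows)),
        encoding="utf-8")
    universe_path = out_dir / "universe.txt"
    universe_path.write_text("".join(f"{g}\n" for g in universe),
                             encoding="utf-8")

    # --- truth manifest ---------------------------------------------------
    truth = SyntheticTruth(
        seed_gene=seed, rng_seed=rng_seed, direct_interactors=direct,
        interactors_by_tissue=membership, confidence_by_edge=truth_conf,
        planted_terms=planted,
    )
    manifest_path = out_dir / "truth_membership.tsv"
    header = "gene\tdirect\t" + "\t".join(tissues)
    rows = [header]
    for gene in partners:
        flags = "\t".join(
            str(int(gene in membership[t])) for t in tissues)
        rows.append(f"{gene}\t{int(gene in direct)}\t{flags}")
    manifest_path.write_text("\n".join(rows) + "\n", encoding="utf-8")

    return SyntheticDataset(
        mitab=mitab_path, expression=expr_path, annotations=anno_path,
        terms=terms_path, universe=universe_path,
        truth_manifest=manifest_path, truth=truth,
    )


def generate_enrichment_instance(
    rng: np.random.Generator,
    n_universe: int = 1000,
    n_study: int = 40,
    n_background_terms: int = 30,
    baseline_prob: float = 0.05,
    planted_excess: float | None = None,
):
    """One over-representation experiment with or without a planted signal.

    Every gene is annotated to each of ``n_background_terms`` background
    terms with probability ``baseline_prob``.  When ``planted_excess`` is
    given, one extra term annotates study genes with probability
    ``min(1, excess * baseline_prob)`` and other genes at baseline,
    emulating a functional category genuinely over-represented in the
    study set.

    Returns ``(annotations, universe, study, planted_term)`` where
    ``planted_term`` is None for a null instance.
    """
    from .io_formats import AnnotationTable

    universe = [f"GEN{i + 1:04d}" for i in range(n_universe)]
    study = list(rng.choice(universe, size=n_study, replace=False))
    gene_terms: dict[str, set[str]] = {g: set() for g in universe}
    term_meta: dict[str, tuple[str, str]] = {}
    ns_cycle = ("BP", "MF", "CC")
    for j in range(n_background_terms):
        term = f"GO:{8000001 + j:07d}"
        term_meta[term] = (ns_cycle[j % 3], f"background process {j + 1}")
        mask = rng.random(n_universe) < baseline_prob
        for g, m in zip(universe, mask):
            if m:
                gene_terms[g].add(term)
    planted_term = None
    if planted_excess is not None:
        planted_term = "GO:9000001"
        term_meta[planted_term] = ("BP", "planted process")
        p_study = min(1.0, planted_excess * baseline_prob)
        study_set = set(study)
        for g in universe:
            p = p_study if g in study_set else baseline_prob
            if rng.random() < p:
                gene_terms[g].add(planted_term)
    annotations = AnnotationTable(gene_terms=gene_terms, term_meta=term_meta)
    return annotations, universe, study, planted_term


# ---------------------------------------------------------------------------
# deterministic in-paper fixture


def _fixture_network(tissue: str, interactors: list[str]) -> PPINetwork:
    graph = nx.Graph()
    graph.add_node("LRRK2")
    for gene in interactors:
        graph.add_edge("LRRK2", gene, confidence=0.9,
                       interaction_types={DIRECT_INTERACTION})
    return PPINetwork(seed="LRRK2", tissue=tissue, graph=graph)


def encode_paper_fixture() -> dict[str, PPINetwork]:
    """Seven deterministic LRRK2 tissue networks encoding the published
    membership statements.

    Placeholder genes PLC001..PLC034 are present in all seven networks so
    scaffolding is visibly separate from the named genes.  The resulting
    interactor counts are substantia nigra 39, basal ganglia 40, frontal
    cortex 40, anterior cingulate 40, cerebellum 39, kidney 39, lung 36;
    the five-brain common core has 38 interactors and the seven-network
    differential set is exactly the seven named genes.
    """
    placeholders = [f"PLC{i + 1:03d}" for i in range(_N_PLACEHOLDERS)]
    networks: dict[str, PPINetwork] = {}
    for tissue in FIXTURE_TISSUES:
        named = sorted(g for g, member in FIXTURE_MEMBERSHIP.items()
                       if tissue in member)
        networks[tissue] = _fixture_network(tissue, placeholders + named)
    return networks


FIXTURE_README = """\
LRRK2 tissue-network fixture
============================

Seven seed-centred direct-interaction networks (five brain regions, kidney,
lung) encoding per-gene tissue-membership statements from the source study:

  MAPT, CHGB, PAK6, SH3GL2  all five brain regions and kidney, not lung
  MATK                      all brain regions except cerebellum; lung, not kidney
  MAP2K6                    cerebellum only
  CDC42EP3                  basal ganglia, frontal cortex, anterior cingulate;
                            also kidney and lung (expression reported higher
                            there; membership never stated outright)

Placeholder genes PLC001..PLC034 pad every network so that interactor counts
match the published 39/40/40/40/39 (brain) and 39/36 (kidney/lung) figures
and the five-brain common core has 38 members.

Note: the study also quotes 36 interactors common to brain, kidney and lung;
that figure is arithmetically inconsistent with the per-gene membership
statements above (which imply a 34-gene seven-tissue core) and is therefore
not forced by this fixture.
"""


def write_fixture(out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture networks as edge-list TSVs plus a README."""
    from .io_formats import EDGE_LIST, write_network

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tissue, network in encode_paper_fixture().items():
        path = out_dir / f"lrrk2_{tissue}.tsv"
        write_network(network, path, EDGE_LIST)
        paths[tissue] = path
    (out_dir / "README.txt").write_text(FIXTURE_README, encoding="utf-8")
    return paths


#: NX values for LRRK2 and the seven differential interactors as printed in
#: the source study; cells the study does not state are absent.
_PAPER_NX: dict[str, dict[str, float]] = {
    "LRRK2": {"kidney": 10.6, "lung": 50.4},
    "MATK": {"cerebellum": 1.5, "kidney": 1.1},
    "MAP2K6": {"cerebellum": 13.7},
    "PAK6": {"basal_ganglia": 16.6},
    "CHGB": {"kidney": 1.0, "lung": 1.7},
    "SH3GL2": {"kidney": 1.9, "lung": 13.7},
}


def paper_expression() -> ExpressionMatrix:
    """The NX values the source study states, as a sparse expression matrix."""
    frame = pd.DataFrame(
        {t: {g: vals.get(t, np.nan) for g, vals in _PAPER_NX.items()}
         for t in FIXTURE_TISSUES},
        dtype=float,
    )
    return ExpressionMatrix(frame)
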