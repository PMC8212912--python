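"""GO over-representation analysis (ORA) of an interactor gene set.

For a study set of n genes drawn from a universe of N genes, of which K
are annotated to a term, the probability of observing k or more annotated
study genes under random sampling without replacement is the upper tail of
the hypergeometric distribution:

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

One test is run per term with at least one study hit; the Benjamini-
Hochberg step-up procedure controls the false discovery rate, applied
within each GO namespace (BP, MF, CC) as a separate family by default.
Terms with adjusted p below alpha (default 0.05) are flagged significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AnnotationTable

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "MF", "CC")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Over-representation tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters
    ----------
    k : annotated genes in the study set.
    K : annotated genes in the universe.
    n : study-set size.
    N : universe size.
    """
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted ascending, q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        bad = p[(p < 0) | (p > 1) | np.isnan(p)]
        raise ValueError(f"p-values outside [0, 1]: {bad}")
    _, padj, _, _ = multipletests(p, method="fdr_bh")
    return padj


@dataclass
class EnrichmentResult:
    """Over-representation statistics for one GO term.

    ``fraction`` is the percentage of the study set annotated to the term
    (100 * k / n, with n the study-set size actually tested).
    """

    term: str
    namespace: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    padj: float
    significant: bool
    hits: set[str] = field(default_factory=set)

    @property
    def fraction(self) -> float:
        return 100.0 * self.k / self.n


def run_enrichment(
    study_genes,
    annotations: AnnotationTable,
    universe=None,
    alpha: float = 0.05,
    pool_namespaces: bool = False,
) -> list[EnrichmentResult]:
    """Test every annotated GO term for over-representation in a study set.

    The universe defaults to every gene in the annotation table.  Study
    genes not in the universe are dropped with a warning and the tested n
    reflects the drop.  Only terms with k >= 1 enter the BH family; BH is
    applied per namespace unless ``pool_namespaces`` is set.  Results are
    sorted by adjusted p, then term id.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    universe_set = (
        {g.upper() for g in universe} if universe is not None
        else set(annotations.genes)
    )
    study = {g.upper() for g in study_genes}
    dropped = study - universe_set
    if dropped:
        logger.warning("%d study genes absent from the universe, dropped: %s",
                       len(dropped), ", ".join(sorted(dropped)))
    study &= universe_set
    n, N = len(study), len(universe_set)

    # invert gene->terms once; k and K per term, restricted to the universe
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotations.gene_terms.items():
        if gene not in universe_set:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    raw: list[EnrichmentResult] = []
    for term, (ns, name) in sorted(annotations.term_meta.items()):
        annotated = term_genes.get(term, set())
        hits = annotated & study
        if not hits:
            continue
        k, K = len(hits), len(annotated)
        raw.append(EnrichmentResult(
            term=term, namespace=ns, name=name, k=k, K=K, n=n, N=N,
            p=hypergeom_pvalue(k, K, n, N), padj=1.0, significant=False,
            hits=hits,
        ))

    families = ([raw] if pool_namespaces else
                [[r for r in raw if r.namespace == ns] for ns in NAMESPACES])
    for family in families:
        if not family:
            continue
        padj = bh_adjust([r.p for r in family])
        for r, q in zip(family, padj):
            r.padj = float(q)
            r.significant = q < alpha
    return sorted(raw, key=lambda r: (r.padj, r.term))


def category_fraction(study_genes, term: str,
                      annotations: AnnotationTable) -> float:
    """Percent of the study set directly annotated to a term."""
    study = {g.upper() for g in study_genes}
    if not study:
        raise ValueError("study set is empty")
    if term not in annotations.term_meta:
        raise KeyError(f"unknown term {term!r}")
    return 100.0 * len(annotations.annotated_genes(term) & study) / len(study)


def top_terms(results: list[EnrichmentResult],
              per_namespace: int = 8) -> dict[str, list[EnrichmentResult]]:
    """The most significant terms per namespace, mirroring a top-k summary."""
    out: dict[str, list[EnrichmentResult]] = {}
    for ns in NAMESPACES:
        ns_results = [r for r in results if r.namespace == ns]
        out[ns] = ns_results[:per_namespace]
    return out
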