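# Methods

## Model and assumptions

The analysis treats a tissue-specific interactome as a *filtered depth-1
ego network*: one seed protein, its direct interaction partners, and only
seed–partner edges. The underlying assumptions are (i) an interaction
reported anywhere is possible in a tissue only if both partners' genes
are expressed there — mRNA abundance (consensus NX) is used as a proxy
for protein presence; (ii) the confidence score attached to each
interaction is a consumable input, not something this package derives;
(iii) only the four flat PSI-MI interaction categories (direct
interaction, physical association, association, colocalization) matter,
with no CV-ontology descendant expansion. Partner–partner ("second
shell") edges and deeper neighbourhoods are deliberately out of scope.

Network comparison is purely presence/absence. The rewiring score
`D(v) = 1 − c(v)/m` (node in `c` of `m` networks) is the only comparison
statistic; variance-based rewiring over numeric attributes is not
implemented because node membership is the quantity the downstream
interpretation uses. Ties in rewiring rankings break alphabetically so
reports are deterministic.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_confidence` | 0.72, strict `>` | filter #1 threshold on the [0,1] reliability score; strictness is a switch (`strict_greater`) so boundary records are handled reproducibly |
| `allowed_interaction_types` | `{MI:0407}` | filter #2; exact CV-code set intersection |
| `nx_min` | 1.0 NX | filter #3; a gene is "expressed" in a tissue at NX ≥ 1.0. The upstream resources do not publish their exact cutoff, so this is a named config value surfaced in every run log |
| `alpha` | 0.05 | significance threshold on BH-adjusted p |
| `top_k` | 10 | size of top-expressed interactor rankings |

Genes missing from the expression matrix are treated as not expressed
and dropped (with the dropped list logged); a missing cell is tracked as
absent, never coerced to 0. The seed is exempt from the expression
filter so every tissue network stays anchored on it. Duplicate
interaction records merge keeping the maximum confidence and the union
of evidence sets — one strong piece of evidence suffices to clear
filter #1. Self-loops are dropped.

## Enrichment statistics

Over-representation p-values are the exact hypergeometric upper tail
`P(X ≥ k)` (computed via `scipy.stats.hypergeom.sf`; `k = 0` returns
exactly 1). Only terms with at least one study hit are tested, so the
BH family size `m` stays interpretable. BH correction is applied within
each GO namespace (BP, MF, CC) as a separate family by default, treating
the three aspect datasets as independent analyses; `pool_namespaces=True`
corrects across all tested terms as one family. A gene counts for a term
only if directly annotated in the input table — no ontology
up-propagation — so the statistic is fully determined by the two input
files. The universe defaults to all genes in the annotation table and
can be overridden with an explicit gene list; its size is recorded in
every report.

One consequence of per-namespace families is worth stating: under a
global null, the chance of *any* adjusted p < α across the three
independent families approaches 3α, even though each family's false
discovery rate is controlled at α. The type-I-error and power
simulations in the test suite and acceptance script therefore use the
pooled-family switch, so that the "any significant term" event coincides
with the family the BH bound applies to. The pipeline default remains
per-namespace.

## Synthetic data: what it emulates, what it does not

`generate_dataset` emulates the statistical shape of a hub-protein query
against a curated interaction resource: 120 partners; confidences from a
two-component Beta mixture (high component mean ≈ 0.85, low ≈ 0.45,
55% high) so the 0.72 threshold is exercised from both sides; one
interaction type per record, multinomial with probabilities
0.4 / 0.3 / 0.2 / 0.1 over direct / physical association / association /
colocalization; NX values of `1 + LogNormal(μ=1, σ=0.8)` for expressed
cells with 15% per-tissue dropout (dropout cells uniform on [0, 0.99)),
which plants differential tissue membership; a 1,000-gene annotation
universe with 30 background terms at 5% annotation probability and two
terms planted at 10-fold excess among the direct interactors. The truth
object records the post-filter memberships by applying the same
thresholds to the generated values, so recovery checks are exact by
construction. Identical seeds give byte-identical files.

What the generator does *not* emulate: evidence-based confidence scoring
(scores are i.i.d., not correlated with literature depth), correlated
expression across related tissues, realistic GO term-size distributions
or term–term overlap from the ontology graph, and annotation bias toward
well-studied genes. Passing tests on synthetic data therefore
demonstrate correctness of the filtering/comparison/testing machinery,
not robustness to those real-data artefacts.

`encode_paper_fixture` is the deterministic counterpart: it encodes the
published per-gene tissue memberships of seven LRRK2 interactors across
five brain regions, kidney and lung, padded with visibly-named
placeholder genes (`PLC001…PLC034`, present in all seven networks) so
that interactor counts are 39/40/40/40/39 (brain), 39 (kidney) and 36
(lung) and the five-brain common core has 38 members. The source also
quotes "36 common" interactors across brain, kidney and lung, which is
arithmetically inconsistent with its own per-gene membership statements
(they imply a 34-gene seven-tissue core); the fixture encodes the
membership statements and reports whatever intersection follows.
CDC42EP3's kidney/lung membership is never stated outright and is
encoded as present in both (its expression is reported higher there);
this does not affect its differential status.

## Numerical and design choices

- The threshold comparison is strictly `>` per the published setting,
  with an explicit switch rather than a silent convention.
- Edge-list and GraphML exports store confidences as `repr` of the float
  so round-trips are bit-exact.
- Record canonicalization orders each pair lexicographically, making
  parsing invariant under swapping the two identifier columns.
- Merged reference networks keep the maximum confidence per edge and
  count node/edge presence across inputs; node counts equal the presence
  matrix column sums by construction, and this is tested.
- Degenerate inputs are defined, not errors: an absent seed yields the
  single-node network; zero partners yield valid empty files; an empty
  study set is the one hard error in `category_fraction` (the fraction
  is undefined).
- Simulation sizes (500 null replicates, 200 power replicates, oracle
  enumeration up to N = 12, three end-to-end seeds) were chosen so each
  check has small Monte-Carlo error while the whole suite runs in
  seconds.

## Known limitations

- mRNA as a proxy for protein presence is the method's central
  approximation; protein-level scores can only be passed through as
  annotation, not computed.
- No identifier mapping: gene symbols are the node key and must agree
  across the three inputs.
- Flat annotation tables mean enriched-term counts are not comparable to
  tools that up-propagate the GO graph; the per-term statistics are.
- Presence/absence comparison ignores edge-weight changes between
  tissues; an interaction that weakens without disappearing is invisible
  to it.
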