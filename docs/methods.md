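# Methods

This note documents the models, rules and numerical choices behind
`gotaxon`, and what the synthetic-data tests do and do not demonstrate.

## The constraint model

A *taxon constraint* restricts which organisms a GO term may annotate.
Two verbs exist in curated sources: `never_in(g, T)` — term `g` (and all
of its GO descendants) may not annotate any organism in `subtree(T)` —
and `only_in(g, T)` — `g` may annotate organisms in `subtree(T)` only.
`gotaxon` adds a third, manual-tier-only verb, `allow(g, T)`, whose sole
purpose is to cancel a lower-priority prohibition for one clade; without
it a user could not repair a wrong consortium or automatic constraint.

Prohibitions propagate along two orthogonal hierarchies:

* **down the taxonomy** — a constraint at a clade binds every descendant
  taxon;
* **down the GO DAG** — a prohibited term drags its entire descendant
  closure with it (a function you cannot have implies you cannot have any
  of its specialisations).

Closure queries use `is_a` and `part_of`, the standard
annotation-propagation pair; the relation set is configurable
(`propagating_relations`), and `regulates`-family edges are loaded but
never traversed.

## Automatic derivation

For each reference node `R` and term `g`, let `N(g)` be the corpus-wide
cumulative frequency (annotations to `g` or any GO descendant, counted
once per annotation even through diamonds) and `N_R(g)` the same within
`subtree(R)`. The rule is:

    emit never_in(g, R)  iff  N(g) >= threshold  and  N_R(g) = 0

with `threshold = 500` annotations by default (`min_global_frequency`).
The threshold keeps the derivation away from highly specific functions
that only one model organism exhibits; the zero test makes the rule
*sound by construction*: no term actually used inside the clade can ever
be prohibited for it. Output is stored compactly at GO-topmost qualifying
terms; expansion materialises the closure on demand.

Three deliberate refinements where the base rule is silent:

* **Nested reference nodes.** `N_R` counts *all* cleaned annotations of
  organisms in `subtree(R)`, including those whose closest reference node
  is a deeper nested node. Counting only the closest-node bin would let
  an outer clade prohibit a term that an inner, well-annotated sub-clade
  demonstrably uses.
* **Namespace roots are never emitted.** A sparse clade with zero
  annotations in one namespace would otherwise receive a prohibition of
  the entire subontology.
* **Count unit.** Frequencies count annotation lines by default;
  `count_unit: proteins` switches to distinct gene products per term.

## Cleaning

Rules are applied in a fixed order (a record removed for several reasons
is counted once, under the first match): `ND` evidence, `NOT` qualifier,
namespace-root terms, `RNAcentral` in the DB or attribution column,
*environmental samples* anywhere in the organism's lineage names
(case-insensitive), obsolete or unknown GO ids, unknown taxa. Merged
(retired) taxids and `alt_id` GO ids are transparently redirected; in
multi-organism `taxon:X|taxon:Y` fields the first taxon (the annotated
gene product's organism, by GAF convention) is used. Evidence codes are
otherwise untouched — IEA is retained on purpose, since electronic
annotations are the only functional signal for most of the taxonomy.

## Reference-node selection

The published constraint sets are built on curated reference-node lists;
when none is supplied, selection uses annotation quantity and diversity:
a node qualifies with ≥ `min_annotations_unreliable` (default 1 000)
cumulative cleaned annotations from ≥ `min_species` (default 5) distinct
organisms, and is labelled *reliable* at ≥ `min_annotations_reliable`
(default 50 000). Candidates strictly below a species-ranked node are
excluded. These thresholds are this package's declared stand-in for an
unpublished selection procedure — the dichotomy and its consequences
(both labels derive constraints identically; the label is provenance
only) are what matters, not the specific numbers, and a curated list
loaded via `reference_nodes:` bypasses them entirely.

## Merging and priority

Records keep their source tier (`automatic`, `goc`, `manual`) and
`only_in` is stored natively. Expansion resolves per (taxon, GO term):
tiers apply in ascending priority, each overwriting the previous; within
a tier a prohibition beats a permission (relevant for colliding
consortium axioms; contradictory manual directives on the identical pair
are a hard configuration error). For a query taxon `x`:
`never_in(g, T)` prohibits when `T` is an ancestor-or-self of `x`;
`only_in(g, T)` prohibits when `x ∉ subtree(T)` and permits inside;
`allow(g, T)` permits when `T` is an ancestor-or-self of `x`.

`convert_only_in` also offers the compact rewriting of `only_in` into
sibling-branch `never_in` records (one per branch off the root→T path).
That encoding is exact for every taxon except the strict ancestors of
`T` themselves, where no `never_in` placement can express a prohibition
without leaking into the allowed clade — which is why the merged set
keeps `only_in` native and the rewriting is an export/interoperability
view.

## Evaluation metrics

Species-centric pooling: each GO term's score is the max over the
species' proteins, then propagated upward (a parent scores at least its
best descendant); namespace roots are excluded. Ground truth is
ancestor-closed identically. The threshold grid is the set of distinct
predicted scores united with the 0.01-step sweep; if the distinct scores
alone exceed 101 points only the fixed grid is used, and ties are always
evaluated at the score value itself. Thresholds where nothing is
predicted contribute no precision point (coverage handling) but still
define `ru`/`mi`.

Information content uses base-2 logarithms with add-one smoothing,
`ic(g) = −log₂((N_g+1)/(N_root+1))`, computed from the same cleaned
corpus used for constraint derivation; roots get 0 bits and `ic` is
monotone non-decreasing down the DAG. The log base is a convention
choice (bits); it rescales `wFmax` weights and `Smin` uniformly.

## Synthetic data

The fixture generators emit real files in the exact dialects the loaders
parse (OBO, taxdump, GAF 2.2), all randomness behind one seed
(byte-identical reruns). A bundle defaults to ~25 taxa, ~43 GO terms
across three namespaces (15% diamond parents), four reference nodes, and
~1 500 GAF lines including one batch per cleaning rule, merged-taxid and
alt-id aliases. *Planted patterns* keep a GO branch annotation-free
inside a chosen reference clade while booster lines outside push its
corpus frequency past the 500 threshold, so derivation has real work to
do. The generator re-derives the expected compact output with its own
nested-loop brute force (no shared code with the pipeline) and writes it
as a manifest — the oracle for end-to-end tests and the acceptance
script.

What this does **not** show: statistical realism of real GOA corpora
(annotation-depth distributions, evidence-code mixes, taxon skew), the
scale behaviour on tens of millions of lines, or the biological quality
of constraints derived from real data. Passing tests demonstrate that the
rules are implemented exactly as specified, not that the rules are
complete for production curation.

## Problem sizes

Default test and acceptance-script sizes — 100 and 40 seeded bundles of
the shape above, benchmark instances of a few dozen terms, 1 000 random
metric instances — were chosen so the whole suite re-derives everything
from scratch in well under a minute on one core while still engaging
every rule non-trivially.

## Known limitations

* OWL input is a minimal RDF/XML reader (GO classes, `subClassOf`,
  `part_of` restrictions, RO taxon-constraint restrictions); full OWL
  reasoning and cross-ontology imports are out of scope. OBO is primary.
* Rank-aware taxonomy queries (genus/family rollups) are not provided.
* The audit reports violations; it does not edit or repair GAF files.
* Qualifier values other than `NOT` (e.g. `contributes_to`) are kept.
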