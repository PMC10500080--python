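# gotaxon

Taxon-based Gene Ontology constraints: which functions can an organism
*not* have?

GO annotations are species-agnostic, but most functions are not:
photosynthesis does not happen in trypanosomatids, and a chloroplast
compartment term annotated to a parasite is a database error waiting to
propagate. `gotaxon` derives **never_in** taxon constraints — per-clade
lists of prohibited GO terms — directly from an annotation corpus, merges
them with the Gene Ontology Consortium's curated `never_in_taxon` /
`only_in_taxon` axioms and with user-supplied manual rules, and measures
the effect of constraint filtering on automatic function predictions with
species-centric CAFA metrics.

## Method

1. **Cleaning.** GAF annotations are filtered: `ND` evidence, negated
   (`NOT`) annotations, root terms (`GO:0008150`, `GO:0003674`,
   `GO:0005575`), `RNAcentral` records, *environmental samples* taxa,
   obsolete terms and deleted taxa are removed. IEA annotations are kept —
   for most of the taxonomy they are the only signal.
2. **Reference nodes.** Taxonomy nodes pooling enough annotation quantity
   and organism diversity are selected (or loaded from a curated list) and
   labelled *reliable* / *unreliable*.
3. **Cumulative frequencies.** Every organism is traced to its closest
   reference ancestor. For each GO term `g` and scope, the cumulative
   frequency counts annotations to `g` or any GO descendant of `g`
   (once per annotation, even through DAG diamonds).
4. **Derivation.** A term is marked `never_in` a reference node when its
   corpus-wide cumulative frequency is ≥ 500 (configurable) while its
   cumulative frequency inside the node's subtree is 0. The prohibition
   propagates to all descendant taxa and all GO descendants of the term.
5. **Merging.** Consortium `only_in(g, T)` axioms become `never_in(g, x)`
   for every taxon `x` outside `subtree(T)`. Sources are resolved with
   strict priority **manual > consortium > automatic**; a manual `allow`
   can punch a subtree-shaped hole in any lower-priority prohibition.
6. **Evaluation.** Per species, all scored predictions are pooled into one
   non-redundant GO set (max score per term, ancestor-propagated) and
   swept over thresholds τ:
   `Fmax = max_τ 2·pr·rc/(pr+rc)`, `wFmax` with set sizes replaced by
   information-content sums, and `Smin = min_τ √(ru² + mi²)` where
   `ru`/`mi` are the ic-weighted missed-truth and false-prediction masses,
   `ic(g) = −log₂((N_g+1)/(N_root+1))`.

## Worked example

The package ships deterministic generators for synthetic bundles, so the
whole pipeline can be exercised without downloads:

```bash
gotaxon fixtures -o bundle --seed 11
cat > config.yml <<EOF
ontology: bundle/ontology.obo
gaf: bundle/annotations.gaf
taxdump_dir: bundle
reference_nodes: bundle/reference_nodes.tsv
min_global_frequency: 500
EOF
gotaxon generate -c config.yml -o out
```

`out/cleaning_report.tsv` reconciles the corpus (1498 lines in, 1400
kept, 14 removed per cleaning rule in this bundle), and
`out/constraints.tsv` holds the compact constraint table:

```
#taxon_id  taxon_name  go_id       go_name                    namespace           relation  source     reference_node
10         Clade 10    GO:0000024  molecular_function term 1  molecular_function  never_in  automatic  10
11         Clade 11    GO:0000025  molecular_function term 2  molecular_function  only_in   goc
11         Clade 11    GO:0000034  molecular_function term 11 molecular_function  never_in  goc
```

The single automatic record says: `GO:0000024` is used ≥ 500 times across
the corpus but never inside clade 10, so it (and its GO descendants) is
prohibited for every species of that clade. Querying a species
materializes the full expansion:

```
$ gotaxon query out/constraints.tsv -c config.yml --taxon 20
#taxon: 20 Species 20
#go_id      go_name                    namespace           source
GO:0000024  molecular_function term 1  molecular_function  automatic
GO:0000025  molecular_function term 2  molecular_function  goc
GO:0000027  molecular_function term 4  molecular_function  automatic
...
```

`gotaxon audit GAF constraints.tsv -c config.yml` flags annotations whose
term is prohibited for their organism, and `gotaxon evaluate` produces
the per-(species, namespace, filter) Fmax/wFmax/Smin summary.

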