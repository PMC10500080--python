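"""Deterministic synthetic inputs: ontologies, taxonomies, GAF corpora.

Every generator writes real files in the exact dialects the loaders
consume (OBO, NCBI taxdump, GAF 2.2), so parser code paths are always
exercised.  All randomness flows from one seeded generator: identical
spec + seed give byte-identical output files.

The GAF generator plants ``never_in`` patterns — GO branches kept free of
annotations inside chosen reference clades while well represented outside
— and emits a *manifest* computed by its own naive brute force (explicit
parent-chain walks and per-line ancestor loops, no pruning, no shared
code with the pipeline).  The manifest lists, for every (reference node,
GO term) pair, whether the constraint engine must emit or suppress a
compact ``never_in`` record, and is the independent oracle for end-to-end
tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError

DEFAULT_N_TERMS = {
    "biological_process": 20,
    "molecular_function": 12,
    "cellular_component": 8,
}

_NS_ASPECT = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}

DEFAULT_DIRTY = {
    "nd_evidence": 0.01,
    "not_qualifier": 0.01,
    "root_term": 0.01,
    "rnacentral": 0.01,
    "environmental_sample": 0.01,
    "obsolete_term": 0.01,
    "unknown_taxon": 0.01,
}


@dataclass
class FixtureSpec:
    """Shape parameters for one synthetic input bundle.

    Defaults produce a bundle of roughly 25 taxa, ~43 GO terms and
    ~1500 GAF lines — small enough that the naive manifest brute force is
    instant, large enough that grouping, cumulative counting, threshold
    and zero-frequency rules all engage non-trivially under the default
    corpus-frequency threshold of 500.
    """

    seed: int = 0
    # ontology shape
    n_terms: dict = field(default_factory=lambda: dict(DEFAULT_N_TERMS))
    diamond_fraction: float = 0.15
    part_of_fraction: float = 0.2
    n_obsolete: int = 1
    n_alt_ids: int = 1
    n_goc_never_in: int = 1
    n_goc_only_in: int = 1
    # taxonomy shape
    n_internal: int = 8
    n_leaves: int = 16
    n_ref_nodes: int = 4
    include_env_clade: bool = True
    n_merged: int = 2
    # annotation plan
    n_annotations: int = 800
    n_planted: int = 1
    boost: int = 600
    threshold: int = 500
    dirty: dict = field(default_factory=lambda: dict(DEFAULT_DIRTY))
    extra_lines: list = field(default_factory=list)  # explicit (taxid, go_id)


# ---------------------------------------------------------------------------
# ontology


@dataclass
class OntologyFixture:
    path: Path
    terms: dict  # go_id -> dict(namespace, name, parents=[(parent, rel)], obsolete, alt_ids)
    roots: dict  # namespace -> go_id
    axioms: list  # (go_id, relation_label, taxid)

    @property
    def graph(self):
        from .ontology import load_ontology

        return load_ontology(self.path, fmt="obo")


def _go_id(i: int) -> str:
    return f"GO:{i:07d}"


def make_ontology(spec: FixtureSpec, outdir, taxonomy: "TaxonomyFixture | None" = None) -> OntologyFixture:
    """Write a synthetic OBO file with three namespace roots.

    Terms within a namespace form a random DAG: each term has one parent
    among earlier terms and, with probability ``diamond_fraction``, a
    second parent (creating diamonds).  ``part_of_fraction`` of parent
    links use ``part_of`` instead of ``is_a``.  Taxon-constraint axioms
    are attached to random mid-graph terms when a taxonomy fixture is
    supplied (or to taxon id 1 placeholders otherwise).
    """
    for ns, n in spec.n_terms.items():
        if n < 1:
            raise ConfigError(f"n_terms[{ns}] must be >= 1")
    rng = random.Random(spec.seed * 1_000_003 + 7)
    terms: dict[str, dict] = {}
    roots: dict[str, str] = {}
    counter = 1
    for ns in ("biological_process", "molecular_function", "cellular_component"):
        root = _go_id(counter)
        counter += 1
        roots[ns] = root
        terms[root] = {
            "namespace": ns,
            "name": f"{ns} root",
            "parents": [],
            "obsolete": False,
            "alt_ids": [],
        }
        ns_terms = [root]
        for j in range(spec.n_terms.get(ns, 0)):
            tid = _go_id(counter)
            counter += 1
            parents = [rng.choice(ns_terms)]
            if len(ns_terms) > 1 and rng.random() < spec.diamond_fraction:
                second = rng.choice(ns_terms)
                if second != parents[0]:
                    parents.append(second)
            plinks = [
                (p, "part_of" if rng.random() < spec.part_of_fraction else "is_a")
                for p in parents
            ]
            terms[tid] = {
                "namespace": ns,
                "name": f"{ns} term {j}",
                "parents": plinks,
                "obsolete": False,
                "alt_ids": [],
            }
            ns_terms.append(tid)

    for _ in range(spec.n_obsolete):
        tid = _go_id(counter)
        counter += 1
        terms[tid] = {
            "namespace": "biological_process",
            "name": "withdrawn term",
            "parents": [],
            "obsolete": True,
            "alt_ids": [],
        }

    live = [t for t, d in terms.items() if not d["obsolete"] and d["parents"]]
    for _ in range(spec.n_alt_ids):
        if not live:
            break
        target = rng.choice(live)
        terms[target]["alt_ids"].append(_go_id(counter))
        counter += 1

    axioms: list[tuple[str, str, int]] = []
    taxon_pool = (
        sorted(taxonomy.internal_ids()) if taxonomy is not None else [1]
    )
    for rel, n in (("never_in_taxon", spec.n_goc_never_in),
                   ("only_in_taxon", spec.n_goc_only_in)):
        for _ in range(n):
            if not live:
                break
            axioms.append((rng.choice(live), rel, rng.choice(taxon_pool)))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "ontology.obo"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for tid in sorted(terms):
            d = terms[tid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {tid}\nname: {d['name']}\nnamespace: {d['namespace']}\n")
            for alt in d["alt_ids"]:
                fh.write(f"alt_id: {alt}\n")
            if d["obsolete"]:
                fh.write("is_obsolete: true\n")
            for parent, rel in d["parents"]:
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            for go, rel, taxid in axioms:
                if go == tid:
                    fh.write(f"relationship: {rel} NCBITaxon:{taxid}\n")
        fh.write(
            "\n[Typedef]\nid: part_of\nname: part of\n"
            "\n[Typedef]\nid: never_in_taxon\nname: never in taxon\n"
            "\n[Typedef]\nid: only_in_taxon\nname: only in taxon\n"
        )
    return OntologyFixture(path, terms, roots, axioms)


def naive_ancestors_or_self(fixture_terms: dict, go_id: str) -> set[str]:
    """Brute-force ancestor closure on the generator's own term table."""
    out: set[str] = set()
    stack = [go_id]
    while stack:
        node = stack.pop()
        if node in out:
            continue
        out.add(node)
        for parent, _rel in fixture_terms[node]["parents"]:
            stack.append(parent)
    return out


def naive_descendants(fixture_terms: dict, go_id: str) -> set[str]:
    """Brute-force descendant closure (excluding self), by exhaustive scan."""
    return {
        t
        for t in fixture_terms
        if t != go_id
        and not fixture_terms[t]["obsolete"]
        and go_id in naive_ancestors_or_self(fixture_terms, t)
    }


# ---------------------------------------------------------------------------
# taxonomy


@dataclass
class TaxonomyFixture:
    nodes_path: Path
    names_path: Path
    merged_path: Path
    refs_path: Path
    nodes: dict  # taxid -> dict(parent, rank, name)
    merged: dict  # old -> new
    ref_nodes: dict  # taxid -> label
    leaves: list
    env_taxa: list

    def internal_ids(self):
        return [t for t, d in self.nodes.items() if d["rank"] != "species" and t != 1]

    @property
    def tree(self):
        from .taxonomy import load_taxonomy

        return load_taxonomy(self.nodes_path, self.names_path, self.merged_path)


def naive_lineage(nodes: dict, taxid: int) -> list[int]:
    """Brute-force parent-chain walk on the generator's own node table."""
    chain = [taxid]
    while nodes[taxid]["parent"] != taxid:
        taxid = nodes[taxid]["parent"]
        chain.append(taxid)
    return chain


def make_taxonomy(spec: FixtureSpec, outdir) -> TaxonomyFixture:
    """Write synthetic taxdump files plus a reference-node sidecar TSV.

    The tree has a root (taxid 1), ``n_internal`` unranked internal
    nodes, ``n_leaves`` species leaves, optionally an ``environmental
    samples`` clade, and ``n_merged`` retired ids redirected to leaves.
    Reference nodes are internal nodes with at least two leaf species
    beneath them, labelled reliable/unreliable at random.
    """
    if spec.n_internal < 1 or spec.n_leaves < 1:
        raise ConfigError("taxonomy needs at least one internal node and one leaf")
    rng = random.Random(spec.seed * 1_000_003 + 13)
    nodes: dict[int, dict] = {1: {"parent": 1, "rank": "no rank", "name": "root"}}
    internal = [1]
    taxid = 9
    for i in range(spec.n_internal):
        taxid += 1
        parent = rng.choice(internal)
        nodes[taxid] = {"parent": parent, "rank": "clade", "name": f"Clade {taxid}"}
        internal.append(taxid)
    leaves = []
    for i in range(spec.n_leaves):
        taxid += 1
        parent = rng.choice(internal[1:]) if len(internal) > 1 else 1
        nodes[taxid] = {"parent": parent, "rank": "species", "name": f"Species {taxid}"}
        leaves.append(taxid)

    env_taxa: list[int] = []
    if spec.include_env_clade:
        taxid += 1
        env = taxid
        nodes[env] = {"parent": 1, "rank": "no rank", "name": "environmental samples"}
        taxid += 1
        nodes[taxid] = {"parent": env, "rank": "species",
                        "name": f"uncultured organism {taxid}"}
        env_taxa = [env, taxid]

    merged: dict[int, int] = {}
    for old, leaf in zip(range(900_001, 900_001 + spec.n_merged), leaves):
        merged[old] = leaf

    # reference nodes: internal nodes covering >= 2 leaf species
    def leaf_count(node):
        return sum(1 for s in leaves if node in naive_lineage(nodes, s))

    candidates = [n for n in internal[1:] if leaf_count(n) >= 2]
    rng.shuffle(candidates)
    ref_nodes = {}
    for n in sorted(candidates[: spec.n_ref_nodes]):
        ref_nodes[n] = rng.choice(("reliable", "unreliable"))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes_path = outdir / "nodes.dmp"
    names_path = outdir / "names.dmp"
    merged_path = outdir / "merged.dmp"
    refs_path = outdir / "reference_nodes.tsv"
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for t in sorted(nodes):
            d = nodes[t]
            fh.write(f"{t}\t|\t{d['parent']}\t|\t{d['rank']}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for t in sorted(nodes):
            fh.write(f"{t}\t|\t{nodes[t]['name']}\t|\t\t|\tscientific name\t|\n")
            fh.write(f"{t}\t|\talias {t}\t|\t\t|\tsynonym\t|\n")
    with open(merged_path, "w", encoding="utf-8") as fh:
        for old in sorted(merged):
            fh.write(f"{old}\t|\t{merged[old]}\t|\n")
    with open(refs_path, "w", encoding="utf-8") as fh:
        fh.write("#taxid\tlabel\n")
        for t in sorted(ref_nodes):
            fh.write(f"{t}\t{ref_nodes[t]}\n")
    return TaxonomyFixture(
        nodes_path, names_path, merged_path, refs_path,
        nodes, merged, ref_nodes, leaves, env_taxa,
    )


# ---------------------------------------------------------------------------
# GAF corpus with planted truth


@dataclass
class GafFixture:
    path: Path
    manifest_path: Path
    clean_plan: list  # (resolved_taxid, go_id) for every clean line
    planted: list  # (ref_taxid, go_id)
    emit: set  # (ref_taxid, go_id) compact records the engine MUST produce
    suppress: set  # (ref_taxid, go_id) pairs it must NOT produce


def _gaf_line(db, protein, go_id, taxid, aspect, evidence="IEA", qualifier="involved_in",
              assigned_by="FixtureDB"):
    fields = [
        db, protein, protein.lower(), qualifier, go_id, "GO_REF:0000001",
        evidence, "", aspect, "", "", "protein", f"taxon:{taxid}", "20230601",
        assigned_by, "", "",
    ]
    return "\t".join(fields) + "\n"


def compute_manifest(fixture_terms, fixture_nodes, ref_nodes, clean_plan, threshold):
    """Naive re-derivation of the compact ``never_in`` output.

    Pure nested loops over the generator's own tables: per-line ancestor
    closures for cumulative counts, parent-chain walks for subtree
    membership, exhaustive ancestor scans for topmost pruning.  Returns
    ``(emit, suppress)`` partitioning (reference node x live non-root
    term) pairs.
    """
    roots = {
        d["namespace"]: t
        for t, d in fixture_terms.items()
        if not d["obsolete"] and not d["parents"]
    }
    live_terms = [
        t for t, d in fixture_terms.items()
        if not d["obsolete"] and t not in roots.values()
    ]
    global_cum = {
        t: sum(1 for _taxid, go in clean_plan
               if t in naive_ancestors_or_self(fixture_terms, go))
        for t in fixture_terms if not fixture_terms[t]["obsolete"]
    }
    emit, suppress = set(), set()
    for ref in ref_nodes:
        in_subtree = [
            (taxid, go) for taxid, go in clean_plan
            if ref in naive_lineage(fixture_nodes, taxid)
        ]
        ref_cum = {
            t: sum(1 for _taxid, go in in_subtree
                   if t in naive_ancestors_or_self(fixture_terms, go))
            for t in fixture_terms if not fixture_terms[t]["obsolete"]
        }
        candidates = {
            t for t in live_terms
            if global_cum[t] >= threshold and ref_cum[t] == 0
        }
        for t in live_terms:
            is_top = t in candidates and not any(
                a in candidates
                for a in naive_ancestors_or_self(fixture_terms, t) - {t}
            )
            (emit if is_top else suppress).add((ref, t))
    return emit, suppress


def make_gaf(spec: FixtureSpec, onto: OntologyFixture, taxo: TaxonomyFixture,
             outdir) -> GafFixture:
    """Write a GAF 2.2 corpus realising the annotation plan, plus manifest.

    Planted patterns pick a reference clade and a GO branch; base
    sampling never annotates the branch inside the clade, while booster
    lines outside the clade push the branch's corpus-wide cumulative
    frequency past the derivation threshold.  Dirty lines (ND, NOT, root
    terms, RNAcentral, environmental samples, obsolete terms, unknown
    taxa) exercise every cleaning rule and are excluded from the
    manifest's brute-force counts.
    """
    rng = random.Random(spec.seed * 1_000_003 + 29)
    terms = onto.terms
    nodes = taxo.nodes
    roots = set(onto.roots.values())
    live_terms = sorted(
        t for t, d in terms.items() if not d["obsolete"] and t not in roots
    )
    species = [s for s in taxo.leaves]
    if not species or not live_terms:
        raise ConfigError("fixture needs at least one species and one non-root term")

    # choose planted (reference clade, GO branch) pairs; the clade must
    # leave some species outside it, otherwise no booster lines can exist
    planted: list[tuple[int, str]] = []
    refs = [
        r for r in sorted(taxo.ref_nodes)
        if any(r not in naive_lineage(nodes, s) for s in species)
    ]
    deep_terms = [t for t in live_terms if terms[t]["parents"]]
    for k in range(spec.n_planted):
        if not refs or not deep_terms:
            break
        ref = refs[rng.randrange(len(refs))]
        branch = deep_terms[rng.randrange(len(deep_terms))]
        planted.append((ref, branch))

    closure_cache = {
        b: {b} | naive_descendants(terms, b) for _r, b in planted
    }

    def allowed(taxid: int, go_id: str) -> bool:
        for ref, branch in planted:
            if ref in naive_lineage(nodes, taxid) and go_id in closure_cache[branch]:
                return False
        return True

    clean_plan: list[tuple[int, str]] = []
    lines: list[str] = []
    alias_of = {new: old for old, new in taxo.merged.items()}

    def emit_clean(taxid: int, go_id: str):
        clean_plan.append((taxid, go_id))
        written_taxid = taxid
        if taxid in alias_of and rng.random() < 0.3:
            written_taxid = alias_of[taxid]  # exercise merged-id redirects
        written_go = go_id
        if terms[go_id]["alt_ids"] and rng.random() < 0.2:
            written_go = terms[go_id]["alt_ids"][0]  # exercise alt_id resolution
        protein = f"P{rng.randrange(10_000):05d}"
        aspect = _NS_ASPECT[terms[go_id]["namespace"]]
        lines.append(_gaf_line("UniProtKB", protein, written_go, written_taxid, aspect))

    # base corpus
    for _ in range(spec.n_annotations):
        for _try in range(50):
            taxid = rng.choice(species)
            go_id = rng.choice(live_terms)
            if allowed(taxid, go_id):
                emit_clean(taxid, go_id)
                break

    # booster lines push each planted branch past the corpus threshold
    for ref, branch in planted:
        outside = [s for s in species if ref not in naive_lineage(nodes, s)]
        pool = sorted(closure_cache[branch])
        if not outside:
            continue
        for _ in range(spec.boost):
            taxid = rng.choice(outside)
            go_id = rng.choice(pool)
            if allowed(taxid, go_id):
                emit_clean(taxid, go_id)

    # explicit user-plan lines, validated against the planted truth
    for taxid, go_id in spec.extra_lines:
        if not allowed(taxid, go_id):
            raise ConfigError(
                f"plan line ({taxid}, {go_id}) violates a planted never_in pattern"
            )
        emit_clean(taxid, go_id)

    # dirty lines, one batch per cleaning rule
    obsolete_terms = [t for t, d in terms.items() if d["obsolete"]]
    n_total = len(clean_plan)
    for reason, frac in spec.dirty.items():
        n = max(1, round(frac * n_total)) if frac > 0 else 0
        for _ in range(n):
            taxid = rng.choice(species)
            go_id = rng.choice(live_terms)
            if reason == "nd_evidence":
                lines.append(_gaf_line("UniProtKB", "P99999", go_id, taxid, "P",
                                       evidence="ND"))
            elif reason == "not_qualifier":
                lines.append(_gaf_line("UniProtKB", "P99998", go_id, taxid, "P",
                                       qualifier="NOT|involved_in"))
            elif reason == "root_term":
                lines.append(_gaf_line("UniProtKB", "P99997", sorted(roots)[0],
                                       taxid, "P"))
            elif reason == "rnacentral":
                lines.append(_gaf_line("RNAcentral", "URS000075", go_id, taxid, "P"))
            elif reason == "environmental_sample" and taxo.env_taxa:
                lines.append(_gaf_line("UniProtKB", "P99996", go_id,
                                       taxo.env_taxa[-1], "P"))
            elif reason == "obsolete_term" and obsolete_terms:
                lines.append(_gaf_line("UniProtKB", "P99995",
                                       rng.choice(obsolete_terms), taxid, "P"))
            elif reason == "unknown_taxon":
                lines.append(_gaf_line("UniProtKB", "P99994", go_id, 999_999, "P"))

    rng.shuffle(lines)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "annotations.gaf"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n!generated-by: gotaxon fixtures "
                 f"(seed {spec.seed})\n")
        fh.writelines(lines)

    emit, suppress = compute_manifest(
        terms, nodes, sorted(taxo.ref_nodes), clean_plan, spec.threshold
    )
    manifest_path = outdir / "manifest.tsv"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        fh.write(f"# seed: {spec.seed}\n# threshold: {spec.threshold}\n")
        fh.write("#ref_node\tgo_id\texpected\n")
        for ref, go in sorted(emit):
            fh.write(f"{ref}\t{go}\temit\n")
        for ref, go in sorted(suppress):
            fh.write(f"{ref}\t{go}\tsuppress\n")
    return GafFixture(path, manifest_path, clean_plan, planted, emit, suppress)


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    ontology: OntologyFixture
    taxonomy: TaxonomyFixture
    gaf: GafFixture


def make_bundle(spec: FixtureSpec, outdir) -> FixtureBundle:
    """Generate a complete input bundle (ontology + taxonomy + GAF) in
    ``outdir``."""
    outdir = Path(outdir)
    taxo = make_taxonomy(spec, outdir)
    onto = make_ontology(spec, outdir, taxonomy=taxo)
    gaf = make_gaf(spec, onto, taxo, outdir)
    return FixtureBundle(spec, onto, taxo, gaf)


def read_manifest(path):
    """Read a manifest TSV back into ``(emit, suppress)`` pair sets."""
    emit, suppress = set(), set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            ref, go, expected = line.rstrip("\n").split("\t")
            (emit if expected == "emit" else suppress).add((int(ref), go))
    return emit, suppress
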