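"""Automatic taxon-constraint derivation from annotation frequencies.

The derivation works per reference node:

1. cleaned annotations are grouped under each organism's closest reference
   ancestor;
2. for every GO term, a *cumulative frequency* is computed — the number of
   annotations to the term or any of its GO descendants (each annotation
   counted once per ancestor term, even through diamonds);
3. a term is marked ``never_in`` a reference node when it is well
   represented in the whole corpus (cumulative frequency >= a threshold,
   default 500) yet completely absent (cumulative frequency 0) inside the
   node's subtree.

A ``never_in`` constraint applies to the reference node and all descendant
taxa, and prohibits the term together with all of its GO descendants.
Storage is compact: one record at the (reference node, GO-topmost term)
pair; :func:`expand_constraints` materialises the full prohibited set for
any taxon, resolving the strict source priority manual > consortium (GOC)
> automatic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ConfigError, IntegrityError
from .ontology import OntologyGraph
from .refnodes import ReferenceNodeSet
from .taxonomy import TaxonomyTree, closest_reference_ancestor

GLOBAL = "GLOBAL"

SOURCES = ("automatic", "goc", "manual")  # ascending priority
RELATIONS = ("never_in", "only_in", "allow")

DEFAULT_MIN_GLOBAL_FREQUENCY = 500


@dataclass
class FrequencyTable:
    """Direct and cumulative GO term counts within a scope.

    ``cumulative[g]`` counts every annotation whose term is ``g`` or any GO
    descendant of ``g``; it is therefore monotone non-increasing walking
    down the DAG and equals the namespace total at each root.
    """

    scope: int | str = GLOBAL
    direct: Counter = field(default_factory=Counter)
    cumulative: Counter = field(default_factory=Counter)

    def as_tsv(self) -> str:
        lines = ["#go_id\tdirect\tcumulative"]
        for go_id in sorted(self.cumulative):
            lines.append(f"{go_id}\t{self.direct.get(go_id, 0)}\t{self.cumulative[go_id]}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class ConstraintRecord:
    """One (taxon, GO term, relation) assertion with provenance.

    ``relation`` is ``never_in``/``only_in`` (``allow`` exists only in the
    manual tier, to cancel a lower-priority prohibition).  Automatic
    records are always ``never_in`` and carry their reference node.
    """

    taxon_id: int
    go_id: str
    relation: str
    source: str
    reference_node: int | None = None

    def __post_init__(self):
        if self.relation not in RELATIONS:
            raise ValueError(f"bad relation {self.relation!r}")
        if self.source not in SOURCES:
            raise ValueError(f"bad source {self.source!r}")
        if self.source == "automatic" and (
            self.relation != "never_in" or self.reference_node is None
        ):
            raise ValueError("automatic records must be never_in with a reference node")
        if self.relation == "allow" and self.source != "manual":
            raise ValueError("allow is a manual-tier directive")


class ConstraintSet:
    """A deduplicated collection of constraint records with provenance."""

    def __init__(self, records=(), provenance: dict | None = None):
        self.records: list[ConstraintRecord] = []
        self._seen: set[tuple] = set()
        self.provenance: dict = dict(provenance or {})
        self.conflicts: list[tuple[ConstraintRecord, ConstraintRecord]] = []
        for rec in records:
            self.add(rec)

    def add(self, rec: ConstraintRecord) -> None:
        key = (rec.taxon_id, rec.go_id, rec.relation, rec.source)
        if key not in self._seen:
            self._seen.add(key)
            self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_source(self, source: str) -> list[ConstraintRecord]:
        return [r for r in self.records if r.source == source]

    def sorted_records(self) -> list[ConstraintRecord]:
        return sorted(
            self.records,
            key=lambda r: (SOURCES.index(r.source), r.taxon_id, r.go_id, r.relation),
        )


# ---------------------------------------------------------------------------
# grouping and frequencies


def group_by_reference(records, t: TaxonomyTree, refs: ReferenceNodeSet):
    """Partition annotations by their organism's closest reference ancestor.

    Returns ``(groups, discarded)`` where ``groups`` maps reference taxid to
    the records binned under it and ``discarded`` holds records whose
    organism lies under no reference node.  The partition is exhaustive.
    """
    refset = refs.taxids()
    groups: dict[int, list] = {r: [] for r in refset}
    discarded: list = []
    cache: dict[int, int | None] = {}
    for rec in records:
        ref = cache.get(rec.taxon_id, -1)
        if ref == -1:
            ref = closest_reference_ancestor(t, rec.taxon_id, refset)
            cache[rec.taxon_id] = ref
        if ref is None:
            discarded.append(rec)
        else:
            groups[ref].append(rec)
    return groups, discarded


def compute_frequencies(
    records, g: OntologyGraph, scope=GLOBAL, count_unit: str = "annotations"
) -> FrequencyTable:
    """Count direct and cumulative GO term usage within a scope.

    ``count_unit="annotations"`` counts annotation lines (the default);
    ``"proteins"`` counts distinct annotated gene products per term
    instead.
    """
    if count_unit not in ("annotations", "proteins"):
        raise ConfigError(f"count_unit must be annotations|proteins, got {count_unit!r}")
    ft = FrequencyTable(scope=scope)
    if count_unit == "annotations":
        for rec in records:
            term = g.resolve(rec.go_id)
            ft.direct[term] += 1
            for anc in g.ancestors_or_self(term):
                ft.cumulative[anc] += 1
    else:
        direct_sets: dict[str, set] = {}
        cum_sets: dict[str, set] = {}
        for rec in records:
            term = g.resolve(rec.go_id)
            direct_sets.setdefault(term, set()).add(rec.object_id)
            for anc in g.ancestors_or_self(term):
                cum_sets.setdefault(anc, set()).add(rec.object_id)
        ft.direct = Counter({k: len(v) for k, v in direct_sets.items()})
        ft.cumulative = Counter({k: len(v) for k, v in cum_sets.items()})
    return ft


# ---------------------------------------------------------------------------
# derivation


def derive_never_in(
    global_ft: FrequencyTable,
    ref_ft: FrequencyTable,
    ref_node: int,
    g: OntologyGraph,
    threshold: int = DEFAULT_MIN_GLOBAL_FREQUENCY,
) -> list[ConstraintRecord]:
    """Derive automatic ``never_in`` records for one reference node.

    A term qualifies when its corpus-wide cumulative frequency is at least
    ``threshold`` while its cumulative frequency inside the reference node
    is zero.  Namespace roots are never emitted (a root prohibition would
    outlaw an entire subontology and roots are not annotation terms).  The
    output keeps only GO-topmost qualifying terms: a qualifying term whose
    qualifying ancestor is already emitted is covered by that ancestor's
    descendant closure.
    """
    if threshold < 1:
        raise ConfigError(f"threshold must be >= 1, got {threshold}")
    candidates = {
        term
        for term, cum in global_ft.cumulative.items()
        if cum >= threshold
        and ref_ft.cumulative.get(term, 0) == 0
        and not g.is_root(term)
        and not g.get(term).obsolete
    }
    topmost = [
        term for term in candidates if not (g.ancestors(term) & candidates)
    ]
    return [
        ConstraintRecord(ref_node, term, "never_in", "automatic", ref_node)
        for term in sorted(topmost)
    ]


def derive_all(
    cleaned_records,
    g: OntologyGraph,
    t: TaxonomyTree,
    refs: ReferenceNodeSet,
    threshold: int = DEFAULT_MIN_GLOBAL_FREQUENCY,
    count_unit: str = "annotations",
):
    """Run grouping, frequency computation and derivation for every
    reference node.

    The frequency scope of a reference node covers every cleaned
    annotation whose organism lies in its subtree — including those binned
    under a nested, deeper reference node — so a term used anywhere inside
    a clade is never prohibited for it.  Returns
    ``(auto_constraints, global_ft, per_ref_fts)``.
    """
    records = list(cleaned_records)
    groups, _ = group_by_reference(records, t, refs)
    global_ft = compute_frequencies(records, g, GLOBAL, count_unit)
    auto = ConstraintSet(provenance={"threshold": threshold, "count_unit": count_unit})
    per_ref: dict[int, FrequencyTable] = {}
    ref_lineages = {r: set(t.lineage(r)) for r in refs.taxids()}
    for ref in sorted(refs.taxids()):
        scope_records = []
        for other, recs in groups.items():
            if ref in ref_lineages[other]:  # other is ref itself or nested below
                scope_records.extend(recs)
        ft = compute_frequencies(scope_records, g, ref, count_unit)
        per_ref[ref] = ft
        for rec in derive_never_in(global_ft, ft, ref, g, threshold):
            auto.add(rec)
    return auto, global_ft, per_ref


# ---------------------------------------------------------------------------
# expansion with priority resolution


def effective_constraints(
    cs: ConstraintSet, g: OntologyGraph, t: TaxonomyTree, taxid: int
) -> dict[str, tuple[bool, ConstraintRecord]]:
    """Per-GO-term verdict for one taxon after priority resolution.

    Returns ``{go_id: (prohibited, winning_record)}``.  Tiers are applied
    in ascending priority (automatic, then GOC, then manual), each
    overwriting the verdicts of the previous one term by term.  Within a
    tier a prohibition beats a permission (relevant only for colliding GOC
    axioms; contradictory manual directives are rejected upstream).

    Verdict rules per record, for query taxon ``x``:

    * ``never_in(g, T)``  — prohibits closure(g) when T is an ancestor-or-
      self of x;
    * ``only_in(g, T)``   — prohibits closure(g) when x is outside
      subtree(T), permits it inside;
    * ``allow(g, T)``     — permits closure(g) when T is an ancestor-or-
      self of x.
    """
    taxid = t.resolve(taxid)
    lineage = set(t.lineage(taxid))
    verdict: dict[str, tuple[bool, ConstraintRecord]] = {}
    for source in SOURCES:
        prohibit: dict[str, ConstraintRecord] = {}
        permit: dict[str, ConstraintRecord] = {}
        for rec in cs.by_source(source):
            try:
                rec_taxon = t.resolve(rec.taxon_id)
            except KeyError:
                raise IntegrityError(
                    f"constraint references unknown taxon {rec.taxon_id}"
                ) from None
            if rec.go_id not in g:
                continue
            if rec.relation == "never_in":
                if rec_taxon in lineage:
                    for go in g.descendants_or_self(rec.go_id):
                        prohibit.setdefault(go, rec)
            elif rec.relation == "only_in":
                target = permit if rec_taxon in lineage else prohibit
                for go in g.descendants_or_self(rec.go_id):
                    target.setdefault(go, rec)
            else:  # allow
                if rec_taxon in lineage:
                    for go in g.descendants_or_self(rec.go_id):
                        permit.setdefault(go, rec)
        for go, rec in permit.items():
            if go not in prohibit:
                verdict[go] = (False, rec)
        for go, rec in prohibit.items():
            verdict[go] = (True, rec)
    return verdict


def expand_constraints(
    cs: ConstraintSet, g: OntologyGraph, t: TaxonomyTree, taxid: int
) -> set[str]:
    """Full prohibited GO set for ``taxid`` after priority resolution."""
    return {
        go
        for go, (prohibited, _) in effective_constraints(cs, g, t, taxid).items()
        if prohibited
    }


# ---------------------------------------------------------------------------
# TSV round-trip (the web-style tabular export)

_TSV_COLUMNS = (
    "taxon_id",
    "taxon_name",
    "go_id",
    "go_name",
    "namespace",
    "relation",
    "source",
    "reference_node",
)


def write_constraints(
    cs: ConstraintSet,
    path,
    g: OntologyGraph | None = None,
    t: TaxonomyTree | None = None,
    header_meta: dict | None = None,
) -> None:
    """Write the compact constraint table as TSV with ``#`` metadata lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
        for rec in cs.sorted_records():
            taxon_name = go_name = namespace = ""
            if t is not None and rec.taxon_id in t:
                taxon_name = t.name_of(rec.taxon_id)
            if g is not None and rec.go_id in g:
                info = g.get(rec.go_id)
                go_name, namespace = info.name, info.namespace
            ref = "" if rec.reference_node is None else str(rec.reference_node)
            fh.write(
                "\t".join(
                    (
                        str(rec.taxon_id),
                        taxon_name,
                        rec.go_id,
                        go_name,
                        namespace,
                        rec.relation,
                        rec.source,
                        ref,
                    )
                )
                + "\n"
            )


def read_constraints(path) -> ConstraintSet:
    """Read a constraint TSV written by :func:`write_constraints`."""
    cs = ConstraintSet()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise IntegrityError(f"{path}:{lineno}: expected 8 columns")
            cs.add(
                ConstraintRecord(
                    taxon_id=int(fields[0]),
                    go_id=fields[2],
                    relation=fields[5],
                    source=fields[6],
                    reference_node=int(fields[7]) if fields[7] else None,
                )
            )
    return cs
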