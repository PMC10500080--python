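"""Constraint integration: only_in conversion, manual tier, priority merge,
and annotation auditing.

Three constraint sources are combined under a strict priority:

    manual  >  consortium (GOC)  >  automatic

``only_in(g, T)`` axioms are equivalent to ``never_in(g, x)`` for every
taxon x outside subtree(T); :func:`convert_only_in` materialises the
compact lineage-sibling encoding of that rule.  Manual directives use a
one-line-per-rule configuration file and add an ``allow`` verb so a user
can cancel a bad consortium or automatic prohibition for a clade.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .constraints import ConstraintRecord, ConstraintSet, effective_constraints
from .errors import ConfigError, IntegrityError
from .ontology import GO_ID_RE, GocAxiom, OntologyGraph
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

DIRECTIVES = ("never_in", "only_in", "allow")


@dataclass(frozen=True)
class ManualConstraint:
    """One user-supplied directive: taxon, GO term, verb."""

    taxon_id: int
    go_id: str
    directive: str


def read_manual_constraints(path, t: TaxonomyTree) -> list[ManualConstraint]:
    """Parse the manual-constraint configuration file.

    One directive per non-comment line::

        <taxid or scientific name>  <GO id>  <never_in|only_in|allow>

    The taxon may be given by scientific name (possibly multi-word); it is
    resolved through the taxonomy's name index.
    """
    out: list[ManualConstraint] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.replace("\t", " ").split()
            if len(tokens) < 3:
                raise ConfigError(f"{path}:{lineno}: expected <taxon> <GO id> <verb>")
            directive = tokens[-1].lower()
            go_id = tokens[-2]
            taxon_spec = " ".join(tokens[:-2])
            if directive not in DIRECTIVES:
                raise ConfigError(
                    f"{path}:{lineno}: verb must be one of {DIRECTIVES}, got {directive!r}"
                )
            if not GO_ID_RE.match(go_id):
                raise ConfigError(f"{path}:{lineno}: bad GO id {go_id!r}")
            if taxon_spec.isdigit():
                taxid = int(taxon_spec)
                if taxid not in t:
                    raise ConfigError(f"{path}:{lineno}: unknown taxid {taxid}")
                taxid = t.resolve(taxid)
            else:
                try:
                    taxid = t.find_by_name(taxon_spec)
                except KeyError:
                    raise ConfigError(
                        f"{path}:{lineno}: unresolvable taxon name {taxon_spec!r}"
                    ) from None
            out.append(ManualConstraint(taxid, go_id, directive))
    return out


def convert_only_in(axioms, t: TaxonomyTree) -> list[ConstraintRecord]:
    """Rewrite ``only_in`` axioms as compact ``never_in`` records.

    For ``only_in(g, T)`` the term is prohibited exactly outside
    subtree(T).  The compact encoding attaches one ``never_in`` to every
    sibling branch off the path root -> T, so that expansion yields:
    g prohibited for x  <=>  x not in subtree(T).  ``only_in`` on the
    taxonomy root therefore converts to nothing.

    Accepts :class:`~gotaxon.ontology.GocAxiom` and
    :class:`ManualConstraint` items; non-``only_in`` items are ignored.
    """
    out: list[ConstraintRecord] = []
    for ax in axioms:
        if isinstance(ax, GocAxiom):
            relation, source = ax.relation, "goc"
        else:
            relation, source = ax.directive, "manual"
        if relation != "only_in":
            continue
        try:
            target = t.resolve(ax.taxon_id)
        except KeyError:
            raise IntegrityError(
                f"only_in axiom on {ax.go_id} references unknown taxon {ax.taxon_id}"
            ) from None
        path = set(t.lineage(target))  # target..root
        for node in t.lineage(target)[1:]:  # strict ancestors only
            for child in t.children[node]:
                if child not in path:
                    out.append(ConstraintRecord(child, ax.go_id, "never_in", source))
    return out


def _goc_axioms_to_records(axioms) -> list[ConstraintRecord]:
    return [ConstraintRecord(a.taxon_id, a.go_id, a.relation, "goc") for a in axioms]


def _manual_to_records(manual) -> list[ConstraintRecord]:
    return [ConstraintRecord(m.taxon_id, m.go_id, m.directive, "manual") for m in manual]


def _scopes_overlap(t: TaxonomyTree, a: int, b: int) -> bool:
    try:
        a, b = t.resolve(a), t.resolve(b)
    except KeyError:
        return False
    return a in t.lineage(b) or b in t.lineage(a)


def merge_constraints(
    auto: ConstraintSet,
    goc,
    manual,
    t: TaxonomyTree,
    g: OntologyGraph,
) -> ConstraintSet:
    """Combine the three tiers into one set with conflict reporting.

    ``goc`` may be a list of :class:`~gotaxon.ontology.GocAxiom` or an
    already-built :class:`ConstraintSet`; ``manual`` is a list of
    :class:`ManualConstraint`.  Records are stored verbatim per tier
    (``only_in`` stays native); priority is resolved at expansion time.
    Contradictory manual directives on the identical (taxon, GO) pair are
    a hard error.  The returned set's ``conflicts`` attribute lists every
    ``(winner, overridden)`` pair where a higher tier overturns a lower
    one somewhere in taxon x GO space.
    """
    goc_records = (
        list(goc.records) if isinstance(goc, ConstraintSet) else _goc_axioms_to_records(goc)
    )
    manual_records = _manual_to_records(manual)

    by_pair: dict[tuple[int, str], str] = {}
    for rec in manual_records:
        key = (rec.taxon_id, rec.go_id)
        if key in by_pair and by_pair[key] != rec.relation:
            raise ConfigError(
                f"contradictory manual directives on taxon {rec.taxon_id}, "
                f"{rec.go_id}: {by_pair[key]} vs {rec.relation}"
            )
        by_pair[key] = rec.relation

    merged = ConstraintSet(provenance=dict(auto.provenance))
    for rec in auto:
        merged.add(rec)
    for rec in goc_records:
        merged.add(rec)
    for rec in manual_records:
        merged.add(rec)

    merged.conflicts = _find_conflicts(merged, t, g)
    if merged.conflicts:
        logger.info("%d constraint records overridden by a higher tier",
                    len(merged.conflicts))
    return merged


def _find_conflicts(cs: ConstraintSet, t: TaxonomyTree, g: OntologyGraph):
    """Pairs (winner, overridden) where a higher tier flips a lower tier's
    verdict for some (taxon, GO term).

    For ``never_in``/``allow`` the taxon scope is the record's subtree;
    ``only_in`` prohibits outside its subtree and permits inside, so it
    can clash with either verdict of a lower tier.
    """
    from .constraints import SOURCES

    conflicts = []
    by_tier = {s: cs.by_source(s) for s in SOURCES}
    for hi_idx in range(1, len(SOURCES)):
        for lo_idx in range(hi_idx):
            for hi in by_tier[SOURCES[hi_idx]]:
                for lo in by_tier[SOURCES[lo_idx]]:
                    if hi.go_id not in g or lo.go_id not in g:
                        continue
                    if not (
                        g.descendants_or_self(hi.go_id)
                        & g.descendants_or_self(lo.go_id)
                    ):
                        continue
                    if _taxon_verdicts_clash(hi, lo, t):
                        conflicts.append((hi, lo))
    return conflicts


def _taxon_verdicts_clash(hi: ConstraintRecord, lo: ConstraintRecord, t) -> bool:
    hi_rel, lo_rel = hi.relation, lo.relation
    overlap = _scopes_overlap(t, hi.taxon_id, lo.taxon_id)
    if hi_rel == "never_in" and lo_rel in ("allow", "only_in"):
        # hi prohibits subtree(hi); lo permits inside subtree(lo)
        return overlap
    if hi_rel in ("allow", "only_in") and lo_rel == "never_in":
        # hi permits inside subtree(hi); lo prohibits subtree(lo)
        return overlap
    if hi_rel == "only_in" and lo_rel == "only_in":
        return hi.taxon_id != lo.taxon_id
    return False


# ---------------------------------------------------------------------------
# auditing


@dataclass(frozen=True)
class Violation:
    """An annotation hitting a prohibited term for its organism."""

    record: object  # AnnotationRecord
    constraint: ConstraintRecord


def audit_annotations(records, cs: ConstraintSet, g: OntologyGraph, t: TaxonomyTree):
    """Flag annotations whose GO term is prohibited for their organism.

    Operates on *parsed* (not cleaned) records, so curators see the full
    database — only negated (``NOT``-qualified) lines are skipped, since
    they already assert absence of function.  Annotations to unknown
    taxa/terms cannot be judged and are skipped with a logged count.
    """
    violations: list[Violation] = []
    cache: dict[int, dict] = {}
    skipped = 0
    for rec in records:
        if "NOT" in rec.qualifiers:
            continue
        if rec.taxon_id not in t or rec.go_id not in g:
            skipped += 1
            continue
        taxid = t.resolve(rec.taxon_id)
        verdict = cache.get(taxid)
        if verdict is None:
            verdict = effective_constraints(cs, g, t, taxid)
            cache[taxid] = verdict
        entry = verdict.get(g.resolve(rec.go_id))
        if entry is not None and entry[0]:
            violations.append(Violation(rec, entry[1]))
    if skipped:
        logger.warning("audit skipped %d records with unknown taxon/term", skipped)
    return violations


def violations_tsv(violations) -> str:
    lines = [
        "#object_id\ttaxon_id\tgo_id\tevidence_code\t"
        "violated_constraint_go\trelation\tsource"
    ]
    for v in violations:
        r, c = v.record, v.constraint
        lines.append(
            f"{r.object_id}\t{r.taxon_id}\t{r.go_id}\t{r.evidence_code}\t"
            f"{c.go_id}\t{c.relation}\t{c.source}"
        )
    return "\n".join(lines) + "\n"
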