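"""Gene Ontology graph: loading, ancestor/descendant closure, taxon axioms.

The ontology is held as a lightweight DAG over GO terms.  Edges point from a
term to its parents and carry a relation label.  Only *propagating*
relations (by default ``is_a`` and ``part_of``, the standard
annotation-propagation pair) take part in closure queries; other relations
(e.g. the ``regulates`` family) are retained on the graph but never
traversed.

Consortium taxon-constraint axioms (``never_in_taxon`` / ``only_in_taxon``)
embedded in the ontology file are extracted into :class:`GocAxiom` records.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import obonet

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")
NCBITAXON_RE = re.compile(r"NCBITaxon[:_](\d+)")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: relations over which annotations propagate up the DAG
DEFAULT_PROPAGATING = ("is_a", "part_of")

_AXIOM_RELATIONS = {"never_in_taxon": "never_in", "only_in_taxon": "only_in"}


@dataclass(frozen=True)
class TermInfo:
    """Metadata for one GO term."""

    id: str
    name: str
    namespace: str
    obsolete: bool = False
    alt_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class GocAxiom:
    """A consortium taxon-constraint axiom attached to a GO term."""

    go_id: str
    relation: str  # "never_in" | "only_in"
    taxon_id: int


class OntologyGraph:
    """The GO DAG plus term metadata and embedded taxon-constraint axioms.

    Parameters
    ----------
    terms
        Mapping from primary GO id to :class:`TermInfo`.
    edges
        Iterable of ``(child, parent, relation)`` triples over primary ids.
    axioms
        Taxon-constraint axioms read from the source file.
    propagating
        Relation labels traversed by closure queries.
    """

    def __init__(self, terms, edges, axioms=(), propagating=DEFAULT_PROPAGATING):
        self.terms: dict[str, TermInfo] = dict(terms)
        self.propagating = tuple(propagating)
        self.axioms: list[GocAxiom] = list(axioms)
        self._alt: dict[str, str] = {}
        for info in self.terms.values():
            for alt in info.alt_ids:
                self._alt[alt] = info.id
        self._parents: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        self._children: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
        for child, parent, rel in edges:
            self._parents[child].append((parent, rel))
            self._children[parent].append((child, rel))
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}
        self.roots: dict[str, str] = self._find_roots()
        self._check_acyclic()
        self._check_rooted()

    # -- structure checks ---------------------------------------------------

    def _find_roots(self):
        roots: dict[str, str] = {}
        for tid, info in self.terms.items():
            if info.obsolete:
                continue
            if not [p for p, rel in self._parents[tid] if rel in self.propagating]:
                if info.namespace in roots:
                    raise IntegrityError(
                        f"namespace {info.namespace} has multiple roots: "
                        f"{roots[info.namespace]}, {tid}"
                    )
                roots[info.namespace] = tid
        return roots

    def _check_acyclic(self):
        # Kahn's algorithm over propagating edges
        indeg = {t: 0 for t in self.terms}
        for child in self.terms:
            for parent, rel in self._parents[child]:
                if rel in self.propagating:
                    indeg[parent] += 1
        queue = [t for t, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for parent, rel in self._parents[node]:
                if rel in self.propagating:
                    indeg[parent] -= 1
                    if indeg[parent] == 0:
                        queue.append(parent)
        if seen != len(self.terms):
            raise IntegrityError("cycle detected in the propagating-relation closure")

    def _check_rooted(self):
        for tid, info in self.terms.items():
            if info.obsolete or tid in self.roots.values():
                continue
            root = self.roots.get(info.namespace)
            if root is None or root not in self.ancestors(tid):
                raise IntegrityError(
                    f"term {tid} does not reach its namespace root via "
                    f"propagating relations"
                )

    # -- lookups ------------------------------------------------------------

    def __contains__(self, go_id: str) -> bool:
        return go_id in self.terms or go_id in self._alt

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, go_id: str) -> str:
        """Return the primary id for ``go_id`` (follows alt_id merges)."""
        if go_id in self.terms:
            return go_id
        if go_id in self._alt:
            return self._alt[go_id]
        raise KeyError(go_id)

    def get(self, go_id: str) -> TermInfo:
        return self.terms[self.resolve(go_id)]

    def is_root(self, go_id: str) -> bool:
        try:
            return self.resolve(go_id) in self.roots.values()
        except KeyError:
            return False

    def namespace_root(self, go_id: str) -> str:
        return self.roots[self.get(go_id).namespace]

    def parents(self, go_id: str) -> set[str]:
        tid = self.resolve(go_id)
        return {p for p, rel in self._parents[tid] if rel in self.propagating}

    def children(self, go_id: str) -> set[str]:
        tid = self.resolve(go_id)
        return {c for c, rel in self._children[tid] if rel in self.propagating}

    # -- closures -----------------------------------------------------------

    def ancestors(self, go_id: str) -> frozenset[str]:
        """Transitive parents under propagating relations, excluding self."""
        tid = self.resolve(go_id)
        cached = self._anc_cache.get(tid)
        if cached is None:
            out: set[str] = set()
            stack = list(self.parents(tid))
            while stack:
                node = stack.pop()
                if node not in out:
                    out.add(node)
                    stack.extend(self.parents(node))
            cached = frozenset(out)
            self._anc_cache[tid] = cached
        return cached

    def ancestors_or_self(self, go_id: str) -> frozenset[str]:
        tid = self.resolve(go_id)
        return self.ancestors(tid) | {tid}

    def descendants(self, go_id: str) -> set[str]:
        """Transitive closure of children under propagating relations.

        Excludes ``go_id`` itself; each descendant appears exactly once
        even in diamond-shaped regions of the DAG.
        """
        tid = self.resolve(go_id)
        cached = self._desc_cache.get(tid)
        if cached is None:
            out: set[str] = set()
            stack = list(self.children(tid))
            while stack:
                node = stack.pop()
                if node not in out:
                    out.add(node)
                    stack.extend(self.children(node))
            cached = frozenset(out)
            self._desc_cache[tid] = cached
        return set(cached)

    def descendants_or_self(self, go_id: str) -> frozenset[str]:
        tid = self.resolve(go_id)
        return frozenset(self.descendants(tid)) | {tid}


def descendants(g: OntologyGraph, go_id: str) -> set[str]:
    """Module-level alias for :meth:`OntologyGraph.descendants`."""
    return g.descendants(go_id)


def extract_goc_axioms(g: OntologyGraph) -> list[GocAxiom]:
    """Return the taxon-constraint axioms embedded in the ontology.

    Order-stable by ``(go_id, relation, taxon_id)``.
    """
    return sorted(g.axioms, key=lambda a: (a.go_id, a.relation, a.taxon_id))


# ---------------------------------------------------------------------------
# loading


def load_ontology(path, fmt: str = "obo", propagating=DEFAULT_PROPAGATING) -> OntologyGraph:
    """Load a GO graph from an OBO flat file or an RDF/XML OWL file.

    Taxon-constraint axioms are recognised on relationship lines (OBO) or
    object/annotation properties (OWL) whose label contains
    ``never_in_taxon`` / ``only_in_taxon``; taxon ids are parsed from
    ``NCBITaxon:<digits>`` tokens.
    """
    if fmt == "obo":
        return _load_obo(path, propagating)
    if fmt == "owl":
        return _load_owl(path, propagating)
    raise ValueError(f"unknown ontology format {fmt!r}")


def _load_obo(path, propagating) -> OntologyGraph:
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except ValueError as exc:
        raise FormatError(f"cannot parse OBO file {path}: {exc}") from exc
    default_ns = (raw.graph.get("default-namespace") or [""])[0]

    terms: dict[str, TermInfo] = {}
    edges: list[tuple[str, str, str]] = []
    axioms: list[GocAxiom] = []
    skipped_axioms = 0

    for node, data in raw.nodes(data=True):
        if not GO_ID_RE.match(node):
            continue  # edge targets that are not GO terms (e.g. NCBITaxon ids)
        obsolete = str(data.get("is_obsolete", "")).lower() == "true"
        info = TermInfo(
            id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", default_ns),
            obsolete=obsolete,
            alt_ids=tuple(data.get("alt_id", ())),
        )
        terms[node] = info
        if obsolete:
            continue  # obsolete terms participate in no edges
        for parent in data.get("is_a", ()):
            edges.append((node, parent, "is_a"))
        for entry in data.get("relationship", ()):
            parts = entry.split()
            if len(parts) < 2:
                continue
            rel, target = parts[0], parts[1]
            if rel in _AXIOM_RELATIONS:
                m = NCBITAXON_RE.search(target)
                if m:
                    axioms.append(GocAxiom(node, _AXIOM_RELATIONS[rel], int(m.group(1))))
                else:
                    skipped_axioms += 1
            elif GO_ID_RE.match(target):
                edges.append((node, target, rel))

    # drop edges whose endpoints are unknown or obsolete
    clean_edges = [
        (c, p, r)
        for c, p, r in edges
        if p in terms and not terms[p].obsolete and not terms[c].obsolete
    ]
    kept_axioms = []
    for ax in axioms:
        if ax.go_id in terms and not terms[ax.go_id].obsolete:
            kept_axioms.append(ax)
        else:
            skipped_axioms += 1
    if skipped_axioms:
        logger.warning("skipped %d unusable taxon-constraint axioms", skipped_axioms)
    if not terms:
        raise FormatError(f"no [Term] stanzas with GO ids found in {path}")

    g = OntologyGraph(terms, clean_edges, kept_axioms, propagating)
    g.skipped_axioms = skipped_axioms
    return g


# OWL (RDF/XML) property IRIs used by the GO release
_OWL_PART_OF = "http://purl.obolibrary.org/obo/BFO_0000050"
_OWL_NEVER_IN = "http://purl.obolibrary.org/obo/RO_0002161"
_OWL_ONLY_IN = "http://purl.obolibrary.org/obo/RO_0002160"


def _load_owl(path, propagating) -> OntologyGraph:
    import rdflib
    from rdflib.namespace import OWL, RDF, RDFS

    graph = rdflib.Graph()
    try:
        graph.parse(str(path))
    except Exception as exc:  # rdflib raises a zoo of parser errors
        raise FormatError(f"cannot parse OWL file {path}: {exc}") from exc

    obo = "http://purl.obolibrary.org/obo/"
    oio = rdflib.Namespace("http://www.geneontology.org/formats/oboInOwl#")

    def to_go(uri) -> str | None:
        s = str(uri)
        if s.startswith(obo + "GO_"):
            return "GO:" + s[len(obo + "GO_"):]
        return None

    terms: dict[str, TermInfo] = {}
    edges: list[tuple[str, str, str]] = []
    axioms: list[GocAxiom] = []

    for cls in graph.subjects(RDF.type, OWL.Class):
        go_id = to_go(cls)
        if go_id is None:
            continue
        name = str(graph.value(cls, RDFS.label) or "")
        ns = str(graph.value(cls, oio.hasOBONamespace) or "")
        obsolete = bool(graph.value(cls, OWL.deprecated))
        alt_ids = tuple(str(v) for v in graph.objects(cls, oio.hasAlternativeId))
        terms[go_id] = TermInfo(go_id, name, ns, obsolete, alt_ids)
        if obsolete:
            continue
        for sup in graph.objects(cls, RDFS.subClassOf):
            parent = to_go(sup)
            if parent is not None:
                edges.append((go_id, parent, "is_a"))
                continue
            # anonymous restriction: part_of / taxon constraints
            prop = graph.value(sup, OWL.onProperty)
            filler = graph.value(sup, OWL.someValuesFrom) or graph.value(
                sup, OWL.allValuesFrom
            )
            if prop is None or filler is None:
                continue
            prop_s, filler_s = str(prop), str(filler)
            if prop_s == _OWL_PART_OF and to_go(filler):
                edges.append((go_id, to_go(filler), "part_of"))
            elif prop_s in (_OWL_NEVER_IN, _OWL_ONLY_IN):
                m = NCBITAXON_RE.search(filler_s)
                if m:
                    rel = "never_in" if prop_s == _OWL_NEVER_IN else "only_in"
                    axioms.append(GocAxiom(go_id, rel, int(m.group(1))))

    if not terms:
        raise FormatError(f"no GO classes found in OWL file {path}")
    clean_edges = [
        (c, p, r)
        for c, p, r in edges
        if p in terms and not terms[p].obsolete and not terms[c].obsolete
    ]
    return OntologyGraph(terms, clean_edges, axioms, propagating)
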