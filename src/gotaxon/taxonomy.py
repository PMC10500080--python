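"""NCBI-style taxonomy: taxdump loading, lineage queries, reference lookup.

The tree follows the NCBI taxdump conventions: the root (taxid 1) is its
own parent, fields in the ``.dmp`` files are separated by ``\\t|\\t`` and
lines end with ``\\t|``.  Merged (retired) taxids are transparently
redirected at every entry point; deleted ids are simply unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import IntegrityError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    scientific_name: str = ""


class TaxonomyTree:
    """Rooted taxon tree with merged-id redirects and name lookup."""

    def __init__(self, nodes: dict[int, TaxonNode], merged: dict[int, int] | None = None):
        self.nodes = dict(nodes)
        self.merged = dict(merged or {})
        for old in self.merged:
            if old in self.nodes:
                raise IntegrityError(f"merged id {old} also present as a node")
        orphans = [
            n.taxid
            for n in self.nodes.values()
            if n.parent not in self.nodes and n.parent != n.taxid
        ]
        if orphans:
            raise IntegrityError(f"orphan nodes (parent absent): {sorted(orphans)}")
        roots = [n.taxid for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise IntegrityError(f"expected exactly one root, found {sorted(roots)}")
        self.root = roots[0]
        self.children: dict[int, list[int]] = {t: [] for t in self.nodes}
        for n in self.nodes.values():
            if n.taxid != n.parent:
                self.children[n.parent].append(n.taxid)
        for kids in self.children.values():
            kids.sort()
        # cycle check: every parent chain must reach the root
        for taxid in self.nodes:
            self.lineage(taxid)
        self._names: dict[str, int] = {}
        for n in self.nodes.values():
            if n.scientific_name:
                self._names.setdefault(n.scientific_name.lower(), n.taxid)

    # -- lookups ------------------------------------------------------------

    def resolve(self, taxid: int) -> int:
        """Follow merged-id redirects; raise ``KeyError`` for unknown ids."""
        taxid = self.merged.get(taxid, taxid)
        if taxid not in self.nodes:
            raise KeyError(taxid)
        return taxid

    def __contains__(self, taxid: int) -> bool:
        return self.merged.get(taxid, taxid) in self.nodes

    def get(self, taxid: int) -> TaxonNode:
        return self.nodes[self.resolve(taxid)]

    def name_of(self, taxid: int) -> str:
        return self.get(taxid).scientific_name

    def find_by_name(self, name: str) -> int:
        """Resolve a scientific name (case-insensitive) to a taxid."""
        taxid = self._names.get(name.strip().lower())
        if taxid is None:
            raise KeyError(name)
        return taxid

    def suggest_names(self, name: str, limit: int = 5) -> list[str]:
        """Names containing the query substring — used for error messages."""
        q = name.strip().lower()
        hits = [n.scientific_name for n in self.nodes.values()
                if q and q in n.scientific_name.lower()]
        return sorted(hits)[:limit]

    # -- traversal ----------------------------------------------------------

    def lineage(self, taxid: int) -> list[int]:
        """Parent chain from ``taxid`` (inclusive) up to the root."""
        node = self.resolve(taxid)
        chain = [node]
        seen = {node}
        while node != self.root:
            node = self.nodes[node].parent
            if node in seen:
                raise IntegrityError(f"cycle in parent chain at taxid {node}")
            seen.add(node)
            chain.append(node)
        return chain

    def subtree(self, taxid: int) -> set[int]:
        """All taxa at or below ``taxid``."""
        start = self.resolve(taxid)
        out = {start}
        stack = [start]
        while stack:
            for child in self.children[stack.pop()]:
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out


def is_in_subtree(t: TaxonomyTree, query: int, ancestor: int) -> bool:
    """True iff ``ancestor`` lies on ``query``'s parent chain (or equals it)."""
    return t.resolve(ancestor) in t.lineage(query)


def closest_reference_ancestor(t: TaxonomyTree, taxid: int, refset) -> int | None:
    """First member of ``refset`` met walking from ``taxid`` toward the root.

    ``taxid`` itself is eligible.  Returns ``None`` when the walk reaches
    the root without a hit.
    """
    resolved_refs = set()
    for r in refset:
        try:
            resolved_refs.add(t.resolve(r))
        except KeyError:
            continue
    for node in t.lineage(taxid):
        if node in resolved_refs:
            return node
    return None


# ---------------------------------------------------------------------------
# taxdump parsing


def _dmp_rows(path):
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\t|")
            if not line.strip():
                continue
            yield [f.strip() for f in line.split("\t|\t")]


def load_taxonomy(nodes_path, names_path, merged_path=None) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from NCBI taxdump flat files.

    ``names.dmp`` rows of class ``scientific name`` provide node names; a
    node with no such row keeps an empty name (with a warning).
    """
    raw_nodes: dict[int, tuple[int, str]] = {}
    for row in _dmp_rows(nodes_path):
        taxid, parent, rank = int(row[0]), int(row[1]), row[2] if len(row) > 2 else ""
        raw_nodes[taxid] = (parent, rank)

    names: dict[int, str] = {}
    for row in _dmp_rows(names_path):
        if len(row) >= 4 and row[3] == "scientific name":
            names.setdefault(int(row[0]), row[1])

    missing = [t for t in raw_nodes if t not in names]
    if missing:
        logger.warning(
            "%d taxa have no scientific name (e.g. %s)", len(missing), missing[:3]
        )

    merged: dict[int, int] = {}
    if merged_path is not None:
        for row in _dmp_rows(merged_path):
            merged[int(row[0])] = int(row[1])

    nodes = {
        taxid: TaxonNode(taxid, parent, rank, names.get(taxid, ""))
        for taxid, (parent, rank) in raw_nodes.items()
    }
    return TaxonomyTree(nodes, merged)
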