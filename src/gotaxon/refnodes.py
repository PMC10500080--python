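"""Reference taxonomic nodes: automatic selection and list loading.

Constraints are not derived per species — annotation coverage is far too
uneven for that — but per *reference node*: a taxonomy node that pools the
annotations of every organism beneath it.  Nodes are selected on the
quantity (cumulative annotation count) and diversity (distinct annotated
organisms) of the evidence in their subtree, and labelled:

* ``reliable``   — richly annotated branches (model-organism clades),
* ``unreliable`` — sparsely annotated branches, for which only a small but
  still usable constraint set can be derived.

Both labels generate constraints with identical rules; the label is pure
provenance.  Users may bypass selection entirely by supplying a curated
node list via :func:`load_reference_nodes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ConfigError, IntegrityError
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

LABELS = ("reliable", "unreliable")


@dataclass
class SelectionParams:
    """Thresholds for automatic reference-node selection.

    A node qualifies when its subtree holds at least
    ``min_annotations_unreliable`` cleaned annotations from at least
    ``min_species`` distinct organisms; it is labelled ``reliable`` when
    the annotation count also reaches ``min_annotations_reliable``.
    """

    min_annotations_unreliable: int = 1_000
    min_annotations_reliable: int = 50_000
    min_species: int = 5

    def __post_init__(self):
        if self.min_annotations_reliable < self.min_annotations_unreliable:
            raise ConfigError("reliable threshold must be >= unreliable threshold")


@dataclass
class RefNodeInfo:
    label: str
    n_annotations: int = 0
    n_species: int = 0


@dataclass
class ReferenceNodeSet:
    nodes: dict[int, RefNodeInfo] = field(default_factory=dict)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def taxids(self) -> set[int]:
        return set(self.nodes)

    def as_tsv(self, t: TaxonomyTree | None = None) -> str:
        lines = ["#taxid\tlabel\tn_annotations\tn_species\tname"]
        for taxid in sorted(self.nodes):
            info = self.nodes[taxid]
            name = t.name_of(taxid) if t is not None and taxid in t else ""
            lines.append(
                f"{taxid}\t{info.label}\t{info.n_annotations}\t{info.n_species}\t{name}"
            )
        return "\n".join(lines) + "\n"


def _below_species(t: TaxonomyTree, taxid: int) -> bool:
    """True when a strict ancestor of ``taxid`` has rank ``species``."""
    return any(t.nodes[a].rank == "species" for a in t.lineage(taxid)[1:])


def select_reference_nodes(
    records, t: TaxonomyTree, params: SelectionParams | None = None
) -> ReferenceNodeSet:
    """Pick reference nodes from cleaned annotations.

    Counts are cumulative over each node's subtree (every annotation is
    credited to the whole lineage of its organism).  Candidates below a
    species-ranked node (strains, subspecies) are excluded.  Nested
    qualifying nodes are all retained: organisms later resolve to the
    deepest one via closest-reference-ancestor lookup.
    """
    params = params or SelectionParams()
    ann_counts: dict[int, int] = {}
    species: dict[int, set[int]] = {}
    n = 0
    for rec in records:
        n += 1
        for node in t.lineage(rec.taxon_id):
            ann_counts[node] = ann_counts.get(node, 0) + 1
            species.setdefault(node, set()).add(rec.taxon_id)
    if n == 0:
        logger.warning("empty annotation stream: no reference nodes selected")
        return ReferenceNodeSet()

    out = ReferenceNodeSet()
    for taxid, count in ann_counts.items():
        if count < params.min_annotations_unreliable:
            continue
        if len(species[taxid]) < params.min_species:
            continue
        if _below_species(t, taxid):
            continue
        label = (
            "reliable" if count >= params.min_annotations_reliable else "unreliable"
        )
        out.nodes[taxid] = RefNodeInfo(label, count, len(species[taxid]))
    return out


def load_reference_nodes(path, t: TaxonomyTree) -> ReferenceNodeSet:
    """Load a curated reference-node list (TSV: taxid, label)."""
    out = ReferenceNodeSet()
    unknown: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            taxid_s, label = fields[0], fields[1].lower()
            if label not in LABELS:
                raise IntegrityError(
                    f"{path}:{lineno}: label must be one of {LABELS}, got {label!r}"
                )
            taxid = int(taxid_s)
            if taxid not in t:
                unknown.append(taxid)
                continue
            taxid = t.resolve(taxid)
            if taxid in out.nodes:
                raise IntegrityError(f"{path}:{lineno}: duplicate taxid {taxid}")
            out.nodes[taxid] = RefNodeInfo(label)
    if unknown:
        raise IntegrityError(f"{path}: unknown taxids {sorted(unknown)}")
    return out
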