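"""GAF annotation streaming and corpus cleaning.

Reads GAF 2.x files (optionally gzipped) into lightweight
:class:`AnnotationRecord` objects and applies the cleaning rules used
before constraint derivation:

* ``ND`` evidence (no biological data),
* negated annotations (``NOT`` in the qualifier column),
* annotations to the namespace root terms,
* records tagged ``RNAcentral``,
* organisms inside an ``environmental samples`` clade,
* annotations to obsolete/unknown GO terms,
* unknown (deleted) taxa.

Evidence codes are otherwise untouched: electronically inferred (IEA)
annotations are deliberately retained, since for most of the taxonomy they
are the only functional signal available.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

from .errors import FormatError
from .ontology import OntologyGraph
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

#: removal reasons, in the order rules are applied; a record removed for
#: several reasons is counted under the first that matches
REMOVAL_REASONS = (
    "nd_evidence",
    "not_qualifier",
    "root_term",
    "rnacentral",
    "environmental_sample",
    "obsolete_term",
    "unknown_taxon",
)

_ENV_TAG = "environmental sample"


@dataclass(frozen=True)
class AnnotationRecord:
    """One GAF line reduced to the fields the pipeline uses."""

    db: str
    object_id: str
    object_symbol: str
    qualifiers: tuple[str, ...]
    go_id: str
    evidence_code: str
    taxon_id: int
    assigned_by: str = ""


@dataclass
class CleaningReport:
    """Per-reason removal counts; reconciles against the input size."""

    counts: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REMOVAL_REASONS}
    )
    total_in: int = 0
    total_out: int = 0

    def check(self) -> None:
        assert self.total_out == self.total_in - sum(self.counts.values())

    def as_tsv(self) -> str:
        lines = [f"{reason}\t{self.counts[reason]}" for reason in REMOVAL_REASONS]
        lines += [f"total_in\t{self.total_in}", f"total_out\t{self.total_out}"]
        return "\n".join(lines) + "\n"


def _parse_taxon(field_value: str) -> int | None:
    """``taxon:9606|taxon:5693`` -> 9606 (first taxon = the gene product's)."""
    first = field_value.split("|")[0].strip()
    if first.lower().startswith("taxon:"):
        first = first[6:]
    try:
        return int(first)
    except ValueError:
        return None


def read_gaf(path):
    """Yield one :class:`AnnotationRecord` per non-comment GAF line.

    Comment lines start with ``!``; gzip input is transparent.  Malformed
    lines are skipped with a logged count; if more than half of the
    non-comment lines are malformed the file is rejected as not-a-GAF.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    ok = bad = 0
    with opener(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 15:
                bad += 1
                continue
            taxon = _parse_taxon(fields[12])
            go_id = fields[4].strip()
            if taxon is None or not go_id.startswith("GO:"):
                bad += 1
                continue
            ok += 1
            yield AnnotationRecord(
                db=fields[0],
                object_id=fields[1],
                object_symbol=fields[2],
                qualifiers=tuple(q for q in fields[3].split("|") if q),
                go_id=go_id,
                evidence_code=fields[6].strip(),
                taxon_id=taxon,
                assigned_by=fields[14].strip(),
            )
    if bad:
        logger.warning("skipped %d malformed GAF lines in %s", bad, path)
    if bad > ok:
        raise FormatError(
            f"{path}: {bad} of {bad + ok} data lines malformed — not a GAF 2.x file?"
        )


def _removal_reason(
    rec: AnnotationRecord, g: OntologyGraph, t: TaxonomyTree
) -> str | None:
    if rec.evidence_code == "ND":
        return "nd_evidence"
    if "NOT" in rec.qualifiers:
        return "not_qualifier"
    if g.is_root(rec.go_id):
        return "root_term"
    if rec.db.lower() == "rnacentral" or rec.assigned_by.lower() == "rnacentral":
        return "rnacentral"
    if rec.taxon_id in t:
        for anc in t.lineage(rec.taxon_id):
            if _ENV_TAG in t.nodes[anc].scientific_name.lower():
                return "environmental_sample"
    if rec.go_id not in g or g.get(rec.go_id).obsolete:
        return "obsolete_term"
    if rec.taxon_id not in t:
        return "unknown_taxon"
    return None


def iter_clean(records, g: OntologyGraph, t: TaxonomyTree, report: CleaningReport):
    """Streaming core of :func:`clean_annotations`; fills ``report`` as it goes.

    Retained records come out in input order with the GO id resolved to its
    primary form and the taxon id merged-redirected.
    """
    for rec in records:
        report.total_in += 1
        reason = _removal_reason(rec, g, t)
        if reason is not None:
            report.counts[reason] += 1
            continue
        report.total_out += 1
        resolved_go = g.resolve(rec.go_id)
        resolved_taxon = t.resolve(rec.taxon_id)
        if resolved_go != rec.go_id or resolved_taxon != rec.taxon_id:
            rec = AnnotationRecord(
                rec.db,
                rec.object_id,
                rec.object_symbol,
                rec.qualifiers,
                resolved_go,
                rec.evidence_code,
                resolved_taxon,
                rec.assigned_by,
            )
        yield rec


def clean_annotations(records, g: OntologyGraph, t: TaxonomyTree):
    """Apply the cleaning rules; return ``(kept_records, CleaningReport)``."""
    report = CleaningReport()
    kept = list(iter_clean(records, g, t, report))
    report.check()
    return kept, report
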