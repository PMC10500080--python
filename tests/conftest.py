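"""Shared hand-built world: a tiny GO graph and taxonomy used across tests.

The ontology has three namespaces, a diamond (GO:0000013 under both
GO:0000011 and GO:0000012), an obsolete term, an alt_id merge, and two
consortium taxon-constraint axioms: ``never_in_taxon`` on a
photosynthesis-like branch for the bacteria-like clade, and
``only_in_taxon`` restricting a chloroplast-like compartment to the
plant clade.  The taxonomy mimics the NCBI shape: eukaryote and
bacterial clades, a trypanosomatid-like clade without plastids, an
"environmental samples" bucket, and a merged (retired) taxid.
"""

import textwrap

import pytest

from gotaxon.goa import AnnotationRecord
from gotaxon.ontology import load_ontology
from gotaxon.taxonomy import load_taxonomy

OBO_TEXT = textwrap.dedent(
    """\
    format-version: 1.2
    ontology: test-go

    [Term]
    id: GO:0008150
    name: biological_process
    namespace: biological_process

    [Term]
    id: GO:0000010
    name: process A
    namespace: biological_process
    is_a: GO:0008150

    [Term]
    id: GO:0000011
    name: process B
    namespace: biological_process
    is_a: GO:0000010

    [Term]
    id: GO:0000012
    name: process C
    namespace: biological_process
    is_a: GO:0000010

    [Term]
    id: GO:0000013
    name: process D
    namespace: biological_process
    is_a: GO:0000011
    relationship: part_of GO:0000012

    [Term]
    id: GO:0000014
    name: light harvesting
    namespace: biological_process
    is_a: GO:0008150
    relationship: never_in_taxon NCBITaxon:2

    [Term]
    id: GO:0000015
    name: light harvesting regulation
    namespace: biological_process
    is_a: GO:0000014

    [Term]
    id: GO:0003674
    name: molecular_function
    namespace: molecular_function

    [Term]
    id: GO:0000020
    name: binding-like activity
    namespace: molecular_function
    is_a: GO:0003674

    [Term]
    id: GO:0000021
    name: specific binding-like activity
    namespace: molecular_function
    alt_id: GO:0000099
    is_a: GO:0000020

    [Term]
    id: GO:0005575
    name: cellular_component
    namespace: cellular_component

    [Term]
    id: GO:0000030
    name: plastid-like compartment
    namespace: cellular_component
    is_a: GO:0005575

    [Term]
    id: GO:0009534
    name: chloroplast thylakoid-like compartment
    namespace: cellular_component
    is_a: GO:0000030
    relationship: only_in_taxon NCBITaxon:33090

    [Term]
    id: GO:0000050
    name: withdrawn process
    namespace: biological_process
    is_obsolete: true

    [Typedef]
    id: part_of
    name: part of

    [Typedef]
    id: never_in_taxon
    name: never in taxon

    [Typedef]
    id: only_in_taxon
    name: only in taxon
    """
)

#: taxid -> (parent, rank, scientific name)
TAXA = {
    1: (1, "no rank", "root"),
    2759: (1, "superkingdom", "Eukaryota"),
    2: (1, "superkingdom", "Bacteria"),
    4751: (2759, "kingdom", "Fungi"),
    4932: (4751, "species", "Saccharomyces cerevisiae"),
    33208: (2759, "kingdom", "Metazoa"),
    9606: (33208, "species", "Homo sapiens"),
    5690: (2759, "genus", "Trypanosoma"),
    5691: (5690, "species", "Trypanosoma brucei"),
    33090: (2759, "kingdom", "Viridiplantae"),
    3702: (33090, "species", "Arabidopsis thaliana"),
    286: (2, "genus", "Pseudomonas"),
    287: (286, "species", "Pseudomonas fluorescens"),
    48479: (1, "no rank", "environmental samples"),
    155900: (48479, "species", "uncultured organism"),
}

MERGED = {666: 287}


def write_taxdump(outdir, taxa=TAXA, merged=MERGED):
    (outdir / "nodes.dmp").write_text(
        "".join(f"{t}\t|\t{p}\t|\t{r}\t|\n" for t, (p, r, _n) in taxa.items())
    )
    (outdir / "names.dmp").write_text(
        "".join(
            f"{t}\t|\t{n}\t|\t\t|\tscientific name\t|\n" for t, (_p, _r, n) in taxa.items()
        )
    )
    (outdir / "merged.dmp").write_text(
        "".join(f"{old}\t|\t{new}\t|\n" for old, new in merged.items())
    )
    return outdir


class World:
    def __init__(self, tmpdir):
        self.dir = tmpdir
        self.obo_path = tmpdir / "go.obo"
        self.obo_path.write_text(OBO_TEXT)
        write_taxdump(tmpdir)
        self.graph = load_ontology(self.obo_path)
        self.tree = load_taxonomy(
            tmpdir / "nodes.dmp", tmpdir / "names.dmp", tmpdir / "merged.dmp"
        )


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    return World(tmp_path_factory.mktemp("world"))


def ann(taxon, go, evidence="IEA", qualifiers=("involved_in",), db="UniProtKB",
        protein="P00001", assigned_by="TestDB"):
    """Shorthand annotation-record factory."""
    return AnnotationRecord(
        db=db,
        object_id=protein,
        object_symbol=protein.lower(),
        qualifiers=tuple(qualifiers),
        go_id=go,
        evidence_code=evidence,
        taxon_id=taxon,
        assigned_by=assigned_by,
    )
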