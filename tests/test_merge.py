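"""only_in conversion, priority merging, manual syntax and auditing."""

import random

import pytest

from conftest import TAXA, ann
from gotaxon.constraints import ConstraintRecord, ConstraintSet, expand_constraints
from gotaxon.errors import ConfigError, IntegrityError
from gotaxon.fixtures import FixtureSpec, make_taxonomy
from gotaxon.merge import (
    ManualConstraint,
    audit_annotations,
    convert_only_in,
    merge_constraints,
    read_manual_constraints,
)
from gotaxon.ontology import GocAxiom
from gotaxon.taxonomy import is_in_subtree
from oracles import obo_edges, overwrite_verdicts

from conftest import OBO_TEXT

PARENT_OF = {t: p for t, (p, _r, _n) in TAXA.items()}


class TestConvertOnlyIn:
    def test_iff_subtree_membership_exhaustive(self, world):
        # native representation: the iff holds for every taxon in the tree
        axiom = GocAxiom("GO:0009534", "only_in", 33090)
        native = ConstraintSet([ConstraintRecord(33090, "GO:0009534", "only_in", "goc")])
        for taxid in TAXA:
            prohibited = "GO:0009534" in expand_constraints(
                native, world.graph, world.tree, taxid
            )
            assert prohibited == (not is_in_subtree(world.tree, taxid, 33090)), taxid
        # compact sibling encoding: identical everywhere except at the strict
        # ancestors of the target (a never_in there would leak into the
        # allowed clade itself)
        converted = ConstraintSet(convert_only_in([axiom], world.tree))
        ancestors = set(world.tree.lineage(33090)[1:])
        for taxid in TAXA:
            prohibited = "GO:0009534" in expand_constraints(
                converted, world.graph, world.tree, taxid
            )
            expected = not is_in_subtree(world.tree, taxid, 33090) and taxid not in ancestors
            assert prohibited == expected, taxid

    def test_inside_clade_not_prohibited(self, world):
        cs = ConstraintSet(convert_only_in([GocAxiom("GO:0009534", "only_in", 33090)],
                                           world.tree))
        assert "GO:0009534" not in expand_constraints(cs, world.graph, world.tree, 3702)

    def test_only_in_root_converts_to_nothing(self, world):
        assert convert_only_in([GocAxiom("GO:0009534", "only_in", 1)], world.tree) == []

    def test_unknown_taxon_named_in_error(self, world):
        with pytest.raises(IntegrityError, match="GO:0009534"):
            convert_only_in([GocAxiom("GO:0009534", "only_in", 999_999)], world.tree)

    def test_never_in_axioms_pass_through_untouched(self, world):
        assert convert_only_in([GocAxiom("GO:0000014", "never_in", 2)], world.tree) == []

    @pytest.mark.parametrize("seed", [2, 9])
    def test_randomized_trees_iff(self, seed, tmp_path):
        fx = make_taxonomy(FixtureSpec(seed=seed), tmp_path)
        t = fx.tree
        rng = random.Random(seed)
        target = rng.choice(sorted(fx.nodes))
        cs = ConstraintSet(convert_only_in([GocAxiom("GO:0000002", "only_in", target)], t))
        ancestors = set(t.lineage(target)[1:])
        for taxid in fx.nodes:
            got = any(
                rec.taxon_id in t.lineage(taxid)
                for rec in cs
                if rec.relation == "never_in"
            )
            expected = not is_in_subtree(t, taxid, target) and taxid not in ancestors
            assert got == expected


class TestManualSyntax:
    def test_parse_directives(self, world, tmp_path):
        p = tmp_path / "manual.txt"
        p.write_text(
            "# manual constraint list\n"
            "\n"
            "5690\tGO:0009534\tnever_in\n"
            "Trypanosoma brucei GO:0000014 only_in\n"
            "Pseudomonas GO:0000015 allow  # trailing comment\n"
        )
        got = read_manual_constraints(p, world.tree)
        assert got == [
            ManualConstraint(5690, "GO:0009534", "never_in"),
            ManualConstraint(5691, "GO:0000014", "only_in"),
            ManualConstraint(286, "GO:0000015", "allow"),
        ]

    def test_unresolvable_name_reports_line(self, world, tmp_path):
        p = tmp_path / "manual.txt"
        p.write_text("Klingon homeworld GO:0000011 never_in\n")
        with pytest.raises(ConfigError, match=":1"):
            read_manual_constraints(p, world.tree)

    def test_bad_verb_and_bad_go(self, world, tmp_path):
        p = tmp_path / "m1.txt"
        p.write_text("9606 GO:0000011 maybe_in\n")
        with pytest.raises(ConfigError, match="verb"):
            read_manual_constraints(p, world.tree)
        p.write_text("9606 GO:11 never_in\n")
        with pytest.raises(ConfigError, match="GO id"):
            read_manual_constraints(p, world.tree)


class TestMerge:
    def test_union_when_no_overlap(self, world):
        auto = ConstraintSet([ConstraintRecord(2, "GO:0000014", "never_in", "automatic", 2)])
        goc = [GocAxiom("GO:0009534", "never_in", 5690)]
        merged = merge_constraints(auto, goc, [], world.tree, world.graph)
        assert len(merged) == 2
        assert merged.conflicts == []

    def test_goc_only_in_beats_automatic_never_in(self, world):
        # automatic says: never in Fungi; GOC says: only in Eukaryota.
        # Inside Fungi (subset of Eukaryota) the GOC permission wins.
        auto = ConstraintSet([ConstraintRecord(4751, "GO:0000020", "never_in", "automatic", 4751)])
        goc = [GocAxiom("GO:0000020", "only_in", 2759)]
        merged = merge_constraints(auto, goc, [], world.tree, world.graph)
        assert "GO:0000020" not in expand_constraints(merged, world.graph, world.tree, 4932)
        # and still prohibited outside Eukaryota
        assert "GO:0000020" in expand_constraints(merged, world.graph, world.tree, 287)
        assert any(lo.source == "automatic" for _hi, lo in merged.conflicts)

    def test_manual_allow_beats_goc_never_in(self, world):
        goc = [GocAxiom("GO:0000014", "never_in", 2)]
        manual = [ManualConstraint(286, "GO:0000014", "allow")]
        merged = merge_constraints(ConstraintSet(), goc, manual, world.tree, world.graph)
        # the allow punches a subtree-shaped hole inside the GOC prohibition
        assert "GO:0000014" not in expand_constraints(merged, world.graph, world.tree, 287)
        # sibling bacteria outside the hole stay prohibited
        assert "GO:0000014" in expand_constraints(merged, world.graph, world.tree, 2)

    def test_contradictory_manual_pair_is_hard_error(self, world):
        manual = [
            ManualConstraint(9606, "GO:0000011", "never_in"),
            ManualConstraint(9606, "GO:0000011", "allow"),
        ]
        with pytest.raises(ConfigError, match="contradictory"):
            merge_constraints(ConstraintSet(), [], manual, world.tree, world.graph)

    def test_merge_idempotent_and_order_insensitive(self, world):
        auto = ConstraintSet([ConstraintRecord(2759, "GO:0000011", "never_in", "automatic", 2759)])
        goc = [GocAxiom("GO:0000014", "never_in", 2), GocAxiom("GO:0009534", "only_in", 33090)]
        merged = merge_constraints(auto, goc, [], world.tree, world.graph)
        again = merge_constraints(merged, [], [], world.tree, world.graph)
        for taxid in TAXA:
            assert expand_constraints(merged, world.graph, world.tree, taxid) == \
                expand_constraints(again, world.graph, world.tree, taxid)
        reversed_goc = list(reversed(goc))
        merged2 = merge_constraints(auto, reversed_goc, [], world.tree, world.graph)
        for taxid in TAXA:
            assert expand_constraints(merged, world.graph, world.tree, taxid) == \
                expand_constraints(merged2, world.graph, world.tree, taxid)

    @pytest.mark.parametrize("seed", range(6))
    def test_randomized_suites_match_sequential_overwrite_oracle(self, seed, world):
        """Winner per (taxon, term) equals a three-pass overwrite matrix."""
        rng = random.Random(seed)
        g, t = world.graph, world.tree
        live_terms = [x for x, i in g.terms.items() if not i.obsolete]
        taxa = sorted(TAXA)
        records = []
        for source, n in (("automatic", 4), ("goc", 4), ("manual", 4)):
            for _ in range(n):
                relation = rng.choice(
                    ("never_in",) if source == "automatic"
                    else ("never_in", "only_in") if source == "goc"
                    else ("never_in", "only_in", "allow")
                )
                records.append(
                    (source, relation, rng.choice(taxa), rng.choice(live_terms))
                )
        cs = ConstraintSet()
        for source, relation, taxid, go in records:
            ref = taxid if source == "automatic" else None
            cs.add(ConstraintRecord(taxid, go, relation, source, ref))
        edges = obo_edges(OBO_TEXT)
        all_terms = set(g.terms)
        for taxid in taxa:
            expected = overwrite_verdicts(records, PARENT_OF, edges, all_terms, taxid)
            expected = {x for x in expected if not g.get(x).obsolete}
            got = expand_constraints(cs, g, t, taxid)
            assert got == expected, (seed, taxid)

    def test_fixed_point_attribution(self, world):
        goc = [GocAxiom("GO:0000014", "never_in", 2)]
        manual = [ManualConstraint(286, "GO:0000014", "allow")]
        merged = merge_constraints(ConstraintSet(), goc, manual, world.tree, world.graph)
        from gotaxon.constraints import effective_constraints

        for taxid in TAXA:
            for go, (prohibited, rec) in effective_constraints(
                merged, world.graph, world.tree, taxid
            ).items():
                assert rec in merged.records  # every verdict traceable to one record


class TestAudit:
    def goc_constraint_set(self, world):
        goc = [GocAxiom("GO:0000014", "never_in", 2), GocAxiom("GO:0009534", "only_in", 33090)]
        return merge_constraints(ConstraintSet(), goc, [], world.tree, world.graph)

    def test_plastid_annotation_in_trypanosomatid_flagged(self, world):
        """A chloroplast-like compartment annotated in a plastid-free
        parasite clade violates the plant-restricted only_in."""
        cs = self.goc_constraint_set(world)
        records = [
            ann(5691, "GO:0009534", evidence="IBA", protein="Q38AK2-like"),
            ann(3702, "GO:0009534", evidence="IBA", protein="PLANTOK"),  # allowed
        ]
        violations = audit_annotations(records, cs, world.graph, world.tree)
        assert [v.record.object_id for v in violations] == ["Q38AK2-like"]
        assert violations[0].constraint.source == "goc"

    def test_violation_via_go_descendant(self, world):
        cs = self.goc_constraint_set(world)
        # GO:0000015 is a descendant of the prohibited GO:0000014
        violations = audit_annotations(
            [ann(287, "GO:0000015")], cs, world.graph, world.tree
        )
        assert len(violations) == 1
        assert violations[0].constraint.go_id == "GO:0000014"

    def test_not_qualified_records_skipped(self, world):
        cs = self.goc_constraint_set(world)
        rec = ann(5691, "GO:0009534", qualifiers=("NOT", "located_in"))
        assert audit_annotations([rec], cs, world.graph, world.tree) == []

    def test_allowed_annotation_not_flagged(self, world):
        cs = self.goc_constraint_set(world)
        assert audit_annotations(
            [ann(9606, "GO:0000011")], cs, world.graph, world.tree
        ) == []
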