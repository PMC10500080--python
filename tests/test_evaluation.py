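"""Species-centric aggregation, constraint filtering and CAFA-style metrics."""

import math
import random
from collections import Counter

import numpy as np
import pytest

from conftest import ann
from gotaxon.constraints import ConstraintRecord, ConstraintSet, FrequencyTable
from gotaxon.errors import DataError
from gotaxon.evaluation import (
    GroundTruth,
    ICTable,
    SpeciesPrediction,
    aggregate_species,
    apply_constraint_filter,
    close_truth,
    evaluate_benchmark,
    information_content,
    metric_curve,
)
from oracles import naive_curve, naive_fmax


class TestAggregation:
    def test_max_over_proteins(self, world):
        sp = aggregate_species(
            [("p1", "GO:0000021", 0.7), ("p2", "GO:0000021", 0.9)], 9606, world.graph
        )
        assert sp.scores["GO:0000021"] == 0.9

    def test_empty_input_empty_prediction(self, world):
        assert aggregate_species([], 9606, world.graph).scores == {}

    def test_ancestor_inherits_descendant_score(self, world):
        sp = aggregate_species([("p1", "GO:0000021", 0.8)], 9606, world.graph)
        assert sp.scores["GO:0000020"] >= 0.8
        # roots are excluded from the pooled set
        assert "GO:0003674" not in sp.scores

    def test_closure_equals_per_threshold_set_closure(self, world):
        g = world.graph
        triples = [("p1", "GO:0000013", 0.9), ("p1", "GO:0000011", 0.4),
                   ("p2", "GO:0000015", 0.6)]
        sp = aggregate_species(triples, 9606, g, propagate=True)
        for tau in (0.9, 0.6, 0.4, 0.1):
            flat = {}
            for _p, go, s in triples:
                flat[go] = max(flat.get(go, 0), s)
            expected = set()
            for go, s in flat.items():
                if s >= tau:
                    expected |= {a for a in g.ancestors_or_self(go) if not g.is_root(a)}
            got = {go for go, s in sp.scores.items() if s >= tau}
            assert got == expected

    def test_score_out_of_range_rejected(self, world):
        with pytest.raises(DataError):
            aggregate_species([("p1", "GO:0000021", 1.2)], 9606, world.graph)


class TestFiltering:
    def cs(self):
        return ConstraintSet([ConstraintRecord(2, "GO:0000014", "never_in", "automatic", 2)])

    def test_prohibited_term_removed(self, world):
        sp = SpeciesPrediction(287, {"GO:0000014": 0.9, "GO:0000011": 0.5})
        out = apply_constraint_filter(sp, self.cs(), world.graph, world.tree)
        assert set(out.scores) == {"GO:0000011"}

    def test_identity_without_applicable_constraints(self, world):
        sp = SpeciesPrediction(9606, {"GO:0000014": 0.9})
        out = apply_constraint_filter(sp, self.cs(), world.graph, world.tree)
        assert out.scores == sp.scores

    def test_idempotent(self, world):
        sp = SpeciesPrediction(287, {"GO:0000014": 0.9, "GO:0000011": 0.5})
        once = apply_constraint_filter(sp, self.cs(), world.graph, world.tree)
        twice = apply_constraint_filter(once, self.cs(), world.graph, world.tree)
        assert once.scores == twice.scores


class TestInformationContent:
    def test_root_ic_zero(self, world):
        ft = FrequencyTable(cumulative=Counter({"GO:0008150": 100, "GO:0000010": 50}))
        ic = information_content(ft, world.graph)
        assert ic["GO:0008150"] == 0.0

    def test_hand_arithmetic(self, world):
        ft = FrequencyTable(cumulative=Counter({"GO:0008150": 99, "GO:0000010": 24}))
        ic = information_content(ft, world.graph)
        assert ic["GO:0000010"] == pytest.approx(-math.log2(25 / 100)) == pytest.approx(2.0)

    def test_term_as_frequent_as_root_has_zero_ic(self, world):
        ft = FrequencyTable(cumulative=Counter({"GO:0008150": 40, "GO:0000010": 40}))
        ic = information_content(ft, world.graph)
        assert ic["GO:0000010"] == 0.0

    def test_monotone_along_edges(self, world):
        rng = random.Random(0)
        recs = [ann(9606, rng.choice(["GO:0000011", "GO:0000013", "GO:0000015",
                                      "GO:0000021", "GO:0009534"]))
                for _ in range(200)]
        from gotaxon.constraints import compute_frequencies

        ic = information_content(compute_frequencies(recs, world.graph), world.graph)
        for go, info in world.graph.terms.items():
            if info.obsolete:
                continue
            for parent in world.graph.parents(go):
                assert ic[go] >= ic[parent] - 1e-12

    def test_empty_table_rejected(self, world):
        with pytest.raises(DataError):
            information_content(FrequencyTable(), world.graph)


def uniform_ic(terms, value=1.0):
    return ICTable({t: value for t in terms})


class TestMetricCurve:
    def test_perfect_prediction(self):
        ic = uniform_ic(["a", "b"], 2.0)
        sp = SpeciesPrediction(1, {"a": 0.9, "b": 0.8})
        curve = metric_curve(sp, {"a", "b"}, ic)
        assert curve.fmax == 1.0
        assert curve.smin == 0.0

    def test_fully_disjoint_prediction(self):
        ic = uniform_ic(["a", "b", "c"])
        curve = metric_curve(SpeciesPrediction(1, {"a": 0.5}), {"b", "c"}, ic)
        assert curve.fmax == 0.0

    def test_half_right_half_wrong(self):
        # P = {a,b}, T = {a,c} at a single threshold: pr = rc = F = 1/2
        ic = uniform_ic(["a", "b", "c"])
        curve = metric_curve(SpeciesPrediction(1, {"a": 0.5, "b": 0.5}), {"a", "c"}, ic)
        assert curve.fmax == pytest.approx(0.5)

    def test_empty_truth_rejected(self):
        with pytest.raises(DataError):
            metric_curve(SpeciesPrediction(1, {"a": 0.5}), set(), uniform_ic(["a"]))

    def test_uniform_ic_weighted_equals_unweighted(self):
        rng = random.Random(42)
        for _ in range(50):
            universe = [f"t{i}" for i in range(rng.randrange(2, 12))]
            scores = {t: round(rng.random(), 2) for t in universe if rng.random() < 0.7}
            truth = {t for t in universe if rng.random() < 0.5} or {universe[0]}
            curve = metric_curve(SpeciesPrediction(1, scores), truth, uniform_ic(universe))
            assert curve.wfmax == pytest.approx(curve.fmax, abs=1e-12)

    def test_matches_naive_per_threshold_recomputation(self):
        rng = random.Random(7)
        for _ in range(100):
            universe = [f"t{i}" for i in range(rng.randrange(2, 10))]
            ic = {t: rng.uniform(0.1, 5.0) for t in universe}
            scores = {t: round(rng.random(), 2) for t in universe if rng.random() < 0.7}
            truth = {t for t in universe if rng.random() < 0.5} or {universe[0]}
            curve = metric_curve(SpeciesPrediction(1, scores), truth, ICTable(ic))
            expected = naive_curve(scores, truth, ic, curve.thresholds)
            for i in range(len(curve.thresholds)):
                if expected["precision"][i] is None:
                    assert np.isnan(curve.precision[i])
                else:
                    assert curve.precision[i] == pytest.approx(expected["precision"][i])
                assert curve.recall[i] == pytest.approx(expected["recall"][i])
                assert curve.ru[i] == pytest.approx(expected["ru"][i])
                assert curve.mi[i] == pytest.approx(expected["mi"][i])
            assert curve.fmax == pytest.approx(naive_fmax(scores, truth, curve.thresholds))

    def test_monotone_in_threshold(self):
        rng = random.Random(13)
        for _ in range(30):
            universe = [f"t{i}" for i in range(8)]
            ic = ICTable({t: rng.uniform(0.1, 3.0) for t in universe})
            scores = {t: round(rng.random(), 2) for t in universe}
            truth = set(rng.sample(universe, 4))
            c = metric_curve(SpeciesPrediction(1, scores), truth, ic)
            # thresholds descend: recall and mi grow, ru shrinks
            assert (np.diff(c.recall) >= -1e-12).all()
            assert (np.diff(c.mi) >= -1e-12).all()
            assert (np.diff(c.ru) <= 1e-12).all()


class TestBenchmark:
    def ic_for(self, world):
        from gotaxon.constraints import compute_frequencies

        recs = [ann(9606, go) for go in ("GO:0000011", "GO:0000013", "GO:0000021",
                                         "GO:0009534")] * 10
        return information_content(compute_frequencies(recs, world.graph), world.graph)

    def truth_for(self, world, taxid, terms):
        return GroundTruth(taxid, close_truth(terms, world.graph))

    def test_identical_pred_and_truth_all_ones(self, world):
        truth = {9606: self.truth_for(world, 9606, {"GO:0000013", "GO:0000021"})}
        preds = {9606: [("p1", "GO:0000013", 1.0), ("p1", "GO:0000021", 1.0)]}
        table = evaluate_benchmark(preds, truth, {}, world.graph, world.tree,
                                   self.ic_for(world))
        assert (table["fmax"] == 1.0).all()
        assert (table["smin"] == 0.0).all()

    def test_empty_constraint_set_rows_identical(self, world):
        truth = {9606: self.truth_for(world, 9606, {"GO:0000013"})}
        preds = {9606: [("p1", "GO:0000013", 0.8), ("p1", "GO:0000015", 0.4)]}
        table = evaluate_benchmark(
            preds, truth, {"empty": ConstraintSet()}, world.graph, world.tree,
            self.ic_for(world)
        )
        unfilt = table[table["filter"] == "unfilt"].drop(columns="filter")
        filt = table[table["filter"] == "empty"].drop(columns="filter")
        assert unfilt.reset_index(drop=True).equals(filt.reset_index(drop=True))

    def test_filtering_out_of_domain_false_positives_improves_fmax(self, world):
        """False positives inside the prohibited set, truth outside it:
        the filter can only help."""
        cs = ConstraintSet([ConstraintRecord(2, "GO:0000014", "never_in", "automatic", 2)])
        truth = {287: self.truth_for(world, 287, {"GO:0000013"})}
        preds = {287: [("p1", "GO:0000013", 0.8),
                       ("p1", "GO:0000014", 0.9),   # out-of-domain FP
                       ("p1", "GO:0000015", 0.7)]}  # descendant FP
        table = evaluate_benchmark(preds, truth, {"ft": cs}, world.graph, world.tree,
                                   self.ic_for(world))
        bp = table[table["namespace"] == "biological_process"]
        f_unfilt = bp[bp["filter"] == "unfilt"]["fmax"].iloc[0]
        f_filt = bp[bp["filter"] == "ft"]["fmax"].iloc[0]
        assert f_filt > f_unfilt

    def test_species_absent_from_truth_skipped(self, world):
        table = evaluate_benchmark(
            {4932: [("p1", "GO:0000013", 0.5)]}, {}, {}, world.graph, world.tree,
            self.ic_for(world)
        )
        assert table.empty
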