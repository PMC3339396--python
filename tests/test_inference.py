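import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contextabc.dictionaries import Level
from contextabc.inference import (
    Bridge,
    InferredRelation,
    abc_join,
    exclude_direct,
    rank,
    score_bridges,
    score_relations,
)
from contextabc.interactions import ContextVector, Interaction, canonical_key
from contextabc.similarity import SimilarityMeasure


def make_interaction(acc1, lvl1, acc2, lvl2, freq=1):
    key = canonical_key((acc1, Level(lvl1)), (acc2, Level(lvl2)))
    return Interaction(key=key, frequency=freq, support={"1"})


def drug_gene(d, g, freq=1):
    return make_interaction(d, "drug", g, "gene", freq)


def gene_disease(g, z, freq=1):
    return make_interaction(g, "gene", z, "disease", freq)


class TestAbcJoin:
    def test_single_chain(self):
        assert abc_join([drug_gene("D1", "G1"), gene_disease("G1", "Z1")]) == [
            ("D1", "G1", "Z1")
        ]

    def test_no_shared_gene(self):
        assert abc_join([drug_gene("D1", "G1"), gene_disease("G2", "Z1")]) == []

    def test_two_bridges_for_one_pair(self):
        inters = [
            drug_gene("D1", "G1"), drug_gene("D1", "G2"),
            gene_disease("G1", "Z1"), gene_disease("G2", "Z1"),
        ]
        triples = abc_join(inters)
        assert triples == [("D1", "G1", "Z1"), ("D1", "G2", "Z1")]

    @settings(deadline=None, max_examples=100)
    @given(
        dg=st.sets(st.tuples(st.sampled_from("DEF"), st.sampled_from("GHJ")),
                   max_size=9),
        gz=st.sets(st.tuples(st.sampled_from("GHJ"), st.sampled_from("XYZ")),
                   max_size=9),
    )
    def test_matches_nested_loop_oracle(self, dg, gz):
        inters = [drug_gene(f"D{a}", f"G{b}") for a, b in dg]
        inters += [gene_disease(f"G{b}", f"Z{c}") for b, c in gz]
        expected = sorted(
            (f"D{a}", f"G{b}", f"Z{c}")
            for (a, b), (b2, c) in itertools.product(dg, gz)
            if b == b2
        )
        assert abc_join(inters) == expected

    def test_invariant_to_input_ordering(self):
        inters = [
            drug_gene("D1", "G1"), drug_gene("D2", "G1"),
            gene_disease("G1", "Z1"), gene_disease("G1", "Z2"),
        ]
        assert abc_join(inters) == abc_join(list(reversed(inters)))


class TestScoreBridges:
    def test_hand_evaluated_example(self):
        # τ = 0.95: only B1 is meaningful
        bridges = [
            Bridge("B1", sim=0.96, freq_ab=3, freq_bc=2, meaningful=True),
            Bridge("B2", sim=0.5, freq_ab=10, freq_bc=10, meaningful=False),
        ]
        scores = score_bridges(bridges)
        assert scores == {"baseline": 106.0, "sum": 0.96, "max": 0.96, "hybrid": 6.0}

    def test_no_meaningful_bridges(self):
        bridges = [Bridge("B1", 0.2, 4, 5, False)]
        scores = score_bridges(bridges)
        assert scores == {"baseline": 20.0, "sum": 0.0, "max": 0.0, "hybrid": 0.0}

    def test_all_meaningful_makes_hybrid_equal_baseline(self):
        bridges = [Bridge("B1", 0.9, 2, 3, True), Bridge("B2", 0.8, 4, 1, True)]
        scores = score_bridges(bridges)
        assert scores["hybrid"] == scores["baseline"] == 10.0

    @settings(deadline=None, max_examples=500)
    @given(
        data=st.lists(
            st.tuples(st.floats(0, 1), st.integers(1, 20), st.integers(1, 20)),
            min_size=1, max_size=8,
        ),
        tau=st.floats(-1, 1),
    )
    def test_scoring_identities(self, data, tau):
        bridges = [
            Bridge(f"B{i}", sim, fa, fb, meaningful=sim > tau)
            for i, (sim, fa, fb) in enumerate(data)
        ]
        s = score_bridges(bridges)
        assert s["hybrid"] <= s["baseline"]
        assert s["max"] <= s["sum"] + 1e-12  # cosine sims are non-negative
        assert s["max"] >= 0.0
        if all(b.meaningful for b in bridges):
            assert s["hybrid"] == s["baseline"]


class TestScoreRelations:
    def setup_world(self, tau=0.95):
        inters = [
            drug_gene("D1", "G1", freq=3), gene_disease("G1", "Z1", freq=2),
            drug_gene("D1", "G2", freq=10), gene_disease("G2", "Z1", freq=10),
        ]
        # G1 bridge: identical context vectors (cosine 1); G2: orthogonal
        cvs = [
            ContextVector(inters[0].key, {"a": 2.0, "b": 1.0}, 1),
            ContextVector(inters[1].key, {"a": 2.0, "b": 1.0}, 1),
            ContextVector(inters[2].key, {"c": 1.0}, 1),
            ContextVector(inters[3].key, {"d": 1.0}, 1),
        ]
        measure = SimilarityMeasure("cosine", tau)
        triples = abc_join(inters)
        return inters, cvs, measure, triples

    def test_bridges_aggregated_per_pair(self):
        inters, cvs, measure, triples = self.setup_world()
        (rel,) = score_relations(triples, inters, cvs, measure)
        assert (rel.drug, rel.disease) == ("D1", "Z1")
        assert len(rel.bridges) == 2
        assert rel.scores["baseline"] == 106.0
        assert rel.scores["hybrid"] == 6.0
        assert rel.scores["sum"] == pytest.approx(1.0)
        assert rel.scores["max"] == pytest.approx(1.0)
        assert rel.best_bridge.gene == "G1"

    def test_threshold_degeneracy_admits_all(self):
        inters, cvs, _, triples = self.setup_world()
        measure = SimilarityMeasure("cosine", -1.0)
        (rel,) = score_relations(triples, inters, cvs, measure)
        assert rel.scores["hybrid"] == rel.scores["baseline"]

    def test_missing_context_vector_names_interaction(self):
        inters, cvs, measure, triples = self.setup_world()
        with pytest.raises(KeyError, match="G2"):
            score_relations(triples, inters, cvs[:3], measure)

    def test_undefined_similarity_keeps_bridge_in_baseline(self):
        inters, cvs, _, triples = self.setup_world()
        # an empty vector densifies to all zeros: Spearman is undefined on
        # that bridge, which stays in the baseline but is never meaningful
        cvs = cvs[:3] + [ContextVector(inters[3].key, {}, 1)]
        measure = SimilarityMeasure("spearman", 0.9)
        (rel,) = score_relations(triples, inters, cvs, measure)
        assert rel.scores["baseline"] == 106.0
        genes = {b.gene: b for b in rel.bridges}
        assert genes["G1"].meaningful  # identical vectors: rho = 1
        assert not genes["G2"].meaningful
        assert genes["G2"].sim != genes["G2"].sim  # nan

    def test_scores_invariant_to_interaction_order(self):
        inters, cvs, measure, triples = self.setup_world()
        (r1,) = score_relations(triples, inters, cvs, measure)
        (r2,) = score_relations(
            list(reversed(triples)), list(reversed(inters)),
            list(reversed(cvs)), measure,
        )
        assert r1.scores == r2.scores


def rel(drug, disease, **scores):
    return InferredRelation(drug=drug, disease=disease, scores=scores)


class TestRank:
    def test_descending_by_score(self):
        rels = [rel("D1", "Z1", hybrid=5.0), rel("D2", "Z1", hybrid=3.0),
                rel("D3", "Z1", hybrid=9.0)]
        assert [r.scores["hybrid"] for r in rank(rels, "hybrid")] == [9.0, 5.0, 3.0]

    def test_ties_broken_lexicographically(self):
        rels = [rel("D2", "Z1", hybrid=1.0), rel("D1", "Z2", hybrid=1.0),
                rel("D1", "Z1", hybrid=1.0)]
        ranked = rank(rels, "hybrid")
        assert [(r.drug, r.disease) for r in ranked] == [
            ("D1", "Z1"), ("D1", "Z2"), ("D2", "Z1"),
        ]

    def test_rank_is_stable_under_rerun_and_shuffle(self):
        rels = [rel(f"D{i}", f"Z{i % 3}", hybrid=float(i % 4)) for i in range(12)]
        ranked1 = rank(rels, "hybrid")
        shuffled = rels[:]
        random.Random(7).shuffle(shuffled)
        ranked2 = rank(shuffled, "hybrid")
        assert [(r.drug, r.disease) for r in ranked1] == [
            (r.drug, r.disease) for r in ranked2
        ]
        assert rank(rels, "hybrid") == ranked1

    def test_unknown_or_missing_score_rejected(self):
        with pytest.raises(ValueError):
            rank([], "bogus")
        with pytest.raises(ValueError):
            rank([rel("D1", "Z1", baseline=1.0)], "hybrid")


class TestExcludeDirect:
    def test_drops_directly_cooccurring_pairs(self):
        rels = [rel("D1", "Z1", hybrid=1.0), rel("D2", "Z2", hybrid=1.0)]
        assert exclude_direct(rels, {("D1", "Z1")}) == rels[1:]

    def test_canonical_score_names(self):
        from contextabc.inference import SCORE_NAMES

        assert set(SCORE_NAMES) == {"baseline", "sum", "max", "hybrid"}
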