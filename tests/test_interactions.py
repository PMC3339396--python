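import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contextabc.dictionaries import Level, Role
from contextabc.interactions import (
    build_context_vectors,
    canonical_key,
    direct_pairs,
    extract_interactions,
)
from contextabc.tagging import EntityMention


def mention(aid, si, acc, level, role=Role.INTERACTION, start=0, end=1):
    return EntityMention(aid, si, start, end, acc.lower(), acc, Level(level), role)


def interaction_by_accs(interactions, acc1, acc2):
    for it in interactions:
        if set(it.accessions) == {acc1, acc2}:
            return it
    raise AssertionError(f"no interaction {acc1}-{acc2}")


class TestExtract:
    def test_pattern_restriction_drug_gene_and_gene_disease(self):
        ms = [
            mention("1", 0, "D1", "drug", start=0, end=2),
            mention("1", 0, "G1", "gene", start=3, end=5),
            mention("1", 0, "Z1", "disease", start=6, end=8),
        ]
        inters = extract_interactions(ms)
        assert {frozenset(it.accessions) for it in inters} == {
            frozenset({"D1", "G1"}), frozenset({"G1", "Z1"}),
        }  # no direct D1-Z1 interaction

    def test_two_sentences_one_abstract(self):
        ms = [
            mention("1", 0, "D1", "drug"), mention("1", 0, "G1", "gene"),
            mention("1", 1, "D1", "drug"), mention("1", 1, "G1", "gene"),
        ]
        (it,) = extract_interactions(ms)
        assert it.frequency == 2
        assert it.support == {"1"}

    def test_two_drugs_no_interaction(self):
        ms = [mention("1", 0, "D1", "drug"), mention("1", 0, "D2", "drug")]
        assert extract_interactions(ms) == []

    def test_mention_multiplicity_does_not_multiply(self):
        # drug mentioned twice in the sentence: still one incidence
        ms = [
            mention("1", 0, "D1", "drug", start=0, end=2),
            mention("1", 0, "D1", "drug", start=10, end=12),
            mention("1", 0, "G1", "gene", start=4, end=6),
        ]
        (it,) = extract_interactions(ms)
        assert it.frequency == 1

    def test_context_role_mentions_ignored(self):
        ms = [
            mention("1", 0, "D1", "drug"),
            mention("1", 0, "G1", "gene", role=Role.CONTEXT),
        ]
        assert extract_interactions(ms) == []

    def test_canonical_key_is_order_independent(self):
        k1 = canonical_key(("D1", Level.DRUG), ("G1", Level.GENE))
        k2 = canonical_key(("G1", Level.GENE), ("D1", Level.DRUG))
        assert k1 == k2
        assert k1 == (("D1", Level.DRUG), ("G1", Level.GENE))

    def test_direct_pairs_detects_drug_disease_cooccurrence(self):
        ms = [
            mention("1", 0, "D1", "drug"), mention("1", 0, "Z1", "disease"),
            mention("1", 1, "D2", "drug"), mention("1", 2, "Z2", "disease"),
        ]
        assert direct_pairs(ms) == {("D1", "Z1")}


levels = {"D": "drug", "G": "gene", "Z": "disease"}
random_mentions = st.lists(
    st.tuples(
        st.sampled_from(["1", "2", "3"]),           # abstract
        st.integers(min_value=0, max_value=3),       # sentence
        st.sampled_from(["D1", "D2", "G1", "G2", "Z1", "Z2"]),
    ),
    max_size=25,
)


class TestFrequencyOracle:
    @settings(deadline=None, max_examples=150)
    @given(random_mentions)
    def test_frequency_matches_brute_force_recount(self, raw):
        ms = [mention(aid, si, acc, levels[acc[0]]) for aid, si, acc in raw]
        inters = extract_interactions(ms)
        # oracle: for every (sentence, admissible pair) incidence, recount
        sentences = {}
        for aid, si, acc in raw:
            sentences.setdefault((aid, si), set()).add(acc)
        expected = {}
        for (aid, _si), accs in sentences.items():
            for a1, a2 in itertools.combinations(sorted(accs), 2):
                pair = {levels[a1[0]], levels[a2[0]]}
                if pair not in ({"drug", "gene"}, {"gene", "disease"}):
                    continue
                rec = expected.setdefault(frozenset({a1, a2}), [0, set()])
                rec[0] += 1
                rec[1].add(aid)
        got = {
            frozenset(it.accessions): [it.frequency, it.support] for it in inters
        }
        assert got == expected

    @settings(deadline=None, max_examples=50)
    @given(random_mentions)
    def test_output_independent_of_mention_order(self, raw):
        ms = [mention(aid, si, acc, levels[acc[0]]) for aid, si, acc in raw]
        a = extract_interactions(ms)
        b = extract_interactions(list(reversed(ms)))
        assert [(it.key, it.frequency, it.support) for it in a] == [
            (it.key, it.frequency, it.support) for it in b
        ]


class TestContextVectors:
    def key(self):
        return canonical_key(("D1", Level.DRUG), ("G1", Level.GENE))

    def make_interaction(self, support):
        ms = []
        for i, aid in enumerate(support):
            ms += [mention(aid, 0, "D1", "drug"), mention(aid, 0, "G1", "gene")]
        (it,) = extract_interactions(ms)
        return it

    def test_single_abstract_equals_counts(self):
        it = self.make_interaction(["1"])
        (cv,) = build_context_vectors([it], {"1": {"a": 2, "b": 1}})
        assert cv.values == {"a": 2.0, "b": 1.0}
        assert cv.n_abstracts == 1

    def test_two_abstract_averaging(self):
        it = self.make_interaction(["1", "2"])
        (cv,) = build_context_vectors(
            [it], {"1": {"a": 2}, "2": {"a": 1, "c": 2}}
        )
        assert cv.values == {"a": 1.5, "c": 1.0}

    def test_members_excluded_by_default(self):
        it = self.make_interaction(["1"])
        (cv,) = build_context_vectors([it], {"1": {"D1": 3, "G1": 1}})
        assert cv.values == {}

    def test_include_self_terms_flag(self):
        it = self.make_interaction(["1"])
        (cv,) = build_context_vectors(
            [it], {"1": {"D1": 3, "a": 1}}, include_self_terms=True
        )
        assert cv.values == {"D1": 3.0, "a": 1.0}

    def test_missing_abstract_counts_as_empty(self):
        it = self.make_interaction(["1", "2"])
        (cv,) = build_context_vectors([it], {"1": {"a": 2.0}})
        assert cv.values == {"a": 1.0}

    def test_empty_support_is_error(self):
        from contextabc.interactions import Interaction

        bad = Interaction(key=self.key(), frequency=1, support=set())
        with pytest.raises(ValueError, match="empty support"):
            build_context_vectors([bad], {})

    @settings(deadline=None, max_examples=60)
    @given(
        counts=st.dictionaries(
            st.sampled_from(["1", "2", "3"]),
            st.dictionaries(st.sampled_from("abcde"),
                            st.integers(min_value=1, max_value=9), max_size=5),
            min_size=1, max_size=3,
        )
    )
    def test_values_bounded_by_max_single_abstract_count(self, counts):
        support = sorted(counts)
        it = self.make_interaction(support)
        (cv,) = build_context_vectors([it], counts)
        for term, value in cv.values.items():
            per_abs = [counts[aid].get(term, 0) for aid in support]
            assert 0 <= value <= max(per_abs)
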