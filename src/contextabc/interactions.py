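"""Sentence co-occurrence interactions and per-interaction context vectors.

An interaction is an unordered typed accession pair — restricted to the
drug–gene and gene–disease patterns — whose members are both mentioned in at
least one sentence. Its frequency counts sentences containing both members
(one incidence per sentence regardless of mention multiplicity); its support
is the set of abstracts contributing at least one such sentence.

The context vector of an interaction averages, over its supporting
abstracts, the abstract-level counts of every context term:

    CV_i[t] = ( sum over supporting abstracts j of count_j(t) ) / n

with n the number of supporting abstracts. Terms equal to either member of
the interaction are excluded by default so that an interaction cannot be
similar to another merely through its own members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .corpus import Corpus
from .dictionaries import Level, Role
from .tagging import EntityMention

log = logging.getLogger(__name__)

__all__ = [
    "InteractionKey",
    "Interaction",
    "ContextVector",
    "ADMISSIBLE_LEVEL_PAIRS",
    "canonical_key",
    "extract_interactions",
    "build_context_vectors",
    "direct_pairs",
    "write_interactions",
    "write_context_vectors",
]

# (accession, level) pair, sorted by (level value, accession).
Member = tuple[str, Level]
InteractionKey = tuple[Member, Member]

ADMISSIBLE_LEVEL_PAIRS = (
    frozenset({Level.DRUG, Level.GENE}),
    frozenset({Level.GENE, Level.DISEASE}),
)


def canonical_key(m1: Member, m2: Member) -> InteractionKey:
    """Canonical unordered pair key: sorted by level then accession."""
    a, b = sorted((m1, m2), key=lambda m: (m[1].value, m[0]))
    return (a, b)


@dataclass
class Interaction:
    """A typed co-occurrence pair with its sentence frequency and support."""

    key: InteractionKey
    frequency: int = 0
    support: set[str] = field(default_factory=set)

    @property
    def levels(self) -> frozenset[Level]:
        return frozenset({self.key[0][1], self.key[1][1]})

    @property
    def accessions(self) -> tuple[str, str]:
        return (self.key[0][0], self.key[1][0])

    def member(self, level: Level) -> str:
        """Accession of the member at the given level."""
        for acc, lv in self.key:
            if lv is level:
                return acc
        raise KeyError(f"interaction {self.key} has no {level.value} member")


@dataclass
class ContextVector:
    """Averaged context-term count vector of one interaction.

    ``values`` is sparse: absent terms are zero over the global context
    vocabulary. For an interaction supported by a single abstract the vector
    equals that abstract's context count map (minus the members).
    """

    key: InteractionKey
    values: dict[str, float]
    n_abstracts: int


def extract_interactions(
    mentions: Iterable[EntityMention], corpus: Corpus | None = None
) -> list[Interaction]:
    """Extract drug–gene and gene–disease sentence co-occurrence interactions.

    For every sentence, each unordered pair of distinct tagged entities whose
    level pair is admissible contributes one incidence to that pair's
    frequency; the abstract joins the pair's support set. Mention
    multiplicity within the sentence does not multiply the count.

    Only interaction-role mentions are considered; ``corpus`` is accepted for
    interface symmetry and future validation but not required.
    """
    per_sentence: dict[tuple[str, int], set[Member]] = {}
    for m in mentions:
        if m.role is not Role.INTERACTION:
            continue
        per_sentence.setdefault((m.abstract_id, m.sentence_index), set()).add(
            (m.accession, m.level)
        )

    table: dict[InteractionKey, Interaction] = {}
    for (abstract_id, _si), members in per_sentence.items():
        members_sorted = sorted(members, key=lambda m: (m[1].value, m[0]))
        for i in range(len(members_sorted)):
            for j in range(i + 1, len(members_sorted)):
                m1, m2 = members_sorted[i], members_sorted[j]
                if frozenset({m1[1], m2[1]}) not in ADMISSIBLE_LEVEL_PAIRS:
                    continue
                if m1[0] == m2[0]:
                    continue
                key = canonical_key(m1, m2)
                inter = table.setdefault(key, Interaction(key=key))
                inter.frequency += 1
                inter.support.add(abstract_id)

    out = sorted(table.values(), key=lambda it: it.key)
    log.info("extracted %d interactions from %d tagged sentences",
             len(out), len(per_sentence))
    return out


def direct_pairs(mentions: Iterable[EntityMention]) -> set[tuple[str, str]]:
    """Drug–disease pairs that co-occur directly in some sentence.

    Used by the optional open-discovery filter that removes already
    co-published pairs from the inferred candidates.
    """
    per_sentence: dict[tuple[str, int], set[Member]] = {}
    for m in mentions:
        if m.role is not Role.INTERACTION:
            continue
        per_sentence.setdefault((m.abstract_id, m.sentence_index), set()).add(
            (m.accession, m.level)
        )
    pairs: set[tuple[str, str]] = set()
    for members in per_sentence.values():
        drugs = [acc for acc, lv in members if lv is Level.DRUG]
        diseases = [acc for acc, lv in members if lv is Level.DISEASE]
        pairs.update((d, z) for d in drugs for z in diseases)
    return pairs


def build_context_vectors(
    interactions: Iterable[Interaction],
    context_counts: Mapping[str, Mapping[str, int]],
    *,
    include_self_terms: bool = False,
) -> list[ContextVector]:
    """Average abstract-level context counts over each interaction's support.

    Parameters
    ----------
    interactions:
        Extracted interactions with non-empty support.
    context_counts:
        Per-abstract context term -> count maps (missing abstracts count as
        empty).
    include_self_terms:
        Keep context terms whose accession equals an interaction member
        (excluded by default).
    """
    out: list[ContextVector] = []
    for inter in interactions:
        if not inter.support:
            raise ValueError(f"interaction {inter.key} has empty support")
        n = len(inter.support)
        totals: dict[str, float] = {}
        members = set(inter.accessions)
        for aid in inter.support:
            for term, count in context_counts.get(aid, {}).items():
                if not include_self_terms and term in members:
                    continue
                totals[term] = totals.get(term, 0.0) + count
        out.append(
            ContextVector(
                key=inter.key,
                values={t: v / n for t, v in sorted(totals.items())},
                n_abstracts=n,
            )
        )
    return out


def write_interactions(interactions: Iterable[Interaction], path: str | Path) -> None:
    """TSV: acc1, level1, acc2, level2, frequency, n_abstracts."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("acc1\tlevel1\tacc2\tlevel2\tfrequency\tn_abstracts\n")
        for it in interactions:
            (a1, l1), (a2, l2) = it.key
            fh.write(
                f"{a1}\t{l1.value}\t{a2}\t{l2.value}\t{it.frequency}\t{len(it.support)}\n"
            )


def write_context_vectors(vectors: Iterable[ContextVector], path: str | Path) -> None:
    """Sparse TSV triples: interaction_key, term, value."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("interaction_key\tterm\tvalue\n")
        for cv in vectors:
            (a1, l1), (a2, l2) = cv.key
            key_str = f"{a1}:{l1.value}--{a2}:{l2.value}"
            for term, value in cv.values.items():
                fh.write(f"{key_str}\t{term}\t{value:.10g}\n")
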