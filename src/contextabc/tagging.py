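"""Dictionary-based entity tagging and abstract-level context counting.

Tagging is pure dictionary matching constrained to token boundaries: a match
may not start or end mid-word, so "ache" never fires inside "headache".
Within a sentence, candidate matches are resolved longest-first with ties
broken leftmost; the surviving spans are non-overlapping per role. A term
that maps to several accessions (possibly at different levels) emits one
mention per (accession, level) at the same span — disambiguation is left to
the downstream interaction pattern filters.

Context counting collapses synonyms to their accession ID and counts at the
abstract level: the context profile of an interaction is the bag of context
accessions tagged anywhere in the abstracts that support it.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .corpus import Corpus
from .dictionaries import EntityDictionary, Level, Role, normalize_term

log = logging.getLogger(__name__)

__all__ = [
    "EntityMention",
    "tag_corpus",
    "count_context_terms",
    "context_counts_by_abstract",
    "write_mentions",
    "read_mentions",
]

_TOKEN = re.compile(r"\w+", re.UNICODE)


@dataclass(frozen=True, order=True)
class EntityMention:
    """One tagged entity occurrence.

    ``start``/``end`` are character offsets into the abstract text (not the
    sentence); ``surface`` is the exact text slice matched.
    """

    abstract_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    accession: str
    level: Level
    role: Role


def _candidate_matches(
    sent_text: str, dictionary: EntityDictionary
) -> list[tuple[int, int, str]]:
    """All token-boundary-aligned dictionary matches in a sentence.

    Returns (start, end, normalized_term) triples with offsets local to the
    sentence text.
    """
    tokens = list(_TOKEN.finditer(sent_text))
    max_len = dictionary.max_term_tokens
    terms = dictionary.terms
    out: list[tuple[int, int, str]] = []
    for i in range(len(tokens)):
        for j in range(i, min(i + max_len, len(tokens))):
            start, end = tokens[i].start(), tokens[j].end()
            term = normalize_term(sent_text[start:end])
            if term in terms:
                out.append((start, end, term))
    return out


def _resolve_overlaps(
    candidates: list[tuple[int, int, str]]
) -> list[tuple[int, int, str]]:
    """Longest match wins; ties broken leftmost; result spans non-overlapping."""
    accepted: list[tuple[int, int, str]] = []
    for start, end, term in sorted(candidates, key=lambda c: (-(c[1] - c[0]), c[0])):
        if all(end <= a_start or start >= a_end for a_start, a_end, _ in accepted):
            accepted.append((start, end, term))
    accepted.sort()
    return accepted


def tag_corpus(c: Corpus, dictionary: EntityDictionary) -> list[EntityMention]:
    """Tag every sentence of the corpus against one dictionary.

    Requires sentence spans to be populated (see
    :func:`contextabc.corpus.split_corpus`). Emitted mentions carry the
    dictionary's role. Output order is deterministic: corpus order, then
    sentence, then span, then (accession, level).
    """
    if len(dictionary) == 0:
        raise ValueError("cannot tag with an empty dictionary")
    mentions: list[EntityMention] = []
    for a in c:
        if not a.sentences:
            raise ValueError(f"abstract {a.id!r} has no sentence spans; split first")
        for si, (s_start, s_end) in enumerate(a.sentences):
            sent_text = a.text[s_start:s_end]
            for start, end, term in _resolve_overlaps(
                _candidate_matches(sent_text, dictionary)
            ):
                for accession, level in sorted(dictionary.lookup(term)):
                    mentions.append(
                        EntityMention(
                            abstract_id=a.id,
                            sentence_index=si,
                            start=s_start + start,
                            end=s_start + end,
                            surface=a.text[s_start + start : s_start + end],
                            accession=accession,
                            level=level,
                            role=dictionary.role,
                        )
                    )
    log.info(
        "tagged %d mentions (role=%s) over %d abstracts",
        len(mentions), dictionary.role.value, len(c),
    )
    return mentions


def count_context_terms(
    mentions: list[EntityMention], abstract_id: str
) -> dict[str, int]:
    """Abstract-level context-term counts for one abstract.

    Counts context-role mentions per accession across the whole abstract
    (synonyms collapse to their accession).
    """
    return dict(
        Counter(
            m.accession
            for m in mentions
            if m.role is Role.CONTEXT and m.abstract_id == abstract_id
        )
    )


def context_counts_by_abstract(
    mentions: list[EntityMention],
) -> dict[str, dict[str, int]]:
    """Context counts for every abstract appearing in the mention list."""
    counters: dict[str, Counter[str]] = {}
    for m in mentions:
        if m.role is Role.CONTEXT:
            counters.setdefault(m.abstract_id, Counter())[m.accession] += 1
    return {aid: dict(c) for aid, c in counters.items()}


_MENTION_COLUMNS = (
    "abstract_id sentence_index start end surface accession level role".split()
)


def write_mentions(mentions: list[EntityMention], path: str | Path) -> None:
    """Write mentions as TSV with a header row."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_MENTION_COLUMNS) + "\n")
        for m in mentions:
            fh.write(
                f"{m.abstract_id}\t{m.sentence_index}\t{m.start}\t{m.end}\t"
                f"{m.surface}\t{m.accession}\t{m.level.value}\t{m.role.value}\n"
            )


def read_mentions(path: str | Path) -> list[EntityMention]:
    """Read mentions from the TSV produced by :func:`write_mentions`."""
    mentions: list[EntityMention] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MENTION_COLUMNS:
            raise ValueError(f"unexpected mention TSV header: {header}")
        for line in fh:
            if not line.strip():
                continue
            aid, si, start, end, surface, acc, level, role = line.rstrip("\n").split("\t")
            mentions.append(
                EntityMention(
                    aid, int(si), int(start), int(end), surface, acc,
                    Level(level), Role(role),
                )
            )
    return mentions
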