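"""Multi-level entity dictionaries.

Entity recognition is driven by flat term dictionaries at four biological
levels — gene, drug, disease, symptom. A dictionary plays one of two roles:
``interaction`` dictionaries (PharmGKB/CTD-like) feed sentence co-occurrence
extraction, while ``context`` dictionaries (UMLS-like) feed the context-term
vectors built around each interaction. Several surface terms (synonyms) may
share one accession ID, and one surface term may map to several accessions,
possibly at different levels.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

log = logging.getLogger(__name__)

__all__ = [
    "Level",
    "Role",
    "DictionaryEntry",
    "EntityDictionary",
    "normalize_term",
    "load_dictionary",
    "write_dictionary",
    "merge",
]


class Level(str, Enum):
    """Biological level of a dictionary entity."""

    GENE = "gene"
    DRUG = "drug"
    DISEASE = "disease"
    SYMPTOM = "symptom"


class Role(str, Enum):
    """Whether matches from a dictionary feed interactions or context vectors."""

    INTERACTION = "interaction"
    CONTEXT = "context"


_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Normalize a surface term: strip, collapse internal whitespace, lowercase.

    Matching is case-insensitive throughout; normalization is the single
    point where that convention is defined.
    """
    return _WS.sub(" ", term.strip()).lower()


@dataclass(frozen=True, order=True)
class DictionaryEntry:
    """One (term, accession, level, source) row of an entity dictionary.

    ``term`` is stored normalized (see :func:`normalize_term`).
    """

    term: str
    accession: str
    level: Level
    source: str = ""


@dataclass
class EntityDictionary:
    """A set of dictionary entries with a fixed role and a term index.

    Lookup is exact on the normalized term and deterministic. The same term
    may resolve to several ``(accession, level)`` pairs (cross-level
    ambiguity is retained here and resolved downstream).
    """

    role: Role
    entries: set[DictionaryEntry] = field(default_factory=set)
    _index: dict[str, set[tuple[str, Level]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._index = {}
        for e in self.entries:
            self._index.setdefault(e.term, set()).add((e.accession, e.level))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[DictionaryEntry]:
        return iter(sorted(self.entries))

    def add(self, entry: DictionaryEntry) -> None:
        self.entries.add(entry)
        self._index.setdefault(entry.term, set()).add((entry.accession, entry.level))

    def lookup(self, term: str) -> set[tuple[str, Level]]:
        """Exact lookup of a (raw or normalized) term.

        Returns the set of ``(accession, level)`` pairs the term maps to;
        empty set when absent.
        """
        return set(self._index.get(normalize_term(term), ()))

    @property
    def terms(self) -> set[str]:
        """All normalized terms present in the dictionary."""
        return set(self._index)

    @property
    def max_term_tokens(self) -> int:
        """Longest term length in whitespace tokens (0 for empty dictionary)."""
        if not self._index:
            return 0
        return max(len(t.split()) for t in self._index)


def load_dictionary(
    path: str | Path,
    role: Role | str,
    *,
    header: bool = False,
) -> EntityDictionary:
    """Load an entity dictionary from a TSV file.

    Expected columns: term, accession, level, optional source. Rows with
    fewer than 3 fields, an unknown level, or an empty term after
    normalization are skipped with a warning count. A missing file is fatal.

    Parameters
    ----------
    path:
        TSV file, UTF-8, no header line unless ``header=True``.
    role:
        ``interaction`` or ``context``; marks how matches are used downstream.
    header:
        Skip the first line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dictionary file not found: {path}")
    d = EntityDictionary(role=Role(role))
    n_rows = 0
    n_skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_rows += 1
            fields = line.split("\t")
            if len(fields) < 3:
                log.warning("%s:%d: malformed row (<3 columns), skipped", path, lineno)
                n_skipped += 1
                continue
            term = normalize_term(fields[0])
            accession = fields[1].strip()
            try:
                level = Level(fields[2].strip().lower())
            except ValueError:
                log.warning(
                    "%s:%d: unknown level %r, skipped", path, lineno, fields[2]
                )
                n_skipped += 1
                continue
            if not term or not accession:
                log.warning("%s:%d: empty term or accession, skipped", path, lineno)
                n_skipped += 1
                continue
            source = fields[3].strip() if len(fields) > 3 else ""
            d.add(DictionaryEntry(term, accession, level, source))
    if n_rows == 0:
        log.warning("%s: empty dictionary file", path)
    log.info(
        "loaded %d entries (%d rows, %d skipped) from %s [role=%s]",
        len(d), n_rows, n_skipped, path, d.role.value,
    )
    return d


def write_dictionary(d: EntityDictionary, path: str | Path) -> None:
    """Write a dictionary back to TSV (term, accession, level, source), sorted."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for e in sorted(d.entries):
            fh.write(f"{e.term}\t{e.accession}\t{e.level.value}\t{e.source}\n")


def merge(d1: EntityDictionary, d2: EntityDictionary) -> EntityDictionary:
    """Set union of two dictionaries with the same role.

    Supports combined runs over separately sourced dictionaries (e.g. a
    PharmGKB-like and a CTD-like interaction dictionary).
    """
    if d1.role != d2.role:
        raise ValueError(
            f"cannot merge dictionaries with different roles: "
            f"{d1.role.value} vs {d2.role.value}"
        )
    return EntityDictionary(role=d1.role, entries=set(d1.entries) | set(d2.entries))


def dictionary_from_rows(
    rows: Iterable[tuple[str, str, str | Level]] | Iterable[tuple[str, str, str | Level, str]],
    role: Role | str,
) -> EntityDictionary:
    """Build a dictionary from in-memory (term, accession, level[, source]) rows."""
    d = EntityDictionary(role=Role(role))
    for row in rows:
        term, accession, level = row[0], row[1], Level(row[2])
        source = row[3] if len(row) > 3 else ""
        d.add(DictionaryEntry(normalize_term(term), accession, level, source))
    return d
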