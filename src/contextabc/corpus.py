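"""Abstract corpus I/O and sentence splitting.

Abstracts are read from PubMed-style XML (PMID + ArticleTitle + AbstractText)
or from JSONL (one ``{"id": ..., "text": ...}`` object per line). Title and
abstract body are concatenated with ``". "`` into a single text; entity
tagging and context counting then operate on sentence spans of that text.

Sentence splitting is a deterministic rule-based splitter behind a small
interface, so a statistical splitter could be substituted without touching
the rest of the pipeline; the co-occurrence method itself does not depend on
which splitter produced the spans.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Protocol

from lxml import etree

log = logging.getLogger(__name__)

__all__ = [
    "Abstract",
    "Corpus",
    "RuleBasedSplitter",
    "read_corpus",
    "write_corpus_jsonl",
    "split_sentences",
    "split_corpus",
]

Span = tuple[int, int]


@dataclass
class Abstract:
    """One abstract: id, full text, and sentence spans.

    Spans are 0-based half-open character intervals into ``text``, sorted,
    non-overlapping, and covering all non-whitespace characters.
    """

    id: str
    text: str
    sentences: list[Span] = field(default_factory=list)

    def sentence_text(self, i: int) -> str:
        s, e = self.sentences[i]
        return self.text[s:e]


@dataclass
class Corpus:
    """Ordered collection of abstracts with unique ids."""

    abstracts: list[Abstract] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.abstracts]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate abstract ids in corpus")

    def __len__(self) -> int:
        return len(self.abstracts)

    def __iter__(self) -> Iterator[Abstract]:
        return iter(self.abstracts)

    def __getitem__(self, abstract_id: str) -> Abstract:
        for a in self.abstracts:
            if a.id == abstract_id:
                return a
        raise KeyError(abstract_id)


class SentenceSplitter(Protocol):
    def split(self, text: str) -> list[Span]: ...


# Tokens that end with "." but do not end a sentence.
_ABBREVIATIONS = frozenset(
    "dr mr mrs ms prof st fig figs no vs al etc e.g i.e ref eq cf approx".split()
)


class RuleBasedSplitter:
    """Deterministic sentence splitter.

    A boundary is a terminal ``.``, ``!`` or ``?`` followed by whitespace and
    an uppercase letter or digit, unless the token ending at the period is a
    known abbreviation ("Dr.", "Fig.", "e.g." ...). With no boundary found
    the whole text is a single sentence.
    """

    _boundary = re.compile(r"[.!?]+(?=\s+[A-Z0-9])")
    _last_token = re.compile(r"(\S+)$")

    def __init__(self, abbreviations: frozenset[str] = _ABBREVIATIONS) -> None:
        self.abbreviations = abbreviations

    def _is_abbreviation(self, text: str, punct_start: int) -> bool:
        m = self._last_token.search(text[:punct_start])
        if m is None:
            return False
        token = m.group(1).lower().rstrip(".")
        return token in self.abbreviations

    def split(self, text: str) -> list[Span]:
        cuts: list[int] = []
        for m in self._boundary.finditer(text):
            if text[m.start()] == "." and self._is_abbreviation(text, m.start()):
                continue
            cuts.append(m.end())
        spans: list[Span] = []
        prev = 0
        for cut in cuts + [len(text)]:
            seg = text[prev:cut]
            lstrip = len(seg) - len(seg.lstrip())
            rstrip = len(seg) - len(seg.rstrip())
            start, end = prev + lstrip, cut - rstrip
            if start < end:
                spans.append((start, end))
            prev = cut
        if not spans and text.strip():
            raise AssertionError("non-empty text produced no sentence span")
        return spans


_DEFAULT_SPLITTER = RuleBasedSplitter()


def split_sentences(a: Abstract, splitter: SentenceSplitter | None = None) -> Abstract:
    """Return a copy of the abstract with sentence spans populated."""
    if not a.text.strip():
        raise ValueError(f"abstract {a.id!r} has empty text")
    splitter = splitter or _DEFAULT_SPLITTER
    return replace(a, sentences=splitter.split(a.text))


def split_corpus(c: Corpus, splitter: SentenceSplitter | None = None) -> Corpus:
    """Sentence-split every abstract of a corpus."""
    return Corpus([split_sentences(a, splitter) for a in c])


def _read_pubmed_xml(path: Path) -> Iterator[tuple[str, str]]:
    tree = etree.parse(str(path))
    for art in tree.iter("PubmedArticle"):
        pmid_el = art.find(".//PMID")
        pmid = pmid_el.text.strip() if pmid_el is not None and pmid_el.text else ""
        title_el = art.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() if title_el is not None else ""
        parts = [
            "".join(el.itertext()).strip()
            for el in art.findall(".//Abstract/AbstractText")
        ]
        body = " ".join(p for p in parts if p)
        # A record without abstract text yields an empty text and is skipped
        # (with a warning) by read_corpus.
        yield pmid, _join_title_body(title, body) if body else ""


def _join_title_body(title: str, body: str) -> str:
    title = title.rstrip()
    if title and not title.endswith((".", "!", "?")):
        title += "."
    return f"{title} {body}".strip()


def _read_jsonl(path: Path) -> Iterator[tuple[str, str]]:
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: invalid JSON line") from exc
            yield str(obj.get("id", "")), str(obj.get("text", ""))


def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Read abstracts from a file.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"pubmed_xml"`` or ``"jsonl"``.

    Records with empty text are skipped with a warning; on a duplicate id the
    first record wins. An unparseable file raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus file not found: {path}")
    if format == "pubmed_xml":
        records = _read_pubmed_xml(path)
    elif format == "jsonl":
        records = _read_jsonl(path)
    else:
        raise ValueError(f"unknown corpus format: {format!r}")

    abstracts: list[Abstract] = []
    seen: set[str] = set()
    n_skipped = 0
    for rid, text in records:
        if not rid or not text.strip():
            log.warning("skipping record with missing id or empty text (id=%r)", rid)
            n_skipped += 1
            continue
        if rid in seen:
            log.warning("duplicate abstract id %r: keeping first occurrence", rid)
            n_skipped += 1
            continue
        seen.add(rid)
        abstracts.append(Abstract(id=rid, text=text))
    log.info("read %d abstracts (%d skipped) from %s", len(abstracts), n_skipped, path)
    return Corpus(abstracts)


def write_corpus_jsonl(c: Corpus, path: str | Path) -> None:
    """Write a corpus as JSONL with keys id, text."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for a in c:
            fh.write(json.dumps({"id": a.id, "text": a.text}, sort_keys=True))
            fh.write("\n")
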