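"""Precision@k evaluation of ranked drug–disease candidates.

The gold standard is a curated set of known drug–disease pairs (in the
original setting, PharmGKB's or CTD's drug–disease interaction tables).
Precision@k is the fraction of the top-k ranked candidates found in the gold
set; k stays in the denominator even when fewer than k candidates exist, so
short rankings are penalized consistently. Prediction and gold accessions
must share a namespace — no cross-ontology mapping is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .inference import InferredRelation

log = logging.getLogger(__name__)

__all__ = ["GoldStandard", "load_gold", "precision_at_k", "evaluate_all"]

DEFAULT_KS = (100, 500, 1000)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class GoldStandard:
    """Deduplicated, order-canonical set of known drug–disease pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def from_pairs(cls, pairs) -> "GoldStandard":
        return cls({_canonical(a, b) for a, b in pairs})

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return _canonical(*pair) in self.pairs


def load_gold(path: str | Path) -> GoldStandard:
    """Load a 2-column TSV of drug/disease accession pairs.

    Pair order within a row is irrelevant (rows are canonicalized), and
    duplicates collapse. Malformed rows are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gold standard file not found: {path}")
    pairs: set[tuple[str, str]] = set()
    n_skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                log.warning("%s:%d: malformed gold row, skipped", path, lineno)
                n_skipped += 1
                continue
            pairs.add(_canonical(fields[0], fields[1]))
    if not pairs:
        log.warning("%s: empty gold standard", path)
    log.info("loaded %d gold pairs (%d rows skipped) from %s", len(pairs), n_skipped, path)
    return GoldStandard(pairs)


def precision_at_k(
    ranked: Sequence[InferredRelation], gold: GoldStandard, k: int
) -> float:
    """|top-k ∩ gold| / k, with k in the denominator regardless of length."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not ranked:
        log.warning("precision_at_k on an empty ranking -> 0.0")
        return 0.0
    hits = sum(1 for r in ranked[:k] if (r.drug, r.disease) in gold)
    return hits / k


def evaluate_all(
    rankings: Mapping[str, Sequence[InferredRelation]],
    gold: GoldStandard,
    ks: Sequence[int] = DEFAULT_KS,
) -> pd.DataFrame:
    """Precision matrix over scoring functions × cutoffs.

    Returns a tidy DataFrame with columns score_name, k, precision; one row
    per (scoring function, k).
    """
    rows = []
    for score_name, ranked in rankings.items():
        for k in ks:
            p = precision_at_k(ranked, gold, k)
            rows.append({"score_name": score_name, "k": k, "precision": p})
            log.info("precision@%d [%s] = %.4f", k, score_name, p)
    return pd.DataFrame(rows, columns=["score_name", "k", "precision"])
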