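"""ABC inference: join interactions through bridge genes and score candidates.

Given drug–gene and gene–disease interactions, every shared gene B links a
drug A to a disease C (the classic A–B, B–C ⇒ A–C inference). Each bridge
carries the similarity between the context vectors of its two supporting
interactions; a bridge is *meaningful* when that similarity strictly exceeds
the threshold τ of the chosen measure.

Four scores are computed per inferred (A, C) pair:

- ``baseline``: Σ over ALL bridges of freq(A–B)·freq(B–C) — the
  frequency-only ABC model.
- ``sum``: Σ over meaningful bridges of the similarity.
- ``max``: maximum similarity over meaningful bridges (0 if none).
- ``hybrid``: Σ over meaningful bridges of freq(A–B)·freq(B–C) — the
  frequency score restricted to context-coherent bridges.

Candidates with no meaningful bridge are retained with similarity-based
scores of 0 so that every ranking covers the same candidate universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import isnan, nan
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .dictionaries import Level
from .interactions import ContextVector, Interaction, InteractionKey, canonical_key
from .similarity import SimilarityMeasure, UndefinedSimilarityError, build_vocabulary

log = logging.getLogger(__name__)

__all__ = [
    "Bridge",
    "InferredRelation",
    "SCORE_NAMES",
    "abc_join",
    "score_bridges",
    "score_relations",
    "rank",
    "exclude_direct",
    "write_ranked",
]

SCORE_NAMES = ("baseline", "sum", "max", "hybrid")


@dataclass(frozen=True)
class Bridge:
    """One gene B linking A–B and B–C, with its context similarity."""

    gene: str
    sim: float  # nan when the similarity is undefined for this pair
    freq_ab: int
    freq_bc: int
    meaningful: bool


@dataclass
class InferredRelation:
    """A candidate drug–disease pair with its bridges and four scores."""

    drug: str
    disease: str
    bridges: list[Bridge] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)

    @property
    def best_bridge(self) -> Bridge | None:
        """Meaningful bridge of highest similarity, ties to lowest gene id."""
        candidates = [b for b in self.bridges if b.meaningful]
        if not candidates:
            return None
        return max(candidates, key=lambda b: (b.sim, b.gene))


def abc_join(interactions: Iterable[Interaction]) -> list[tuple[str, str, str]]:
    """All (drug A, gene B, disease C) triples linked by a shared gene.

    Output is sorted and deterministic; the triple count equals the
    brute-force double loop over drug–gene × gene–disease interactions.
    """
    drugs_by_gene: dict[str, list[str]] = {}
    diseases_by_gene: dict[str, list[str]] = {}
    for it in interactions:
        levels = it.levels
        if levels == frozenset({Level.DRUG, Level.GENE}):
            drugs_by_gene.setdefault(it.member(Level.GENE), []).append(
                it.member(Level.DRUG)
            )
        elif levels == frozenset({Level.GENE, Level.DISEASE}):
            diseases_by_gene.setdefault(it.member(Level.GENE), []).append(
                it.member(Level.DISEASE)
            )
    triples = [
        (a, b, c)
        for b in sorted(set(drugs_by_gene) & set(diseases_by_gene))
        for a in sorted(drugs_by_gene[b])
        for c in sorted(diseases_by_gene[b])
    ]
    triples.sort()
    log.info("ABC join produced %d triples", len(triples))
    return triples


def score_bridges(bridges: Sequence[Bridge]) -> dict[str, float]:
    """The four scores of a relation from its (already thresholded) bridges."""
    meaningful = [b for b in bridges if b.meaningful]
    return {
        "baseline": float(sum(b.freq_ab * b.freq_bc for b in bridges)),
        "sum": float(sum(b.sim for b in meaningful)),
        "max": float(max((b.sim for b in meaningful), default=0.0)),
        "hybrid": float(sum(b.freq_ab * b.freq_bc for b in meaningful)),
    }


def score_relations(
    triples: Iterable[tuple[str, str, str]],
    interactions: Iterable[Interaction],
    context_vectors: Iterable[ContextVector] | Mapping[InteractionKey, ContextVector],
    measure: SimilarityMeasure,
    vocabulary: Sequence[str] | None = None,
) -> list[InferredRelation]:
    """Score every inferred (A, C) pair by aggregating its bridges.

    Each bridge's similarity compares the context vectors of its A–B and B–C
    interactions over the global vocabulary (built from all supplied vectors
    when not given). A triple whose interactions lack a context vector is an
    error naming the interaction. An undefined similarity (e.g. Spearman on
    a constant vector) marks the bridge non-meaningful with ``sim = nan``;
    such bridges still count toward the baseline score.
    """
    inter_by_key = {it.key: it for it in interactions}
    if isinstance(context_vectors, Mapping):
        cv_by_key = dict(context_vectors)
    else:
        cv_by_key = {cv.key: cv for cv in context_vectors}
    if vocabulary is None:
        vocabulary = build_vocabulary(cv_by_key.values())

    sim_cache: dict[tuple[InteractionKey, InteractionKey], float] = {}

    def _cv(key: InteractionKey) -> ContextVector:
        try:
            return cv_by_key[key]
        except KeyError:
            raise KeyError(f"missing context vector for interaction {key}") from None

    relations: dict[tuple[str, str], InferredRelation] = {}
    for a, b, c in triples:
        key_ab = canonical_key((a, Level.DRUG), (b, Level.GENE))
        key_bc = canonical_key((b, Level.GENE), (c, Level.DISEASE))
        cache_key = (key_ab, key_bc)
        if cache_key not in sim_cache:
            try:
                sim_cache[cache_key] = measure(_cv(key_ab), _cv(key_bc), vocabulary)
            except UndefinedSimilarityError:
                sim_cache[cache_key] = nan
        sim = sim_cache[cache_key]
        bridge = Bridge(
            gene=b,
            sim=sim,
            freq_ab=inter_by_key[key_ab].frequency,
            freq_bc=inter_by_key[key_bc].frequency,
            meaningful=measure.is_meaningful(sim),
        )
        rel = relations.setdefault((a, c), InferredRelation(drug=a, disease=c))
        rel.bridges.append(bridge)

    out = []
    for (a, c), rel in sorted(relations.items()):
        rel.scores = score_bridges(rel.bridges)
        out.append(rel)
    log.info("scored %d inferred drug-disease relations", len(out))
    return out


def rank(
    relations: Iterable[InferredRelation], score_name: str
) -> list[InferredRelation]:
    """Deterministic ranking: descending score, ties ascending (drug, disease)."""
    if score_name not in SCORE_NAMES:
        raise ValueError(f"unknown score {score_name!r}; expected one of {SCORE_NAMES}")
    rels = list(relations)
    for r in rels:
        if score_name not in r.scores:
            raise ValueError(f"relation {r.drug}-{r.disease} lacks score {score_name!r}")
    return sorted(rels, key=lambda r: (-r.scores[score_name], r.drug, r.disease))


def exclude_direct(
    relations: Iterable[InferredRelation], direct: set[tuple[str, str]]
) -> list[InferredRelation]:
    """Drop candidates whose (drug, disease) pair co-occurs directly in text.

    Classical open-discovery filtering; off by default because curated
    answer sets include already-published pairs.
    """
    return [r for r in relations if (r.drug, r.disease) not in direct]


def write_ranked(
    ranked: Sequence[InferredRelation], score_name: str, path: str | Path
) -> None:
    """TSV: rank, drug_acc, disease_acc, score_name, score, n_bridges,
    best_bridge_gene, best_bridge_sim."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(
            "rank\tdrug_acc\tdisease_acc\tscore_name\tscore\tn_bridges\t"
            "best_bridge_gene\tbest_bridge_sim\n"
        )
        for i, r in enumerate(ranked, start=1):
            best = r.best_bridge
            gene = best.gene if best else ""
            sim = f"{best.sim:.10g}" if best and not isnan(best.sim) else ""
            fh.write(
                f"{i}\t{r.drug}\t{r.disease}\t{score_name}\t"
                f"{r.scores[score_name]:.10g}\t{len(r.bridges)}\t{gene}\t{sim}\n"
            )
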