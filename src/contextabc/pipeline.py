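"""End-to-end pipeline orchestration.

Stages run strictly in order — tag → extract → vectors → infer → rank →
evaluate — and every stage's output is persisted in the run directory, so
each stage is independently inspectable and re-runnable. The pipeline is a
pure function of its inputs and configuration: no clock, locale or hidden
state enters any output, and identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

from . import corpus as corpus_mod
from . import dictionaries as dict_mod
from .dictionaries import EntityDictionary, Role
from .evaluation import DEFAULT_KS, GoldStandard, evaluate_all, load_gold
from .inference import (
    SCORE_NAMES,
    InferredRelation,
    abc_join,
    exclude_direct,
    rank,
    score_relations,
    write_ranked,
)
from .interactions import (
    build_context_vectors,
    direct_pairs,
    extract_interactions,
    write_context_vectors,
    write_interactions,
)
from .similarity import DEFAULT_THRESHOLDS, build_vocabulary, get_measure
from .tagging import context_counts_by_abstract, tag_corpus, write_mentions

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "analyze", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Loadable from a YAML file with the same key hierarchy; CLI flags
    override file values.
    """

    interaction_dictionaries: list[str] = field(default_factory=list)
    context_dictionaries: list[str] = field(default_factory=list)
    corpus: str = ""
    corpus_format: str = "jsonl"  # "jsonl" | "pubmed_xml"
    gold: str | None = None
    output_dir: str = "contextabc_run"
    measure: str = "cosine"
    threshold: float | None = None  # None -> canonical default for the measure
    scores: list[str] = field(default_factory=lambda: list(SCORE_NAMES))
    ks: list[int] = field(default_factory=lambda: list(DEFAULT_KS))
    include_self_terms: bool = False
    exclude_direct: bool = False
    header: bool = False  # dictionary TSVs carry a header line
    seed: int = 0  # used by the simulate subcommand

    def __post_init__(self) -> None:
        if self.threshold is None:
            self.threshold = DEFAULT_THRESHOLDS[self.measure]
        unknown = set(self.scores) - set(SCORE_NAMES)
        if unknown:
            raise ValueError(f"unknown score names: {sorted(unknown)}")
        if any(k < 1 for k in self.ks):
            raise ValueError(f"all k values must be >= 1, got {self.ks}")
        if self.measure == "cosine" and not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"cosine threshold must be in [0,1], got {self.threshold}")
        if self.measure == "spearman" and not -1.0 <= self.threshold <= 1.0:
            raise ValueError(
                f"spearman threshold must be in [-1,1], got {self.threshold}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    """In-memory outputs of every stage of one analysis."""

    corpus: corpus_mod.Corpus
    interaction_mentions: list
    context_mentions: list
    interactions: list
    context_vectors: list
    vocabulary: list[str]
    relations: list[InferredRelation]
    rankings: dict[str, list[InferredRelation]]
    report = None  # populated when a gold standard is evaluated

    def counts(self) -> dict[str, int]:
        return {
            "abstracts": len(self.corpus),
            "interaction_mentions": len(self.interaction_mentions),
            "context_mentions": len(self.context_mentions),
            "interactions": len(self.interactions),
            "context_vocabulary": len(self.vocabulary),
            "relations": len(self.relations),
        }


def analyze(
    c: corpus_mod.Corpus,
    interaction_dictionary: EntityDictionary,
    context_dictionary: EntityDictionary,
    measure_name: str = "cosine",
    threshold: float | None = None,
    *,
    scores: Sequence[str] = SCORE_NAMES,
    include_self_terms: bool = False,
    exclude_direct_pairs: bool = False,
) -> PipelineResult:
    """Run tag → extract → vectors → infer → rank in memory.

    The corpus may arrive unsplit; sentence spans are computed when missing.
    """
    if any(not a.sentences for a in c):
        c = corpus_mod.split_corpus(c)
    measure = get_measure(measure_name, threshold)

    interaction_mentions = tag_corpus(c, interaction_dictionary)
    context_mentions = tag_corpus(c, context_dictionary)

    interactions = extract_interactions(interaction_mentions, c)
    context_counts = context_counts_by_abstract(context_mentions)
    vectors = build_context_vectors(
        interactions, context_counts, include_self_terms=include_self_terms
    )
    vocabulary = build_vocabulary(vectors)
    triples = abc_join(interactions)
    relations = score_relations(triples, interactions, vectors, measure, vocabulary)
    if exclude_direct_pairs:
        relations = exclude_direct(relations, direct_pairs(interaction_mentions))
    rankings = {name: rank(relations, name) for name in scores}
    return PipelineResult(
        corpus=c,
        interaction_mentions=interaction_mentions,
        context_mentions=context_mentions,
        interactions=interactions,
        context_vectors=vectors,
        vocabulary=vocabulary,
        relations=relations,
        rankings=rankings,
    )


def _load_merged(paths: Sequence[str], role: Role, header: bool) -> EntityDictionary:
    if not paths:
        raise ValueError(f"no {role.value} dictionary configured")
    d = dict_mod.load_dictionary(paths[0], role, header=header)
    for p in paths[1:]:
        d = dict_mod.merge(d, dict_mod.load_dictionary(p, role, header=header))
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages from files to files; returns the run summary.

    On a stage failure, previously written outputs are retained and a
    ``failed_stage.txt`` marker names the failed stage before the exception
    propagates.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if config.gold is not None and not Path(config.gold).exists():
            raise FileNotFoundError(f"gold standard file not found: {config.gold}")

        stage = "load"
        interaction_dict = _load_merged(
            config.interaction_dictionaries, Role.INTERACTION, config.header
        )
        context_dict = _load_merged(
            config.context_dictionaries, Role.CONTEXT, config.header
        )
        c = corpus_mod.read_corpus(config.corpus, config.corpus_format)

        stage = "analyze"
        result = analyze(
            c,
            interaction_dict,
            context_dict,
            config.measure,
            config.threshold,
            scores=config.scores,
            include_self_terms=config.include_self_terms,
            exclude_direct_pairs=config.exclude_direct,
        )

        stage = "persist"
        write_mentions(
            result.interaction_mentions + result.context_mentions,
            outdir / "mentions.tsv",
        )
        write_interactions(result.interactions, outdir / "interactions.tsv")
        write_context_vectors(result.context_vectors, outdir / "context_vectors.tsv")
        for name, ranked in result.rankings.items():
            write_ranked(ranked, name, outdir / f"ranked_{name}.tsv")

        summary = {
            "config": asdict(config),
            "counts": result.counts(),
        }

        if config.gold is not None:
            stage = "evaluate"
            gold = load_gold(config.gold)
            report = evaluate_all(result.rankings, gold, config.ks)
            report.to_csv(outdir / "report.tsv", sep="\t", index=False)
            summary["precision"] = {
                f"{row.score_name}@{row.k}": row.precision
                for row in report.itertuples()
            }

        stage = "summary"
        with (outdir / "run_summary.json").open("w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        marker = outdir / "failed_stage.txt"
        if marker.exists():
            marker.unlink()
        return summary
    except Exception:
        (outdir / "failed_stage.txt").write_text(stage + "\n", encoding="utf-8")
        log.error("pipeline failed at stage %r", stage)
        raise
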