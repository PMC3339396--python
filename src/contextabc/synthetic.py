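"""Synthetic test worlds with planted drug–gene–disease chains.

The generator emits everything one end-to-end run needs — entity
dictionaries, an abstract corpus, a gold-standard pair file and a truth
manifest — with full control over the two properties the context-vector
method exploits:

- *coherent* chains: the A–B and B–C interactions of a chain draw their
  abstract context terms from one shared per-chain multinomial (with
  probability ``coherence``; otherwise from the uniform background), so
  their context vectors agree and the bridge passes the similarity filter.
  Their (A, C) pairs form the gold standard.
- *decoy* chains: A–B and B–C contexts come from disjoint distributions, and
  their interaction frequencies are inflated by
  ``decoy_frequency_multiplier`` — they dominate a frequency-only ranking
  but are not gold and should fail the context filter.

Abstracts are templated ("<A> interacts with <B>. <context terms>.") so the
sentence splitter and the dictionary tagger are exercised realistically but
deterministically, and every accession carries two surface synonyms so
synonym collapsing is exercised too. Context terms live at the symptom level
plus a sprinkling of non-chain gene/disease-level terms, mirroring a
multi-level context dictionary. Everything is reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import Abstract, Corpus, write_corpus_jsonl
from .dictionaries import (
    DictionaryEntry,
    EntityDictionary,
    Level,
    Role,
    write_dictionary,
)

log = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "Chain", "World", "generate_world", "truth_manifest", "write_world"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic world.

    Defaults describe a small but non-trivial world: equally many coherent
    and decoy chains, strongly coherent contexts (95% of context draws from
    the chain's own distribution) and decoys five times as frequent as the
    true chains.
    """

    n_drugs: int = 30
    n_genes: int = 30
    n_diseases: int = 30
    n_context_terms: int = 60
    n_coherent_chains: int = 10
    n_decoy_chains: int = 10
    abstracts_per_interaction: int = 3
    context_terms_per_abstract: int = 15
    coherence: float = 0.95
    decoy_frequency_multiplier: float = 5.0
    chain_context_size: int = 5  # terms in each chain's own multinomial
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_drugs": self.n_drugs,
            "n_genes": self.n_genes,
            "n_diseases": self.n_diseases,
            "n_context_terms": self.n_context_terms,
            "n_coherent_chains": self.n_coherent_chains,
            "n_decoy_chains": self.n_decoy_chains,
            "abstracts_per_interaction": self.abstracts_per_interaction,
            "context_terms_per_abstract": self.context_terms_per_abstract,
            "chain_context_size": self.chain_context_size,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError(f"coherence must be in [0, 1], got {self.coherence}")
        if self.decoy_frequency_multiplier < 1.0:
            raise ValueError(
                f"decoy_frequency_multiplier must be >= 1, "
                f"got {self.decoy_frequency_multiplier}"
            )
        n_chains = self.n_coherent_chains + self.n_decoy_chains
        if n_chains > min(self.n_drugs, self.n_genes, self.n_diseases):
            raise ValueError(
                f"{n_chains} chains need at least that many drugs, genes and "
                f"diseases for unique assignment; have "
                f"{self.n_drugs}/{self.n_genes}/{self.n_diseases}"
            )
        if 2 * self.chain_context_size > self.n_context_terms:
            raise ValueError(
                "n_context_terms must be >= 2*chain_context_size so decoy "
                "chains can draw disjoint distributions"
            )


@dataclass(frozen=True)
class Chain:
    """One planted A–B–C chain and its generative parameters."""

    chain_id: str
    kind: str  # "coherent" | "decoy"
    drug: str
    gene: str
    disease: str
    freq_ab: int
    freq_bc: int
    dist_ab: str  # context-distribution id for A-B abstracts
    dist_bc: str
    terms_ab: tuple[str, ...] = field(repr=False)
    terms_bc: tuple[str, ...] = field(repr=False)


@dataclass
class World:
    """A generated world: inputs for every pipeline stage plus ground truth."""

    config: SyntheticConfig
    interaction_dictionary: EntityDictionary
    context_dictionary: EntityDictionary
    corpus: Corpus
    gold_pairs: set[tuple[str, str]]
    chains: list[Chain]


def _accessions(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _synonyms(accession: str) -> tuple[str, str]:
    # Capitalized single tokens: the splitter needs an uppercase sentence
    # start, and normalization lowercases them again before lookup.
    base = accession.lower().capitalize()
    return (base, base + "syn")


# Context levels cycle so most context terms are symptoms but some sit at the
# gene/disease level, like a multi-level context dictionary would.
_CONTEXT_LEVEL_CYCLE = (
    Level.SYMPTOM, Level.SYMPTOM, Level.SYMPTOM, Level.GENE, Level.DISEASE,
)


def generate_world(cfg: SyntheticConfig) -> World:
    """Generate a reproducible world from the configuration's seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    drugs = _accessions("DRG", cfg.n_drugs)
    genes = _accessions("GEN", cfg.n_genes)
    diseases = _accessions("DIS", cfg.n_diseases)
    context_terms = _accessions("CTX", cfg.n_context_terms)

    interaction_dict = EntityDictionary(role=Role.INTERACTION)
    for acc_list, level in ((drugs, Level.DRUG), (genes, Level.GENE),
                            (diseases, Level.DISEASE)):
        for acc in acc_list:
            for syn in _synonyms(acc):
                interaction_dict.add(
                    DictionaryEntry(syn.lower(), acc, level, "synthetic")
                )
    context_dict = EntityDictionary(role=Role.CONTEXT)
    for i, acc in enumerate(context_terms):
        level = _CONTEXT_LEVEL_CYCLE[i % len(_CONTEXT_LEVEL_CYCLE)]
        for syn in _synonyms(acc):
            context_dict.add(DictionaryEntry(syn.lower(), acc, level, "synthetic"))

    n_chains = cfg.n_coherent_chains + cfg.n_decoy_chains
    chain_drugs = [drugs[i] for i in rng.permutation(cfg.n_drugs)[:n_chains]]
    chain_genes = [genes[i] for i in rng.permutation(cfg.n_genes)[:n_chains]]
    chain_diseases = [diseases[i] for i in rng.permutation(cfg.n_diseases)[:n_chains]]

    coherent_freq = cfg.abstracts_per_interaction
    decoy_freq = max(1, round(cfg.abstracts_per_interaction
                              * cfg.decoy_frequency_multiplier))

    chains: list[Chain] = []
    for i in range(n_chains):
        coherent = i < cfg.n_coherent_chains
        cid = f"chain{i:03d}"
        if coherent:
            idx = rng.choice(cfg.n_context_terms, size=cfg.chain_context_size,
                             replace=False)
            terms = tuple(context_terms[j] for j in sorted(idx))
            chains.append(Chain(
                chain_id=cid, kind="coherent",
                drug=chain_drugs[i], gene=chain_genes[i], disease=chain_diseases[i],
                freq_ab=coherent_freq, freq_bc=coherent_freq,
                dist_ab=f"{cid}-shared", dist_bc=f"{cid}-shared",
                terms_ab=terms, terms_bc=terms,
            ))
        else:
            idx = rng.choice(cfg.n_context_terms, size=2 * cfg.chain_context_size,
                             replace=False)
            ab = tuple(context_terms[j] for j in sorted(idx[: cfg.chain_context_size]))
            bc = tuple(context_terms[j] for j in sorted(idx[cfg.chain_context_size:]))
            chains.append(Chain(
                chain_id=cid, kind="decoy",
                drug=chain_drugs[i], gene=chain_genes[i], disease=chain_diseases[i],
                freq_ab=decoy_freq, freq_bc=decoy_freq,
                dist_ab=f"{cid}-ab", dist_bc=f"{cid}-bc",
                terms_ab=ab, terms_bc=bc,
            ))

    abstracts: list[Abstract] = []
    counter = 0

    def _surface(acc: str) -> str:
        return _synonyms(acc)[int(rng.integers(2))]

    def _context_sentence(chain_terms: tuple[str, ...]) -> str:
        words = []
        for _ in range(cfg.context_terms_per_abstract):
            if rng.random() < cfg.coherence:
                acc = chain_terms[int(rng.integers(len(chain_terms)))]
            else:
                acc = context_terms[int(rng.integers(cfg.n_context_terms))]
            words.append(_surface(acc))
        return " ".join(words) + "."

    for chain in chains:
        for e1, e2, freq, terms in (
            (chain.drug, chain.gene, chain.freq_ab, chain.terms_ab),
            (chain.gene, chain.disease, chain.freq_bc, chain.terms_bc),
        ):
            for _ in range(freq):
                counter += 1
                text = (
                    f"{_surface(e1)} interacts with {_surface(e2)}. "
                    f"{_context_sentence(terms)}"
                )
                abstracts.append(Abstract(id=f"SYN{counter:06d}", text=text))

    gold = {(c.drug, c.disease) for c in chains if c.kind == "coherent"}
    log.info(
        "generated world: %d abstracts, %d coherent + %d decoy chains, seed=%d",
        len(abstracts), cfg.n_coherent_chains, cfg.n_decoy_chains, cfg.seed,
    )
    return World(
        config=cfg,
        interaction_dictionary=interaction_dict,
        context_dictionary=context_dict,
        corpus=Corpus(abstracts),
        gold_pairs=gold,
        chains=chains,
    )


def truth_manifest(world: World) -> pd.DataFrame:
    """Per-chain ground truth: type, members, planted frequencies, dist ids."""
    rows = [
        {
            "chain_id": c.chain_id,
            "kind": c.kind,
            "drug": c.drug,
            "gene": c.gene,
            "disease": c.disease,
            "freq_ab": c.freq_ab,
            "freq_bc": c.freq_bc,
            "dist_ab": c.dist_ab,
            "dist_bc": c.dist_bc,
        }
        for c in world.chains
    ]
    return pd.DataFrame(rows)


def write_world(world: World, outdir: str | Path) -> dict[str, Path]:
    """Write the world's files; returns the path of each artifact.

    Emits exactly the formats the pipeline consumes: dictionary TSVs, a
    JSONL corpus, a 2-column gold TSV, and the truth manifest TSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interaction_dictionary": outdir / "interaction_dictionary.tsv",
        "context_dictionary": outdir / "context_dictionary.tsv",
        "corpus": outdir / "corpus.jsonl",
        "gold": outdir / "gold.tsv",
        "manifest": outdir / "manifest.tsv",
        "config": outdir / "world_config.tsv",
    }
    write_dictionary(world.interaction_dictionary, paths["interaction_dictionary"])
    write_dictionary(world.context_dictionary, paths["context_dictionary"])
    write_corpus_jsonl(world.corpus, paths["corpus"])
    with paths["gold"].open("w", encoding="utf-8") as fh:
        for drug, disease in sorted(world.gold_pairs):
            fh.write(f"{drug}\t{disease}\n")
    truth_manifest(world).to_csv(paths["manifest"], sep="\t", index=False)
    cfg_df = pd.DataFrame(
        sorted(asdict(world.config).items()), columns=["key", "value"]
    )
    cfg_df.to_csv(paths["config"], sep="\t", index=False)
    return paths
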