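# Methods

## Model

`contextabc` implements context-filtered ABC inference over a corpus of
biomedical abstracts. The underlying assumptions are:

- A sentence-level co-occurrence of a drug and a gene (or a gene and a
  disease) is evidence of an interaction; the pattern is deliberately
  restricted to drug–gene and gene–disease so that the A–B–C join always
  yields drug–disease candidates (drug repositioning).
- The biomedical entities co-occurring with an interaction *in the same
  abstract* characterize the context in which that interaction is
  discussed. If the A–B literature and the B–C literature discuss their
  interactions in similar contexts, the inferred A–C link is more likely
  to be meaningful than one bridged by a gene whose two literatures are
  unrelated.

The context vector of interaction *i* is the average over its *n*
supporting abstracts of the abstract-level context-term count maps:
CV_i = Σ_j CV_ij / n. Context-term identity is the accession ID, so
synonyms collapse before counting. The interaction's own members are
excluded from its vector by default (`--include-self-terms` reverses
this): a shared member would otherwise manufacture similarity between the
two vectors of every bridge.

Candidates are scored four ways (baseline, sum, max, hybrid; see README).
"Meaningful" uses the strict inequality sim > τ: a bridge exactly at the
threshold is excluded. Candidates with no meaningful bridge keep
similarity-based scores of 0 and rank last rather than being dropped, so
the baseline and filtered rankings are over the same candidate universe
and their precisions are directly comparable.

## Similarity measures

- **Cosine** over the global context vocabulary; 0 is returned when either
  vector has zero norm. Values lie in [0, 1] for count vectors.
- **Spearman** is the standard rank correlation: fractional ranks with
  tie correction, equivalently Pearson correlation of the ranks (computed
  via `scipy.stats.spearmanr`); on untied data this equals
  1 − 6·Σd²/(n(n²−1)). Sparse vectors are densified over the shared
  vocabulary before ranking so that absent terms form an explicit zero tie
  group — this reproduces the fixed global dimension a materialized
  term-space would have, and it is why the vocabulary argument is
  mandatory for Spearman (for cosine zeros are inert). A vector that is
  constant over the vocabulary has no rank ordering; the similarity is
  then *undefined* and signalled with `UndefinedSimilarityError`. During
  inference an undefined bridge similarity is recorded as NaN: the bridge
  is never meaningful but still contributes to the baseline score.

Default thresholds follow the canonical settings of the method: cosine
τ = 0.945 (the alternative answer-set setting used 0.95), Spearman
τ = 0.999999999 (alternative 0.999999998). The Spearman thresholds sit
that close to 1 because, with a vocabulary of hundreds-to-thousands of
terms of which most are zero in both vectors, the zero tie group alone
pushes every rank correlation near 1; only near-exact rank agreement on
the informative terms clears the cutoff. All thresholds are configurable
(`similarity.threshold` / `--threshold`).

## Tagging conventions

The original system used a statistical sentence splitter and HMM-based
NER; this package deliberately uses deterministic components, since the
inference method is agnostic to how mentions were produced:

- Sentence boundaries: terminal `.!?` followed by whitespace and an
  uppercase letter or digit, with an abbreviation exception list ("Dr.",
  "Fig.", "e.g.", ...). The splitter sits behind a one-method interface so
  a statistical splitter can be substituted.
- Dictionary matching is exact on normalized terms (lowercase, collapsed
  whitespace), constrained to token boundaries, with overlaps resolved
  longest-match-first and ties leftmost. A term mapping to several
  accessions or levels emits one mention per mapping; the interaction
  pattern filter resolves the ambiguity downstream.
- Interaction frequency counts co-occurrence *sentences*, not mention
  pairs: repeating a drug three times in one sentence is still one
  incidence. Context counting is abstract-level.

## Synthetic worlds

`generate_world` emulates exactly the statistical structure the method
exploits, not MEDLINE realism. Each planted chain A–B–C contributes
templated abstracts ("&lt;A&gt; interacts with &lt;B&gt;. &lt;context
terms&gt;.") — one co-occurrence sentence plus one context sentence whose
terms are drawn from the chain's multinomial (probability `coherence`) or
the uniform background (1 − `coherence`). Coherent chains share one
distribution between their A–B and B–C abstracts and define the gold
standard; decoy chains use disjoint distributions and appear
`decoy_frequency_multiplier` times as often. Two surface synonyms per
accession exercise synonym collapsing; context terms sit at the symptom
level plus some non-chain gene/disease-level terms, mirroring a
multi-level context dictionary.

Defaults (chosen once as the package's study conditions): 30 drugs, 30
genes, 30 diseases; 60 context terms; 10 coherent + 10 decoy chains, each
chain's multinomial uniform over 5 terms; 3 abstracts per interaction; 15
context draws per abstract; coherence 0.95; decoy multiplier 5. At these
settings the coherent-bridge cosine concentrates near 1 (two averages of
the same concentrated multinomial) and the decoy-bridge cosine near 0
(disjoint supports touching only through background draws), so τ = 0.8 is
used as the operating point for synthetic benchmarks — the midpoint
separating the two regimes, far from both. With coherence 0 and
multiplier 1 the planted signal vanishes and hybrid and baseline rankings
coincide up to ties.

What passing on synthetic worlds does **not** show: robustness to real
abstracts' sentence complexity, synonym ambiguity across levels, skewed
term distributions, or answer-set incompleteness. Published evaluations of
this method family on ~78k disease-specific abstracts against curated
databases report precisions in the sub-1% to ~19% range depending on the
answer set; desk-scale synthetic precisions near 1.0 reflect the planted
separation, not expected field performance.

## Numerical and determinism conventions

- All randomness flows through `numpy.random.default_rng(seed)`; a world
  is byte-identical across runs for the same config.
- Rankings sort by descending score with ties broken ascending by (drug,
  disease) accession, so output order never depends on dict iteration or
  input order; the whole pipeline is a pure function of (inputs, config).
- Interaction keys are canonical (sorted by level then accession); gold
  pairs are canonicalized order-insensitively.
- Floats in TSV outputs are formatted with `%.10g`.
- Degenerate inputs: empty dictionary or unsplit corpus at tagging and
  empty interaction support at vector building raise; empty rankings
  evaluate to precision 0 with a warning; records without abstract text
  and malformed dictionary/gold rows are skipped with warnings.

## Test problem sizes

The default synthetic world (360 abstracts) runs in well under a second,
so property suites run it across 20 seeds; the heavier oracle-equivalence
suites use 100 random corpora of ≤ 20 abstracts against brute-force
recounts. These sizes were chosen to exercise every code path — multi-
sentence abstracts, synonym collapse, decoy dominance — while keeping the
whole suite in seconds.

## Known limitations

- No directionality, negation handling or relation typing: co-occurrence
  is the only evidence unit.
- Exact dictionary matching only — no fuzzy matching or abbreviation
  expansion; recall on real text depends entirely on dictionary coverage.
- Multi-hop chains (beyond one bridge gene) and open-discovery seeding
  are out of scope; `--exclude-direct` provides classical already-known
  filtering but is off by default.
- Accession namespaces of predictions and the gold standard must match;
  no cross-ontology identifier mapping is attempted.
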