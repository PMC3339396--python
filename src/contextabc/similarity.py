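"""Similarity measures between context vectors.

Two measures are supported, both computed over the global context vocabulary
(every context term seen for any interaction): cosine similarity and
Spearman rank correlation. Sparse vectors are densified over the shared
vocabulary before comparison so that zero-valued terms participate — for
Spearman this matters, because absent terms form a large tie group of zeros
whose fractional ranks contribute to the coefficient exactly as they would
with an explicitly materialized fixed-dimension vector.

Spearman is the standard coefficient: fractional ranks, then
1 − 6·Σd²/(n(n²−1)) when ranks are untied, equivalently Pearson correlation
of the ranks, which is what is computed here (and what handles ties
correctly). A vector with all-equal values has no rank ordering, so the
coefficient is undefined; this is signalled with
:class:`UndefinedSimilarityError` rather than silently returning a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .interactions import ContextVector

__all__ = [
    "UndefinedSimilarityError",
    "SimilarityMeasure",
    "cosine",
    "spearman",
    "build_vocabulary",
    "densify",
    "get_measure",
    "DEFAULT_THRESHOLDS",
]

# Meaningfulness cutoffs used in the original evaluation settings
# (PharmGKB-style answer set; the CTD-style setting used 0.95 / 0.999999998).
DEFAULT_THRESHOLDS: dict[str, float] = {
    "cosine": 0.945,
    "spearman": 0.999999999,
}


class UndefinedSimilarityError(ValueError):
    """Raised when a similarity value is mathematically undefined."""


def _as_mapping(v: ContextVector | Mapping[str, float]) -> Mapping[str, float]:
    if isinstance(v, ContextVector):
        return v.values
    return v


def build_vocabulary(vectors: Iterable[ContextVector]) -> list[str]:
    """Sorted union of context terms over all vectors (the global dimension)."""
    vocab: set[str] = set()
    for v in vectors:
        vocab.update(v.values)
    return sorted(vocab)


def densify(
    v: ContextVector | Mapping[str, float], vocabulary: Sequence[str]
) -> np.ndarray:
    """Dense float array of the vector over an ordered vocabulary."""
    m = _as_mapping(v)
    return np.array([m.get(t, 0.0) for t in vocabulary], dtype=float)


def cosine(
    u: ContextVector | Mapping[str, float],
    v: ContextVector | Mapping[str, float],
    vocabulary: Sequence[str] | None = None,
) -> float:
    """Cosine similarity Σu·v / (‖u‖‖v‖); 0.0 when either norm is zero.

    For non-negative context vectors the value lies in [0, 1]. The
    vocabulary is optional for cosine (absent terms contribute nothing);
    when omitted the union of the two key sets is used.
    """
    mu, mv = _as_mapping(u), _as_mapping(v)
    if vocabulary is None:
        vocabulary = sorted(set(mu) | set(mv))
    du, dv = densify(mu, vocabulary), densify(mv, vocabulary)
    nu, nv = np.linalg.norm(du), np.linalg.norm(dv)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(du, dv) / (nu * nv))


def spearman(
    u: ContextVector | Mapping[str, float],
    v: ContextVector | Mapping[str, float],
    vocabulary: Sequence[str],
) -> float:
    """Spearman rank correlation over the shared vocabulary.

    Raises :class:`UndefinedSimilarityError` for a vocabulary of size < 2 or
    when either vector is constant over it (no rank ordering exists).
    """
    if len(vocabulary) < 2:
        raise UndefinedSimilarityError(
            f"spearman needs a vocabulary of size >= 2, got {len(vocabulary)}"
        )
    du, dv = densify(u, vocabulary), densify(v, vocabulary)
    if np.ptp(du) == 0.0 or np.ptp(dv) == 0.0:
        raise UndefinedSimilarityError(
            "spearman undefined: a vector is constant over the vocabulary"
        )
    rho = stats.spearmanr(du, dv).statistic
    return float(rho)


@dataclass(frozen=True)
class SimilarityMeasure:
    """A named similarity measure with its meaningfulness threshold τ.

    A bridge whose similarity strictly exceeds τ is "meaningful" and passes
    the context filter during inference.
    """

    name: str
    threshold: float

    def __post_init__(self) -> None:
        if self.name not in ("cosine", "spearman"):
            raise ValueError(f"unknown similarity measure: {self.name!r}")

    def __call__(
        self,
        u: ContextVector | Mapping[str, float],
        v: ContextVector | Mapping[str, float],
        vocabulary: Sequence[str],
    ) -> float:
        if self.name == "cosine":
            return cosine(u, v, vocabulary)
        return spearman(u, v, vocabulary)

    def is_meaningful(self, sim: float) -> bool:
        return bool(np.isfinite(sim) and sim > self.threshold)


def get_measure(name: str, threshold: float | None = None) -> SimilarityMeasure:
    """Build a measure by name, defaulting τ to the canonical setting."""
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[name]
    return SimilarityMeasure(name=name, threshold=threshold)
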