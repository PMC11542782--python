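"""k-nearest-neighbor SDTM-field suggestion over learned embeddings.

The trained encoder embeds every training field; a query field is answered by
its k nearest training embeddings (exact Euclidean search, default k = 5) and
three decision modes: does the true class appear among the k neighbors at
all, is it the single nearest neighbor's class, and is it the plurality class
of the k.  The three modes correspond to progressively stricter auto-suggest
behaviors and their accuracies are ordered by construction (containment can
never be beaten by the stricter modes).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io import Corpus
from .encoding import concatenate_fields, encode_batch
from .siamese import TrainedEncoder, embed_batch

__all__ = ["ReferenceIndex", "Suggestion", "build_index", "suggest", "decide"]

DEFAULT_K = 5


@dataclass
class ReferenceIndex:
    """Training-set embeddings with aligned labels and source-row identifiers."""

    embeddings: np.ndarray  # (n, embedding_dim)
    labels: list[str]
    record_refs: list[int]

    def __post_init__(self) -> None:
        n = len(self.embeddings)
        if not (n == len(self.labels) == len(self.record_refs)):
            raise ValueError("embeddings, labels and record_refs must align")


@dataclass
class Suggestion:
    """Ranked neighbors plus the three decision-mode answers for one query."""

    neighbors: list[tuple[str, float, int]]  # (label, distance, record_ref) ascending
    nearest_label: str
    majority_label: str
    top_k_labels: set[str]


def build_index(encoder: TrainedEncoder, train_corpus: Corpus, k: int = DEFAULT_K) -> ReferenceIndex:
    """Embed every training record through the shared subnetwork."""
    train_corpus.validate(labeled=True)
    if len(train_corpus) < k:
        raise ValueError(f"need at least k={k} records to build a reference index")
    if encoder.vocab is None:
        raise ValueError("encoder carries no vocabulary; train it with one")
    seqs = encode_batch(
        (concatenate_fields(r) for r in train_corpus),
        encoder.vocab,
        encoder.config.max_len,
    )
    emb = embed_batch(encoder, seqs)
    return ReferenceIndex(
        embeddings=emb,
        labels=[r.label for r in train_corpus],
        record_refs=list(range(len(train_corpus))),
    )


def suggest(index: ReferenceIndex, query: np.ndarray, k: int = DEFAULT_K) -> Suggestion:
    """Exact k-NN by Euclidean distance with reproducible tie handling.

    Distance ties are broken by ascending record_ref; a tied majority vote is
    resolved in favor of the tied class whose member appears earliest in the
    ranked neighbor list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    query = np.asarray(query, dtype=np.float64)
    if query.shape != (index.embeddings.shape[1],):
        raise ValueError(
            f"query dimension {query.shape} does not match index "
            f"({index.embeddings.shape[1]},)"
        )
    d = np.sqrt(np.sum((index.embeddings - query) ** 2, axis=1))
    refs = np.asarray(index.record_refs)
    order = np.lexsort((refs, d))[:k]
    neighbors = [(index.labels[i], float(d[i]), int(refs[i])) for i in order]
    nearest_label = neighbors[0][0]
    votes = Counter(lab for lab, _, _ in neighbors)
    top = max(votes.values())
    tied = {lab for lab, c in votes.items() if c == top}
    majority_label = next(lab for lab, _, _ in neighbors if lab in tied)
    return Suggestion(
        neighbors=neighbors,
        nearest_label=nearest_label,
        majority_label=majority_label,
        top_k_labels={lab for lab, _, _ in neighbors},
    )


def decide(suggestion: Suggestion, true_label: str) -> tuple[bool, bool, bool]:
    """The three decision-mode answers: (contains, nearest_hit, majority_hit)."""
    return (
        true_label in suggestion.top_k_labels,
        suggestion.nearest_label == true_label,
        suggestion.majority_label == true_label,
    )
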