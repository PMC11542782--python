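"""End-to-end glue: corpus → vocabulary → pairs → trained encoder → suggester.

The training side of the pipeline sees only the training corpus: the
vocabulary, the sequence length and every contrastive pair derive from it
alone, so held-out records cannot influence the encoder (the leakage
guarantee the evaluation relies on).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import Corpus, normalize_corpus
from .encoding import Vocabulary, build_vocabulary, concatenate_fields, encode_batch, tokenize
from .pairing import PairSet, generate_pairs
from .siamese import ModelConfig, TrainedEncoder, train_siamese, _forward, _pair_loss

__all__ = ["FittedPipeline", "fit_encoder", "training_pair_accuracy", "encode_corpus"]


@dataclass
class FittedPipeline:
    """A trained encoder plus the training-side artifacts it was fitted on."""

    encoder: TrainedEncoder
    vocab: Vocabulary
    sequences: np.ndarray
    pairs: PairSet
    train_pair_accuracy: float


def encode_corpus(corpus: Corpus, vocab: Vocabulary, max_len: int) -> np.ndarray:
    """Normalize, concatenate and dictionary-encode every record."""
    corpus = normalize_corpus(corpus)
    return encode_batch(
        (concatenate_fields(r) for r in corpus), vocab, max_len
    )


def training_pair_accuracy(
    encoder: TrainedEncoder, sequences: np.ndarray, pairs: PairSet,
    batch_size: int = 512,
) -> float:
    """Thresholded same/different accuracy of the trained model on given pairs."""
    correct = 0
    for start in range(0, len(pairs), batch_size):
        sl = slice(start, start + batch_size)
        Xa = sequences[pairs.a[sl]]
        Xb = sequences[pairs.b[sl]]
        X = np.concatenate([Xa, Xb], axis=0)
        out, _ = _forward(encoder.params, X, keep_cache=False)
        za, zb = out[: len(Xa)], out[len(Xa) :]
        _, _, _, pred = _pair_loss(za, zb, pairs.target[sl], encoder.config)
        correct += int((pred == pairs.target[sl]).sum())
    return correct / len(pairs)


def fit_encoder(
    train_corpus: Corpus,
    model_config: ModelConfig | None = None,
    n_same: int = 20,
    n_diff: int = 20,
    seed: int = 0,
    max_len_cap: int | None = None,
) -> FittedPipeline:
    """Fit the full training side on a labeled corpus.

    The sequence length defaults to the longest concatenated training text
    (optionally capped for memory control); ``model_config``, if given, acts
    as a template whose data-dependent fields (``vocab_size``, ``max_len``)
    are filled in here.  ``seed`` drives pair sampling and, when no template
    carries its own seed, the model initialization and shuffling.
    """
    train_corpus = normalize_corpus(train_corpus)
    train_corpus.validate(labeled=True)
    texts = [concatenate_fields(r) for r in train_corpus]
    vocab = build_vocabulary(texts)
    observed_max = max(len(tokenize(t)) for t in texts)
    max_len = min(observed_max, max_len_cap) if max_len_cap else observed_max
    if model_config is None:
        config = ModelConfig(vocab_size=vocab.size, max_len=max_len, seed=seed)
    else:
        config = replace(model_config, vocab_size=vocab.size, max_len=max_len)
    sequences = encode_batch(texts, vocab, max_len)
    pairs = generate_pairs([r.label for r in train_corpus], n_same, n_diff, seed=seed)
    encoder = train_siamese(pairs, sequences, config, vocab=vocab)
    acc = training_pair_accuracy(encoder, sequences, pairs)
    return FittedPipeline(
        encoder=encoder,
        vocab=vocab,
        sequences=sequences,
        pairs=pairs,
        train_pair_accuracy=acc,
    )
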