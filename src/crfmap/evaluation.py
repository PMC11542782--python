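"""Holdout and cross-validated evaluation of the mapping pipeline.

The headline protocol is a 20% stratified holdout: split first, then build
the vocabulary and contrastive pairs from the training side only, train the
encoder, index the training embeddings and answer every held-out field with
the three k-NN decision modes.  Accuracy and macro-F1 are reported per mode;
per-class accuracy against training support exposes the how-much-data-do-I-
need trend, and a 2-D PCA projection of the embeddings supports visual
inspection of cluster compactness.

Macro-F1 averages over the classes present in the truth set, with the
zero-division → 0 convention.  For the containment mode, which answers a set
question rather than naming one class, the per-record prediction is scored as
the true label when it is contained and as the nearest label otherwise.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .io import Corpus
from .knn import DEFAULT_K, build_index, decide, suggest
from .pairing import stratified_split
from .pipeline import encode_corpus, fit_encoder
from .siamese import ModelConfig, embed_batch

__all__ = [
    "EvalReport",
    "MODES",
    "macro_f1",
    "evaluate_split",
    "evaluate_holdout",
    "cross_validate",
    "support_accuracy_table",
    "pca_project",
]

MODES = ("contains", "nearest", "majority")


@dataclass
class EvalReport:
    """Per-mode accuracy/macro-F1 plus a per-class breakdown of one run."""

    accuracy: dict[str, float]
    macro_f1: dict[str, float]
    per_class: pd.DataFrame
    n_train: int
    n_test: int
    train_pair_accuracy: float
    seed: int
    config: dict
    history: list[dict]

    def to_dict(self) -> dict:
        out = asdict(self)
        out["per_class"] = self.per_class.to_dict(orient="records")
        return out


def macro_f1(true_labels: list[str], predicted_labels: list[str]) -> float:
    """Unweighted mean F1 over the classes present in the truth labels.

    Classes with no true and no predicted positives contribute 0 (they cannot
    occur here since averaging is restricted to observed truth classes, where
    a zero-support class is impossible); zero-division cases score 0.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    if len(true_labels) == 0:
        raise ValueError("cannot compute macro-F1 on empty inputs")
    classes = sorted(set(true_labels))
    return float(
        f1_score(
            true_labels,
            predicted_labels,
            labels=classes,
            average="macro",
            zero_division=0,
        )
    )


def evaluate_split(
    train_corpus: Corpus,
    test_corpus: Corpus,
    model_config: ModelConfig | None = None,
    k: int = DEFAULT_K,
    n_same: int = 20,
    n_diff: int = 20,
    seed: int = 0,
    max_len_cap: int | None = None,
) -> EvalReport:
    """Train on one corpus, score the three k-NN modes on another."""
    fitted = fit_encoder(
        train_corpus,
        model_config=model_config,
        n_same=n_same,
        n_diff=n_diff,
        seed=seed,
        max_len_cap=max_len_cap,
    )
    encoder = fitted.encoder
    index = build_index(encoder, train_corpus, k=k)
    test_seqs = encode_corpus(test_corpus, fitted.vocab, encoder.config.max_len)
    test_emb = embed_batch(encoder, test_seqs)
    truths = [r.label for r in test_corpus]
    hits = {m: [] for m in MODES}
    preds = {m: [] for m in MODES}
    for emb, truth in zip(test_emb, truths):
        sg = suggest(index, emb, k=k)
        contains, nearest_hit, majority_hit = decide(sg, truth)
        hits["contains"].append(contains)
        hits["nearest"].append(nearest_hit)
        hits["majority"].append(majority_hit)
        preds["contains"].append(truth if contains else sg.nearest_label)
        preds["nearest"].append(sg.nearest_label)
        preds["majority"].append(sg.majority_label)
    accuracy = {m: float(np.mean(hits[m])) for m in MODES}
    f1s = {m: macro_f1(truths, preds[m]) for m in MODES}

    train_counts = pd.Series([r.label for r in train_corpus]).value_counts()
    rows = []
    for label in sorted(set(truths)):
        mask = np.asarray([t == label for t in truths])
        rows.append(
            {
                "label": label,
                "train_support": int(train_counts.get(label, 0)),
                "test_count": int(mask.sum()),
                "accuracy": float(np.mean(np.asarray(hits["nearest"])[mask])),
                "unseen_in_train": label not in train_counts.index,
            }
        )
    return EvalReport(
        accuracy=accuracy,
        macro_f1=f1s,
        per_class=pd.DataFrame(rows),
        n_train=len(train_corpus),
        n_test=len(test_corpus),
        train_pair_accuracy=fitted.train_pair_accuracy,
        seed=seed,
        config=asdict(encoder.config),
        history=encoder.history,
    )


def evaluate_holdout(
    corpus: Corpus,
    model_config: ModelConfig | None = None,
    test_fraction: float = 0.2,
    seed: int = 0,
    k: int = DEFAULT_K,
    n_same: int = 20,
    n_diff: int = 20,
    max_len_cap: int | None = None,
) -> EvalReport:
    """The headline protocol: stratified holdout, train-side-only artifacts."""
    split = stratified_split(corpus, test_fraction, seed)
    return evaluate_split(
        split.train,
        split.test,
        model_config=model_config,
        k=k,
        n_same=n_same,
        n_diff=n_diff,
        seed=seed,
        max_len_cap=max_len_cap,
    )


def cross_validate(
    corpus: Corpus,
    folds: int = 5,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    k: int = DEFAULT_K,
    n_same: int = 20,
    n_diff: int = 20,
    max_len_cap: int | None = None,
) -> list[EvalReport]:
    """Stratified k-fold variant; vocabulary and pairs are rebuilt per fold."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    corpus.validate(labeled=True)
    labels = [r.label for r in corpus.records]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        train = Corpus([corpus.records[i] for i in train_idx], source=corpus.source)
        test = Corpus([corpus.records[i] for i in test_idx], source=corpus.source)
        reports.append(
            evaluate_split(
                train,
                test,
                model_config=model_config,
                k=k,
                n_same=n_same,
                n_diff=n_diff,
                seed=seed + fold,
                max_len_cap=max_len_cap,
            )
        )
    return reports


def support_accuracy_table(report: EvalReport, threshold: int = 100) -> dict:
    """Per-class (train_support, accuracy) plus group means around a threshold.

    The default threshold of 100 training examples separates the
    well-supported classes from the data-starved ones.
    """
    per_class = report.per_class[["label", "train_support", "accuracy"]].copy()
    low = per_class[per_class["train_support"] < threshold]["accuracy"]
    high = per_class[per_class["train_support"] >= threshold]["accuracy"]
    return {
        "per_class": per_class,
        "threshold": threshold,
        "mean_accuracy_below": float(low.mean()) if len(low) else float("nan"),
        "mean_accuracy_at_or_above": float(high.mean()) if len(high) else float("nan"),
    }


def pca_project(embeddings: np.ndarray, dims: int = 2) -> np.ndarray:
    """Mean-centered principal-component scores with a fixed sign convention.

    Each component is oriented so its largest-magnitude loading is positive,
    which removes the sign ambiguity of the eigendecomposition.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < dims + 1:
        raise ValueError(f"need at least {dims + 1} vectors for a {dims}-D projection")
    pca = PCA(n_components=dims, svd_solver="full")
    scores = pca.fit_transform(X)
    for j, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            scores[:, j] = -scores[:, j]
    return scores
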