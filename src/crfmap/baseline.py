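"""Lexical baseline: TF-IDF features with a gradient-boosted-tree classifier.

The comparison method represents the conventional approach to field mapping:
bag-of-words TF-IDF vectors over the same concatenated four-field text the
metric-learning pipeline consumes (same normalization, same tokenizer), with
a minimum document frequency of 2, fed to gradient-boosted trees at library
defaults.  Sharing the text pipeline isolates the representational difference
between lexical overlap and learned embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.feature_extraction.text import TfidfVectorizer

from .io import Corpus, CorpusValidationError, normalize_corpus
from .encoding import concatenate_fields, tokenize
from .evaluation import EvalReport, macro_f1
from .pairing import stratified_split
from .siamese import ModelConfig  # noqa: F401  (re-exported for symmetry in examples)

__all__ = ["BaselineModel", "train_baseline", "predict_baseline", "evaluate_baseline"]


@dataclass
class BaselineModel:
    vectorizer: TfidfVectorizer
    classifier: HistGradientBoostingClassifier

    @property
    def feature_vocabulary(self) -> dict[str, int]:
        return dict(self.vectorizer.vocabulary_)


def _texts(corpus: Corpus) -> list[str]:
    return [concatenate_fields(r) for r in normalize_corpus(corpus)]


def train_baseline(train_corpus: Corpus, seed: int = 0) -> BaselineModel:
    """Fit TF-IDF (min document frequency 2) + boosted trees on a labeled corpus."""
    train_corpus.validate(labeled=True)
    if len(train_corpus) < 2:
        raise CorpusValidationError("baseline training needs at least 2 documents")
    if len(train_corpus.label_set()) < 2:
        raise CorpusValidationError("baseline training needs at least 2 labels")
    vectorizer = TfidfVectorizer(analyzer=tokenize, min_df=2)
    X = vectorizer.fit_transform(_texts(train_corpus))
    clf = HistGradientBoostingClassifier(random_state=seed)
    clf.fit(X.toarray(), [r.label for r in train_corpus])
    return BaselineModel(vectorizer=vectorizer, classifier=clf)


def predict_baseline(model: BaselineModel, corpus: Corpus) -> list[str]:
    """One predicted label per record; unseen terms simply contribute nothing."""
    X = model.vectorizer.transform(_texts(corpus))
    return [str(p) for p in model.classifier.predict(X.toarray())]


def evaluate_baseline(
    corpus: Corpus, test_fraction: float = 0.2, seed: int = 0
) -> EvalReport:
    """Holdout evaluation under the exact split discipline of the main pipeline.

    The same (corpus, test_fraction, seed) triple yields byte-identical
    train/test membership as :func:`crfmap.evaluation.evaluate_holdout`, so
    the two reports are head-to-head comparable.  The report carries a single
    accuracy and macro-F1 (no k-NN decision modes).
    """
    split = stratified_split(corpus, test_fraction, seed)
    model = train_baseline(split.train, seed=seed)
    preds = predict_baseline(model, split.test)
    truths = [r.label for r in split.test]
    acc = float(np.mean([p == t for p, t in zip(preds, truths)]))
    import pandas as pd

    train_counts = pd.Series([r.label for r in split.train]).value_counts()
    rows = []
    for label in sorted(set(truths)):
        mask = np.asarray([t == label for t in truths])
        correct = np.asarray([p == t for p, t in zip(preds, truths)])[mask]
        rows.append(
            {
                "label": label,
                "train_support": int(train_counts.get(label, 0)),
                "test_count": int(mask.sum()),
                "accuracy": float(correct.mean()),
                "unseen_in_train": label not in train_counts.index,
            }
        )
    return EvalReport(
        accuracy={"overall": acc},
        macro_f1={"overall": macro_f1(truths, preds)},
        per_class=pd.DataFrame(rows),
        n_train=len(split.train),
        n_test=len(split.test),
        train_pair_accuracy=float("nan"),
        seed=seed,
        config={"method": "tfidf+gbt", "min_df": 2},
        history=[],
    )
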