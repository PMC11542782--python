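"""Leakage-safe splitting and same/different-class pair generation.

The twin-network objective is trained on pairs of fields: a pair whose two
members map to the same SDTM variable carries target 0, a cross-class pair
carries target 1.  Per record, ``n_same`` positive and ``n_diff`` negative
partners are sampled (default 20 + 20), uniformly with replacement across
draws but never pairing a record with itself.

Splitting happens *before* pairing: pairs are generated from one side of the
split only, so no pair can straddle the train/test boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import Corpus, CorpusValidationError

__all__ = ["LabeledSplit", "PairSet", "stratified_split", "generate_pairs"]

logger = logging.getLogger(__name__)


@dataclass
class LabeledSplit:
    """Disjoint train/test corpora with the indices into the source corpus."""

    train: Corpus
    test: Corpus
    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    seed: int
    singleton_labels: list[str]


@dataclass
class PairSet:
    """Encoded index pairs with contrastive targets (0 same class, 1 different).

    ``a`` and ``b`` index into the record list the pairs were generated from;
    callers gather encoded sequences with these indices.
    """

    a: np.ndarray
    b: np.ndarray
    target: np.ndarray

    def __len__(self) -> int:
        return len(self.target)


def stratified_split(corpus: Corpus, test_fraction: float, seed: int) -> LabeledSplit:
    """Per-label proportional holdout split.

    Every label's test share matches ``test_fraction`` within one record;
    labels with ≥ 2 records appear on both sides whenever arithmetic allows,
    and single-record labels go to train (reported via a warning).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    corpus.validate(labeled=True)
    labels = np.asarray([r.label for r in corpus.records])
    if len(set(labels)) < 2:
        raise CorpusValidationError(
            "stratified split requires at least two labels (cross-class pairs "
            "are impossible otherwise)"
        )
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    singletons: list[str] = []
    for label in sorted(set(labels)):
        members = np.flatnonzero(labels == label)
        if len(members) == 1:
            singletons.append(label)
            train_idx.extend(members.tolist())
            continue
        members = rng.permutation(members)
        n_test = int(round(len(members) * test_fraction))
        # keep at least one record on each side when the class allows it
        n_test = min(max(n_test, 1), len(members) - 1)
        test_idx.extend(members[:n_test].tolist())
        train_idx.extend(members[n_test:].tolist())
    if singletons:
        warnings.warn(
            f"{len(singletons)} label(s) with a single record kept in train: "
            f"{singletons}",
            stacklevel=2,
        )
    train_idx_arr = np.sort(np.asarray(train_idx, dtype=np.int64))
    test_idx_arr = np.sort(np.asarray(test_idx, dtype=np.int64))
    return LabeledSplit(
        train=Corpus([corpus.records[i] for i in train_idx_arr], source=corpus.source),
        test=Corpus([corpus.records[i] for i in test_idx_arr], source=corpus.source),
        train_indices=train_idx_arr,
        test_indices=test_idx_arr,
        fraction=test_fraction,
        seed=seed,
        singleton_labels=singletons,
    )


def generate_pairs(
    labels: list[str],
    n_same: int = 20,
    n_diff: int = 20,
    seed: int = 0,
) -> PairSet:
    """Sample per-record positive and negative partners.

    For each record: ``n_same`` partners sharing its label (target 0) and
    ``n_diff`` partners with a different label (target 1), uniform with
    replacement, never the record itself.  A record whose label has no other
    member contributes no positive pairs (logged).  Deterministic given seed.
    """
    if n_same < 1 or n_diff < 1:
        raise ValueError("n_same and n_diff must be >= 1")
    if not labels:
        raise CorpusValidationError("cannot generate pairs from an empty record list")
    lab = np.asarray(labels)
    if len(set(labels)) < 2:
        raise CorpusValidationError("pair generation requires at least two labels")
    rng = np.random.default_rng(seed)
    members = {l: np.flatnonzero(lab == l) for l in set(labels)}
    a_out: list[np.ndarray] = []
    b_out: list[np.ndarray] = []
    t_out: list[np.ndarray] = []
    n_singleton = 0
    for i in range(len(lab)):
        same = members[lab[i]]
        same_others = same[same != i]
        if len(same_others) == 0:
            n_singleton += 1
        else:
            partners = rng.choice(same_others, size=n_same, replace=True)
            a_out.append(np.full(n_same, i, dtype=np.int64))
            b_out.append(partners.astype(np.int64))
            t_out.append(np.zeros(n_same, dtype=np.int64))
        # negatives: uniform over all other-class records via rejection-free
        # index arithmetic on the complement of this record's class
        diff_pool_size = len(lab) - len(same)
        draws = rng.integers(0, diff_pool_size, size=n_diff)
        complement = np.setdiff1d(np.arange(len(lab)), same, assume_unique=False)
        partners = complement[draws]
        a_out.append(np.full(n_diff, i, dtype=np.int64))
        b_out.append(partners.astype(np.int64))
        t_out.append(np.ones(n_diff, dtype=np.int64))
    if n_singleton:
        logger.info("%d record(s) in singleton classes contributed no same-class pairs", n_singleton)
    return PairSet(
        a=np.concatenate(a_out), b=np.concatenate(b_out), target=np.concatenate(t_out)
    )
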