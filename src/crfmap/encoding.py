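"""Text concatenation and dictionary encoding of eCRF field metadata.

The four metadata strings of a field are concatenated into one space-joined
string and dictionary-encoded: the first token observed in the training text
stream receives index 1, the second new token index 2, and so on.  Index 0 is
reserved — it encodes both out-of-vocabulary tokens at prediction time and
right-padding, mirroring how the mapping model treats missing words.

The vocabulary must be built from the *training* split only; tokens that only
occur in held-out data therefore encode to 0, which is exactly the
disjoint-vocabulary failure mode the downstream evaluation probes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .io import FieldRecord

__all__ = [
    "Vocabulary",
    "concatenate_fields",
    "tokenize",
    "build_vocabulary",
    "encode",
    "encode_batch",
    "save_vocabulary",
    "load_vocabulary",
]


@dataclass(frozen=True)
class Vocabulary:
    """First-seen-order token→index map; indices are exactly 1..size."""

    index_of: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.index_of)

    def __contains__(self, token: str) -> bool:
        return token in self.index_of

    def __getitem__(self, token: str) -> int:
        return self.index_of.get(token, 0)


def concatenate_fields(record: FieldRecord) -> str:
    """Join FormOID, FieldOID, PreText, PostText with single spaces.

    Empty fields are skipped so no doubled or trailing spaces appear.
    """
    parts = [record.form_oid, record.field_oid, record.pre_text, record.post_text]
    return " ".join(p for p in parts if p)


# Punctuation trimmed from token edges; underscore is kept because OID-style
# identifiers like AGT_ACTL_DOSE are single semantic units.
_EDGE_PUNCT = ".,;:!?()[]{}<>\"'`~@#$%^&*+=|\\-/"


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip edge punctuation (not ``_``).

    Interior punctuation survives: ``(ddddd.ddd)`` → ``ddddd.ddd`` and
    ``(MM/DD/YYYY)`` → ``mm/dd/yyyy``.
    """
    out = []
    for raw in text.lower().split():
        tok = raw.strip(_EDGE_PUNCT)
        if tok:
            out.append(tok)
    return out


def build_vocabulary(texts: Iterable[str]) -> Vocabulary:
    """Assign indices 1..n to tokens in order of first occurrence.

    ``texts`` must come from the training split only; leakage of held-out
    vocabulary would mask the out-of-vocabulary behavior the model is
    evaluated under.
    """
    index_of: dict[str, int] = {}
    for text in texts:
        for tok in tokenize(text):
            if tok not in index_of:
                index_of[tok] = len(index_of) + 1
    if not index_of:
        raise ValueError("cannot build a vocabulary from an empty token stream")
    return Vocabulary(index_of)


def encode(text: str, vocab: Vocabulary, max_len: int) -> np.ndarray:
    """Map tokens through the vocabulary (unknown→0), pad/truncate to max_len."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    idx = [vocab[t] for t in tokenize(text)[:max_len]]
    seq = np.zeros(max_len, dtype=np.int64)
    seq[: len(idx)] = idx
    return seq


def encode_batch(texts: Iterable[str], vocab: Vocabulary, max_len: int) -> np.ndarray:
    """Stack :func:`encode` outputs into an (n, max_len) integer matrix."""
    return np.stack([encode(t, vocab, max_len) for t in texts])


def save_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(vocab.index_of, ensure_ascii=False, indent=0))


def load_vocabulary(path: str | Path) -> Vocabulary:
    return Vocabulary(json.loads(Path(path).read_text()))
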