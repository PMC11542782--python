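"""Reading, validating and writing labeled eCRF field-metadata corpora.

A corpus is a flat table of electronic case report form (eCRF) fields.  Each
field carries four metadata strings — the form identifier (FormOID), the field
identifier (FieldOID), the human-readable prompt (PreText, possibly containing
HTML markup) and the supplementary hint (PostText, typically a parenthesized
format such as ``(MM/DD/YYYY)``) — plus, for training data, the SDTM variable
the field maps to (e.g. ``AESTDTC``).  Composite targets joined by ``/`` (e.g.
``AESTDTC/CMSTDTC``) are treated as opaque class names.

On disk a corpus is a UTF-8 CSV with header columns ``FormOID``, ``FieldOID``,
``PreText``, ``PostText`` and, when labeled, ``Target``.
"""

from __future__ import annotations

import html
import io as _io
import re
from dataclasses import dataclass, field, replace
from html.parser import HTMLParser
from pathlib import Path

import pandas as pd

__all__ = [
    "FieldRecord",
    "Corpus",
    "CorpusFormatError",
    "CorpusValidationError",
    "read_corpus",
    "write_corpus",
    "strip_html",
    "normalize_record",
]

REQUIRED_COLUMNS = ("FormOID", "FieldOID", "PreText", "PostText")
LABEL_COLUMN = "Target"


class CorpusFormatError(ValueError):
    """The on-disk table does not match the expected CSV schema."""


class CorpusValidationError(ValueError):
    """A record or corpus violates a content invariant."""


@dataclass(frozen=True)
class FieldRecord:
    """One eCRF field's metadata plus its (optional) SDTM target label."""

    form_oid: str
    field_oid: str
    pre_text: str = ""
    post_text: str = ""
    label: str | None = None


@dataclass
class Corpus:
    """An ordered collection of :class:`FieldRecord` with a provenance note."""

    records: list[FieldRecord]
    source: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    def label_set(self) -> set[str]:
        return {r.label for r in self.records if r.label is not None}

    def validate(self, labeled: bool = False) -> None:
        if not self.records:
            raise CorpusValidationError("corpus contains no records")
        for i, r in enumerate(self.records):
            if not r.form_oid.strip() or not r.field_oid.strip():
                raise CorpusValidationError(
                    f"record {i}: FormOID and FieldOID must be non-empty"
                )
            if labeled and (r.label is None or not r.label.strip()):
                raise CorpusValidationError(f"record {i}: empty Target label")


class _TagStripper(HTMLParser):
    def __init__(self) -> None:
        super().__init__(convert_charrefs=True)
        self.chunks: list[str] = []

    def handle_data(self, data: str) -> None:
        self.chunks.append(data)


_WS = re.compile(r"\s+")


def strip_html(text: str) -> str:
    """Remove markup tags, unescape entities and collapse whitespace.

    Best-effort on malformed markup; never raises.
    """
    if not text:
        return ""
    parser = _TagStripper()
    try:
        parser.feed(text)
        parser.close()
        out = "".join(parser.chunks)
    except Exception:  # malformed markup: fall back to a regex sweep
        out = html.unescape(re.sub(r"<[^>]*>", " ", text))
    return _WS.sub(" ", out).strip()


def normalize_record(record: FieldRecord) -> FieldRecord:
    """Strip HTML from all four text fields and trim the OIDs.

    The label is never touched.  Raises :class:`CorpusValidationError` if an
    OID is empty after trimming.
    """
    rec = replace(
        record,
        form_oid=strip_html(record.form_oid),
        field_oid=strip_html(record.field_oid),
        pre_text=strip_html(record.pre_text),
        post_text=strip_html(record.post_text),
    )
    if not rec.form_oid or not rec.field_oid:
        raise CorpusValidationError("FormOID and FieldOID must be non-empty after trimming")
    return rec


def normalize_corpus(corpus: Corpus) -> Corpus:
    """Apply :func:`normalize_record` to every record."""
    return Corpus([normalize_record(r) for r in corpus.records], source=corpus.source)


def read_corpus(path: str | Path, has_labels: bool = True) -> Corpus:
    """Read a corpus CSV.

    Parameters
    ----------
    path
        CSV file with header ``FormOID,FieldOID,PreText,PostText[,Target]``.
    has_labels
        When True the ``Target`` column is required and must be non-empty on
        every row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CorpusValidationError(f"{path}: empty corpus (no rows)") from None
    for col in REQUIRED_COLUMNS + ((LABEL_COLUMN,) if has_labels else ()):
        if col not in df.columns:
            raise CorpusFormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise CorpusValidationError(f"{path}: empty corpus (header only)")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        label = row.get(LABEL_COLUMN, "") if LABEL_COLUMN in df.columns else ""
        if has_labels and not str(label).strip():
            raise CorpusValidationError(f"{path}: row {i + 1}: empty Target label")
        records.append(
            FieldRecord(
                form_oid=row["FormOID"],
                field_oid=row["FieldOID"],
                pre_text=row["PreText"],
                post_text=row["PostText"],
                label=str(label) if str(label) else None,
            )
        )
    return Corpus(records, source=str(path))


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as CSV with RFC-4180 quoting; read_corpus round-trips it."""
    corpus.validate(labeled=False)
    rows = [
        {
            "FormOID": r.form_oid,
            "FieldOID": r.field_oid,
            "PreText": r.pre_text,
            "PostText": r.post_text,
            LABEL_COLUMN: r.label if r.label is not None else "",
        }
        for r in corpus.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
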