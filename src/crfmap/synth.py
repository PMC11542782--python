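"""Synthetic labeled eCRF-metadata corpora with controllable structure.

Real annotated-CRF corpora are proprietary, so this generator fabricates
labeled field tables that reproduce the statistical features the mapping
method has to cope with: OID-style jargon identifiers, natural-phrase
prompts, parenthesized format hints, heavy class-support imbalance,
cross-domain confusable classes that share prompt vocabulary and differ only
in their OIDs (the AEENDTC-vs-CMENDTC situation), occasional HTML markup in
prompts, and partial train/test vocabulary disjointness via injected
never-repeated tokens.

The seed lexicon of clinical-flavored words below is curated but arbitrary;
pseudo-words are synthesized on top of it whenever a configuration needs more
distinct vocabulary than the lexicon holds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io import Corpus, FieldRecord
from .encoding import concatenate_fields, tokenize

__all__ = ["SynthConfig", "GroundTruth", "generate_corpus", "corpus_stats"]

FIGURE4_SUPPORTS = (10, 25, 50, 100, 200)

_DOMAIN_PREFIXES = ["AE", "CM", "MH", "VS", "DM", "LB", "EG", "EX", "DS", "PE"]
_VARIABLE_SUFFIXES = [
    "STDTC", "ENDTC", "ORRES", "ORRESU", "TERM", "DECOD", "DOSE", "DOSU",
    "TRT", "OCCUR", "SEV", "REL", "OUT", "DTC", "CAT", "SCAT", "BODSYS",
    "DOSFRQ", "ROUTE", "STAT",
]

_NATURAL_WORDS = [
    "date", "start", "end", "onset", "resolution", "blood", "pressure",
    "systolic", "diastolic", "heart", "rate", "temperature", "weight",
    "height", "dose", "total", "daily", "unit", "frequency", "route",
    "medication", "drug", "treatment", "event", "adverse", "severity",
    "outcome", "history", "medical", "condition", "diagnosis", "birth",
    "sex", "race", "ethnicity", "visit", "baseline", "screening", "value",
    "result", "measurement", "pulse", "respiratory", "oxygen", "body",
    "mass", "actual", "planned", "ongoing", "serious", "related", "action",
    "taken", "indication", "reason", "term", "verbatim", "preferred",
    "collected", "time", "clinical", "site", "subject", "assessment",
]

_FORMAT_HINTS = [
    "(dd/mm/yyyy)", "(MM/DD/YYYY)", "(MMM dd yyyy)", "(hh:mm)", "(GMT)",
    "(ddddd.ddd)", "(dddddddd)", "(mmHg)", "(bpm)", "(kg)", "(cm)", "(mg)",
    "(mg/dL)", "(beats/min)", "(check one)", "(yes/no)", "(units)",
]

_SYLLABLES = [
    "ba", "co", "da", "dex", "fen", "gly", "lor", "mab", "nib", "pra",
    "quin", "ril", "sol", "tra", "vex", "zol", "mide", "pril", "stat",
    "tide", "zan", "cor", "lin", "dol",
]

_HTML_WRAPPERS = [
    "<b>{}</b>",
    "<i>{}</i>",
    "<span style=\"font-weight:bold\">{}</span>",
    "<p>{}</p>",
    "{}&nbsp;",
]


@dataclass
class SynthConfig:
    """Knobs of the generated world.

    ``class_supports`` is either an explicit per-class record count, or the
    profile ``"balanced"`` (every class gets ``support`` records) or
    ``"figure4"`` (supports cycle through 10/25/50/100/200 to make training
    support an independent variable).  ``shared_token_fraction`` is the
    probability that a prompt word comes from the corpus-wide shared pool
    rather than the class's own pool — the task-difficulty dial.
    ``confusable_groups`` lists class-index sets that share prompt and format
    vocabulary and differ only in their OIDs.  ``variants_per_class`` emulates
    distinct study builds collecting the same variable: each variant carries
    its own OIDs and prompt sub-vocabulary, so classes with few records cover
    only part of their variants in training — the mechanism behind the
    support-accuracy dependence and the OID-heavy out-of-vocabulary failures
    seen in practice.  ``oov_injection_rate`` is the
    fraction of records that receive a never-repeated novel token, so any such
    record landing in a holdout split is out-of-vocabulary by construction.
    """

    n_classes: int = 10
    class_supports: list[int] | str = "balanced"
    support: int = 150
    tokens_per_class: int = 12
    variants_per_class: int = 8
    shared_token_fraction: float = 0.3
    confusable_groups: list[list[int]] = field(default_factory=list)
    oov_injection_rate: float = 0.1
    html_fraction: float = 0.15
    seed: int = 0

    def resolved_supports(self) -> list[int]:
        if isinstance(self.class_supports, str):
            if self.class_supports == "balanced":
                return [self.support] * self.n_classes
            if self.class_supports == "figure4":
                cycle = itertools.cycle(FIGURE4_SUPPORTS)
                return [next(cycle) for _ in range(self.n_classes)]
            raise ValueError(f"unknown support profile {self.class_supports!r}")
        if len(self.class_supports) != self.n_classes:
            raise ValueError("class_supports length must equal n_classes")
        return list(self.class_supports)

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        supports = self.resolved_supports()
        if any(s < 1 for s in supports):
            raise ValueError("all class supports must be >= 1")
        for frac_name in ("shared_token_fraction", "oov_injection_rate", "html_fraction"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must lie in [0, 1]")
        seen: set[int] = set()
        for group in self.confusable_groups:
            for idx in group:
                if not 0 <= idx < self.n_classes:
                    raise ValueError(f"confusable group references invalid class {idx}")
                if idx in seen:
                    raise ValueError(f"class {idx} appears in two confusable groups")
                seen.add(idx)


@dataclass
class GroundTruth:
    """Generated corpus plus the generating class template of each record."""

    corpus: Corpus
    template_ids: list[int]
    class_labels: list[str]
    config: SynthConfig


class _WordFactory:
    """Deterministic supplier of unique pseudo-words."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[str] = set()

    def word(self) -> str:
        while True:
            n = int(self.rng.integers(2, 4))
            w = "".join(self.rng.choice(_SYLLABLES) for _ in range(n))
            if w not in self.used:
                self.used.add(w)
                return w

    def words(self, k: int) -> list[str]:
        return [self.word() for _ in range(k)]


def _abbrev(word: str) -> str:
    return word[:4].upper()


@dataclass
class _BuildVariant:
    """One way a class is collected in some study build: its own OIDs and a
    sub-vocabulary of the class word pool."""

    form_oid: str
    field_oid_options: list[str]
    sub_pool: list[str]
    hint: str


@dataclass
class _ClassTemplate:
    label: str
    variants: list[_BuildVariant]
    word_pool: list[str]       # shared within a confusable group
    hint_pool: list[str]       # shared within a confusable group


def _make_templates(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[list[_ClassTemplate], list[str]]:
    factory = _WordFactory(rng)
    group_of = {}
    for g, group in enumerate(config.confusable_groups):
        for idx in group:
            group_of[idx] = g
    # class labels: confusable groups share a variable suffix across distinct
    # domain prefixes (AEENDTC vs CMENDTC); other classes get distinct combos
    combos = [p + s for p, s in itertools.product(_DOMAIN_PREFIXES, _VARIABLE_SUFFIXES)]
    order = rng.permutation(len(combos))
    labels: dict[int, str] = {}
    used_labels: set[str] = set()
    for group in config.confusable_groups:
        suffix = str(rng.choice(_VARIABLE_SUFFIXES))
        prefixes = rng.choice(_DOMAIN_PREFIXES, size=len(group), replace=False)
        for idx, pref in zip(group, prefixes):
            labels[idx] = pref + suffix
            used_labels.add(pref + suffix)
    it = (combos[i] for i in order)
    for idx in range(config.n_classes):
        if idx not in labels:
            lab = next(l for l in it if l not in used_labels)
            labels[idx] = lab
            used_labels.add(lab)
    # prompt-word pools: one per confusable group plus one per free class,
    # disjoint by construction; the shared pool is its own slice
    lexicon = [str(w) for w in rng.permutation(_NATURAL_WORDS)]
    shared_pool = lexicon[:15]
    remaining = lexicon[15:]

    def take_pool() -> list[str]:
        nonlocal remaining
        pool = remaining[: config.tokens_per_class]
        remaining = remaining[config.tokens_per_class :]
        while len(pool) < config.tokens_per_class:
            pool.append(factory.word())
        return pool

    group_pools: dict[int, list[str]] = {}
    group_hints: dict[int, list[str]] = {}
    templates: list[_ClassTemplate] = []
    for idx in range(config.n_classes):
        g = group_of.get(idx)
        if g is not None and g in group_pools:
            pool, hints = group_pools[g], group_hints[g]
        else:
            pool = take_pool()
            hints = [str(h) for h in rng.choice(_FORMAT_HINTS, size=2, replace=False)]
            if g is not None:
                group_pools[g], group_hints[g] = pool, hints
        # every variant gets its own OIDs from globally unique pseudo-words,
        # so OID token sets are disjoint between classes (and inside a
        # confusable group): the OID is the unambiguous signal — when it is
        # in vocabulary
        variants = []
        for _ in range(config.variants_per_class):
            oid_words = factory.words(4)
            form_oid = "_".join(_abbrev(w) for w in oid_words[:2])
            base = [_abbrev(w) for w in oid_words[2:]]
            sub_size = min(4, len(pool))
            variants.append(
                _BuildVariant(
                    form_oid=form_oid,
                    field_oid_options=[
                        "_".join(base),
                        "_".join(base + ["VAL"]),
                        "_".join(base + ["DT"]),
                    ],
                    sub_pool=[str(w) for w in rng.choice(pool, size=sub_size, replace=False)],
                    hint=str(rng.choice(hints)),
                )
            )
        templates.append(
            _ClassTemplate(
                label=labels[idx],
                variants=variants,
                word_pool=pool,
                hint_pool=hints,
            )
        )
    return templates, shared_pool


def _render_pre_text(
    variant: _BuildVariant, config: SynthConfig, shared_pool: list[str],
    rng: np.random.Generator,
) -> str:
    n_words = int(rng.integers(3, 7))
    words = []
    for _ in range(n_words):
        pool = shared_pool if rng.random() < config.shared_token_fraction else variant.sub_pool
        words.append(str(rng.choice(pool)))
    if rng.random() < 0.5:  # casing noise; tokenization lowercases anyway
        words[0] = words[0].capitalize()
    text = " ".join(words)
    if rng.random() < 0.3:
        text += ":"
    return text


def generate_corpus(config: SynthConfig) -> GroundTruth:
    """Sample a labeled corpus from per-class templates, fully seeded.

    Supports are honored exactly and records are emitted class by class in
    label order, so identical configs yield byte-identical corpora.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    templates, shared_pool = _make_templates(config, rng)
    oov_factory = _WordFactory(np.random.default_rng(config.seed + 9))
    supports = config.resolved_supports()
    records: list[FieldRecord] = []
    template_ids: list[int] = []
    for idx, (template, n) in enumerate(zip(templates, supports)):
        for _ in range(n):
            variant = template.variants[int(rng.integers(len(template.variants)))]
            pre = _render_pre_text(variant, config, shared_pool, rng)
            if rng.random() < config.oov_injection_rate:
                # "x" prefix keeps injected tokens disjoint from every pool:
                # syllable-built pool words never start with x
                pre = pre + " x" + oov_factory.word()
            if rng.random() < config.html_fraction:
                wrapper = str(rng.choice(_HTML_WRAPPERS))
                pre = wrapper.format(pre)
            post = "" if rng.random() < 0.1 else variant.hint
            field_oid = str(rng.choice(variant.field_oid_options))
            records.append(
                FieldRecord(
                    form_oid=variant.form_oid,
                    field_oid=field_oid,
                    pre_text=pre,
                    post_text=post,
                    label=template.label,
                )
            )
            template_ids.append(idx)
    corpus = Corpus(records, source=f"synthetic(seed={config.seed})")
    return GroundTruth(
        corpus=corpus,
        template_ids=template_ids,
        class_labels=[t.label for t in templates],
        config=config,
    )


def corpus_stats(gt: GroundTruth) -> dict:
    """Per-class supports, vocabulary size, prompt-token overlap, max length.

    The overlap matrix holds the Jaccard index of per-class prompt (PreText)
    token sets — confusable classes show up as high off-diagonal entries.
    """
    from .io import normalize_record

    labels = gt.class_labels
    supports = {lab: 0 for lab in labels}
    class_tokens: dict[str, set[str]] = {lab: set() for lab in labels}
    all_tokens: set[str] = set()
    max_len = 0
    for rec in gt.corpus:
        rec_n = normalize_record(rec)
        supports[rec_n.label] += 1
        toks = tokenize(concatenate_fields(rec_n))
        all_tokens.update(toks)
        max_len = max(max_len, len(toks))
        class_tokens[rec_n.label].update(tokenize(rec_n.pre_text))
    n = len(labels)
    overlap = np.zeros((n, n))
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            a, b = class_tokens[li], class_tokens[lj]
            union = a | b
            overlap[i, j] = len(a & b) / len(union) if union else 0.0
    return {
        "supports": supports,
        "vocabulary_size": len(all_tokens),
        "pre_text_overlap": overlap,
        "class_labels": labels,
        "max_concat_tokens": max_len,
    }
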