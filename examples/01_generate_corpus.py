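"""Generate a synthetic annotated-CRF corpus and inspect its structure.

Each record is one eCRF field: OID-style identifiers, a natural-language
prompt (sometimes wrapped in HTML), a parenthesized format hint, and the SDTM
variable it maps to.  The confusable pair below shares prompt vocabulary and
differs only in OIDs — the classic AEENDTC-vs-CMENDTC situation.
"""

from crfmap import SynthConfig, corpus_stats, generate_corpus

config = SynthConfig(
    n_classes=6,
    support=40,
    shared_token_fraction=0.4,
    confusable_groups=[[0, 1]],
    oov_injection_rate=0.0,
    seed=42,
)
gt = generate_corpus(config)

print(f"{len(gt.corpus)} records across {len(gt.corpus.label_set())} SDTM targets\n")
print("three sample fields:")
for rec in (gt.corpus[0], gt.corpus[45], gt.corpus[200]):
    print(f"  {rec.form_oid} | {rec.field_oid} | {rec.pre_text!r} | "
          f"{rec.post_text} -> {rec.label}")

stats = corpus_stats(gt)
print(f"\nvocabulary: {stats['vocabulary_size']} distinct tokens; "
      f"longest concatenated field: {stats['max_concat_tokens']} tokens")

labels = stats["class_labels"]
ov = stats["pre_text_overlap"]
print(f"\nprompt-token Jaccard overlap of the confusable pair "
      f"{labels[0]}/{labels[1]}: {ov[0, 1]:.2f}")
print(f"overlap of an unrelated pair {labels[0]}/{labels[4]}: {ov[0, 4]:.2f}")
print("\n(high overlap means the prompts alone cannot separate the pair; "
      "only the OIDs can)")
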