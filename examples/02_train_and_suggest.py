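"""Train the twin-network encoder and rank SDTM suggestions for new fields.

The encoder learns a 32-d embedding in which fields mapping to the same SDTM
variable sit close together; a query field is answered by its 5 nearest
training neighbors.  Queries carry no label — this is the auto-suggest
deployment mode.
"""

from crfmap import (
    Corpus,
    FieldRecord,
    RunConfig,
    SynthConfig,
    build_index,
    generate_corpus,
    run_train,
    suggest_fields,
)

gt = generate_corpus(SynthConfig(n_classes=6, support=50, seed=7))
fitted = run_train(gt.corpus, RunConfig(seed=7))
print("trained; per-epoch pair loss:",
      [round(h["loss"], 4) for h in fitted.encoder.history])
print(f"within-sample pair accuracy: {fitted.train_pair_accuracy:.4f}")

index = build_index(fitted.encoder, gt.corpus)

# unlabeled queries: two fields re-using known metadata, one entirely novel
queries = Corpus(
    [
        FieldRecord(gt.corpus[0].form_oid, gt.corpus[0].field_oid,
                    gt.corpus[0].pre_text, gt.corpus[0].post_text),
        FieldRecord(gt.corpus[120].form_oid, gt.corpus[120].field_oid,
                    gt.corpus[120].pre_text, ""),
        FieldRecord("NEW_FORM", "NEW_FIELD", "completely unseen wording", ""),
    ]
)
for entry in suggest_fields(fitted.encoder, index, queries, k=5):
    top = entry["neighbors"][0]
    print(f"\n{entry['form_oid']}.{entry['field_oid']}:")
    print(f"  nearest: {top['label']} at distance {top['distance']:.3f}")
    print(f"  majority of top 5: {entry['majority_label']}; "
          f"classes in top 5: {entry['top_k_labels']}")
print("\n(distances near 0 mean the query metadata matches a training field; "
      "the all-unknown query lands wherever the zero-encoded sequence embeds)")
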