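"""Train the tiny span encoder on synthetic data and evaluate decoding.

A small run (160 train docs, 20 epochs) that finishes in about two
minutes; the acceptance script runs the full-size version (500 docs, up
to 30 epochs), which reaches a much higher F1.  From-scratch training
spends its first epochs predicting only NONE, so early stopping is given
a burn-in floor (min_epochs).
"""

from spanccd import (
    DecodeConfig,
    EncoderConfig,
    GenConfig,
    TrainConfig,
    baseline_config,
    decode,
    evaluate_docs,
    generate_corpus,
    make_toy_schema,
    train,
)

schema = make_toy_schema()
docs, _ = generate_corpus(GenConfig(n_docs=200, seed=11), schema)
train_docs, test_docs = docs[:160], docs[160:]

params, log = train(
    train_docs,
    schema,
    EncoderConfig(seed=0),
    TrainConfig(learning_rate=3e-3, seed=0, max_epochs=20, min_epochs=20,
                split_fractions=(0.85, 0.15, 0.0)),
)
best = max(r["val_f1"] for r in log)
print(f"trained {len(log)} epochs; best val F1 = {best:.3f}")

for name, cfg in [("full CCD", DecodeConfig()), ("argmax baseline", baseline_config())]:
    preds = {d.doc_id: decode(d, params, schema, params.config, cfg) for d in test_docs}
    rep = evaluate_docs(preds, test_docs)
    m = rep.micro
    print(f"{name:16s} P={m.precision:.3f} R={m.recall:.3f} F1={m.f1:.3f}")
# The constraint-guided decoder trades a little recall for precision by
# suppressing overlapping / conflicting span sets; at this small training
# size both scores are far below the full-size run.
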