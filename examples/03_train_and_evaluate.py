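"""The full pipeline: generate, split, train, predict, score.

Runs the desk-scale benchmark end to end on the trivial separability
level (every mention is a gazetteer term), where a well-trained model
should approach the F1=100 ceiling.  Takes a few minutes on one CPU.
"""
from pathlib import Path

import pharmaconer as ph

SEED = 11
out = Path("scratch/example-train")

spec = ph.separability_dial(ph.CorpusSpec(n_docs=200, seed=SEED), "trivial")
corpus = ph.generate(spec, out_dir=out / "corpus")

# the two rare classes have too few mentions to learn; drop them and
# target the frequent chemical + protein classes
docs = ph.discard_rare_classes(corpus.docs, ["No_Normalizables", "Unclear"])
train_docs, dev_docs, test_docs = ph.stratified_split(
    docs, ph.SplitSpec(seed=SEED))
print(f"split: {len(train_docs)} train / {len(dev_docs)} dev / "
      f"{len(test_docs)} test documents")

features = ph.FeatureExtractor(
    pos_vocab=ph.PosVocabulary.from_corpus(train_docs),
    gazetteer=ph.load_gazetteer(out / "corpus" / "gazetteer.txt"),
    affixes=ph.load_affixes(out / "corpus" / "affixes.tsv"))
labels = sorted({e.label for d in train_docs for e in d.entities})
config = ph.ModelConfig(labels=labels, d_char=8, d_char_lstm=8,
                        d_token=16, d_token_lstm=24, dropout_rate=0.25,
                        seed=SEED)
model = ph.SequenceTagger(
    config, ph.TokenVocabulary.build(train_docs, dim=16, seed=SEED),
    ph.CharVocabulary.build(train_docs), features)

result = ph.train(train_docs, dev_docs, model,
                  ph.TrainConfig(patience=10, max_epochs=12,
                                 optimizer="adam", learning_rate=0.01,
                                 seed=SEED))
print(f"stopped after {len(result.history)} epochs; "
      f"best dev F1 {result.best_dev_f1:.2f} at epoch {result.best_epoch}")

report = ph.evaluate(test_docs, ph.predict_documents(model, test_docs))
print(ph.report_format(report))

# Precision/recall/F1 are entity-level with strict span+label matching;
# accuracy is per-token.  Dev F1 drives early stopping and checkpoint
# selection, the test block is only touched here at the end.
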