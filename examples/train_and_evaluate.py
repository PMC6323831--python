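"""Train the multi-channel LSTM on the planted-signal corpus and score it.

One repetition of the end-to-end experiment: ontology-channel model vs
words-only baseline on the same train/test split.  Runs in well under a
minute on one CPU.
"""

from ontorel.experiment import run_config
from ontorel.synthetic import (
    SyntheticSpec, corpus_vocabulary, gen_corpus, gen_ontology, gen_vectors,
)

spec = SyntheticSpec(seed=42, n_sentences=300)
onto = gen_ontology(spec)
train_docs, _ = gen_corpus(spec, onto)
test_docs, _ = gen_corpus(spec, onto, n_sentences=120, seed=spec.seed + 577)
vectors = gen_vectors(spec, corpus_vocabulary(train_docs + test_docs))

onto_report = run_config(
    ("concat_ancestors", "common_ancestors"), spec, onto,
    train_docs, test_docs, seed=42,
)
words_report = run_config(
    ("words",), spec, onto, train_docs, test_docs, seed=42, word_vectors=vectors,
)

print("held-out detection scores (positive vs negative):")
print(f"  ontology channels  P={onto_report.detection.precision:.3f} "
      f"R={onto_report.detection.recall:.3f} F1={onto_report.detection.f1:.3f}")
print(f"  words only         P={words_report.detection.precision:.3f} "
      f"R={words_report.detection.recall:.3f} F1={words_report.detection.f1:.3f}")
print("\nLabels are a function of ontology ancestry alone, so the gap shows")
print("the ontology channels carrying information absent from the text.")
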