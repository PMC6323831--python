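"""Detection vs classification scoring and multi-system overlap analysis.

Hand-built predictions over four gold pairs show how a correctly
detected pair with the wrong interaction type is scored, and how the
Venn partition attributes true positives to systems.
"""

from ontorel import CandidatePair, overlap_analysis, score


def pair(name, label, provenance="gold"):
    return CandidatePair(f"{name}a", f"{name}b", label, provenance, "doc1", "s1")


gold = [pair("p1", "effect"), pair("p2", "mechanism"),
        pair("p3", "negative"), pair("p4", "advice")]
pred = [pair("p1", "effect", "predicted"),      # right pair, right type
        pair("p2", "advice", "predicted"),      # right pair, wrong type
        pair("p3", "negative", "predicted"),    # true negative
        pair("p4", "negative", "predicted")]    # missed

report = score(gold, pred)
d, c = report.detection, report.classification
print(f"detection       P={d.precision:.3f} R={d.recall:.3f} F1={d.f1:.3f}")
print(f"classification  P={c.precision:.3f} R={c.recall:.3f} F1={c.f1:.3f}")
print("(a wrong-type positive counts as detection TP but classification FP+FN)")

gold_keys = {p.key for p in gold if p.is_positive}
systems = {
    "words": {pred[0].key},
    "ontology": {pred[0].key, pred[1].key},
}
part = overlap_analysis(gold_keys, systems)
print("\noverlap regions (which systems found which gold pairs):")
for region in sorted(part.regions, key=lambda k: sorted(k)):
    print(f"  {'&'.join(sorted(region))}: {part.regions[region]}")
print("unique true positives per system:", part.unique_true_positives)
print("gold pairs found by no system:", part.global_false_negatives)
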