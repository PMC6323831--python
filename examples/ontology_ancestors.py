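"""Ancestor sequences and fuzzy entity linking on a small ontology.

Builds a six-term is-a DAG, prints the three ancestry representations of
a concept pair, and links a misspelled mention through a synonym.
"""

import pathlib
import tempfile

from ontorel import load_obo

OBO = """format-version: 1.2
ontology: demo

[Term]
id: D:0
name: chemical compound

[Term]
id: D:1
name: amine
is_a: D:0

[Term]
id: D:2
name: aromatic compound
is_a: D:0

[Term]
id: D:3
name: catecholamine
is_a: D:1

[Term]
id: D:4
name: aralkylamino compound
is_a: D:1
is_a: D:2

[Term]
id: D:5
name: dopamine
synonym: "hydroxytyramine" EXACT []
is_a: D:3
"""

path = pathlib.Path(tempfile.mkdtemp()) / "demo.obo"
path.write_text(OBO)
graph = load_obo(path)

print("ancestors(dopamine), most general first, self last:")
print("  ", [graph.concepts[c].label for c in graph.ancestors("D:5")])
print("common_ancestors(dopamine, aralkylamino compound):")
print("  ", [graph.concepts[c].label for c in graph.common_ancestors("D:5", "D:4")])
print("concat_ancestors length:", len(graph.concat_ancestors("D:5", "D:4")),
      "= |Anc(c1)| + |Anc(c2)| with selves appended")

match = graph.link_entity("hydroxytiramine")  # one-letter misspelling
print(f"linking 'hydroxytiramine': {match.concept_id} "
      f"({graph.concepts[match.concept_id].label}), score={match.score:.3f}, "
      f"via {match.matched_via}")
# The score is normalised Levenshtein similarity; matches at or above 0.7
# are accepted, preferring preferred labels over synonyms.
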