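"""Self-contained synthetic fixtures: toy ontology, corpus and word vectors.

The generator plants a recoverable signal: a *marker* concept is chosen
in a random is-a DAG, and a candidate pair is positive exactly when the
marker is a common ancestor of the two linked concepts.  Labels are thus
a deterministic function of ontology ancestry and carry no lexical
footprint — entity surfaces are arbitrary generated names (sometimes
lightly corrupted to exercise fuzzy linking) and filler text is drawn
from a label-independent template vocabulary.  A classifier can
therefore only solve the task through the ontology channels, which is
the property the end-to-end experiment certifies.

Generation is a pure function of the spec: identical specs produce
byte-identical OBO / XML / vector files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np

from .corpus import Document, EntityMention, Sentence, CandidatePair, write_ddi_xml
from .ontology import Concept, OntologyGraph
from .vectors import save_word2vec_text
from .preprocess import simple_tokenize

__all__ = ["SyntheticSpec", "SyntheticOntology", "InfeasibleSpecError",
           "gen_ontology", "gen_corpus", "gen_vectors", "generate_dataset"]


class InfeasibleSpecError(Exception):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    seed: int = 7
    n_concepts: int = 60
    max_depth: int = 4
    branching: int = 3
    n_sentences: int = 500
    positive_rate: float = 0.25
    positive_type: str = "effect"
    label_rule: str = "common_ancestor"  # or "own_ancestor"
    vocab_size: int = 40
    vector_dim: int = 50
    corruption_prob: float = 0.2
    second_parent_prob: float = 0.2


_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu "
    "ka ke ki ko ku la le li lo lu ma me mi mo mu na ne ni no nu "
    "pa pe pi po pu ra re ri ro ru sa se si so su ta te ti to tu "
    "va ve vi vo vu za ze zi zo zu"
).split()


class _NameFactory:
    """Unique pronounceable names, >= 6 characters (so that a single edit
    keeps normalised similarity >= 0.8)."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used: set[str] = set()

    def word(self, n_syllables: int = 3) -> str:
        while True:
            w = "".join(self.rng.choice(_SYLLABLES) for _ in range(n_syllables))
            if w not in self.used:
                self.used.add(w)
                return w


@dataclass
class SyntheticOntology:
    graph: OntologyGraph
    marker: str  # concept planted as the positive-label signal
    obo_text: str


def _concept_id(i: int) -> str:
    return f"SYN:{i:07d}"


def gen_ontology(spec: SyntheticSpec) -> SyntheticOntology:
    """Random is-a DAG with controlled depth/branching and a marker concept.

    Roughly ``second_parent_prob`` of non-root concepts get a second
    parent, exercising multi-parent ancestry.  The marker is the depth>=1
    concept with the most descendants and must have at least two.
    """
    if spec.n_concepts < spec.max_depth + 2:
        raise InfeasibleSpecError("n_concepts must exceed max_depth + 1")
    rng = np.random.default_rng(spec.seed)
    names = _NameFactory(rng)
    depth = [0]
    parents: list[list[int]] = [[]]
    children = [0]
    for i in range(1, spec.n_concepts):
        children.append(0)
        eligible = [j for j in range(i) if depth[j] < spec.max_depth
                    and children[j] < spec.branching]
        if not eligible:
            eligible = [j for j in range(i) if depth[j] < spec.max_depth]
        p = int(rng.choice(eligible))
        ps = [p]
        children[p] += 1
        depth.append(depth[p] + 1)
        if rng.random() < spec.second_parent_prob:
            extra = [j for j in range(i) if j != p and depth[j] < depth[-1]]
            if extra:
                ps.append(int(rng.choice(extra)))
        parents.append(ps)

    concepts = []
    edges = []
    for i in range(spec.n_concepts):
        n_syn = int(rng.integers(0, 3))
        concepts.append(
            Concept(
                id=_concept_id(i),
                label=names.word(),
                synonyms=tuple(names.word() for _ in range(n_syn)),
            )
        )
        edges.extend((_concept_id(i), _concept_id(j)) for j in parents[i])
    graph = OntologyGraph(concepts, edges)

    # descendants per concept via the ancestor relation
    n_desc = {c.id: 0 for c in concepts}
    for c in concepts:
        for a in graph.ancestors(c.id)[:-1]:
            n_desc[a] += 1
    candidates = [
        (n_desc[c.id], c.id) for c in concepts if graph.concept_depth(c.id) >= 1
    ]
    # most-descendants wins, ties broken toward the smallest concept id
    marker = min(candidates, key=lambda t: (-t[0], t[1]))[1]
    if n_desc[marker] < 2:
        raise InfeasibleSpecError("marker concept has fewer than 2 descendants")

    lines = ["format-version: 1.2", ""]
    for c in concepts:
        lines.append("[Term]")
        lines.append(f"id: {c.id}")
        lines.append(f"name: {c.label}")
        for s in c.synonyms:
            lines.append(f'synonym: "{s}" EXACT []')
        for j in parents[int(c.id.split(":")[1])]:
            lines.append(f"is_a: {_concept_id(j)}")
        lines.append("")
    return SyntheticOntology(graph=graph, marker=marker, obo_text="\n".join(lines) + "\n")


def _corrupt(word: str, rng: np.random.Generator) -> str:
    pos = int(rng.integers(0, len(word)))
    if rng.random() < 0.5 and len(word) > 5:
        return word[:pos] + word[pos + 1 :]  # deletion
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    repl = alphabet[int(rng.integers(0, 26))]
    return word[:pos] + repl + word[pos + 1 :]


def _is_positive(graph: OntologyGraph, marker: str, c1: str, c2: str, rule: str) -> bool:
    if rule == "common_ancestor":
        return marker in graph.common_ancestors(c1, c2)
    if rule == "own_ancestor":
        return marker in graph.ancestors(c1) or marker in graph.ancestors(c2)
    raise ValueError(f"unknown label_rule {rule!r}")


def gen_corpus(
    spec: SyntheticSpec,
    ontology: SyntheticOntology,
    n_sentences: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[list[Document], dict[str, str]]:
    """Generate an annotated corpus whose pair labels are planted in ancestry.

    Each sentence carries 2-4 entity mentions whose surfaces are concept
    labels or synonyms, corrupted by one character edit with probability
    ``corruption_prob``.  Returns (documents, entity-id -> intended
    concept-id gold links).  ``n_sentences``/``seed`` default to the
    spec's values; a distinct seed yields an i.i.d. corpus over the same
    ontology (e.g. a held-out test set).
    """
    graph, marker = ontology.graph, ontology.marker
    n_sentences = spec.n_sentences if n_sentences is None else n_sentences
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    inside = [
        c for c in graph.concepts
        if marker in graph.common_ancestors(c, c)  # marker is ancestor-or-self
    ]
    outside = [c for c in graph.concepts if c not in set(inside)]
    if not inside or len(outside) < 4:
        raise InfeasibleSpecError("marker subtree or its complement is too small")
    q = float(np.sqrt(spec.positive_rate))

    filler_rng = np.random.default_rng(spec.seed + 2)
    filler_names = _NameFactory(filler_rng)
    fillers = [filler_names.word(2) for _ in range(spec.vocab_size)]

    documents: list[Document] = []
    links: dict[str, str] = {}
    sents_per_doc = 5
    for s in range(n_sentences):
        d = s // sents_per_doc
        if s % sents_per_doc == 0:
            doc_id = f"SYNDDI.d{d}"
            documents.append(
                Document(id=doc_id, source_type="drugbank" if d % 2 == 0 else "medline")
            )
        doc = documents[-1]
        n_ent = int(rng.integers(2, 5))
        pool_in = list(inside)
        pool_out = list(outside)
        chosen: list[str] = []
        for _ in range(n_ent):
            use_inside = rng.random() < q
            pool = pool_in if use_inside and pool_in else pool_out
            cid = pool.pop(int(rng.integers(0, len(pool))))
            chosen.append(cid)

        words: list[tuple[str, Optional[int]]] = []  # (token, entity slot)
        for k in range(int(rng.integers(1, 3))):
            words.append((fillers[int(rng.integers(0, len(fillers)))], None))
        for e_i, cid in enumerate(chosen):
            concept = graph.concepts[cid]
            surface = concept.label
            if concept.synonyms and rng.random() < 0.3:
                surface = concept.synonyms[int(rng.integers(0, len(concept.synonyms)))]
            if rng.random() < spec.corruption_prob:
                surface = _corrupt(surface, rng)
            words.append((surface, e_i))
            for _ in range(int(rng.integers(1, 4))):
                words.append((fillers[int(rng.integers(0, len(fillers)))], None))

        sid = f"{doc.id}.s{s % sents_per_doc}"
        text_parts: list[str] = []
        offset = 0
        entities: list[EntityMention] = []
        for tok, slot in words:
            if text_parts:
                offset += 1  # joining space
            start = offset
            text_parts.append(tok)
            offset += len(tok)
            if slot is not None:
                eid = f"{sid}.e{slot}"
                entities.append(
                    EntityMention(id=eid, text=tok, char_start=start, char_end=offset - 1)
                )
                links[eid] = chosen[slot]
        text = " ".join(text_parts) + " ."
        sent = Sentence(id=sid, text=text, entities=entities)
        for i in range(n_ent):
            for j in range(i + 1, n_ent):
                positive = _is_positive(graph, marker, chosen[i], chosen[j], spec.label_rule)
                sent.gold_pairs.append(
                    CandidatePair(
                        e1=entities[i].id,
                        e2=entities[j].id,
                        label=spec.positive_type if positive else "negative",
                        provenance="gold",
                        doc_id=doc.id,
                        sentence_id=sid,
                    )
                )
        doc.sentences.append(sent)
    return documents, links


def gen_vectors(
    spec: SyntheticSpec, vocabulary: list[str], seed: Optional[int] = None
) -> tuple[list[str], np.ndarray]:
    """One seeded random unit vector per vocabulary token."""
    rng = np.random.default_rng(spec.seed + 3 if seed is None else seed)
    tokens = sorted(set(vocabulary))
    mat = rng.normal(size=(len(tokens), spec.vector_dim))
    mat /= np.linalg.norm(mat, axis=1, keepdims=True)
    return tokens, mat


def corpus_vocabulary(documents: list[Document]) -> list[str]:
    vocab = set()
    for doc in documents:
        for sent in doc.sentences:
            vocab.update(t.text for t in simple_tokenize(sent.text))
    return sorted(vocab)


def generate_dataset(spec: SyntheticSpec, outdir) -> dict:
    """Write ontology.obo, corpus.xml, vectors.txt and manifest.json.

    Returns the manifest (spec, marker concept, file names, counts,
    entity->concept gold links).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    onto = gen_ontology(spec)
    (out / "ontology.obo").write_text(onto.obo_text)
    documents, links = gen_corpus(spec, onto)
    write_ddi_xml(documents, out / "corpus.xml")
    tokens, mat = gen_vectors(spec, corpus_vocabulary(documents))
    save_word2vec_text(tokens, mat, out / "vectors.txt")
    n_pairs = sum(len(s.gold_pairs) for d in documents for s in d.sentences)
    n_pos = sum(
        p.is_positive for d in documents for s in d.sentences for p in s.gold_pairs
    )
    manifest = {
        "spec": asdict(spec),
        "marker_concept": onto.marker,
        "files": {"ontology": "ontology.obo", "corpus": "corpus.xml", "vectors": "vectors.txt"},
        "n_documents": len(documents),
        "n_pairs": n_pairs,
        "positive_fraction": n_pos / n_pairs if n_pairs else 0.0,
        "gold_links": links,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
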