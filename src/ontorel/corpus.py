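"""Corpus containers and I/O for the SemEval-2013 Task 9 DDI XML dialect.

The dialect nests ``document -> sentence -> entity / pair`` elements.
Entities carry 0-based *inclusive* character offsets (``charOffset``,
possibly semicolon-separated for discontinuous mentions, reduced here to
their first span).  Pairs reference two entity ids and carry a ``ddi``
flag plus an optional interaction ``type`` from {mechanism, effect,
advice, int}.  A candidate pair is unordered: (e1, e2) and (e2, e1) name
the same instance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from lxml import etree

__all__ = [
    "LABELS",
    "POSITIVE_LABELS",
    "NEGATIVE",
    "EntityMention",
    "CandidatePair",
    "Sentence",
    "Document",
    "CorpusError",
    "read_ddi_xml",
    "write_ddi_xml",
    "write_predictions",
    "read_predictions",
    "annotate_genes_by_exact_match",
]

NEGATIVE = "negative"
POSITIVE_LABELS = ("mechanism", "effect", "advice", "int")
LABELS = (NEGATIVE,) + POSITIVE_LABELS


class CorpusError(Exception):
    pass


@dataclass(frozen=True)
class EntityMention:
    id: str
    text: str
    char_start: int  # 0-based inclusive
    char_end: int  # 0-based inclusive
    entity_type: str = "drug"
    concept_id: Optional[str] = None

    def __post_init__(self):
        if self.char_start > self.char_end:
            raise CorpusError(f"entity {self.id}: char_start > char_end")


@dataclass(frozen=True)
class CandidatePair:
    """An unordered pair of co-mentioned entities with a relation label.

    ``provenance`` records how the pair arose: annotated in the corpus
    (``gold``), enumerated from a sentence (``generated``), filtered out
    by a negative-instance rule (``auto_negative``) or produced by a
    classifier (``predicted``).
    """

    e1: str
    e2: str
    label: str = NEGATIVE
    provenance: str = "gold"
    doc_id: str = ""
    sentence_id: str = ""

    def __post_init__(self):
        if self.e1 == self.e2:
            raise CorpusError(f"pair with identical entities: {self.e1}")
        if self.label not in LABELS:
            raise CorpusError(f"unknown pair label {self.label!r}")

    @property
    def key(self) -> tuple[str, str, frozenset]:
        """Order-insensitive identity of the pair within the corpus."""
        return (self.doc_id, self.sentence_id, frozenset((self.e1, self.e2)))

    @property
    def is_positive(self) -> bool:
        return self.label != NEGATIVE

    def relabeled(self, label: str, provenance: str) -> "CandidatePair":
        return replace(self, label=label, provenance=provenance)


@dataclass
class Sentence:
    id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    gold_pairs: list[CandidatePair] = field(default_factory=list)

    def __post_init__(self):
        for e in self.entities:
            if e.char_end >= len(self.text):
                raise CorpusError(
                    f"entity {e.id} offset {e.char_start}-{e.char_end} outside "
                    f"sentence {self.id!r} of length {len(self.text)}"
                )

    def entity_by_id(self, entity_id: str) -> EntityMention:
        for e in self.entities:
            if e.id == entity_id:
                return e
        raise KeyError(entity_id)


@dataclass
class Document:
    id: str
    source_type: str = "other"  # drugbank | medline | other
    sentences: list[Sentence] = field(default_factory=list)


def _infer_source_type(doc_id: str, attr: Optional[str]) -> str:
    if attr:
        return attr.lower()
    lowered = doc_id.lower()
    if "drugbank" in lowered:
        return "drugbank"
    if "medline" in lowered:
        return "medline"
    return "other"


def _first_span(char_offset: str) -> tuple[int, int]:
    first = char_offset.split(";")[0]
    start, end = first.split("-")
    return int(start), int(end)


def read_ddi_xml(path) -> list[Document]:
    """Parse a DDI-dialect XML file into :class:`Document` objects.

    The root element may be a single ``<document>`` or a ``<corpus>``
    wrapping several.  A pair without a ``type`` attribute (or with
    ``ddi="false"``) is negative.  A pair citing an unknown entity id is
    an error.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    doc_elems = [root] if root.tag == "document" else root.findall(".//document")
    documents = []
    for delem in doc_elems:
        doc_id = delem.get("id", "")
        doc = Document(id=doc_id, source_type=_infer_source_type(doc_id, delem.get("origin")))
        for selem in delem.findall("sentence"):
            sid = selem.get("id", "")
            text = selem.get("text", "")
            entities = []
            for eelem in selem.findall("entity"):
                start, end = _first_span(eelem.get("charOffset"))
                entities.append(
                    EntityMention(
                        id=eelem.get("id"),
                        text=text[start : end + 1],
                        char_start=start,
                        char_end=end,
                        entity_type=eelem.get("type", "drug"),
                        concept_id=eelem.get("conceptId"),
                    )
                )
            sent = Sentence(id=sid, text=text, entities=entities)
            known = {e.id for e in entities}
            for pelem in selem.findall("pair"):
                e1, e2 = pelem.get("e1"), pelem.get("e2")
                for eid in (e1, e2):
                    if eid not in known:
                        raise CorpusError(
                            f"pair in sentence {sid} references unknown entity {eid!r}"
                        )
                is_ddi = pelem.get("ddi", "false").lower() == "true"
                label = pelem.get("type") if is_ddi else None
                sent.gold_pairs.append(
                    CandidatePair(
                        e1=e1,
                        e2=e2,
                        label=label or NEGATIVE,
                        provenance="gold",
                        doc_id=doc_id,
                        sentence_id=sid,
                    )
                )
            doc.sentences.append(sent)
        documents.append(doc)
    return documents


def write_ddi_xml(documents: Iterable[Document], path) -> None:
    """Serialise documents back to the DDI XML dialect (corpus root)."""
    root = etree.Element("corpus")
    for doc in documents:
        delem = etree.SubElement(root, "document", id=doc.id, origin=doc.source_type)
        for sent in doc.sentences:
            selem = etree.SubElement(delem, "sentence", id=sent.id, text=sent.text)
            for e in sent.entities:
                attrs = {
                    "id": e.id,
                    "charOffset": f"{e.char_start}-{e.char_end}",
                    "type": e.entity_type,
                    "text": e.text,
                }
                if e.concept_id:
                    attrs["conceptId"] = e.concept_id
                etree.SubElement(selem, "entity", **attrs)
            for i, p in enumerate(sent.gold_pairs):
                attrs = {"id": f"{sent.id}.p{i}", "e1": p.e1, "e2": p.e2}
                if p.is_positive:
                    attrs["ddi"] = "true"
                    attrs["type"] = p.label
                else:
                    attrs["ddi"] = "false"
                etree.SubElement(selem, "pair", **attrs)
    etree.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# -- prediction files --------------------------------------------------


def write_predictions(pairs: Iterable[CandidatePair], path) -> None:
    """Emit one TSV row per pair: doc | sentence | e1 | e2 | flag | type.

    ``flag`` is 1 for a predicted interaction (type column filled) and 0
    otherwise; auto-negatives are emitted with flag 0 and empty type.
    """
    with open(path, "w") as fh:
        for p in pairs:
            if p.provenance not in ("predicted", "auto_negative"):
                raise CorpusError(
                    f"refusing to write pair with provenance {p.provenance!r}"
                )
            flag = 1 if p.is_positive and p.provenance == "predicted" else 0
            type_col = p.label if flag else ""
            fh.write(f"{p.doc_id}\t{p.sentence_id}\t{p.e1}\t{p.e2}\t{flag}\t{type_col}\n")


def read_predictions(path) -> list[CandidatePair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            doc_id, sid, e1, e2, flag, type_col = line.rstrip("\n").split("\t")
            label = type_col if flag == "1" else NEGATIVE
            pairs.append(
                CandidatePair(
                    e1=e1, e2=e2, label=label, provenance="predicted",
                    doc_id=doc_id, sentence_id=sid,
                )
            )
    return pairs


# -- HP-corpus style gene annotation ----------------------------------


def annotate_genes_by_exact_match(
    documents: list[Document],
    lexicon: list[str],
    relation_file: dict[str, set[str]],
    positive_label: str = "int",
) -> list[Document]:
    """Add gene mentions by exact string matching and label gene-phenotype pairs.

    Matching is case-sensitive with word boundaries.  For every sentence,
    each (phenotype-with-concept-id, gene) co-occurrence becomes a gold
    pair: positive (``positive_label``) when the gene symbol appears in
    ``relation_file[phenotype concept id]``, else negative.  Documents are
    modified in place and returned.
    """
    patterns = [(sym, re.compile(r"(?<![\w-])" + re.escape(sym) + r"(?![\w-])")) for sym in lexicon]
    for doc in documents:
        for sent in doc.sentences:
            genes = []
            n = 0
            for sym, pat in patterns:
                for m in pat.finditer(sent.text):
                    gene = EntityMention(
                        id=f"{sent.id}.g{n}",
                        text=sym,
                        char_start=m.start(),
                        char_end=m.end() - 1,
                        entity_type="gene",
                    )
                    genes.append(gene)
                    n += 1
            phenos = [e for e in sent.entities if e.entity_type == "phenotype" and e.concept_id]
            sent.entities.extend(genes)
            for ph in phenos:
                linked = relation_file.get(ph.concept_id, set())
                for g in genes:
                    label = positive_label if g.text in linked else NEGATIVE
                    sent.gold_pairs.append(
                        CandidatePair(
                            e1=ph.id, e2=g.id, label=label, provenance="gold",
                            doc_id=doc.id, sentence_id=sent.id,
                        )
                    )
    return documents
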