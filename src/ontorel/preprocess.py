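"""Turn annotated sentences into classifiable instances.

Pipeline per candidate pair:

1. enumerate all E-choose-2 unordered entity pairs of the sentence;
2. dependency-parse the sentence (pluggable parser) and extract the
   shortest dependency path (SDP) between the two entity head tokens;
3. mask every entity token on the path with a generic token so the model
   cannot memorise entity surface strings;
4. tag each SDP token with a coarse WordNet hypernym class (supersense);
5. link both entities to ontology concepts and attach the
   concatenated-ancestor and common-ancestor sequences;
6. apply the negative-instance filtering rules; filtered pairs skip the
   network and are predicted negative.

The dependency parser and supersense tagger are interfaces: production
runs can adapt an industrial parser/tagger, while the bundled
deterministic implementations keep the whole pipeline self-contained.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from hashlib import md5
from typing import Iterable, Optional, Protocol, Sequence

from .corpus import NEGATIVE, CandidatePair, Document, EntityMention, Sentence
from .ontology import OntologyGraph

__all__ = [
    "Token",
    "DependencyParse",
    "Parser",
    "ChainParser",
    "SupersenseTagger",
    "LexiconSupersenseTagger",
    "SUPERSENSE_INVENTORY",
    "NULL_SUPERSENSE",
    "DEFAULT_MASK_TOKEN",
    "InstanceFeatures",
    "UnmappableEntityError",
    "simple_tokenize",
    "generate_candidate_pairs",
    "shortest_dependency_path",
    "mask_entities",
    "attach_ontology_sequences",
    "filter_negatives",
    "build_anti_positive_list",
    "build_instances",
]

log = logging.getLogger(__name__)

DEFAULT_MASK_TOKEN = "entity"

# 26 WordNet noun lexicographer classes + 15 verb classes = 41 categories.
SUPERSENSE_INVENTORY = tuple(
    "noun." + c
    for c in (
        "Tops act animal artifact attribute body cognition communication event "
        "feeling food group location motive object person phenomenon plant "
        "possession process quantity relation shape state substance time"
    ).split()
) + tuple(
    "verb." + c
    for c in (
        "body change cognition communication competition consumption contact "
        "creation emotion motion perception possession social stative weather"
    ).split()
)
NULL_SUPERSENSE = "0"


class UnmappableEntityError(Exception):
    """An entity mention aligns with no token of the parse."""


@dataclass(frozen=True)
class Token:
    text: str
    char_start: int  # 0-based inclusive
    char_end: int  # 0-based inclusive


@dataclass
class DependencyParse:
    """A single-rooted dependency tree over a token sequence.

    ``heads[i]`` is the index of token i's syntactic head; the root
    points to itself.  ``labels[i]`` is the dependency relation name.
    """

    tokens: list[Token]
    heads: list[int]
    labels: list[str]

    def __post_init__(self):
        n = len(self.tokens)
        if not (len(self.heads) == len(self.labels) == n):
            raise ValueError("tokens/heads/labels length mismatch")
        roots = [i for i, h in enumerate(self.heads) if h == i]
        if n and len(roots) != 1:
            raise ValueError(f"parse must have exactly one root, got {roots}")
        if any(not 0 <= h < n for h in self.heads):
            raise ValueError("head index out of range")
        # a single root whose other nodes each have one head is a tree iff
        # every node reaches the root (no detached cycles)
        for i in range(n):
            seen = set()
            j = i
            while self.heads[j] != j:
                if j in seen:
                    raise ValueError("head graph contains a cycle")
                seen.add(j)
                j = self.heads[j]


class Parser(Protocol):
    def parse(self, sentence_text: str) -> DependencyParse: ...


class SupersenseTagger(Protocol):
    def tag(self, tokens: Sequence[str]) -> list[str]: ...


_TOKEN_RE = re.compile(r"\w+(?:[-'/]\w+)*|[^\w\s]", re.UNICODE)


def simple_tokenize(text: str) -> list[Token]:
    """Deterministic whitespace/punctuation tokenizer with char spans."""
    return [
        Token(m.group(0), m.start(), m.end() - 1) for m in _TOKEN_RE.finditer(text)
    ]


class ChainParser:
    """Deterministic bundled parser: each token's head is its predecessor.

    The resulting right-branching chain is a valid dependency tree on any
    sentence, which makes shortest-path extraction, governor lookup and
    the whole downstream pipeline exercisable without an external
    syntactic model.  The SDP between two tokens is then simply the
    contiguous token span between them.
    """

    def parse(self, sentence_text: str) -> DependencyParse:
        tokens = simple_tokenize(sentence_text)
        heads = [max(i - 1, 0) for i in range(len(tokens))]
        labels = ["root" if i == 0 else "dep" for i in range(len(tokens))]
        return DependencyParse(tokens, heads, labels)


class LexiconSupersenseTagger:
    """Fixed word->class supersense tagger.

    Words found in the lexicon get their assigned class; unknown words
    get a stable pseudo-random class from the 41-category inventory
    (seeded by the word's hash) so that every token carries a category,
    mirroring a real tagger's full coverage.  The mask token and
    punctuation receive the null class.
    """

    def __init__(self, lexicon: Optional[dict[str, str]] = None,
                 mask_token: str = DEFAULT_MASK_TOKEN,
                 hash_unknown: bool = True):
        self.lexicon = dict(lexicon or {})
        for cls in self.lexicon.values():
            if cls not in SUPERSENSE_INVENTORY and cls != NULL_SUPERSENSE:
                raise ValueError(f"class {cls!r} outside the supersense inventory")
        self.mask_token = mask_token
        self.hash_unknown = hash_unknown

    def tag(self, tokens: Sequence[str]) -> list[str]:
        out = []
        for tok in tokens:
            if tok == self.mask_token or not any(c.isalnum() for c in tok):
                out.append(NULL_SUPERSENSE)
            elif tok.lower() in self.lexicon:
                out.append(self.lexicon[tok.lower()])
            elif self.hash_unknown:
                h = int(md5(tok.lower().encode()).hexdigest(), 16)
                out.append(SUPERSENSE_INVENTORY[h % len(SUPERSENSE_INVENTORY)])
            else:
                out.append(NULL_SUPERSENSE)
        return out


@dataclass
class InstanceFeatures:
    """The per-pair model input, one sequence per network channel."""

    pair: CandidatePair
    sdp_tokens: list[str]
    wordnet_classes: list[str]
    concat_ancestor_seq: list[str]
    common_ancestor_seq: list[str]

    def __post_init__(self):
        if len(self.sdp_tokens) != len(self.wordnet_classes):
            raise ValueError("sdp_tokens and wordnet_classes must align")


# -- candidate pairs ---------------------------------------------------


def generate_candidate_pairs(sentence: Sentence, doc_id: str = "") -> list[CandidatePair]:
    """All E-choose-2 unordered entity pairs, labelled from gold pairs."""
    gold = {p.key: p for p in sentence.gold_pairs}
    ents = sorted(sentence.entities, key=lambda e: (e.char_start, e.id))
    pairs = []
    for i in range(len(ents)):
        for j in range(i + 1, len(ents)):
            cand = CandidatePair(
                e1=ents[i].id, e2=ents[j].id, label=NEGATIVE,
                provenance="generated", doc_id=doc_id, sentence_id=sentence.id,
            )
            g = gold.get(cand.key)
            if g is not None:
                cand = cand.relabeled(g.label, "gold")
            pairs.append(cand)
    return pairs


# -- SDP and masking ---------------------------------------------------


def entity_head_token(parse: DependencyParse, entity: EntityMention) -> int:
    """Index of the token whose span contains the mention's last character."""
    for i, tok in enumerate(parse.tokens):
        if tok.char_start <= entity.char_end <= tok.char_end:
            return i
    raise UnmappableEntityError(
        f"entity {entity.id!r} ({entity.text!r} @ {entity.char_start}-{entity.char_end}) "
        "aligns with no token"
    )


def shortest_dependency_path(
    parse: DependencyParse, e1: EntityMention, e2: EntityMention
) -> list[int]:
    """The unique tree path between the two entity head tokens.

    Ordered from e1's side to e2's side, endpoints included.  Computed by
    intersecting the two root-ward head chains at the lowest common
    ancestor.
    """
    t1 = entity_head_token(parse, e1)
    t2 = entity_head_token(parse, e2)

    def chain(i: int) -> list[int]:
        out = [i]
        while parse.heads[i] != i:
            i = parse.heads[i]
            out.append(i)
        return out

    up1, up2 = chain(t1), chain(t2)
    in2 = {tok: k for k, tok in enumerate(up2)}
    for k1, tok in enumerate(up1):
        if tok in in2:
            return up1[: k1 + 1] + up2[: in2[tok]][::-1]
    raise ValueError("tokens share no ancestor; parse is not a tree")


def mask_entities(
    sdp_tokens: Sequence[str],
    entity_positions: Iterable[int],
    mask_token: str = DEFAULT_MASK_TOKEN,
) -> list[str]:
    """Replace every entity token on the path (candidate or not) by the mask."""
    positions = set(entity_positions)
    return [mask_token if i in positions else tok for i, tok in enumerate(sdp_tokens)]


# -- ontology sequences ------------------------------------------------


def attach_ontology_sequences(
    pair: CandidatePair,
    links: dict[str, Optional[str]],
    graph: OntologyGraph,
) -> tuple[list[str], list[str]]:
    """(concatenated-ancestor, common-ancestor) sequences for a pair.

    When either entity lacks a linked concept, both sequences are empty
    and the ontology channels see a blank input.
    """
    c1, c2 = links.get(pair.e1), links.get(pair.e2)
    if not c1 or not c2:
        return [], []
    return graph.concat_ancestors(c1, c2), graph.common_ancestors(c1, c2)


# -- negative-instance filtering --------------------------------------


def _is_punct_or_space(text: str) -> bool:
    return all(
        ch.isspace() or unicodedata.category(ch).startswith("P") for ch in text
    )


def _governor(parse: DependencyParse, entity: EntityMention) -> Optional[str]:
    """Lower-cased head word of the entity's head token (None at root)."""
    t = entity_head_token(parse, entity)
    h = parse.heads[t]
    if h == t:
        return None
    return parse.tokens[h].text.lower()


def filter_negatives(
    pairs: list[CandidatePair],
    sentence: Sentence,
    parse: Optional[DependencyParse] = None,
    anti_positive_list: Iterable[str] = (),
) -> tuple[list[CandidatePair], list[CandidatePair]]:
    """Partition pairs into (kept, auto_negative) by three rules.

    A pair is auto-negative when any rule fires:

    1. both entities have the same text, case-insensitively (a drug does
       not interact with itself);
    2. only punctuation/whitespace separates the two mentions (lists,
       enumerations, abbreviation introductions);
    3. both entities' syntactic governors are on the anti-positive list.

    Auto-negatives are excluded from training and predicted negative at
    inference; nothing is dropped silently.
    """
    anti = set(anti_positive_list)
    kept, auto = [], []
    for pair in pairs:
        a = sentence.entity_by_id(pair.e1)
        b = sentence.entity_by_id(pair.e2)
        first, second = (a, b) if a.char_start <= b.char_start else (b, a)
        fired = a.text.casefold() == b.text.casefold()
        if not fired and first.char_end < second.char_start:
            between = sentence.text[first.char_end + 1 : second.char_start]
            fired = _is_punct_or_space(between)
        if not fired and parse is not None and anti:
            try:
                g1, g2 = _governor(parse, a), _governor(parse, b)
            except UnmappableEntityError:
                g1 = g2 = None
            fired = g1 in anti and g2 in anti
        if fired:
            auto.append(pair.relabeled(pair.label, "auto_negative"))
        else:
            kept.append(pair)
    return kept, auto


def build_anti_positive_list(
    documents: list[Document],
    parses: dict[str, DependencyParse],
    min_count: int = 3,
) -> list[str]:
    """Governor lemmas seen >= min_count times over entities, never over a
    positive pair's entity.

    ``parses`` maps sentence id -> parse.  Lemmas are approximated by
    lower-cased surface forms (the bundled pipeline has no lemmatizer;
    an adapted parser may supply lemmas as token texts).
    """
    counts: dict[str, int] = {}
    ever_positive: set[str] = set()
    for doc in documents:
        for sent in doc.sentences:
            parse = parses.get(sent.id)
            if parse is None:
                continue
            positive_entities = {
                eid
                for p in sent.gold_pairs
                if p.is_positive
                for eid in (p.e1, p.e2)
            }
            for ent in sent.entities:
                try:
                    gov = _governor(parse, ent)
                except UnmappableEntityError:
                    continue
                if gov is None:
                    continue
                counts[gov] = counts.get(gov, 0) + 1
                if ent.id in positive_entities:
                    ever_positive.add(gov)
    return sorted(
        g for g, c in counts.items() if c >= min_count and g not in ever_positive
    )


# -- full pipeline ------------------------------------------------------


def build_instances(
    documents: list[Document],
    graph: Optional[OntologyGraph] = None,
    parser: Optional[Parser] = None,
    tagger: Optional[SupersenseTagger] = None,
    mask_token: str = DEFAULT_MASK_TOKEN,
    link_threshold: float = 0.7,
    filtering: bool = True,
    anti_positive_list: Iterable[str] = (),
) -> tuple[list[InstanceFeatures], list[CandidatePair]]:
    """Run the whole preprocessing pipeline over a corpus.

    Returns (instances for the classifier, auto-negative pairs).  Entity
    mentions keep a corpus-supplied concept id when present; otherwise
    they are fuzzy-linked against the ontology.  Pairs whose entities
    cannot be aligned with the parse are dropped with a warning (the
    documented unmappable-entity behaviour).
    """
    parser = parser or ChainParser()
    tagger = tagger or LexiconSupersenseTagger(mask_token=mask_token)
    link_cache: dict[str, Optional[str]] = {}

    def link(mention_text: str) -> Optional[str]:
        if graph is None:
            return None
        if mention_text not in link_cache:
            m = graph.link_entity(mention_text, threshold=link_threshold)
            link_cache[mention_text] = m.concept_id if m else None
        return link_cache[mention_text]

    instances: list[InstanceFeatures] = []
    auto_all: list[CandidatePair] = []
    for doc in documents:
        for sent in doc.sentences:
            pairs = generate_candidate_pairs(sent, doc_id=doc.id)
            if not pairs:
                continue
            parse = parser.parse(sent.text)
            if filtering:
                kept, auto = filter_negatives(pairs, sent, parse, anti_positive_list)
                auto_all.extend(auto)
            else:
                kept = pairs
            links = {
                e.id: e.concept_id if e.concept_id else link(e.text)
                for e in sent.entities
            }
            # any token overlapping any mention span gets masked on the path
            entity_tokens = {
                i
                for e in sent.entities
                for i, tok in enumerate(parse.tokens)
                if tok.char_start <= e.char_end and e.char_start <= tok.char_end
            }
            for pair in kept:
                e1 = sent.entity_by_id(pair.e1)
                e2 = sent.entity_by_id(pair.e2)
                try:
                    path = shortest_dependency_path(parse, e1, e2)
                except UnmappableEntityError as exc:
                    log.warning("dropping pair %s: %s", pair.key, exc)
                    continue
                raw = [parse.tokens[i].text for i in path]
                on_path_entities = [k for k, i in enumerate(path) if i in entity_tokens]
                sdp = mask_entities(raw, on_path_entities, mask_token)
                classes = tagger.tag(sdp)
                concat_seq, common_seq = attach_ontology_sequences(pair, links, graph) \
                    if graph is not None else ([], [])
                instances.append(
                    InstanceFeatures(
                        pair=pair,
                        sdp_tokens=sdp,
                        wordnet_classes=classes,
                        concat_ancestor_seq=concat_seq,
                        common_ancestor_seq=common_seq,
                    )
                )
    return instances, auto_all
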