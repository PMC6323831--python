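"""Ontology handling: OBO loading, ancestor sequences and fuzzy entity linking.

A biomedical ontology (ChEBI, the Human Phenotype Ontology, the Gene
Ontology, ...) is modelled as a directed acyclic graph whose nodes are
concepts and whose edges are *is-a* (subsumption) relations, which are
transitive.  The ancestors of a concept ``c`` are all concepts reachable
from ``c`` by following is-a edges, i.e. the image of ``c`` under the
transitive closure of the edge relation.

Three sequence representations are derived from ancestry and feed the
corresponding network channels:

* ``ancestors(c)`` -- the ancestor set of ``c`` ordered most-general-first
  (by depth, ties by id), with ``c`` itself in the final position;
* ``common_ancestors(c1, c2)`` -- the intersection of the two ancestor
  sets (the concepts themselves participate only under subsumption or
  equality), same ordering;
* ``concat_ancestors(c1, c2)`` -- the two ``ancestors`` sequences joined
  end to end.

Entity mentions from text are linked to concepts by case-insensitive
normalised Levenshtein similarity against preferred labels, falling back
to synonyms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

import edlib
import networkx as nx
import obonet

__all__ = [
    "Concept",
    "ConceptMatch",
    "OntologyGraph",
    "OntologyError",
    "CycleError",
    "UnknownConceptError",
    "load_obo",
    "levenshtein_similarity",
    "write_ancestor_cache",
    "read_ancestor_cache",
]

DEFAULT_LINK_THRESHOLD = 0.7


class OntologyError(Exception):
    """Base class for ontology problems."""


class CycleError(OntologyError):
    """The is-a relation contains a cycle (ontologies must be DAGs)."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("is-a cycle detected: " + " -> ".join(cycle + cycle[:1]))


class UnknownConceptError(OntologyError, KeyError):
    def __init__(self, concept_id: str):
        self.concept_id = concept_id
        super().__init__(f"unknown concept id: {concept_id!r}")


@dataclass(frozen=True)
class Concept:
    """One ontology term: identifier, preferred label, synonyms."""

    id: str
    label: str
    synonyms: tuple[str, ...] = ()
    obsolete: bool = False


@dataclass(frozen=True)
class ConceptMatch:
    """Result of linking a free-text mention to a concept."""

    concept_id: str
    score: float
    matched_via: str  # "label" or "synonym"


class OntologyGraph:
    """A DAG of concepts connected by is-a edges.

    Only subsumption edges are stored; every other relationship type in
    the source file is dropped.  Edges point child -> parent.
    """

    def __init__(self, concepts: Iterable[Concept], is_a_edges: Iterable[tuple[str, str]]):
        self.concepts: dict[str, Concept] = {c.id: c for c in concepts}
        self.is_a_edges: set[tuple[str, str]] = set(is_a_edges)
        for child, parent in self.is_a_edges:
            for cid in (child, parent):
                if cid not in self.concepts:
                    raise OntologyError(f"edge endpoint {cid!r} is not a known concept")
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        g.add_edges_from(self.is_a_edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise CycleError(cycle)
        self._g = g
        self._depths = self._compute_depths()

    # -- basic queries -------------------------------------------------

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def _require(self, concept_id: str) -> None:
        if concept_id not in self.concepts:
            raise UnknownConceptError(concept_id)

    def parents(self, concept_id: str) -> list[str]:
        self._require(concept_id)
        return sorted(self._g.successors(concept_id))

    def roots(self) -> list[str]:
        return sorted(n for n in self._g if self._g.out_degree(n) == 0)

    def _compute_depths(self) -> dict[str, int]:
        # longest is-a path from any root, DP over a topological order of
        # the parent->child orientation
        depth = {}
        for node in reversed(list(nx.topological_sort(self._g))):
            ps = list(self._g.successors(node))
            depth[node] = 0 if not ps else 1 + max(depth[p] for p in ps)
        return depth

    def concept_depth(self, concept_id: str) -> int:
        """Length of the longest is-a path from a root to the concept."""
        self._require(concept_id)
        return self._depths[concept_id]

    # -- ancestor sequences --------------------------------------------

    def _sort_key(self, concept_id: str) -> tuple[int, str]:
        return (self._depths[concept_id], concept_id)

    @lru_cache(maxsize=None)
    def _ancestor_set(self, concept_id: str) -> frozenset[str]:
        """Proper ancestors (transitive closure image, excluding self)."""
        return frozenset(nx.descendants(self._g, concept_id))

    def ancestors(self, concept_id: str) -> list[str]:
        """Ancestors ordered most-general-first, self in final position."""
        self._require(concept_id)
        anc = sorted(self._ancestor_set(concept_id), key=self._sort_key)
        anc.append(concept_id)
        return anc

    def common_ancestors(self, c1: str, c2: str) -> list[str]:
        """Shared ancestry of two concepts, most-general-first.

        The intersection is taken over ancestor-or-self sets, so the
        concepts themselves appear only when one subsumes the other (or
        ``c1 == c2``, in which case the result equals ``ancestors(c1)``).
        Symmetric in its arguments.
        """
        self._require(c1)
        self._require(c2)
        s1 = self._ancestor_set(c1) | {c1}
        s2 = self._ancestor_set(c2) | {c2}
        return sorted(s1 & s2, key=self._sort_key)

    def concat_ancestors(self, c1: str, c2: str) -> list[str]:
        """``ancestors(c1)`` followed by ``ancestors(c2)``."""
        return self.ancestors(c1) + self.ancestors(c2)

    # -- entity linking ------------------------------------------------

    def link_entity(
        self, mention: str, threshold: float = DEFAULT_LINK_THRESHOLD
    ) -> Optional[ConceptMatch]:
        """Link a text mention to the best-matching non-obsolete concept.

        The best case-insensitive normalised-Levenshtein match against
        preferred labels is accepted when its score reaches ``threshold``.
        Otherwise the best synonym match is considered and returned only
        when it strictly beats the label score; failing that, the label
        match is returned if it reaches the threshold, else no match.
        Ties are broken toward the lexicographically smallest concept id.
        """
        if not mention:
            raise ValueError("mention must be non-empty")
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")

        def best(pairs: Iterable[tuple[str, str]]) -> Optional[tuple[float, str]]:
            top: Optional[tuple[float, str]] = None
            for cid, text in pairs:
                s = levenshtein_similarity(mention, text)
                if top is None or s > top[0] or (s == top[0] and cid < top[1]):
                    top = (s, cid)
            return top

        live = [c for c in self.concepts.values() if not c.obsolete]
        label_best = best((c.id, c.label) for c in live)
        if label_best is None:
            return None
        if label_best[0] >= threshold:
            return ConceptMatch(label_best[1], label_best[0], "label")
        syn_best = best((c.id, s) for c in live for s in c.synonyms)
        if syn_best is not None and syn_best[0] > label_best[0]:
            return ConceptMatch(syn_best[1], syn_best[0], "synonym")
        return None


def levenshtein_similarity(a: str, b: str) -> float:
    """1 - editdist(lower(a), lower(b)) / max(len(a), len(b)), in [0, 1]."""
    a, b = a.lower(), b.lower()
    if not a and not b:
        return 1.0
    d = edlib.align(a, b)["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _parse_synonym(raw: str) -> Optional[str]:
    # OBO synonym lines look like:  "aspirin" EXACT []
    if raw.startswith('"'):
        end = raw.find('"', 1)
        if end > 0:
            return raw[1:end]
    return raw.strip() or None


def load_obo(path) -> OntologyGraph:
    """Load an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Every ``[Term]`` stanza becomes a concept (obsolete terms are kept but
    flagged); only ``is_a`` lines become edges.  Raises :class:`CycleError`
    when the is-a relation is cyclic.
    """
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except (ValueError, KeyError) as exc:  # malformed stanza
        raise OntologyError(f"cannot parse OBO file {path}: {exc}") from exc

    concepts = []
    edges = []
    for node, data in raw.nodes(data=True):
        syns = tuple(
            s for s in (_parse_synonym(x) for x in data.get("synonym", [])) if s
        )
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        concepts.append(
            Concept(id=node, label=data.get("name", node), synonyms=syns, obsolete=obsolete)
        )
        for parent in data.get("is_a", []):
            edges.append((node, parent))
    known = {c.id for c in concepts}
    # is_a targets missing a stanza of their own get a minimal concept
    for _, parent in edges:
        if parent not in known:
            concepts.append(Concept(id=parent, label=parent))
            known.add(parent)
    return OntologyGraph(concepts, edges)


# -- ancestor-sequence cache ------------------------------------------


def write_ancestor_cache(rows: Iterable[tuple[str, str, list[str]]], path) -> None:
    """Write (entity-id, concept-id, ancestor sequence) rows as TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for entity_id, concept_id, seq in rows:
            w.writerow([entity_id, concept_id, "|".join(seq)])


def read_ancestor_cache(path) -> list[tuple[str, str, list[str]]]:
    out = []
    with open(path, newline="") as fh:
        for entity_id, concept_id, seq in csv.reader(fh, delimiter="\t"):
            out.append((entity_id, concept_id, seq.split("|") if seq else []))
    return out
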