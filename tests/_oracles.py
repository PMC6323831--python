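"""Independent brute-force oracles used to verify the graph operations.

Kept deliberately naive: transitive closure by iterated relation
composition until fixpoint, depth by exhaustive path enumeration.
"""

from __future__ import annotations

import numpy as np

from ontorel.ontology import Concept, OntologyGraph


def closure(edges: set[tuple[str, str]]) -> set[tuple[str, str]]:
    """Smallest transitive relation containing ``edges`` (fixpoint iteration)."""
    t = set(edges)
    while True:
        new = {(a, c) for (a, b) in t for (b2, c) in t if b == b2} - t
        if not new:
            return t
        t |= new


def oracle_ancestors(edges: set[tuple[str, str]], node: str) -> set[str]:
    return {a for (c, a) in closure(edges) if c == node}


def oracle_depth(edges: set[tuple[str, str]], nodes: list[str], node: str) -> int:
    """Longest path from any root by exhaustive DFS over parent edges."""
    parents = {n: [] for n in nodes}
    for c, p in edges:
        parents[c].append(p)

    def longest(n: str) -> int:
        return 0 if not parents[n] else 1 + max(longest(p) for p in parents[n])

    return longest(node)


def random_dag(rng: np.random.Generator, n_nodes: int) -> OntologyGraph:
    """Random DAG: node i>=1 gets 1-2 parents among nodes with smaller index."""
    ids = [f"N:{i}" for i in range(n_nodes)]
    concepts = [Concept(id=i, label=i.lower()) for i in ids]
    edges = set()
    for i in range(1, n_nodes):
        n_par = 1 + int(rng.random() < 0.3)
        for j in rng.choice(i, size=min(n_par, i), replace=False):
            edges.add((ids[i], ids[int(j)]))
    return OntologyGraph(concepts, edges)
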