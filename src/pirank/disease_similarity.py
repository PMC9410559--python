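"""Wang-style semantic similarity between disease terms on an ontology DAG.

Each term n induces semantic contributions over T_n, the set containing n and
its ancestors: S_n(n) = 1 and, walking away from n,

    S_n(i) = max { delta * S_n(j) : j child of i, j in T_n }

with decay factor delta = 0.5.  The similarity of two terms is the shared
contribution mass over the total contribution mass:

    S_D(m, n) = sum_{i in T_m ^ T_n} (S_m(i) + S_n(i))
                / (sum_j S_m(j) + sum_j S_n(j)).

Terms with disjoint ancestry (possible in multi-rooted ontologies) get
similarity 0.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .data_io import DataError, OntologyDAG
from .sequence_similarity import SimilarityMatrix

DECAY_FACTOR = 0.5
"""Per-edge decay of a term's semantic contribution to its ancestors."""

__all__ = [
    "DECAY_FACTOR",
    "semantic_contributions",
    "semantic_similarity",
    "disease_similarity_matrix",
]


def semantic_contributions(dag: OntologyDAG, n: str,
                           decay: float = DECAY_FACTOR) -> dict[str, float]:
    """Map each node of T_n = {n} + ancestors(n) to its contribution S_n."""
    if n not in dag:
        raise DataError(f"node {n!r} not in ontology")
    t_n = dag.ancestors(n) | {n}
    sub = dag.graph.subgraph(t_n)
    contributions: dict[str, float] = {}
    # Reverse topological order: children before parents, so every S_n(child)
    # needed by a node is ready when the node is processed.
    for node in reversed(list(nx.topological_sort(sub))):
        if node == n:
            contributions[node] = 1.0
        else:
            contributions[node] = max(
                decay * contributions[child] for child in sub.successors(node)
            )
    return contributions


def semantic_similarity(dag: OntologyDAG, m: str, n: str,
                        decay: float = DECAY_FACTOR) -> float:
    """Similarity in [0, 1]; 1 iff m == n, 0 iff T_m and T_n are disjoint."""
    s_m = semantic_contributions(dag, m, decay)
    s_n = semantic_contributions(dag, n, decay)
    shared = set(s_m) & set(s_n)
    if not shared:
        return 0.0
    numerator = sum(s_m[i] + s_n[i] for i in shared)
    denominator = sum(s_m.values()) + sum(s_n.values())
    return numerator / denominator


def disease_similarity_matrix(dag: OntologyDAG, diseases: list[str],
                              decay: float = DECAY_FACTOR) -> SimilarityMatrix:
    """Square symmetric similarity matrix over the listed disease terms."""
    for d in diseases:
        if d not in dag:
            raise DataError(f"disease {d!r} not in ontology")
    cache = {d: semantic_contributions(dag, d, decay) for d in diseases}
    totals = {d: sum(c.values()) for d, c in cache.items()}
    n = len(diseases)
    values = np.eye(n)
    for i in range(n):
        s_m = cache[diseases[i]]
        for j in range(i + 1, n):
            s_n = cache[diseases[j]]
            shared = set(s_m) & set(s_n)
            if shared:
                num = sum(s_m[x] + s_n[x] for x in shared)
                values[i, j] = values[j, i] = num / (
                    totals[diseases[i]] + totals[diseases[j]]
                )
    return SimilarityMatrix(list(diseases), list(diseases), values)
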