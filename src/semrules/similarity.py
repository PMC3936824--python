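"""Pairwise concept-similarity metrics over ontology DAGs.

Two families are provided:

* The custom exponential path metrics designed for phenotype and disease
  hierarchies.  Both share the form::

      SemSim(c1, c2) = depth(LCA) / (Dist(c1, c2) + depth(LCA))

  where ``depth(LCA)`` is the plain edge-count depth of the lowest common
  ancestor and ``Dist`` is an exponential transform of the taxonomic path
  length ``l`` between the concepts: ``2**l`` for phenotypes and
  ``10**(l-2)`` for diseases (whose hierarchy is only two levels deep, so
  intra-group siblings at ``l = 2`` get distance 1 and similarity 0.5).
  Identical non-root concepts have distance 0 (similarity 1); the root
  compared with itself has distance 1 by convention (similarity 0, since its
  depth is 0).

* The classic baselines: Resnik, Lin and Jiang–Conrath (information-content
  based) and Wu & Palmer (edge based), plus the exact-match indicator that
  reduces every semantic measure to its traditional twin.

When the corpus never annotates any common ancestor of a pair, the
IC-based metrics have an undefined (infinite-IC) MICA; that pair is treated
as completely dissimilar (similarity 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .ontology import CorpusStats, OntologyGraph

__all__ = [
    "METRICS",
    "SimilarityFunction",
    "sem_sim_custom",
    "resnik",
    "lin",
    "jiang_conrath",
    "wu_palmer",
    "exact_sim",
    "clamp01",
]

METRICS = ("exact", "custom", "resnik", "lin", "jiang_conrath", "wu_palmer")


def clamp01(s: float) -> float:
    """Clamp a similarity value into [0, 1]."""
    return min(1.0, max(0.0, s))


def sem_sim_custom(graph: OntologyGraph, c1: str, c2: str) -> float:
    """Custom exponential path similarity; dispatches the distance transform
    on ``graph.kind`` (phenotype vs disease)."""
    graph._check(c1)
    graph._check(c2)
    if c1 == c2:
        if c1 == graph.root:
            return 0.0  # Dist(root, root) = 1 by convention, depth 0
        return 1.0  # Dist = 0
    l = graph.shortest_path_len(c1, c2)
    if graph.kind == "phenotype":
        dist = 2.0**l
    else:
        dist = 10.0 ** (l - 2)
    n3 = graph.depth(graph.lca(c1, c2))
    return n3 / (dist + n3)


def resnik(
    stats: CorpusStats, graph: OntologyGraph, c1: str, c2: str
) -> float:
    """IC of the most informative common ancestor; 0 when the MICA is
    undefined (no common ancestor ever annotated — completely dissimilar).

    Unbounded above; pass through :func:`clamp01` before use in semantic
    support.
    """
    m = graph.mica(stats, c1, c2)
    if m is None:
        return 0.0
    return stats.information_content(m)


def lin(stats: CorpusStats, graph: OntologyGraph, c1: str, c2: str) -> float:
    """Lin similarity ``2*IC(MICA) / (IC(c1) + IC(c2))``.

    0 when the MICA or either concept's IC is undefined.  Note that with
    non-propagated corpus frequencies the MICA can be rarer than the
    concepts themselves, so values above 1 are possible; callers clamp.
    """
    m = graph.mica(stats, c1, c2)
    if m is None:
        return 0.0
    ic1 = stats.information_content(c1)
    ic2 = stats.information_content(c2)
    if ic1 is None or ic2 is None:
        return 0.0
    denom = ic1 + ic2
    if denom == 0.0:
        # both concepts annotate every case; so does the MICA: identity
        return 1.0
    return 2.0 * stats.information_content(m) / denom


def jiang_conrath(
    stats: CorpusStats, graph: OntologyGraph, c1: str, c2: str
) -> float:
    """Bounded Jiang–Conrath similarity ``1 / (1 + d)`` with the JC distance
    ``d = IC(c1) + IC(c2) - 2*IC(MICA)`` clamped at 0.

    Negative distances can arise from non-propagated frequencies (the MICA
    rarer than the concepts); they are clamped so output stays in [0, 1].
    Undefined MICA or IC yields 0.
    """
    m = graph.mica(stats, c1, c2)
    if m is None:
        return 0.0
    ic1 = stats.information_content(c1)
    ic2 = stats.information_content(c2)
    if ic1 is None or ic2 is None:
        return 0.0
    d = max(0.0, ic1 + ic2 - 2.0 * stats.information_content(m))
    return 1.0 / (1.0 + d)


def wu_palmer(graph: OntologyGraph, c1: str, c2: str) -> float:
    """Wu & Palmer similarity ``2*N3 / (N1 + N2 + 2*N3)``.

    ``N3`` is the depth of the LCA; ``N1``/``N2`` are the ascending edge
    counts from each concept to the LCA.  0 when the LCA is the root.
    """
    graph._check(c1)
    graph._check(c2)
    a = graph.lca(c1, c2)
    n3 = graph.depth(a)
    if n3 == 0:
        return 0.0
    n1 = graph.up_distance(c1, a)
    n2 = graph.up_distance(c2, a)
    return 2.0 * n3 / (n1 + n2 + 2.0 * n3)


def exact_sim(i1, i2) -> float:
    """Exact-match indicator: 1 for identical items, else 0."""
    return 1.0 if i1 == i2 else 0.0


@dataclass
class SimilarityFunction:
    """Callable similarity on typed items, dispatching by metric and kind.

    Items are ``mining.Item`` instances (concept + kind).  Pairs of
    different kinds (phenotype vs disease) score 0 under every metric.
    With ``clamp`` on (the default, and required for semantic support) the
    output is confined to [0, 1].

    Results are memoised per concept pair, which matters when scoring
    thousands of rule/transaction combinations.
    """

    metric: str
    phenotype_graph: OntologyGraph | None = None
    disease_graph: OntologyGraph | None = None
    stats: CorpusStats | None = None
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(
                f"unknown metric {self.metric!r}; choose from {METRICS}"
            )
        if self.metric in ("resnik", "lin", "jiang_conrath") and self.stats is None:
            raise ValueError(f"metric {self.metric!r} requires corpus stats")
        self._cache: dict[tuple, float] = {}

    def _graph_for(self, kind: str) -> OntologyGraph:
        g = self.phenotype_graph if kind == "phenotype" else self.disease_graph
        if g is None:
            raise ValueError(f"no {kind} ontology configured for this metric")
        return g

    def __call__(self, i1, i2) -> float:
        if i1.kind != i2.kind:
            return 0.0
        if self.metric == "exact":
            return exact_sim(i1, i2)
        key = (i1.concept, i2.concept, i1.kind)
        if key not in self._cache:
            rkey = (i2.concept, i1.concept, i1.kind)
            self._cache[key] = self._cache[rkey] = self._raw(
                self._graph_for(i1.kind), i1.concept, i2.concept
            )
        return self._cache[key]

    def _raw(self, graph: OntologyGraph, c1: str, c2: str) -> float:
        if self.metric == "custom":
            s = sem_sim_custom(graph, c1, c2)
        elif self.metric == "resnik":
            s = resnik(self.stats, graph, c1, c2)
        elif self.metric == "lin":
            s = lin(self.stats, graph, c1, c2)
        elif self.metric == "jiang_conrath":
            s = jiang_conrath(self.stats, graph, c1, c2)
        elif self.metric == "wu_palmer":
            s = wu_palmer(graph, c1, c2)
        else:  # pragma: no cover
            raise AssertionError(self.metric)
        return clamp01(s) if self.clamp else s


def similarity_matrix(sim: SimilarityFunction, items: list) -> "list[list[float]]":
    """Dense pairwise similarity matrix in the order of ``items``."""
    return [[sim(a, b) for b in items] for a in items]
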