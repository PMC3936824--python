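"""Ontology DAGs and the graph primitives behind every similarity metric.

An :class:`OntologyGraph` is a rooted directed acyclic graph of concepts
linked by subclass (``is_a``) edges, as in the Human Phenotype Ontology or
the Bone Dysplasia Ontology.  All distances used here are taxonomic: a path
between two distinct concepts always ascends from each concept to a common
ancestor, never through arbitrary undirected walks.

Information content is estimated from a clinical corpus: the probability of
a concept is its raw (non-propagated) per-case annotation frequency divided
by the number of cases, and ``IC(c) = -ln p(c)``.  Concepts never annotated
have undefined (conceptually infinite) information content, which callers
receive as ``None``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx
import obonet

__all__ = [
    "OntologyGraph",
    "CorpusStats",
    "OntologyError",
    "load_obo",
    "write_obo",
]


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown concepts."""


@dataclass(frozen=True)
class CorpusStats:
    """Per-concept annotation frequencies over a corpus of patient cases.

    Frequencies are *non-propagated*: a case annotated with a concept counts
    for that exact concept only, not for its ancestors.  Concepts absent from
    ``concept_freq`` have frequency zero.
    """

    case_count: int
    concept_freq: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.case_count < 1:
            raise ValueError(f"case_count must be >= 1, got {self.case_count}")
        for cid, f in self.concept_freq.items():
            if not 0 <= f <= self.case_count:
                raise ValueError(
                    f"frequency of {cid!r} is {f}, outside [0, {self.case_count}]"
                )

    def freq(self, concept: str) -> int:
        return self.concept_freq.get(concept, 0)

    def information_content(self, concept: str) -> float | None:
        """``-ln(freq/case_count)`` in nats, or None when the frequency is 0.

        A zero frequency models the real-corpus situation where a (usually
        generic) concept never appears in any clinical summary; its IC is
        conceptually infinite and is reported as ``None`` rather than raised.
        """
        f = self.freq(concept)
        if f == 0:
            return None
        return -math.log(f / self.case_count)


class OntologyGraph:
    """Rooted subclass DAG over concept identifiers.

    Parameters
    ----------
    edges:
        ``(child, parent)`` subclass pairs.
    labels:
        Optional human-readable names.
    kind:
        ``"phenotype"`` or ``"disease"``; drives the distance transform of
        the custom similarity metric.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        labels: Mapping[str, str] | None = None,
        kind: str = "phenotype",
        concepts: Iterable[str] | None = None,
    ) -> None:
        if kind not in ("phenotype", "disease"):
            raise ValueError(f"kind must be 'phenotype' or 'disease', got {kind!r}")
        self.kind = kind
        g = nx.DiGraph()
        if concepts is not None:
            g.add_nodes_from(concepts)
        for child, parent in edges:
            g.add_edge(child, parent)  # edge direction: child -> parent
        if len(g) == 0:
            raise OntologyError("ontology has no concepts")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"subclass cycle detected: {cycle}")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise OntologyError(
                f"ontology must have exactly one root, found {len(roots)}: "
                f"{sorted(roots)[:5]}"
            )
        self.root: str = roots[0]
        self._g = g
        self.labels: dict[str, str] = dict(labels or {})
        # every concept must reach the root by ascending is_a edges
        unreachable = set(g.nodes) - nx.ancestors(g, self.root) - {self.root}
        if unreachable:
            raise OntologyError(
                f"concepts cannot reach root {self.root!r}: {sorted(unreachable)[:5]}"
            )
        # up-distance maps are the workhorse of every query; cache per concept
        self._updist = lru_cache(maxsize=None)(self._compute_updist)

    # -- basic container protocol -------------------------------------------------

    @property
    def concepts(self) -> set[str]:
        return set(self._g.nodes)

    def __contains__(self, concept: str) -> bool:
        return concept in self._g

    def __len__(self) -> int:
        return len(self._g)

    def parents(self, concept: str) -> set[str]:
        self._check(concept)
        return set(self._g.successors(concept))

    def children(self, concept: str) -> set[str]:
        self._check(concept)
        return set(self._g.predecessors(concept))

    def siblings(self, concept: str) -> set[str]:
        """Concepts sharing at least one parent with ``concept`` (excluded)."""
        self._check(concept)
        sibs: set[str] = set()
        for p in self._g.successors(concept):
            sibs.update(self._g.predecessors(p))
        sibs.discard(concept)
        return sibs

    def subclass_edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges)

    def _check(self, concept: str) -> None:
        if concept not in self._g:
            raise OntologyError(f"unknown concept {concept!r} ({self.kind} ontology)")

    # -- taxonomic queries --------------------------------------------------------

    def _compute_updist(self, concept: str) -> dict[str, int]:
        """Minimum ascending edge count from ``concept`` to each ancestor."""
        return nx.single_source_shortest_path_length(self._g, concept)

    def ancestors(self, concept: str) -> set[str]:
        """All concepts reachable by ascending edges, including ``concept``."""
        self._check(concept)
        return set(self._updist(concept))

    def up_distance(self, concept: str, ancestor: str) -> int | None:
        """Minimum ascending edge count, or None if not an ancestor."""
        self._check(concept)
        self._check(ancestor)
        return self._updist(concept).get(ancestor)

    def depth(self, concept: str) -> int:
        """Minimum number of subclass edges from ``concept`` to the root."""
        self._check(concept)
        return self._updist(concept)[self.root]

    def shortest_path_len(self, c1: str, c2: str) -> int:
        """Taxonomic distance: shortest ascent from each concept to a shared
        ancestor, minimised over all common ancestors; 0 for identical concepts."""
        self._check(c1)
        self._check(c2)
        if c1 == c2:
            return 0
        d1, d2 = self._updist(c1), self._updist(c2)
        common = d1.keys() & d2.keys()
        return min(d1[a] + d2[a] for a in common)

    def lca(self, c1: str, c2: str) -> str:
        """Lowest common ancestor: common ancestor of maximal depth.

        Each concept counts as its own ancestor.  Ties (possible under
        multiple inheritance) break lexicographically on the concept ID.
        """
        self._check(c1)
        self._check(c2)
        common = self._updist(c1).keys() & self._updist(c2).keys()
        return min(common, key=lambda a: (-self.depth(a), a))

    def mica(self, stats: CorpusStats, c1: str, c2: str) -> str | None:
        """Most informative common ancestor under corpus-derived IC.

        Only common ancestors with nonzero corpus frequency qualify; when
        none exists the MICA is undefined (returns None) — the situation the
        Resnik and Lin metrics cannot handle.  Ties break by higher IC, then
        greater depth, then lexicographic ID.
        """
        self._check(c1)
        self._check(c2)
        common = self._updist(c1).keys() & self._updist(c2).keys()
        candidates = [a for a in common if stats.freq(a) > 0]
        if not candidates:
            return None
        return min(
            candidates,
            key=lambda a: (-stats.information_content(a), -self.depth(a), a),
        )


def load_obo(path, kind: str = "phenotype") -> OntologyGraph:
    """Load an OBO 1.2 flat file into a validated :class:`OntologyGraph`.

    Only ``[Term]`` stanzas with ``id``, ``name`` and ``is_a`` are used;
    obsolete terms and non-``is_a`` relationships are ignored.  Raises
    :class:`OntologyError` for cycles and zero/multiple roots, and whatever
    obonet raises for files that are not OBO at all.
    """
    g = obonet.read_obo(path, ignore_obsolete=True)
    edges = [(c, p) for c, p, key in g.edges(keys=True) if key == "is_a"]
    labels = {n: data["name"] for n, data in g.nodes(data=True) if "name" in data}
    return OntologyGraph(edges, labels=labels, kind=kind, concepts=g.nodes)


def write_obo(graph: OntologyGraph, path) -> None:
    """Write the graph back as a minimal OBO 1.2 flat file (id/name/is_a)."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for cid in sorted(graph.concepts):
            fh.write("\n[Term]\n")
            fh.write(f"id: {cid}\n")
            name = graph.labels.get(cid)
            if name:
                fh.write(f"name: {name}\n")
            for parent in sorted(graph.parents(cid)):
                pname = graph.labels.get(parent)
                suffix = f" ! {pname}" if pname else ""
                fh.write(f"is_a: {parent}{suffix}\n")
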