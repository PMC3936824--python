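"""Synthetic ontologies and patient cohorts with controllable semantic noise.

The generator emulates a rare-disease annotation corpus: a deep phenotype
hierarchy (HPO-like), a shallow two-level disease hierarchy of disorder
groups (BDO-like), and a cohort in which every disorder has a
characteristic profile of phenotypes from which its cases sample.  The
crucial knob is *sibling substitution noise*: with probability ``eps``
a sampled phenotype is replaced by a sibling (same parent) outside the
profile.  Exact matching is blind to such substitutions, while any
structure-aware similarity still scores them highly — this is the semantic
signal the whole framework exists to exploit.

Defaults emulate the published cohort this models: 15 disorders with 26
cases each (≈394 cases), a mean of 4.49 phenotypes per case, and several
hundred distinct phenotype concepts in play.

:func:`worked_example_fixture` instead returns hand-written miniature inputs: the
macrocephaly subtree, the worked three-patient knowledge base (two clinical
features plus an Achondroplasia diagnosis per patient), and the published
2x2 classifier-comparison counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mining import Item, Transaction, TransactionDatabase
from .ontology import OntologyGraph

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_phenotype_ontology",
    "generate_disease_ontology",
    "generate_cohort",
    "worked_example_fixture",
]


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the published cohort statistics."""

    pheno_depth: int = 4
    pheno_branching: int = 5
    branching_jitter: int = 0
    n_groups: int = 5
    n_diseases: int = 15
    cases_per_disease: int = 26
    profile_size: int = 30
    phenotypes_per_case_mean: float = 4.49
    sibling_noise_eps: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "pheno_depth",
            "pheno_branching",
            "n_groups",
            "n_diseases",
            "cases_per_disease",
            "profile_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pheno_depth < 2:
            raise ValueError("pheno_depth must be >= 2")
        if self.n_diseases < self.n_groups:
            raise ValueError("n_diseases must be >= n_groups")
        if not 0.0 <= self.sibling_noise_eps <= 1.0:
            raise ValueError("sibling_noise_eps must be in [0, 1]")
        if self.phenotypes_per_case_mean <= 0:
            raise ValueError("phenotypes_per_case_mean must be positive")
        if self.branching_jitter < 0 or self.branching_jitter >= self.pheno_branching:
            if self.branching_jitter != 0:
                raise ValueError("branching_jitter must be in [0, pheno_branching)")


@dataclass
class GroundTruth:
    """What the generator knows: true disease profiles and case labels."""

    profiles: dict[Item, frozenset[Item]]
    case_assignments: dict[str, Item]


def _pheno_id(n: int) -> str:
    return f"SP:{n:07d}"  # synthetic phenotype CURIE


def generate_phenotype_ontology(cfg: SyntheticConfig, seed: int | None = None) -> OntologyGraph:
    """Rooted tree of configured depth and branching with synthetic CURIEs.

    Deterministic in the seed; jitter (if any) perturbs the child count per
    node by ±``branching_jitter``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    counter = 1
    root = _pheno_id(counter)
    edges: list[tuple[str, str]] = []
    labels = {root: "synthetic phenotype root"}
    frontier = [root]
    for level in range(cfg.pheno_depth):
        nxt = []
        for parent in frontier:
            b = cfg.pheno_branching
            if cfg.branching_jitter:
                b += int(rng.integers(-cfg.branching_jitter, cfg.branching_jitter + 1))
                b = max(1, b)
            for _ in range(b):
                counter += 1
                cid = _pheno_id(counter)
                edges.append((cid, parent))
                labels[cid] = f"synthetic phenotype {counter} (level {level + 1})"
                nxt.append(cid)
        frontier = nxt
    return OntologyGraph(edges, labels=labels, kind="phenotype")


def generate_disease_ontology(cfg: SyntheticConfig, seed: int | None = None) -> OntologyGraph:
    """Two-level disease hierarchy: root -> disorder groups -> disorders.

    Disorders are distributed round-robin over the groups, so every
    disorder sits at depth exactly 2 (mirroring a nosology of disorder
    groups under a single root).
    """
    cfg.validate()
    root = "SD:0000001"
    labels = {root: "synthetic disease root"}
    edges = []
    groups = []
    for g in range(cfg.n_groups):
        gid = f"SD:1{g:06d}"
        groups.append(gid)
        labels[gid] = f"synthetic disorder group {g + 1}"
        edges.append((gid, root))
    for d in range(cfg.n_diseases):
        did = f"SD:2{d:06d}"
        labels[did] = f"synthetic disorder {d + 1}"
        edges.append((did, groups[d % cfg.n_groups]))
    return OntologyGraph(edges, labels=labels, kind="disease")


def _leaves(graph: OntologyGraph) -> list[str]:
    return sorted(c for c in graph.concepts if not graph.children(c))


def generate_cohort(
    cfg: SyntheticConfig,
    pheno_graph: OntologyGraph,
    disease_graph: OntologyGraph,
    seed: int | None = None,
) -> tuple[TransactionDatabase, GroundTruth]:
    """Sample a labelled cohort from per-disorder phenotype profiles.

    Each disorder's profile is a set of leaf phenotypes biased toward one
    top-level branch of the phenotype tree (disorders have characteristic,
    partly overlapping phenotype neighbourhoods).  Each case draws a
    truncated-Poisson (minimum 1) number of distinct profile phenotypes;
    each draw is independently replaced, with probability
    ``sibling_noise_eps``, by a sibling phenotype outside the profile.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    leaves = _leaves(pheno_graph)
    if cfg.profile_size > len(leaves):
        raise ValueError(
            f"profile_size {cfg.profile_size} exceeds {len(leaves)} leaf phenotypes"
        )
    diseases = sorted(
        c for c in disease_graph.concepts if disease_graph.depth(c) == 2
    )[: cfg.n_diseases]
    if len(diseases) < cfg.n_diseases:
        raise ValueError("disease ontology has fewer depth-2 disorders than n_diseases")

    branches = sorted(pheno_graph.children(pheno_graph.root))
    leaves_by_branch = {
        b: [l for l in leaves if b in pheno_graph.ancestors(l)] for b in branches
    }

    profiles: dict[Item, frozenset[Item]] = {}
    for d_i, did in enumerate(diseases):
        home = branches[d_i % len(branches)]
        home_leaves = leaves_by_branch[home]
        n_home = min(int(round(0.8 * cfg.profile_size)), len(home_leaves))
        chosen = set(rng.choice(home_leaves, size=n_home, replace=False))
        remaining = [l for l in leaves if l not in chosen]
        extra = cfg.profile_size - len(chosen)
        if extra > 0:
            chosen |= set(rng.choice(remaining, size=extra, replace=False))
        profiles[Item(did, "disease")] = frozenset(
            Item(c, "phenotype") for c in chosen
        )

    transactions = []
    assignments: dict[str, Item] = {}
    case_n = 0
    for did in diseases:
        disease_item = Item(did, "disease")
        profile = sorted(i.concept for i in profiles[disease_item])
        for _ in range(cfg.cases_per_disease):
            case_n += 1
            case_id = f"case{case_n:05d}"
            k = max(1, int(rng.poisson(cfg.phenotypes_per_case_mean)))
            k = min(k, len(profile))
            sampled = list(rng.choice(profile, size=k, replace=False))
            final: set[str] = set()
            for concept in sampled:
                if rng.random() < cfg.sibling_noise_eps:
                    sibs = sorted(
                        s
                        for s in pheno_graph.siblings(concept)
                        if s not in profile
                    )
                    if sibs:
                        concept = sibs[int(rng.integers(len(sibs)))]
                final.add(concept)
            items = {Item(c, "phenotype") for c in final} | {disease_item}
            transactions.append(Transaction(case_id, frozenset(items)))
            assignments[case_id] = disease_item

    db = TransactionDatabase(tuple(transactions))
    return db, GroundTruth(profiles=profiles, case_assignments=assignments)


def worked_example_fixture() -> tuple[OntologyGraph, OntologyGraph, TransactionDatabase, tuple[int, int, int, int]]:
    """The miniature worked-example inputs.

    Returns ``(phenotype ontology, disease ontology, three-patient
    database, discordance counts)``:

    * a phenotype mini-ontology containing the macrocephaly subtree
      (HP:0000256 with subtypes HP:0004481, HP:0004482, HP:0004488, one
      intermediate node below the root) and the worked-example clinical
      features cf1=HP:0008921 and cf2=HP:0008905 under their shared parent
      HP:0008873, cf3=HP:0000772 and cf4=HP:0000774 (whose parent
      HP:0005257 is a sibling of cf3);
    * a disease mini-ontology with one disorder group holding
      Achondroplasia (bd1) and Diastrophic dysplasia;
    * patients p1={cf1,cf3,bd1}, p2={cf1,cf4,bd1}, p3={cf2,cf3,bd1};
    * the published classifier-comparison cell counts
      (both correct, traditional-only, semantic-only, both wrong)
      = (205, 20, 51, 118).
    """
    pheno_labels = {
        "HP:0000001": "All",
        "HP:0000929": "Abnormality of the skull",
        "HP:0000256": "Macrocephaly",
        "HP:0004481": "Progressive macrocephaly",
        "HP:0004482": "Relative macrocephaly",
        "HP:0004488": "Macrocephaly at birth",
        "HP:0008873": "Disproportionate short-limb short stature",
        "HP:0008921": "Neonatal short-limb short stature",
        "HP:0008905": "Rhizomelic short stature",
        "HP:0000765": "Abnormality of the thorax",
        "HP:0000772": "Abnormality of the ribs",
        "HP:0005257": "Thoracic hypoplasia",
        "HP:0000774": "Narrow chest",
    }
    pheno_edges = [
        ("HP:0000929", "HP:0000001"),
        ("HP:0000256", "HP:0000929"),
        ("HP:0004481", "HP:0000256"),
        ("HP:0004482", "HP:0000256"),
        ("HP:0004488", "HP:0000256"),
        ("HP:0008873", "HP:0000001"),
        ("HP:0008921", "HP:0008873"),
        ("HP:0008905", "HP:0008873"),
        ("HP:0000765", "HP:0000001"),
        ("HP:0000772", "HP:0000765"),
        ("HP:0005257", "HP:0000765"),
        ("HP:0000774", "HP:0005257"),
    ]
    pheno = OntologyGraph(pheno_edges, labels=pheno_labels, kind="phenotype")

    disease_labels = {
        "BDO:0000001": "Bone dysplasia",
        "BDO:0000010": "FGFR3 group",
        "BDO:Achondroplasia": "Achondroplasia",
        "BDO:Diastrophic_dysplasia": "Diastrophic dysplasia",
    }
    disease_edges = [
        ("BDO:0000010", "BDO:0000001"),
        ("BDO:Achondroplasia", "BDO:0000010"),
        ("BDO:Diastrophic_dysplasia", "BDO:0000010"),
    ]
    disease = OntologyGraph(disease_edges, labels=disease_labels, kind="disease")

    cf1 = Item("HP:0008921", "phenotype")
    cf2 = Item("HP:0008905", "phenotype")
    cf3 = Item("HP:0000772", "phenotype")
    cf4 = Item("HP:0000774", "phenotype")
    bd1 = Item("BDO:Achondroplasia", "disease")
    db = TransactionDatabase(
        (
            Transaction("p1", frozenset({cf1, cf3, bd1})),
            Transaction("p2", frozenset({cf1, cf4, bd1})),
            Transaction("p3", frozenset({cf2, cf3, bd1})),
        )
    )
    discordance_counts = (205, 20, 51, 118)
    return pheno, disease, db, discordance_counts
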