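"""Shared fixtures: the worked-example knowledge base and random-instance
generators used by the property tests."""

from __future__ import annotations

import numpy as np
import pytest

import semrules as sr


@pytest.fixture(scope="session")
def fixture_world():
    """(phenotype graph, disease graph, 3-patient db, discordance counts)."""
    return sr.worked_example_fixture()


@pytest.fixture(scope="session")
def worked_items():
    """The worked-example items cf1..cf4 and bd1."""
    return {
        "cf1": sr.Item("HP:0008921", "phenotype"),
        "cf2": sr.Item("HP:0008905", "phenotype"),
        "cf3": sr.Item("HP:0000772", "phenotype"),
        "cf4": sr.Item("HP:0000774", "phenotype"),
        "bd1": sr.Item("BDO:Achondroplasia", "disease"),
    }


def random_ontology(rng: np.random.Generator, n_nodes: int, kind: str = "phenotype",
                    max_parents: int = 2) -> sr.OntologyGraph:
    """Random rooted DAG: node i attaches to 1..max_parents earlier nodes."""
    edges = []
    for i in range(1, n_nodes):
        k = int(rng.integers(1, max_parents + 1))
        parents = rng.choice(i, size=min(k, i), replace=False)
        for p in parents:
            edges.append((f"C:{i:03d}", f"C:{p:03d}"))
    return sr.OntologyGraph(edges, kind=kind)


def random_database(rng: np.random.Generator, n_pheno: int = 6, n_disease: int = 2,
                    n_transactions: int = 10) -> sr.TransactionDatabase:
    """Random typed transactions: a few phenotypes plus at most one disease."""
    phenos = [sr.Item(f"P:{i}", "phenotype") for i in range(n_pheno)]
    diseases = [sr.Item(f"D:{i}", "disease") for i in range(n_disease)]
    transactions = []
    for t in range(n_transactions):
        k = int(rng.integers(1, n_pheno + 1))
        items = set(rng.choice(n_pheno, size=k, replace=False))
        chosen = {phenos[i] for i in items}
        if rng.random() < 0.8:
            chosen.add(diseases[int(rng.integers(n_disease))])
        transactions.append(sr.Transaction(f"t{t}", frozenset(chosen)))
    return sr.TransactionDatabase(tuple(transactions))


def ontology_database(rng: np.random.Generator, pheno: sr.OntologyGraph,
                      disease: sr.OntologyGraph, n_transactions: int = 12,
                      max_items: int = 5) -> sr.TransactionDatabase:
    """Random transactions whose items are concepts of the given ontologies.

    The phenotype root is never used as an annotation (as in real corpora,
    where the root is a bookkeeping concept, not a clinical finding)."""
    pheno_ids = sorted(pheno.concepts - {pheno.root})
    disease_ids = sorted(disease.concepts - {disease.root})
    transactions = []
    for t in range(n_transactions):
        k = int(rng.integers(1, max_items + 1))
        chosen = {
            sr.Item(c, "phenotype")
            for c in rng.choice(pheno_ids, size=min(k, len(pheno_ids)), replace=False)
        }
        if disease_ids and rng.random() < 0.8:
            chosen.add(sr.Item(disease_ids[int(rng.integers(len(disease_ids)))], "disease"))
        transactions.append(sr.Transaction(f"t{t}", frozenset(chosen)))
    return sr.TransactionDatabase(tuple(transactions))
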