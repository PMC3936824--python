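"""Typed transactions and constrained Apriori mining of class association rules.

A patient case is a transaction of typed items: its phenotype annotations
plus (at most) one disease item, the diagnosis.  Mining is classic
level-wise Apriori with two domain constraints: candidate and frequent
itemsets may contain at most one disease item, and a class association rule
is generated only from frequent itemsets that contain exactly one disease
item and at least one phenotype item — the itemset is partitioned into a
phenotype antecedent and a single-disease consequent.

Frequency counting during mining is always traditional (exact-match)
support; semantic measures are attached to the discovered rules afterwards
(see :mod:`semrules.measures`).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .ontology import CorpusStats, OntologyGraph

__all__ = [
    "Item",
    "Transaction",
    "TransactionDatabase",
    "ClassAssociationRule",
    "build_transactions",
    "read_case_table",
    "write_case_table",
    "corpus_stats",
    "constrained_apriori",
    "brute_force_frequent",
    "generate_class_rules",
    "write_rules",
    "read_rules",
]


@dataclass(frozen=True, order=True)
class Item:
    """An ontology-concept annotation typed by its ontology of origin."""

    concept: str
    kind: str  # "phenotype" | "disease"

    def __post_init__(self) -> None:
        if self.kind not in ("phenotype", "disease"):
            raise ValueError(f"item kind must be phenotype|disease, got {self.kind!r}")


@dataclass(frozen=True)
class Transaction:
    """One patient case: a set of phenotype items plus at most one disease item."""

    case_id: str
    items: frozenset[Item]

    def __post_init__(self) -> None:
        n_disease = sum(1 for i in self.items if i.kind == "disease")
        if n_disease > 1:
            raise ValueError(
                f"case {self.case_id!r} carries {n_disease} disease items; at most 1 allowed"
            )

    @property
    def phenotypes(self) -> frozenset[Item]:
        return frozenset(i for i in self.items if i.kind == "phenotype")

    @property
    def disease(self) -> Item | None:
        for i in self.items:
            if i.kind == "disease":
                return i
        return None


@dataclass(frozen=True)
class TransactionDatabase:
    transactions: tuple[Transaction, ...]

    @property
    def n(self) -> int:
        return len(self.transactions)

    def __iter__(self):
        return iter(self.transactions)

    def __len__(self) -> int:
        return len(self.transactions)

    def items(self) -> set[Item]:
        out: set[Item] = set()
        for t in self.transactions:
            out |= t.items
        return out


@dataclass
class ClassAssociationRule:
    """{phenotype itemset} -> disease, with attached interestingness scores."""

    antecedent: frozenset[Item]
    consequent: Item
    support: float
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ValueError("rule antecedent must be non-empty")
        if self.consequent.kind != "disease":
            raise ValueError("rule consequent must be a disease item")
        if any(i.kind != "phenotype" for i in self.antecedent):
            raise ValueError("rule antecedent must contain only phenotype items")

    @property
    def itemset(self) -> frozenset[Item]:
        return self.antecedent | {self.consequent}

    def sort_key(self):
        return (len(self.antecedent), tuple(sorted(i.concept for i in self.antecedent)),
                self.consequent.concept)


def _itemset_key(itemset: frozenset[Item]):
    return (len(itemset), tuple(sorted((i.concept, i.kind) for i in itemset)))


# --------------------------------------------------------------------------
# case table <-> transactions


def build_transactions(
    rows,
    pheno_graph: OntologyGraph,
    disease_graph: OntologyGraph,
) -> TransactionDatabase:
    """Turn parsed case rows into a transaction database.

    ``rows`` is an iterable of ``(case_id, diagnosis_id, [phenotype_ids])``.
    Every concept must resolve in its ontology; duplicated phenotype
    annotations collapse into one item; a case with zero phenotypes is kept
    with a warning.
    """
    transactions = []
    for case_id, diag, phenos in rows:
        if diag not in disease_graph:
            raise KeyError(f"case {case_id!r}: unknown disease concept {diag!r}")
        items = {Item(diag, "disease")}
        for p in phenos:
            if p not in pheno_graph:
                raise KeyError(f"case {case_id!r}: unknown phenotype concept {p!r}")
            items.add(Item(p, "phenotype"))
        if len(items) == 1:
            warnings.warn(f"case {case_id!r} has no phenotype annotations")
        transactions.append(Transaction(str(case_id), frozenset(items)))
    if not transactions:
        raise ValueError("case table is empty")
    return TransactionDatabase(tuple(transactions))


def read_case_table(path) -> list[tuple[str, str, list[str]]]:
    """Read a TSV with columns case_id, diagnosis_id, phenotype_ids
    (comma-separated concept IDs)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"case_id", "diagnosis_id", "phenotype_ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"case table missing columns: {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        phenos = [p.strip() for p in r["phenotype_ids"].split(",") if p.strip()]
        rows.append((r["case_id"], r["diagnosis_id"], phenos))
    return rows


def write_case_table(db: TransactionDatabase, path) -> None:
    recs = []
    for t in db:
        recs.append(
            {
                "case_id": t.case_id,
                "diagnosis_id": t.disease.concept if t.disease else "",
                "phenotype_ids": ",".join(sorted(i.concept for i in t.phenotypes)),
            }
        )
    pd.DataFrame(recs).to_csv(path, sep="\t", index=False)


def corpus_stats(db: TransactionDatabase) -> CorpusStats:
    """Non-propagated per-case concept frequencies over the database.

    Each case contributes at most once per concept; both phenotype and
    disease concepts are counted, so IC-based metrics work on either kind.
    """
    freq: dict[str, int] = {}
    for t in db:
        for item in t.items:
            freq[item.concept] = freq.get(item.concept, 0) + 1
    return CorpusStats(case_count=db.n, concept_freq=freq)


# --------------------------------------------------------------------------
# mining


def _support_count(itemset: frozenset[Item], db: TransactionDatabase) -> int:
    return sum(1 for t in db if itemset <= t.items)


def _at_most_one_disease(itemset: frozenset[Item]) -> bool:
    return sum(1 for i in itemset if i.kind == "disease") <= 1


def constrained_apriori(
    db: TransactionDatabase, min_support_count: int = 5, max_size: int = 10
) -> list[tuple[frozenset[Item], float]]:
    """Level-wise Apriori restricted to itemsets with at most one disease item.

    Returns ``(itemset, support)`` pairs for every itemset of size 1 to
    ``max_size`` whose exact-match support count reaches
    ``min_support_count``, sorted by size then lexicographic concept IDs.
    """
    if db.n == 0:
        raise ValueError("cannot mine an empty database")
    if min_support_count < 1:
        raise ValueError("min_support_count must be >= 1")
    if max_size < 2:
        raise ValueError("max_size must be >= 2")

    out: list[tuple[frozenset[Item], float]] = []
    # L1
    counts: dict[frozenset[Item], int] = {}
    for t in db:
        for i in t.items:
            s = frozenset([i])
            counts[s] = counts.get(s, 0) + 1
    frequent = {s for s, c in counts.items() if c >= min_support_count}
    out.extend((s, counts[s] / db.n) for s in frequent)

    size = 1
    while frequent and size < max_size:
        size += 1
        # candidate generation: join frequent (k-1)-itemsets sharing a prefix
        prev = sorted(frequent, key=_itemset_key)
        candidates: set[frozenset[Item]] = set()
        singles = {next(iter(s)) for s in frequent if len(s) == 1} if size == 2 else None
        if size == 2:
            for a, b in itertools.combinations(sorted(singles), 2):
                c = frozenset([a, b])
                if _at_most_one_disease(c):
                    candidates.add(c)
        else:
            for a, b in itertools.combinations(prev, 2):
                u = a | b
                if len(u) != size or not _at_most_one_disease(u):
                    continue
                # prune: all (k-1)-subsets must be frequent
                if all(u - {x} in frequent for x in u):
                    candidates.add(u)
        if not candidates:
            break
        counts = {c: 0 for c in candidates}
        for t in db:
            ti = t.items
            for c in candidates:
                if c <= ti:
                    counts[c] += 1
        frequent = {c for c, n in counts.items() if n >= min_support_count}
        out.extend((c, counts[c] / db.n) for c in frequent)

    out.sort(key=lambda pair: _itemset_key(pair[0]))
    return out


def brute_force_frequent(
    db: TransactionDatabase, min_support_count: int = 5, max_size: int = 10
) -> list[tuple[frozenset[Item], float]]:
    """Exhaustive frequent-itemset enumeration; the independent oracle for
    :func:`constrained_apriori` on small instances (guarded at 16 items)."""
    if db.n == 0:
        raise ValueError("cannot mine an empty database")
    universe = sorted(db.items())
    if len(universe) > 16:
        raise ValueError(f"brute force guarded at 16 distinct items, got {len(universe)}")
    out = []
    for size in range(1, min(max_size, len(universe)) + 1):
        for combo in itertools.combinations(universe, size):
            s = frozenset(combo)
            if not _at_most_one_disease(s):
                continue
            c = _support_count(s, db)
            if c >= min_support_count:
                out.append((s, c / db.n))
    out.sort(key=lambda pair: _itemset_key(pair[0]))
    return out


def generate_class_rules(
    frequent: list[tuple[frozenset[Item], float]],
) -> list[ClassAssociationRule]:
    """Partition each frequent itemset with exactly one disease item and at
    least one phenotype item into {phenotypes} -> disease."""
    rules = []
    for itemset, support in frequent:
        diseases = [i for i in itemset if i.kind == "disease"]
        phenos = frozenset(i for i in itemset if i.kind == "phenotype")
        if len(diseases) != 1 or not phenos:
            continue
        rules.append(
            ClassAssociationRule(antecedent=phenos, consequent=diseases[0], support=support)
        )
    rules.sort(key=ClassAssociationRule.sort_key)
    return rules


def write_rules(rules: list[ClassAssociationRule], path) -> None:
    """Rules as TSV: antecedent (semicolon-joined), consequent, support,
    one column per attached measure."""
    measures = sorted({m for r in rules for m in r.scores})
    recs = []
    for r in rules:
        rec = {
            "antecedent": ";".join(sorted(i.concept for i in r.antecedent)),
            "consequent": r.consequent.concept,
            "support": r.support,
        }
        for m in measures:
            rec[m] = r.scores.get(m, "")
        recs.append(rec)
    cols = ["antecedent", "consequent", "support"] + measures
    pd.DataFrame(recs, columns=cols).to_csv(path, sep="\t", index=False)


def read_rules(path) -> list[ClassAssociationRule]:
    df = pd.read_csv(path, sep="\t", dtype={"antecedent": str, "consequent": str})
    rules = []
    extra = [c for c in df.columns if c not in ("antecedent", "consequent", "support")]
    for _, r in df.iterrows():
        ante = frozenset(Item(c, "phenotype") for c in r["antecedent"].split(";"))
        rule = ClassAssociationRule(
            antecedent=ante,
            consequent=Item(r["consequent"], "disease"),
            support=float(r["support"]),
        )
        for m in extra:
            v = r[m]
            if v == v:  # not NaN
                rule.scores[m] = float(v)
        rules.append(rule)
    return rules
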