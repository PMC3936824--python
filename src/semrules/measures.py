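"""Traditional and semantic support, and the seven interestingness measures.

Traditional support of an itemset is the fraction of transactions that
contain every item exactly.  Semantic support relaxes the exact match: for
each transaction, each itemset item is matched to the *most similar*
transaction item under a [0,1]-valued similarity, the per-item best scores
are multiplied, and the per-transaction products are averaged::

    SemSupport(I) = (1/n) * sum_t  prod_{i in I}  max_{v in t} sim(i, v)

With the exact-match indicator as ``sim`` this reduces identically to
traditional support, which is why every interestingness measure below
exists in two modes differing only in the support function plugged in.
"""

from __future__ import annotations

import math
from typing import Callable

from .mining import ClassAssociationRule, Item, TransactionDatabase
from .similarity import SimilarityFunction, exact_sim

__all__ = [
    "MEASURES",
    "support",
    "semantic_support",
    "support_function",
    "interestingness",
    "score_rules",
    "INFINITE_CONVICTION",
]

MEASURES = (
    "support",
    "confidence",
    "lift",
    "conviction",
    "leverage",
    "jaccard",
    "cosine",
    "correlation",
)

#: sentinel for conviction of a rule at ceiling confidence; sorts above all
#: finite interestingness values
INFINITE_CONVICTION = math.inf

SupportFunction = Callable[[frozenset], float]


def support(itemset: frozenset, db: TransactionDatabase) -> float:
    """Exact-match support: fraction of transactions containing the itemset.

    The empty itemset is vacuously contained in every transaction.
    """
    if db.n == 0:
        raise ValueError("empty database")
    return sum(1 for t in db if itemset <= t.items) / db.n


def semantic_support(
    itemset: frozenset, db: TransactionDatabase, sim: Callable[[Item, Item], float]
) -> float:
    """Mean over transactions of the product of per-item best similarities.

    ``sim`` must be [0,1]-valued (use a clamped :class:`SimilarityFunction`).
    The max over an empty transaction is 0; the product over an empty
    itemset is 1, so the empty itemset has semantic support 1.
    """
    if db.n == 0:
        raise ValueError("empty database")
    total = 0.0
    for t in db:
        prod = 1.0
        for i in itemset:
            best = 0.0
            for v in t.items:
                s = sim(i, v)
                if s > best:
                    best = s
                    if best >= 1.0:
                        break
            prod *= best
            if prod == 0.0:
                break
        total += prod
    return total / db.n


def support_function(
    db: TransactionDatabase,
    mode: str = "traditional",
    sim: SimilarityFunction | None = None,
) -> SupportFunction:
    """Build the pluggable support function used by all measures.

    ``traditional`` counts exact containment; ``semantic`` needs a clamped
    similarity.  Results are memoised per itemset — each rule evaluates
    supports of its antecedent, consequent and union, and antecedents and
    consequents recur heavily across a rule set.
    """
    cache: dict[frozenset, float] = {}
    if mode == "traditional":
        fn = lambda s: support(s, db)
    elif mode == "semantic":
        if sim is None:
            raise ValueError("semantic mode requires a similarity function")
        fn = lambda s: semantic_support(s, db, sim)
    else:
        raise ValueError(f"mode must be traditional|semantic, got {mode!r}")

    def cached(itemset: frozenset) -> float:
        if itemset not in cache:
            cache[itemset] = fn(itemset)
        return cache[itemset]

    return cached


def interestingness(
    rule: ClassAssociationRule,
    measure: str,
    supp: SupportFunction,
) -> float:
    """One interestingness value for one rule under a given support function.

    With ``S`` the support function, ``X`` the antecedent, ``Q`` the
    consequent and ``XQ`` their union:

    ==============  =====================================================
    confidence      S(XQ) / S(X)
    lift            confidence / S(Q)
    conviction      (1 - S(Q)) / (1 - confidence); +inf at confidence 1
    leverage        S(XQ) - S(X) * S(Q)
    jaccard         S(XQ) / (S(X) + S(Q) - S(XQ))
    cosine          S(XQ) / sqrt(S(X) * S(Q))
    correlation     leverage / sqrt(S(X) S(Q) (1-S(X)) (1-S(Q))); 0 when
                    any variance factor vanishes
    ==============  =====================================================
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    X = rule.antecedent
    Q = frozenset([rule.consequent])
    XQ = rule.itemset
    s_xq = supp(XQ)
    if measure == "support":
        return s_xq
    s_x = supp(X)
    s_q = supp(Q)
    if measure == "leverage":
        return s_xq - s_x * s_q
    if measure == "jaccard":
        denom = s_x + s_q - s_xq
        return s_xq / denom if denom > 0 else 0.0
    if measure == "cosine":
        denom = math.sqrt(s_x * s_q)
        return s_xq / denom if denom > 0 else 0.0
    if measure == "correlation":
        var = s_x * s_q * (1.0 - s_x) * (1.0 - s_q)
        if var <= 0.0:
            return 0.0
        return (s_xq - s_x * s_q) / math.sqrt(var)
    # ratio measures need positive antecedent support
    if s_x == 0.0:
        raise ZeroDivisionError(
            f"zero antecedent support for rule "
            f"{{{';'.join(sorted(i.concept for i in X))}}} -> {rule.consequent.concept}"
        )
    conf = s_xq / s_x
    if measure == "confidence":
        return conf
    if measure == "lift":
        return conf / s_q if s_q > 0 else 0.0
    # conviction
    if conf >= 1.0:
        return INFINITE_CONVICTION
    return (1.0 - s_q) / (1.0 - conf)


def score_rules(
    rules: list[ClassAssociationRule],
    db: TransactionDatabase,
    measures: list[str],
    mode: str = "traditional",
    sim: SimilarityFunction | None = None,
) -> list[ClassAssociationRule]:
    """Attach one score per requested measure to every rule, in place.

    Input order is preserved; the populated list is returned for chaining.
    """
    supp = support_function(db, mode=mode, sim=sim)
    for rule in rules:
        for m in measures:
            rule.scores[m] = interestingness(rule, m, supp)
    return rules
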