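"""Voting-based diagnosis ranking, cross-validated top-K accuracy, and the
McNemar comparison of two classifiers.

A scored rule set becomes a classifier by letting rules *fire* on a new
case and vote for their consequent disorder.  Firing is semantic: a rule's
match score on a case is the product over its antecedent phenotypes of the
best similarity against the case's phenotypes; with the exact-match
similarity this reduces to the classical "antecedent is a subset of the
case" test.  Fired rules are grouped by antecedent, each group backs the
consequent of its highest-scoring rule, and groups contribute either one
vote (simple scheme) or a vote weighted by rule quality (weighted scheme).
The disorder ranking is the vote totals in descending order.

Accuracy at recall cut-off K counts a case as a success only when the true
disorder — the exact concept, not a sub- or superclass — appears among the
top K ranked predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as scipy_stats

from . import measures as measures_mod
from .mining import (
    ClassAssociationRule,
    Item,
    Transaction,
    TransactionDatabase,
    constrained_apriori,
    generate_class_rules,
)
from .similarity import SimilarityFunction

__all__ = [
    "VotingConfig",
    "Prediction",
    "EvaluationReport",
    "DiscordanceTable",
    "fire_rules",
    "vote",
    "top_k_accuracy",
    "cv_predictions",
    "cross_validate",
    "compare_classifiers",
    "discordance",
    "mcnemar",
]


@dataclass
class VotingConfig:
    """How fired rules turn into a diagnosis ranking.

    ``measure`` selects which attached interestingness score ranks rules
    within an antecedent group and weights votes in the weighted scheme.
    In traditional mode firing always uses exact matching regardless of
    ``sim``; in semantic mode the supplied similarity scores partial
    antecedent matches and the match score additionally multiplies the
    vote weight.
    """

    scheme: str = "weighted"  # simple | weighted
    measure: str = "confidence"
    mode: str = "traditional"  # traditional | semantic
    sim: SimilarityFunction | None = None
    firing_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.scheme not in ("simple", "weighted"):
            raise ValueError(f"scheme must be simple|weighted, got {self.scheme!r}")
        if self.mode not in ("traditional", "semantic"):
            raise ValueError(f"mode must be traditional|semantic, got {self.mode!r}")
        if self.mode == "semantic" and self.sim is None:
            raise ValueError("semantic mode requires a similarity function")

    def firing_sim(self) -> SimilarityFunction:
        if self.mode == "traditional":
            return SimilarityFunction(metric="exact")
        return self.sim


@dataclass
class Prediction:
    case_id: str
    ranking: list[tuple[Item, float]]  # (disease, total vote), best first

    def top(self, k: int) -> list[Item]:
        return [d for d, _ in self.ranking[:k]]


@dataclass
class EvaluationReport:
    """Cross-validation outcome: mean accuracy (percent) per recall cut-off,
    plus the per-fold grids it was averaged from."""

    accuracy_at_k: dict[int, float]
    per_fold: list[dict[int, float]]
    n_test: int


@dataclass
class DiscordanceTable:
    """2x2 correct/incorrect cross-tabulation of two paired classifiers."""

    both_correct: int
    a_only: int
    b_only: int
    both_wrong: int

    @property
    def total(self) -> int:
        return self.both_correct + self.a_only + self.b_only + self.both_wrong


def fire_rules(
    case: Transaction,
    rules: list[ClassAssociationRule],
    sim,
    threshold: float = 0.0,
) -> list[tuple[ClassAssociationRule, float]]:
    """Rules whose antecedent matches the case above ``threshold``.

    match_score = prod over antecedent items of the best similarity against
    the case's phenotype items (the diagnosis item, if present, is ignored).
    A rule fires iff its match score strictly exceeds the threshold, so a
    case with no phenotypes fires nothing.
    """
    phenos = case.phenotypes
    fired = []
    for rule in rules:
        score = 1.0
        for a in rule.antecedent:
            best = 0.0
            for p in phenos:
                s = sim(a, p)
                if s > best:
                    best = s
                    if best >= 1.0:
                        break
            score *= best
            if score <= threshold:
                break
        if score > threshold:
            fired.append((rule, score))
    return fired


def vote(
    case: Transaction,
    rules: list[ClassAssociationRule],
    config: VotingConfig,
) -> Prediction:
    """Rank disorders by total vote over fired rules.

    Fired rules are grouped by antecedent; each group votes once, for the
    consequent of its highest-``config.measure`` rule (ties on the measure
    break toward the lexicographically smaller disease ID).  The simple
    scheme adds 1 per group; the weighted scheme adds the group's maximum
    measure value, additionally multiplied by the group's match score in
    semantic mode.  An infinite conviction weight dominates all finite
    votes.  Final ties in the ranking break lexicographically on disease ID.
    """
    fired = fire_rules(case, rules, config.firing_sim(), config.firing_threshold)
    groups: dict[frozenset, list[tuple[ClassAssociationRule, float]]] = {}
    for rule, score in fired:
        groups.setdefault(rule.antecedent, []).append((rule, score))

    totals: dict[Item, float] = {}
    for antecedent, members in groups.items():
        best_rule, best_match = min(
            members,
            key=lambda rm: (-rm[0].scores[config.measure], rm[0].consequent.concept),
        )
        target = best_rule.consequent
        if config.scheme == "simple":
            weight = 1.0
        else:
            weight = best_rule.scores[config.measure]
            if config.mode == "semantic" and math.isfinite(weight):
                weight *= best_match
        totals[target] = totals.get(target, 0.0) + weight

    ranking = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0].concept))
    return Prediction(case_id=case.case_id, ranking=ranking)


def top_k_accuracy(
    predictions: list[Prediction],
    truths: dict[str, Item],
    k: int,
) -> float:
    """Percent of cases whose true disorder is in the top K predictions.

    An empty ranking is a miss; a case without a truth entry is an error.
    """
    if not predictions:
        raise ValueError("no predictions to evaluate")
    hits = 0
    for p in predictions:
        if p.case_id not in truths:
            raise KeyError(f"no ground truth for case {p.case_id!r}")
        if truths[p.case_id] in p.top(k):
            hits += 1
    return 100.0 * hits / len(predictions)


def _stratified_folds(
    db: TransactionDatabase, folds: int, seed: int
) -> list[list[int]]:
    """Seeded fold assignment stratified by diagnosis, so every fold sees
    every disorder when class sizes allow."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for idx, t in enumerate(db):
        key = t.disease.concept if t.disease else ""
        by_class.setdefault(key, []).append(idx)
    assignment: list[list[int]] = [[] for _ in range(folds)]
    offset = 0
    for key in sorted(by_class):
        idxs = np.array(by_class[key])
        rng.shuffle(idxs)
        for j, idx in enumerate(idxs):
            assignment[(j + offset) % folds].append(int(idx))
        offset += len(idxs)  # rotate so small classes spread across folds
    return assignment


def predict_cases(
    cases,
    rules: list[ClassAssociationRule],
    config: VotingConfig,
) -> list[Prediction]:
    return [vote(c, rules, config) for c in cases]


def cv_predictions(
    db: TransactionDatabase,
    config: VotingConfig,
    min_support_count: int = 5,
    max_size: int = 10,
    folds: int = 5,
    seed: int = 0,
    sim_builder=None,
) -> tuple[list[list[Prediction]], dict[str, Item]]:
    """Per-fold held-out predictions from stratified cross-validation.

    Each fold mines and scores rules on its training 80% and votes on its
    held-out 20%.  Fold assignment is a pure function of ``seed``, so two
    classifiers evaluated with the same seed see identical splits — the
    precondition for a paired comparison.

    ``sim_builder``, if given, is called with each training database and
    must return the :class:`SimilarityFunction` for that fold — needed for
    IC-based metrics whose corpus statistics must come from training data
    only.  Otherwise ``config.sim`` is used as-is.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if db.n < folds:
        raise ValueError(f"database of {db.n} cases cannot be split into {folds} folds")
    class_sizes: dict[str, int] = {}
    for t in db:
        key = t.disease.concept if t.disease else ""
        class_sizes[key] = class_sizes.get(key, 0) + 1
    small = [c for c, s in class_sizes.items() if s < folds]
    if small:
        import warnings

        warnings.warn(
            f"{len(small)} disorder(s) have fewer than {folds} cases and will "
            f"be absent from some folds: {sorted(small)[:3]}"
        )

    fold_idx = _stratified_folds(db, folds, seed)
    per_fold_preds: list[list[Prediction]] = []
    truths: dict[str, Item] = {}
    for f in range(folds):
        test_ids = set(fold_idx[f])
        train = TransactionDatabase(
            tuple(t for i, t in enumerate(db) if i not in test_ids)
        )
        test = [t for i, t in enumerate(db) if i in test_ids]
        if not test:
            continue
        frequent = constrained_apriori(train, min_support_count, max_size)
        rules = generate_class_rules(frequent)
        fold_config = config
        if sim_builder is not None and config.mode == "semantic":
            fold_config = VotingConfig(
                scheme=config.scheme,
                measure=config.measure,
                mode=config.mode,
                sim=sim_builder(train),
                firing_threshold=config.firing_threshold,
            )
        measures_mod.score_rules(
            rules,
            train,
            [config.measure],
            mode=config.mode,
            sim=fold_config.sim,
        )
        per_fold_preds.append(predict_cases(test, rules, fold_config))
        truths.update({t.case_id: t.disease for t in test})
    return per_fold_preds, truths


def cross_validate(
    db: TransactionDatabase,
    config: VotingConfig,
    min_support_count: int = 5,
    max_size: int = 10,
    folds: int = 5,
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5),
    seed: int = 0,
    sim_builder=None,
) -> EvaluationReport:
    """Stratified K-fold evaluation: mean top-K accuracy across folds.

    See :func:`cv_predictions` for the fold mechanics."""
    per_fold_preds, truths = cv_predictions(
        db, config, min_support_count, max_size, folds, seed, sim_builder
    )
    per_fold = [
        {k: top_k_accuracy(preds, truths, k) for k in k_values}
        for preds in per_fold_preds
    ]
    accuracy = {
        k: float(np.mean([fold[k] for fold in per_fold])) for k in k_values
    }
    n_test = sum(len(p) for p in per_fold_preds)
    return EvaluationReport(accuracy_at_k=accuracy, per_fold=per_fold, n_test=n_test)


def compare_classifiers(
    db: TransactionDatabase,
    config_a: VotingConfig,
    config_b: VotingConfig,
    min_support_count: int = 5,
    max_size: int = 10,
    folds: int = 5,
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5),
    k: int = 5,
    seed: int = 0,
    sim_builder_a=None,
    sim_builder_b=None,
):
    """Paired comparison of two voting classifiers on identical folds.

    Returns ``(report_a, report_b, table, stat, p)`` where ``table``
    cross-tabulates per-case correctness at cut-off ``k`` over the pooled
    held-out predictions, and ``stat``/``p`` are the McNemar test on its
    discordant cells (``None``/``None`` when there is no discordance).
    """
    preds_a, truths = cv_predictions(
        db, config_a, min_support_count, max_size, folds, seed, sim_builder_a
    )
    preds_b, _ = cv_predictions(
        db, config_b, min_support_count, max_size, folds, seed, sim_builder_b
    )
    pooled_a = [p for fold in preds_a for p in fold]
    pooled_b = [p for fold in preds_b for p in fold]
    table = discordance(pooled_a, pooled_b, truths, k)
    if table.a_only + table.b_only == 0:
        stat, p = None, None
    else:
        stat, p = mcnemar(table.a_only, table.b_only)
    report_a = EvaluationReport(
        accuracy_at_k={
            kk: top_k_accuracy(pooled_a, truths, kk) for kk in k_values
        },
        per_fold=[
            {kk: top_k_accuracy(f, truths, kk) for kk in k_values} for f in preds_a
        ],
        n_test=len(pooled_a),
    )
    report_b = EvaluationReport(
        accuracy_at_k={
            kk: top_k_accuracy(pooled_b, truths, kk) for kk in k_values
        },
        per_fold=[
            {kk: top_k_accuracy(f, truths, kk) for kk in k_values} for f in preds_b
        ],
        n_test=len(pooled_b),
    )
    return report_a, report_b, table, stat, p


def discordance(
    preds_a: list[Prediction],
    preds_b: list[Prediction],
    truths: dict[str, Item],
    k: int,
) -> DiscordanceTable:
    """Cross-tabulate correctness at cut-off K between two paired classifiers."""
    a_by_case = {p.case_id: p for p in preds_a}
    b_by_case = {p.case_id: p for p in preds_b}
    if a_by_case.keys() != b_by_case.keys():
        raise ValueError("classifiers were evaluated on different case sets")
    cells = [0, 0, 0, 0]  # both, a_only, b_only, neither
    for case_id, pa in a_by_case.items():
        truth = truths[case_id]
        ca = truth in pa.top(k)
        cb = truth in b_by_case[case_id].top(k)
        if ca and cb:
            cells[0] += 1
        elif ca:
            cells[1] += 1
        elif cb:
            cells[2] += 1
        else:
            cells[3] += 1
    return DiscordanceTable(*cells)


def mcnemar(b: int, c: int) -> tuple[float, float]:
    """McNemar chi-squared statistic with continuity correction, and its
    p-value from the chi-squared distribution with 1 degree of freedom.

    ``b`` and ``c`` are the discordant cell counts (cases one classifier got
    right and the other wrong, each way).  The continuity correction
    ``|b - c| - 1`` is clamped at 0 so perfect agreement cannot produce a
    positive statistic.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    if b + c == 0:
        raise ValueError("McNemar test undefined with no discordant cases")
    stat = max(0.0, abs(b - c) - 1.0) ** 2 / (b + c)
    p = float(scipy_stats.chi2.sf(stat, df=1))
    return stat, p
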