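"""Rule firing, voting, cross-validated accuracy, discordance and McNemar."""

import math

import numpy as np
import pytest

import semrules as sr
from semrules.classify import _stratified_folds


def _rule(antecedent, consequent, **scores):
    r = sr.ClassAssociationRule(
        antecedent=frozenset(sr.Item(c, "phenotype") for c in antecedent),
        consequent=sr.Item(consequent, "disease"),
        support=0.5,
    )
    r.scores.update(scores)
    return r


def _case(case_id, phenos, disease=None):
    items = {sr.Item(c, "phenotype") for c in phenos}
    if disease:
        items.add(sr.Item(disease, "disease"))
    return sr.Transaction(case_id, frozenset(items))


class TestFireRules:
    def test_subset_firing_under_exact_match(self):
        rules = [_rule({"a", "b"}, "d1"), _rule({"a", "c"}, "d1")]
        case = _case("x", {"a", "b", "z"})
        fired = sr.fire_rules(case, rules, sr.exact_sim, 0.0)
        assert [(r.antecedent, s) for r, s in fired] == [
            (rules[0].antecedent, 1.0)
        ]

    def test_partial_semantic_match(self):
        rules = [_rule({"a"}, "d1")]
        sim = lambda x, y: 1.0 if x == y else 1 / 3
        fired = sr.fire_rules(_case("x", {"b"}), rules, sim, 0.0)
        assert len(fired) == 1
        assert fired[0][1] == pytest.approx(1 / 3)

    def test_no_phenotypes_fires_nothing(self):
        rules = [_rule({"a"}, "d1")]
        assert sr.fire_rules(_case("x", set(), "d9"), rules, sr.exact_sim) == []

    def test_threshold_excludes_weak_matches(self):
        rules = [_rule({"a"}, "d1")]
        sim = lambda x, y: 1.0 if x == y else 1 / 3
        assert sr.fire_rules(_case("x", {"b"}), rules, sim, 0.5) == []


class TestVote:
    def test_simple_scheme_counts_antecedent_groups(self):
        rules = [
            _rule({"a"}, "d1", confidence=0.9),
            _rule({"b"}, "d1", confidence=0.5),
            _rule({"c"}, "d2", confidence=0.99),
        ]
        config = sr.VotingConfig(scheme="simple", measure="confidence")
        pred = sr.vote(_case("x", {"a", "b", "c"}), rules, config)
        assert pred.ranking[0] == (sr.Item("d1", "disease"), 2.0)
        assert pred.ranking[1] == (sr.Item("d2", "disease"), 1.0)

    def test_weighted_scheme_uses_max_measure(self):
        rules = [
            _rule({"a"}, "d1", confidence=0.9),
            _rule({"b"}, "d2", confidence=0.4),
            _rule({"c"}, "d2", confidence=0.4),
        ]
        config = sr.VotingConfig(scheme="weighted", measure="confidence")
        pred = sr.vote(_case("x", {"a", "b", "c"}), rules, config)
        assert pred.ranking[0] == (sr.Item("d1", "disease"), pytest.approx(0.9))
        assert pred.ranking[1] == (sr.Item("d2", "disease"), pytest.approx(0.8))

    def test_group_votes_for_its_best_rule(self):
        # same antecedent, two consequents: group backs the higher measure
        rules = [
            _rule({"a"}, "d1", confidence=0.3),
            _rule({"a"}, "d2", confidence=0.7),
        ]
        config = sr.VotingConfig(scheme="simple", measure="confidence")
        pred = sr.vote(_case("x", {"a"}), rules, config)
        assert [d.concept for d, _ in pred.ranking] == ["d2"]

    def test_infinite_conviction_dominates(self):
        rules = [
            _rule({"a"}, "d1", conviction=math.inf),
            _rule({"b"}, "d2", conviction=100.0),
        ]
        config = sr.VotingConfig(scheme="weighted", measure="conviction")
        pred = sr.vote(_case("x", {"a", "b"}), rules, config)
        assert pred.ranking[0][0].concept == "d1"
        assert math.isinf(pred.ranking[0][1])

    def test_no_fired_rules_empty_ranking(self):
        config = sr.VotingConfig(scheme="simple", measure="confidence")
        pred = sr.vote(_case("x", {"z"}), [_rule({"a"}, "d1", confidence=1.0)], config)
        assert pred.ranking == []

    def test_traditional_equals_semantic_with_exact_sim(self):
        rng = np.random.default_rng(31)
        phenos = [f"p{i}" for i in range(6)]
        rules = [
            _rule(set(rng.choice(phenos, size=2, replace=False)), f"d{i % 3}",
                  confidence=float(rng.random()))
            for i in range(10)
        ]
        trad = sr.VotingConfig(scheme="weighted", measure="confidence",
                               mode="traditional")
        sem = sr.VotingConfig(scheme="weighted", measure="confidence",
                              mode="semantic",
                              sim=sr.SimilarityFunction(metric="exact"))
        for i in range(100):
            k = int(rng.integers(1, 5))
            case = _case(f"c{i}", set(rng.choice(phenos, size=k, replace=False)))
            pt, ps = sr.vote(case, rules, trad), sr.vote(case, rules, sem)
            assert pt.ranking == ps.ranking


class TestTopKAccuracy:
    def _preds(self, rankings):
        return [
            sr.Prediction(f"c{i}", [(sr.Item(d, "disease"), 1.0 - j / 10)
                                    for j, d in enumerate(r)])
            for i, r in enumerate(rankings)
        ]

    def test_all_correct_at_one(self):
        preds = self._preds([["d1"], ["d1"]])
        truths = {p.case_id: sr.Item("d1", "disease") for p in preds}
        assert sr.top_k_accuracy(preds, truths, 1) == 100.0

    def test_cutoff_boundary(self):
        preds = self._preds([["d1", "d2", "d3"]] * 4)
        truths = {p.case_id: sr.Item("d3", "disease") for p in preds}
        assert sr.top_k_accuracy(preds, truths, 2) == 0.0
        assert sr.top_k_accuracy(preds, truths, 3) == 100.0

    def test_fractional_accuracy(self):
        preds = self._preds([["d1"], ["d1"], ["d2"]])
        truths = {p.case_id: sr.Item("d1", "disease") for p in preds}
        assert sr.top_k_accuracy(preds, truths, 1) == pytest.approx(66.67, abs=0.01)

    def test_missing_truth_raises(self):
        preds = self._preds([["d1"]])
        with pytest.raises(KeyError):
            sr.top_k_accuracy(preds, {}, 1)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(32)
        diseases = [f"d{i}" for i in range(6)]
        preds = self._preds(
            [list(rng.permutation(diseases)) for _ in range(20)]
        )
        truths = {p.case_id: sr.Item(str(rng.choice(diseases)), "disease")
                  for p in preds}
        accs = [sr.top_k_accuracy(preds, truths, k) for k in range(1, 7)]
        assert accs == sorted(accs)


@pytest.fixture(scope="module")
def separable_world():
    """Noise-free synthetic cohort: cases never leave their profiles."""
    cfg = sr.SyntheticConfig(
        pheno_depth=3, pheno_branching=3, n_groups=3, n_diseases=6,
        cases_per_disease=10, profile_size=4,
        phenotypes_per_case_mean=3.0, sibling_noise_eps=0.0, seed=5,
    )
    pheno = sr.generate_phenotype_ontology(cfg)
    disease = sr.generate_disease_ontology(cfg)
    db, truth = sr.generate_cohort(cfg, pheno, disease)
    return pheno, disease, db, truth


class TestCrossValidate:
    def test_deterministic_in_seed(self, separable_world):
        _, _, db, _ = separable_world
        config = sr.VotingConfig(scheme="weighted", measure="confidence")
        r1 = sr.cross_validate(db, config, 2, 4, 5, (1, 3, 5), seed=9)
        r2 = sr.cross_validate(db, config, 2, 4, 5, (1, 3, 5), seed=9)
        assert r1.accuracy_at_k == r2.accuracy_at_k
        assert r1.per_fold == r2.per_fold

    def test_disjoint_profiles_classify_perfectly(self):
        # three disorders with disjoint three-phenotype profiles: exact-match
        # rules identify each case uniquely, so top-1 accuracy is 100%
        edges = [("br%d" % b, "r") for b in range(3)]
        profiles = {}
        for b, d in enumerate(["d1", "d2", "d3"]):
            concepts = [f"{d}p{j}" for j in range(3)]
            edges += [(c, "br%d" % b) for c in concepts]
            profiles[d] = concepts
        transactions = []
        for d, concepts in profiles.items():
            for i in range(10):
                pair = [concepts[i % 3], concepts[(i + 1) % 3]]
                items = {sr.Item(c, "phenotype") for c in pair}
                items.add(sr.Item(d, "disease"))
                transactions.append(sr.Transaction(f"{d}c{i}", frozenset(items)))
        db = sr.TransactionDatabase(tuple(transactions))
        config = sr.VotingConfig(scheme="weighted", measure="confidence")
        report = sr.cross_validate(db, config, 2, 3, 5, (1, 3, 5), seed=0)
        assert report.accuracy_at_k[1] == 100.0
        accs = [report.accuracy_at_k[k] for k in (1, 3, 5)]
        assert accs == sorted(accs)

    def test_shuffled_labels_fall_to_chance(self, separable_world):
        _, _, db, _ = separable_world
        rng = np.random.default_rng(33)
        diseases = sorted({t.disease for t in db}, key=lambda d: d.concept)
        shuffled = []
        for i, t in enumerate(db):
            d = diseases[int(rng.integers(len(diseases)))]
            shuffled.append(
                sr.Transaction(t.case_id, t.phenotypes | {d})
            )
        sdb = sr.TransactionDatabase(tuple(shuffled))
        config = sr.VotingConfig(scheme="weighted", measure="confidence")
        report = sr.cross_validate(sdb, config, 1, 3, 5, (1,), seed=0)
        # chance level is 100/6 ~ 16.7%; allow generous Monte-Carlo slack
        assert report.accuracy_at_k[1] < 45.0

    def test_stratified_folds_cover_all_cases_once(self, separable_world):
        _, _, db, _ = separable_world
        folds = _stratified_folds(db, 5, seed=4)
        flat = sorted(i for f in folds for i in f)
        assert flat == list(range(db.n))
        # stratification: every fold sees every disorder (10 cases, 5 folds)
        for f in folds:
            assert {db.transactions[i].disease for i in f} == set(
                t.disease for t in db
            )

    def test_too_few_folds_rejected(self, separable_world):
        _, _, db, _ = separable_world
        config = sr.VotingConfig()
        with pytest.raises(ValueError, match="folds"):
            sr.cross_validate(db, config, 2, 4, 1, (1,), seed=0)


class TestDiscordanceAndMcnemar:
    def _preds(self, case_ids, top):
        return [
            sr.Prediction(c, [(sr.Item(t, "disease"), 1.0)]) for c, t in zip(case_ids, top)
        ]

    def test_identical_predictions_no_discordance(self):
        ids = ["c1", "c2"]
        a = self._preds(ids, ["d1", "d2"])
        truths = {"c1": sr.Item("d1", "disease"), "c2": sr.Item("d1", "disease")}
        table = sr.discordance(a, a, truths, 1)
        assert (table.a_only, table.b_only) == (0, 0)
        assert table.total == 2

    def test_hand_constructed_disagreement(self):
        ids = ["c1", "c2", "c3", "c4"]
        truths = {c: sr.Item("d1", "disease") for c in ids}
        a = self._preds(ids, ["d1", "d1", "d2", "d2"])
        b = self._preds(ids, ["d1", "d2", "d1", "d2"])
        table = sr.discordance(a, b, truths, 1)
        assert (table.both_correct, table.a_only, table.b_only, table.both_wrong) == (
            1, 1, 1, 1,
        )

    def test_case_set_mismatch_rejected(self):
        truths = {"c1": sr.Item("d1", "disease")}
        with pytest.raises(ValueError, match="different case sets"):
            sr.discordance(
                self._preds(["c1"], ["d1"]), self._preds(["c2"], ["d1"]), truths, 1
            )

    def test_published_counts_sum_to_cohort(self, fixture_world):
        _, _, _, counts = fixture_world
        table = sr.DiscordanceTable(*counts)
        assert table.total == 394
        assert table.both_correct + table.a_only == 225  # traditional correct
        assert table.both_correct + table.b_only == 256  # semantic correct

    def test_mcnemar_published_value(self, fixture_world):
        _, _, _, counts = fixture_world
        stat, p = sr.mcnemar(counts[2], counts[1])  # 51, 20
        assert stat == pytest.approx(12.67, abs=0.01)
        assert stat == pytest.approx(900 / 71)
        assert p == pytest.approx(0.00037157, abs=1e-5)

    def test_mcnemar_symmetric(self):
        assert sr.mcnemar(51, 20) == sr.mcnemar(20, 51)

    def test_continuity_correction_clamped(self):
        stat, p = sr.mcnemar(5, 5)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_no_discordance_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            sr.mcnemar(0, 0)
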