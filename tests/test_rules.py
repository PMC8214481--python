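"""Apriori mining, rule metrics and rule grouping."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from herbnet.rules import apriori, generate_rules, group_rules, mine_rules

from conftest import make_db, random_db


def brute_force_frequent(db, min_support):
    """Enumerate every subset of the item universe and count support."""
    items = sorted(db.herbs)
    baskets = [t.herbs for t in db]
    n = len(baskets)
    out = {}
    for r in range(1, len(items) + 1):
        for combo in combinations(items, r):
            s = frozenset(combo)
            c = sum(1 for b in baskets if s <= b)
            if c >= min_support * n:
                out[s] = c
    return out


def brute_force_rules(db, min_support, min_confidence):
    """Score every (lhs, single rhs) split of every itemset by direct counting."""
    baskets = [t.herbs for t in db]
    n = len(baskets)

    def count(s):
        return sum(1 for b in baskets if s <= b)

    rules = {}
    for s, c in brute_force_frequent(db, min_support).items():
        if len(s) < 2:
            continue
        support = c / n
        if support <= min_support:
            continue
        for rhs_item in sorted(s):
            rhs = frozenset([rhs_item])
            lhs = s - rhs
            coverage = count(lhs) / n
            confidence = support / coverage
            if confidence > min_confidence:
                lift = confidence / (count(rhs) / n)
                rules[(lhs, rhs)] = (support, confidence, coverage, lift, c)
    return rules


class TestApriori:
    def test_single_transaction_all_subsets_frequent(self):
        db = make_db([("p1", "case", "AB")])
        freq = apriori(db, min_support=0.5)
        assert freq == {
            frozenset("A"): 1, frozenset("B"): 1, frozenset("AB"): 1,
        }

    def test_support_one_keeps_only_universal_itemsets(self):
        db = make_db([("p1", "case", "ABC"), ("p2", "case", "AB"), ("p3", "case", "AC")])
        freq = apriori(db, min_support=1.0)
        assert set(freq) == {frozenset("A")}

    def test_downward_closure(self):
        rng = np.random.default_rng(20)
        db = random_db(rng, n_items=8, n_transactions=30)
        freq = apriori(db, min_support=0.2)
        for s in freq:
            for item in s:
                assert (s - {item}) in freq or len(s) == 1

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(21)
        for rep in range(10):
            db = random_db(rng, n_items=8, n_transactions=30)
            min_support = float(rng.uniform(0.1, 0.5))
            assert apriori(db, min_support) == brute_force_frequent(db, min_support)

    def test_transaction_order_invariance(self):
        rng = np.random.default_rng(22)
        db = random_db(rng, n_items=6, n_transactions=20)
        shuffled = make_db(
            [(t.prescription_id, t.cohort, t.herbs) for t in reversed(db.transactions)]
        )
        assert apriori(db, 0.2) == apriori(shuffled, 0.2)

    def test_max_len_caps_itemset_size(self):
        db = make_db([("p1", "case", "ABC"), ("p2", "case", "ABC")])
        freq = apriori(db, 0.5, max_len=2)
        assert max(len(s) for s in freq) == 2


class TestRuleMetrics:
    def test_metric_identities_hold_exactly(self):
        rng = np.random.default_rng(23)
        db = random_db(rng, n_items=8, n_transactions=40)
        n = len(db)
        freq = apriori(db, 0.05)
        for r in generate_rules(freq, n, min_support=0.05, min_confidence=0.0):
            assert r.support == pytest.approx(r.count / n, abs=1e-12)
            assert r.confidence == pytest.approx(r.support / r.coverage, abs=1e-12)
            assert 0 <= r.support <= r.coverage <= 1

    def test_lift_symmetry(self):
        rng = np.random.default_rng(24)
        db = random_db(rng, n_items=6, n_transactions=30)
        rules = mine_rules(db, min_support=0.05, min_confidence=0.0)
        by_pair = {(tuple(sorted(r.lhs)), tuple(sorted(r.rhs))): r.lift for r in rules}
        for (lhs, rhs), lift in by_pair.items():
            mirror = (rhs, lhs)
            if mirror in by_pair:
                assert lift == pytest.approx(by_pair[mirror], abs=1e-12)

    def test_rules_match_exhaustive_oracle_on_toy_db(self):
        db = make_db([
            ("p1", "case", "AB"), ("p2", "case", "ABC"), ("p3", "case", "AC"),
            ("p4", "case", "BC"), ("p5", "case", "AB"), ("p6", "case", "C"),
        ])
        mined = mine_rules(db, min_support=0.2, min_confidence=0.5)
        expected = brute_force_rules(db, 0.2, 0.5)
        assert {(r.lhs, r.rhs) for r in mined} == set(expected)
        for r in mined:
            sup, conf, cov, lift, count = expected[(r.lhs, r.rhs)]
            assert r.support == pytest.approx(sup, abs=1e-12)
            assert r.confidence == pytest.approx(conf, abs=1e-12)
            assert r.coverage == pytest.approx(cov, abs=1e-12)
            assert r.lift == pytest.approx(lift, abs=1e-12)
            assert r.count == count

    def test_strict_thresholds_are_exclusive(self):
        # support exactly 0.2 must be dropped under the strict default
        db = make_db([("p1", "case", "AB")] + [(f"q{i}", "case", "C") for i in range(4)])
        assert mine_rules(db, min_support=0.2, min_confidence=0.5) == []
        relaxed = mine_rules(db, min_support=0.2, min_confidence=0.5, strict=False)
        assert {(r.lhs, r.rhs) for r in relaxed} == {
            (frozenset("A"), frozenset("B")), (frozenset("B"), frozenset("A")),
        }

    def test_ordering_by_lift_then_support(self):
        rng = np.random.default_rng(25)
        db = random_db(rng, n_items=6, n_transactions=40)
        rules = mine_rules(db, min_support=0.05, min_confidence=0.0)
        keys = [(-r.lift, -r.support) for r in rules]
        assert keys == sorted(keys)


class TestGroupRules:
    def _rules(self, db):
        return mine_rules(db, min_support=0.1, min_confidence=0.1)

    def test_each_distinct_vector_its_own_cluster(self):
        db = make_db([
            ("p1", "case", "AB"), ("p2", "case", "AB"),
            ("p3", "case", "CD"), ("p4", "case", "CD"),
        ])
        rules = self._rules(db)
        distinct = {tuple(sorted(r.lhs | r.rhs)) for r in rules}
        labels = group_rules(rules, k=len(distinct), seed=0)
        by_vec = {}
        for r, lab in zip(rules, labels):
            by_vec.setdefault(tuple(sorted(r.lhs | r.rhs)), set()).add(lab)
        assert all(len(v) == 1 for v in by_vec.values())
        assert len({tuple(v)[0] for v in by_vec.values()}) == len(distinct)

    def test_mirror_rules_always_co_clustered(self):
        db = make_db([
            ("p1", "case", "AB"), ("p2", "case", "AB"), ("p3", "case", "CD"),
            ("p4", "case", "CD"), ("p5", "case", "AC"),
        ])
        rules = self._rules(db)
        labels = group_rules(rules, k=2, seed=1)
        by_pair = {}
        for r, lab in zip(rules, labels):
            by_pair.setdefault(frozenset(r.lhs | r.rhs), set()).add(lab)
        for pair, labs in by_pair.items():
            assert len(labs) == 1  # A=>B and B=>A share an incidence vector

    def test_planted_disjoint_blocks_recovered(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            rows = []
            for i in range(40):
                block = {"A", "B", "C"} if i % 2 == 0 else {"X", "Y", "Z"}
                keep = {h for h in block if rng.random() < 0.9}
                rows.append((f"p{i}", "case", keep or block))
            db = make_db(rows)
            rules = mine_rules(db, min_support=0.1, min_confidence=0.3)
            labels = group_rules(rules, k=2, seed=rep)
            first = {lab for r, lab in zip(rules, labels) if (r.lhs | r.rhs) <= {"A", "B", "C"}}
            second = {lab for r, lab in zip(rules, labels) if (r.lhs | r.rhs) <= {"X", "Y", "Z"}}
            hits += len(first) == 1 and len(second) == 1 and first != second
        assert hits >= 19

    def test_k_larger_than_distinct_vectors_rejected(self):
        db = make_db([("p1", "case", "AB"), ("p2", "case", "AB")])
        rules = self._rules(db)
        assert len(rules) == 2  # A=>B and B=>A share one incidence vector
        with pytest.raises(ValueError, match="distinct"):
            group_rules(rules, k=2, seed=0)
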