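"""From-scratch Apriori mining and association-rule generation.

The miner is level-wise with the downward-closure pruning property: a
candidate of size k is generated only from two frequent (k-1)-sets sharing a
(k-2)-prefix, and is kept only if all of its (k-1)-subsets are frequent. Rule
metrics follow the market-basket conventions used in clinical co-prescription
studies:

    support    = count(LHS u RHS) / n_transactions
    coverage   = support(LHS)
    confidence = support / coverage
    lift       = confidence / support(RHS)

Rules are retained with strictly support > 0.2 and confidence > 0.5 by
default; both thresholds and the strictness are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io import TransactionDB

__all__ = ["AssociationRule", "apriori", "generate_rules", "group_rules", "mine_rules"]

Itemset = frozenset[str]


@dataclass(frozen=True)
class AssociationRule:
    lhs: Itemset
    rhs: Itemset
    support: float
    confidence: float
    coverage: float
    lift: float
    count: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lhs = ",".join(sorted(self.lhs))
        rhs = ",".join(sorted(self.rhs))
        return (
            f"{lhs} => {rhs} (supp={self.support:.3f}, conf={self.confidence:.3f}, "
            f"lift={self.lift:.3f}, n={self.count})"
        )


def apriori(
    db: TransactionDB,
    min_support: float,
    max_len: int | None = None,
) -> dict[Itemset, int]:
    """All itemsets with support >= ``min_support``, mapped to their counts."""
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must lie in (0, 1]")
    n = len(db)
    if n == 0:
        raise ValueError("empty transaction database")
    min_count = min_support * n
    baskets = [t.herbs for t in db]

    counts: dict[Itemset, int] = {}
    item_counts = db.herb_use_counts()
    current = {
        frozenset([h]): c for h, c in item_counts.items() if c >= min_count
    }
    level = 1
    while current:
        counts.update(current)
        if max_len is not None and level >= max_len:
            break
        candidates = _candidates(list(current), level + 1, set(current))
        if not candidates:
            break
        nxt: dict[Itemset, int] = {}
        for cand in candidates:
            c = sum(1 for basket in baskets if cand <= basket)
            if c >= min_count:
                nxt[cand] = c
        current = nxt
        level += 1
    return counts


def _candidates(
    frequent_prev: list[Itemset], size: int, frequent_set: set[Itemset]
) -> list[Itemset]:
    """Prefix-join candidate generation with subset pruning."""
    sorted_prev = sorted(tuple(sorted(s)) for s in frequent_prev)
    out: list[Itemset] = []
    for i in range(len(sorted_prev)):
        for j in range(i + 1, len(sorted_prev)):
            a, b = sorted_prev[i], sorted_prev[j]
            if a[: size - 2] != b[: size - 2]:
                break  # sorted list: no further shared prefix
            cand = frozenset(a) | frozenset(b)
            if len(cand) != size:
                continue
            if all(cand - {x} in frequent_set for x in cand):
                out.append(cand)
    return out


def generate_rules(
    frequents: dict[Itemset, int],
    n_transactions: int,
    min_support: float = 0.2,
    min_confidence: float = 0.5,
    max_rhs: int = 1,
    strict: bool = True,
) -> list[AssociationRule]:
    """Score every (LHS, RHS) split of each frequent itemset and filter.

    ``frequents`` must come from :func:`apriori` at a mining support no higher
    than ``min_support`` so that all subset counts are available. RHS size is
    capped at ``max_rhs`` (1 reproduces the single-consequent rules of clinical
    co-prescription reports). With ``strict`` (default) the thresholds are
    exclusive, i.e. support > min_support and confidence > min_confidence.
    """
    if n_transactions <= 0:
        raise ValueError("n_transactions must be positive")
    keep = (lambda v, t: v > t) if strict else (lambda v, t: v >= t)
    rules: list[AssociationRule] = []
    for itemset, count in frequents.items():
        if len(itemset) < 2:
            continue
        support = count / n_transactions
        if not keep(support, min_support):
            continue
        for r in range(1, max_rhs + 1):
            if r >= len(itemset):
                break
            for rhs_items in combinations(sorted(itemset), r):
                rhs = frozenset(rhs_items)
                lhs = itemset - rhs
                if lhs not in frequents or rhs not in frequents:
                    continue  # cannot happen under downward closure
                coverage = frequents[lhs] / n_transactions
                rhs_support = frequents[rhs] / n_transactions
                confidence = support / coverage
                lift = confidence / rhs_support
                if keep(confidence, min_confidence):
                    rules.append(
                        AssociationRule(
                            lhs=lhs,
                            rhs=rhs,
                            support=support,
                            confidence=confidence,
                            coverage=coverage,
                            lift=lift,
                            count=count,
                        )
                    )
    rules.sort(
        key=lambda r: (-r.lift, -r.support, tuple(sorted(r.lhs)), tuple(sorted(r.rhs)))
    )
    return rules


def mine_rules(
    db: TransactionDB,
    min_support: float = 0.2,
    min_confidence: float = 0.5,
    max_len: int | None = None,
    max_rhs: int = 1,
    strict: bool = True,
) -> list[AssociationRule]:
    """Convenience: :func:`apriori` followed by :func:`generate_rules`."""
    frequents = apriori(db, min_support=min_support, max_len=max_len)
    return generate_rules(
        frequents,
        n_transactions=len(db),
        min_support=min_support,
        min_confidence=min_confidence,
        max_rhs=max_rhs,
        strict=strict,
    )


def group_rules(rules: list[AssociationRule], k: int, seed: int = 0) -> np.ndarray:
    """Cluster rules by k-means on binary item-incidence vectors.

    Each rule is embedded as a 0/1 vector over the union of all items appearing
    in any LHS or RHS; identical rules therefore always co-cluster, and the
    result is deterministic under ``seed``.
    """
    from sklearn.cluster import KMeans

    if len(rules) < k:
        raise ValueError("need at least k rules")
    items = sorted(set().union(*(r.lhs | r.rhs for r in rules)))
    index = {it: i for i, it in enumerate(items)}
    X = np.zeros((len(rules), len(items)))
    for row, r in enumerate(rules):
        for it in r.lhs | r.rhs:
            X[row, index[it]] = 1.0
    if k > len({tuple(row) for row in X.tolist()}):
        raise ValueError("k exceeds the number of distinct rule incidence vectors")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X)
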