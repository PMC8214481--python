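"""Shared fixtures: tiny hand-checkable databases and graphs."""

from __future__ import annotations

import numpy as np
import pytest

from herbnet.io import Transaction, TransactionDB


def make_db(rows) -> TransactionDB:
    """rows: iterable of (pid, cohort, iterable-of-herbs)."""
    return TransactionDB(
        tuple(Transaction(pid, cohort, frozenset(herbs)) for pid, cohort, herbs in rows)
    )


@pytest.fixture
def tiny_db() -> TransactionDB:
    return make_db(
        [
            ("p1", "case", {"A", "B"}),
            ("p2", "case", {"A", "B"}),
            ("p3", "case", {"A", "C"}),
            ("p4", "control", {"B", "C"}),
            ("p5", "control", {"C"}),
        ]
    )


def random_db(rng: np.random.Generator, n_items: int = 8, n_transactions: int = 30,
              cohort: str = "case") -> TransactionDB:
    """Random transaction database over items i0..i{n_items-1}; no empty baskets."""
    items = [f"i{j}" for j in range(n_items)]
    rows = []
    for t in range(n_transactions):
        mask = rng.random(n_items) < rng.uniform(0.2, 0.7)
        if not mask.any():
            mask[rng.integers(n_items)] = True
        rows.append((f"t{t}", cohort, {items[j] for j in np.flatnonzero(mask)}))
    return make_db(rows)
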