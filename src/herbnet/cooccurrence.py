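"""Weighted herb co-prescription network and hierarchical shell extraction.

The network has herbs as nodes; the weight of an edge is the number of
prescriptions in which the two herbs are used together. The main-herb "shell"
of the network is the largest prefix of the weight-sorted herb pairs whose
cumulative weight S_k still satisfies the degree-coefficient criterion

    S_k * N >= k**alpha * S_N

with N the number of herbs in the data, S_N the total weight over all pairs
and alpha the degree coefficient (2.4 in the clinical application this
package targets). Shells are peeled iteratively from the residual network to
produce a layered core structure; the herbs incident to layer-1 edges are the
reported core herbs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import TransactionDB

__all__ = [
    "WeightedHerbNetwork",
    "ShellLayer",
    "ShellResult",
    "build_network",
    "extract_shell",
    "extract_hierarchy",
]

Edge = tuple[str, str]


@dataclass(frozen=True)
class WeightedHerbNetwork:
    """Co-prescription graph: unordered herb pairs weighted by joint frequency.

    ``n_herbs`` (N) is fixed at the herb count of the originating data and is
    carried unchanged through shell peeling; ``total_pair_weight`` (S_N) is the
    sum of the current edge weights.
    """

    nodes: tuple[str, ...]
    edges: Mapping[Edge, int]
    n_herbs: int

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a >= b:
                raise ValueError(f"edge key must be a sorted pair, got {(a, b)}")
            if w <= 0:
                raise ValueError(f"edge weights must be positive, got {(a, b)}: {w}")

    @property
    def total_pair_weight(self) -> int:
        return sum(self.edges.values())

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_network(db: TransactionDB, cohort_filter: str | None = None) -> WeightedHerbNetwork:
    """Count pairwise co-prescription over ``db`` (optionally one cohort).

    weight(a, b) = number of prescriptions containing both a and b; pairs that
    never co-occur are absent. Single-herb prescriptions contribute no edges
    but their herb still counts toward N.
    """
    if cohort_filter is not None:
        db = db.filter_cohort(cohort_filter)
    if len(db) == 0:
        raise ValueError("no transactions after cohort filtering")
    herbs = sorted(db.herbs)
    index = {h: i for i, h in enumerate(herbs)}
    n_rx, n_h = len(db), len(herbs)
    incidence = np.zeros((n_rx, n_h), dtype=np.int32)
    for r, t in enumerate(db):
        for h in t.herbs:
            incidence[r, index[h]] = 1
    co = incidence.T @ incidence
    iu = np.triu_indices(n_h, k=1)
    weights = co[iu]
    nz = weights > 0
    edges = {
        (herbs[i], herbs[j]): int(w)
        for i, j, w in zip(iu[0][nz], iu[1][nz], weights[nz])
    }
    return WeightedHerbNetwork(tuple(herbs), edges, n_herbs=n_h)


@dataclass(frozen=True)
class ShellLayer:
    """One extracted shell: its edges (weight-descending) and bookkeeping."""

    edges: tuple[tuple[Edge, int], ...]
    cumulative_weights: tuple[int, ...]  # S_k for k = 1..K
    fallback: bool  # True when no k met the criterion and the top edge was forced

    @property
    def herbs(self) -> frozenset[str]:
        out: set[str] = set()
        for (a, b), _ in self.edges:
            out |= {a, b}
        return frozenset(out)


def _sorted_edges(net: WeightedHerbNetwork) -> list[tuple[Edge, int]]:
    # weight descending; ties broken lexicographically on the sorted pair for
    # run-to-run determinism
    return sorted(net.edges.items(), key=lambda kv: (-kv[1], kv[0]))


def extract_shell(
    net: WeightedHerbNetwork, alpha: float = 2.4
) -> tuple[ShellLayer, WeightedHerbNetwork]:
    """Peel one shell off ``net`` and return (layer, residual network).

    The layer is the top-K weight-sorted edges for the largest K with
    S_K * N >= K**alpha * S_N. When no K qualifies the single heaviest edge is
    returned instead (flagged, with a warning) so that iterative peeling always
    terminates. N is left unchanged in the residual.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not net.edges:
        raise ValueError("cannot extract a shell from an edgeless network")
    ranked = _sorted_edges(net)
    s_n = net.total_pair_weight
    n = net.n_herbs
    cum = 0
    best_k = 0
    cumulative: list[int] = []
    for k, (_, w) in enumerate(ranked, start=1):
        cum += w
        cumulative.append(cum)
        if cum * n >= (k ** alpha) * s_n:
            best_k = k
    fallback = best_k == 0
    if fallback:
        warnings.warn(
            "no k satisfies the shell criterion; returning the single heaviest "
            "edge to guarantee progress",
            stacklevel=2,
        )
        best_k = 1
    layer = ShellLayer(
        edges=tuple(ranked[:best_k]),
        cumulative_weights=tuple(cumulative[:best_k]),
        fallback=fallback,
    )
    taken = {e for e, _ in layer.edges}
    residual_edges = {e: w for e, w in net.edges.items() if e not in taken}
    residual = WeightedHerbNetwork(net.nodes, residual_edges, n_herbs=net.n_herbs)
    return layer, residual


@dataclass(frozen=True)
class ShellResult:
    """Layered shell decomposition of a co-prescription network."""

    layers: tuple[ShellLayer, ...]
    alpha: float
    residual: WeightedHerbNetwork

    @property
    def core_herbs(self) -> frozenset[str]:
        """Herbs incident to layer-1 edges — the reported main herbs."""
        return self.layers[0].herbs if self.layers else frozenset()

    def layer_assignment(self) -> dict[Edge, int]:
        out: dict[Edge, int] = {}
        for i, layer in enumerate(self.layers, start=1):
            for e, _ in layer.edges:
                out[e] = i
        return out


def extract_hierarchy(
    net: WeightedHerbNetwork,
    alpha: float = 2.4,
    max_layers: int | None = None,
) -> ShellResult:
    """Repeatedly peel shells until the network is edgeless or ``max_layers``.

    Run to exhaustion, the layers partition the original edge set.
    """
    layers: list[ShellLayer] = []
    current = net
    while current.edges and (max_layers is None or len(layers) < max_layers):
        layer, current = extract_shell(current, alpha)
        layers.append(layer)
    return ShellResult(tuple(layers), alpha=alpha, residual=current)
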