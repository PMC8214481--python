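"""Compound–target–disease-gene network: assembly, dense cores, and RWR.

Three pieces of machinery live here:

* :func:`build_molecular_network` — union of a confidence-weighted protein
  interaction network with bipartite compound→target edges and disease-gene
  markings;
* :func:`mcode_cores` — seeded greedy detection of densely connected
  complexes (vertex weighting by the highest k-core of the closed
  neighbourhood, greedy expansion from the heaviest seed, optional haircut),
  as used to call "core targets" in interaction networks;
* :func:`rwr` — random walk with restart. With restart probability c, seed
  distribution s and column-normalized weighted adjacency W, the walker's
  stationary distribution solves p = (1-c) W p + c s; compounds are ranked by
  their stationary visiting probability and the strict upper quartile is
  retained as the core effective compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .io import HerbAnnotation

__all__ = [
    "MolecularNetwork",
    "Complex",
    "RWRScores",
    "build_molecular_network",
    "mcode_cores",
    "rwr",
    "retain_core_compounds",
]


@dataclass
class MolecularNetwork:
    """Typed heterogeneous graph over compounds, targets and disease genes."""

    graph: nx.Graph
    compounds: frozenset[str]
    targets: frozenset[str]
    disease_genes: frozenset[str]

    @property
    def protein_view(self) -> nx.Graph:
        """Subgraph induced on target/disease-gene (non-compound) nodes."""
        keep = [n for n in self.graph if n not in self.compounds]
        return self.graph.subgraph(keep)


def build_molecular_network(
    ppi_edges: Mapping[tuple[str, str], float],
    annotations: Sequence[HerbAnnotation],
    disease_genes: Iterable[str],
    compound_targets: Mapping[str, Iterable[str]] | None = None,
) -> MolecularNetwork:
    """Union PPI + compound–target bipartite edges, with disease genes marked.

    When a compound-level target map is supplied each compound links only to
    its own targets; otherwise each compound of a herb links to all of that
    herb's targets. PPI edges carry their confidence as weight; compound–target
    edges weigh 1. Disease genes absent from the PPI are added as isolated
    nodes with a warning (they may still act as walk seeds).
    """
    if not ppi_edges:
        raise ValueError("PPI edge set is empty")
    g = nx.Graph()
    for (a, b), conf in ppi_edges.items():
        if a == b:
            continue
        g.add_edge(a, b, weight=float(conf), kind="ppi")

    compounds: set[str] = set()
    targets: set[str] = set(g.nodes)
    for ann in annotations:
        for c in ann.compounds:
            compounds.add(c)
            tgt = compound_targets.get(c, ()) if compound_targets is not None else ann.targets
            for t in tgt:
                g.add_edge(c, t, weight=1.0, kind="compound_target")
                targets.add(t)
        targets |= ann.targets
    orphans = sorted(c for c in compounds if c not in g or g.degree(c) == 0)
    if orphans:
        warnings.warn(
            f"{len(orphans)} compounds have no target edge and were dropped: "
            f"{orphans[:5]}...",
            stacklevel=2,
        )
        compounds -= set(orphans)
        g.remove_nodes_from([c for c in orphans if c in g])

    disease = frozenset(disease_genes)
    isolated = sorted(dg for dg in disease if dg not in g)
    if isolated:
        warnings.warn(
            f"{len(isolated)} disease genes are absent from the network and "
            f"were added as isolated nodes: {isolated[:5]}...",
            stacklevel=2,
        )
        g.add_nodes_from(isolated)
    for n in g.nodes:
        kinds = set()
        if n in compounds:
            kinds.add("compound")
        if n in disease:
            kinds.add("disease_gene")
        if n in targets - compounds:
            kinds.add("target")
        g.nodes[n]["kinds"] = frozenset(kinds) or frozenset({"target"})
    return MolecularNetwork(
        graph=g,
        compounds=frozenset(compounds),
        targets=frozenset(targets - compounds),
        disease_genes=disease,
    )


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Complex:
    nodes: frozenset[str]
    score: float  # density * size
    density: float


def _vertex_weight(g: nx.Graph, v, degree_cutoff: int) -> float:
    if g.degree(v) < degree_cutoff:
        return 0.0
    nbhd = g.subgraph(list(g[v]) + [v])
    core = nx.core_number(nbhd)
    kmax = max(core.values())
    core_nodes = [n for n, k in core.items() if k >= kmax]
    sub = nbhd.subgraph(core_nodes)
    n = sub.number_of_nodes()
    if n < 2:
        return 0.0
    density = 2.0 * sub.number_of_edges() / (n * (n - 1))
    return kmax * density


def mcode_cores(
    g: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    haircut: bool = True,
) -> list[Complex]:
    """Detect dense complexes with the MCODE procedure (fluff off).

    (i) each vertex is weighted by the highest k-core number of its closed
    neighbourhood times that k-core's density; (ii) complexes grow greedily
    from the highest-weighted unused seed, admitting unvisited neighbours whose
    weight exceeds ``(1 - node_score_cutoff)`` of the seed weight; (iii)
    complexes lacking a ``k_core``-core are discarded and, with ``haircut``,
    trimmed to their 2-core. Complexes are scored density x size, descending.
    """
    if g.number_of_nodes() == 0:
        return []
    weights = {v: _vertex_weight(g, v, degree_cutoff) for v in g.nodes}
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    used: set = set()
    complexes: list[Complex] = []
    for seed in order:
        if seed in used or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        used.add(seed)
        while frontier:
            v = frontier.pop()
            for u in g[v]:
                if u in used or u in members:
                    continue
                if weights[u] > threshold:
                    members.add(u)
                    used.add(u)
                    frontier.append(u)
        sub = g.subgraph(members)
        if sub.number_of_nodes() < 2:
            continue
        if max(nx.core_number(sub).values()) < k_core:
            continue
        if haircut:
            sub = nx.k_core(sub, 2)
            if sub.number_of_nodes() < 2:
                continue
        n = sub.number_of_nodes()
        density = 2.0 * sub.number_of_edges() / (n * (n - 1))
        complexes.append(Complex(frozenset(sub.nodes), score=density * n, density=density))
    complexes.sort(key=lambda c: (-c.score, tuple(sorted(c.nodes))))
    return complexes


# ---------------------------------------------------------------------------
# random walk with restart
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RWRScores:
    scores: dict[str, float]
    restart_prob: float
    seeds: frozenset[str]
    iterations: int
    converged: bool

    def of(self, nodes: Iterable[str]) -> dict[str, float]:
        return {n: self.scores[n] for n in nodes}


def rwr(
    net: MolecularNetwork | nx.Graph,
    seeds: Iterable[str],
    restart_prob: float = 0.75,
    tol: float = 1e-9,
    max_iter: int = 10_000,
    normalization: str = "column",
) -> RWRScores:
    """Random walk with restart from ``seeds`` over the weighted graph.

    Iterates p <- (1-c) W p + c s with s uniform over the seeds until the L1
    change drops below ``tol``. W is the column-normalized weighted adjacency
    (``normalization="symmetric"`` switches to D^-1/2 A D^-1/2); isolated nodes
    get a self-loop so that probability mass is conserved.
    """
    g = net.graph if isinstance(net, MolecularNetwork) else net
    if not 0.0 < restart_prob <= 1.0:
        raise ValueError("restart_prob must lie in (0, 1]")
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    missing = sorted(s for s in seeds if s not in g)
    if missing:
        raise ValueError(f"seeds not in the network: {missing}")

    nodes = sorted(g.nodes, key=str)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        A[index[a], index[b]] = w
        A[index[b], index[a]] = w
    col = A.sum(axis=0)
    dangling = col == 0
    if dangling.any():
        A[dangling, dangling] = 1.0
        col = A.sum(axis=0)
    if normalization == "column":
        W = A / col
    elif normalization == "symmetric":
        d = np.sqrt(col)
        W = A / d[None, :] / d[:, None]
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    s = np.zeros(n)
    for node in seeds:
        s[index[node]] = 1.0 / len(seeds)
    p = s.copy()
    c = restart_prob
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p_new = (1.0 - c) * (W @ p) + c * s
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            converged = True
            break
        p = p_new
    return RWRScores(
        scores={node: float(p[index[node]]) for node in nodes},
        restart_prob=restart_prob,
        seeds=seeds,
        iterations=it,
        converged=converged,
    )


def retain_core_compounds(
    scores: RWRScores, compounds: Iterable[str]
) -> list[tuple[str, float]]:
    """Rank compounds by stationary probability; keep those strictly above Q3.

    Q3 is the linearly interpolated 75th percentile of the compound scores.
    With fewer than four scored compounds the quartile is meaningless and all
    are retained with a warning; ties in score are broken by node ID.
    """
    comp = sorted(set(compounds))
    missing = [c for c in comp if c not in scores.scores]
    if missing:
        raise ValueError(f"compounds without a score: {missing[:5]}")
    ranked = sorted(((c, scores.scores[c]) for c in comp), key=lambda t: (-t[1], t[0]))
    if len(ranked) < 4:
        warnings.warn("fewer than 4 compounds; retaining all", stacklevel=2)
        return ranked
    q3 = float(np.quantile([v for _, v in ranked], 0.75))
    kept = [(c, v) for c, v in ranked if v > q3]
    if not kept:
        warnings.warn("no compound strictly above Q3 (tied scores?)", stacklevel=2)
    return kept
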