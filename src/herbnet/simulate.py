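"""Synthetic cohort and molecular-network generators.

The generators produce inputs with the statistical structure the pipeline
assumes, so every stage can be exercised and calibrated without access to
hospital medical records or versioned public databases:

* :func:`simulate_cohort` — cohort-labelled prescriptions whose size follows a
  truncated normal (the real data are summarised only as a mean ± sd of herbs
  per prescription, 23.84 ± 3.88), with a planted densely co-prescribed core
  block, case-enriched "specific" herbs implementing a chosen relative risk at
  the prescription level, and a Zipf-weighted heavy-tailed background.
* :func:`simulate_molecular` — a random protein interaction network, bipartite
  compound→target edges grouped into herbs, a disease gene list, and a gene-set
  collection with one planted enriched term.

Both are deterministic given their spec's ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io import GeneSetCollection, HerbAnnotation, Transaction, TransactionDB

__all__ = [
    "CohortSpec",
    "MolecularSpec",
    "MolecularData",
    "simulate_cohort",
    "simulate_molecular",
]

# Herb names from the clinical vocabulary this pipeline targets; used only as
# readable default IDs for the planted structure.
_DEFAULT_CORE = (
    "huangqi", "danshen", "dangshen", "fuling", "baizhu",
    "danggui", "chenpi", "banxia", "gancao",
)
_DEFAULT_SPECIFIC = ("qumai", "cheqianzi", "ezhu", "qianshi", "niuxi")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic prescription cohort.

    ``rr_target`` is the prescription-level relative risk planted for each
    specific herb: a case prescription contains the herb with probability
    ``rr_target * specific_base_prob``, a control one with
    ``specific_base_prob``.
    """

    n_case: int = 1499
    n_control: int = 1499
    herb_universe_size: int = 425
    mean_rx_size: float = 23.84
    sd_rx_size: float = 3.88
    core_herbs: tuple[str, ...] = _DEFAULT_CORE
    core_inclusion_prob: float = 0.8
    specific_herbs: tuple[str, ...] = _DEFAULT_SPECIFIC
    specific_base_prob: float = 0.05
    rr_target: float = 3.0
    background_zipf_exponent: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 0:
            raise ValueError("need n_case >= 1 and n_control >= 0")
        if not 0.0 < self.core_inclusion_prob <= 1.0:
            raise ValueError("core_inclusion_prob must lie in (0, 1]")
        if not 0.0 <= self.specific_base_prob <= 1.0:
            raise ValueError("specific_base_prob must lie in [0, 1]")
        if self.rr_target < 0:
            raise ValueError("rr_target must be non-negative")
        if self.rr_target * self.specific_base_prob > 1.0:
            raise ValueError("rr_target * specific_base_prob exceeds 1")
        if self.mean_rx_size <= 0 or self.sd_rx_size < 0:
            raise ValueError("prescription size parameters must be positive")
        planted = set(self.core_herbs) | set(self.specific_herbs)
        if len(planted) != len(self.core_herbs) + len(self.specific_herbs):
            raise ValueError("core and specific herb lists overlap or repeat")
        if self.n_background < 0:
            raise ValueError(
                "infeasible spec: planted herbs exceed herb_universe_size"
            )

    @property
    def n_background(self) -> int:
        return self.herb_universe_size - len(self.core_herbs) - len(self.specific_herbs)

    @property
    def background_herbs(self) -> tuple[str, ...]:
        width = max(3, len(str(self.n_background)))
        return tuple(f"bg{i:0{width}d}" for i in range(1, self.n_background + 1))


def simulate_cohort(spec: CohortSpec) -> TransactionDB:
    """Draw a synthetic :class:`~herbnet.io.TransactionDB` from ``spec``.

    Per prescription: a target size is drawn from
    Normal(mean_rx_size, sd_rx_size), rounded and truncated to
    [1, herb_universe_size]; each core herb enters with
    ``core_inclusion_prob``; each specific herb enters with its cohort's
    Bernoulli probability; the remaining slots are filled by Zipf-weighted
    sampling without replacement from the background herbs (rank-r weight
    r**-exponent). The realised size can exceed the target when the Bernoulli
    inclusions alone do.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_case + spec.n_control
    is_case = np.zeros(n, dtype=bool)
    is_case[: spec.n_case] = True

    sizes = np.rint(rng.normal(spec.mean_rx_size, spec.sd_rx_size, size=n))
    sizes = np.clip(sizes, 1, spec.herb_universe_size).astype(int)

    n_core = len(spec.core_herbs)
    n_spec = len(spec.specific_herbs)
    core_in = rng.random((n, n_core)) < spec.core_inclusion_prob if n_core else np.zeros((n, 0), bool)
    if n_spec:
        p = np.where(is_case, spec.rr_target * spec.specific_base_prob, spec.specific_base_prob)
        spec_in = rng.random((n, n_spec)) < p[:, None]
    else:
        spec_in = np.zeros((n, 0), bool)

    n_bg = spec.n_background
    bg_names = spec.background_herbs
    if n_bg:
        ranks = np.arange(1, n_bg + 1, dtype=float)
        log_w = -spec.background_zipf_exponent * np.log(ranks)
        # Gumbel-max trick: top-k keys ~ weighted sampling without replacement
        keys = log_w[None, :] + rng.gumbel(size=(n, n_bg))
        order = np.argsort(-keys, axis=1)
    else:
        order = np.zeros((n, 0), int)

    core_arr = np.asarray(spec.core_herbs, dtype=object)
    spec_arr = np.asarray(spec.specific_herbs, dtype=object)
    transactions: list[Transaction] = []
    for i in range(n):
        herbs = set(core_arr[core_in[i]]) | set(spec_arr[spec_in[i]])
        want = sizes[i] - len(herbs)
        if want > 0 and n_bg:
            take = min(want, n_bg)
            herbs.update(bg_names[j] for j in order[i, :take])
        if not herbs and n_bg:  # size-1 rx where no Bernoulli fired
            herbs.add(bg_names[order[i, 0]])
        cohort = "case" if is_case[i] else "control"
        pid = f"{'case' if is_case[i] else 'ctrl'}{i + 1:05d}"
        transactions.append(Transaction(pid, cohort, frozenset(herbs)))
    return TransactionDB(tuple(transactions))


@dataclass(frozen=True)
class MolecularSpec:
    """Parameters of the synthetic molecular layer.

    ``planted_term_enrichment`` is the fold by which the planted gene set's
    disease-gene density exceeds the background density
    ``n_disease_genes / n_proteins``; 1 means the planted term is drawn
    uniformly (a true null).
    """

    n_proteins: int = 1000
    ppi_model: Literal["erdos_renyi", "preferential_attachment"] = "erdos_renyi"
    ppi_density: float = 0.01
    attachment_m: int = 3
    n_compounds: int = 100
    targets_per_compound: float = 4.0
    n_disease_genes: int = 100
    disease_overlap_frac: float = 0.5
    n_terms: int = 30
    term_size: int = 25
    planted_term_enrichment: float = 5.0
    herb_ids: tuple[str, ...] = _DEFAULT_CORE + _DEFAULT_SPECIFIC
    n_symptoms: int = 68
    symptoms_per_herb: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_disease_genes > self.n_proteins:
            raise ValueError("n_disease_genes exceeds n_proteins")
        if not 0.0 <= self.ppi_density <= 1.0:
            raise ValueError("ppi_density must lie in [0, 1]")
        if not 0.0 <= self.disease_overlap_frac <= 1.0:
            raise ValueError("disease_overlap_frac must lie in [0, 1]")
        if self.planted_term_enrichment < 0:
            raise ValueError("planted_term_enrichment must be non-negative")
        if self.term_size > self.n_proteins:
            raise ValueError("term_size exceeds n_proteins")
        if self.targets_per_compound < 1:
            raise ValueError("targets_per_compound must be >= 1")


@dataclass(frozen=True)
class MolecularData:
    """Bundle produced by :func:`simulate_molecular`."""

    ppi_edges: dict[tuple[str, str], float]
    annotations: tuple[HerbAnnotation, ...]
    compound_targets: dict[str, frozenset[str]]
    disease_genes: tuple[str, ...]
    gene_sets: GeneSetCollection


def simulate_molecular(spec: MolecularSpec) -> MolecularData:
    """Generate PPI edges, herb annotations, disease genes and gene sets.

    PPI edge confidences are Uniform(0.4, 1.0) so that confidence filtering is
    a non-trivial step. Compound→target assignments are uniform; each herb is
    annotated with an equal share of the compounds and with the union of their
    targets. One gene set ("PLANTED") carries disease genes at
    ``planted_term_enrichment`` times the background density (deterministically
    rounded count); with fold 1 it is drawn uniformly like every other term.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_proteins))
    proteins = np.array([f"G{i:0{width}d}" for i in range(1, spec.n_proteins + 1)], dtype=object)

    # --- PPI ---------------------------------------------------------------
    if spec.ppi_model == "erdos_renyi":
        n = spec.n_proteins
        iu = np.triu_indices(n, k=1)
        mask = rng.random(iu[0].shape[0]) < spec.ppi_density
        pairs = list(zip(iu[0][mask], iu[1][mask]))
    else:
        pairs = _preferential_attachment(spec.n_proteins, spec.attachment_m, rng)
    edges: dict[tuple[str, str], float] = {}
    confs = rng.uniform(0.4, 1.0, size=len(pairs))
    for (i, j), c in zip(pairs, confs):
        a, b = proteins[i], proteins[j]
        key = (a, b) if a <= b else (b, a)
        edges[key] = float(c)

    # --- compounds, targets, herbs ------------------------------------------
    cw = len(str(max(spec.n_compounds, 1)))
    compounds = [f"C{i:0{cw}d}" for i in range(1, spec.n_compounds + 1)]
    compound_targets: dict[str, frozenset[str]] = {}
    for c in compounds:
        k = 1 + rng.poisson(max(spec.targets_per_compound - 1.0, 0.0))
        k = min(k, spec.n_proteins)
        idx = rng.choice(spec.n_proteins, size=k, replace=False)
        compound_targets[c] = frozenset(proteins[idx])

    n_herbs = max(len(spec.herb_ids), 1)
    herb_of = rng.integers(0, n_herbs, size=len(compounds))
    symptom_pool = [f"S{i:03d}" for i in range(1, spec.n_symptoms + 1)]
    annotations: list[HerbAnnotation] = []
    for h_idx, herb in enumerate(spec.herb_ids):
        mine = [c for c, owner in zip(compounds, herb_of) if owner == h_idx]
        targets: set[str] = set()
        for c in mine:
            targets |= compound_targets[c]
        n_sym = min(spec.symptoms_per_herb, spec.n_symptoms)
        sym_idx = rng.choice(spec.n_symptoms, size=n_sym, replace=False) if n_sym else []
        annotations.append(
            HerbAnnotation(
                herb_id=herb,
                compounds=frozenset(mine),
                targets=frozenset(targets),
                symptoms=frozenset(symptom_pool[i] for i in sym_idx),
            )
        )

    # --- disease genes -------------------------------------------------------
    all_targets = sorted(set().union(*(a.targets for a in annotations)) or set())
    n_from_targets = int(round(spec.disease_overlap_frac * spec.n_disease_genes))
    n_from_targets = min(n_from_targets, len(all_targets))
    disease: list[str] = []
    if n_from_targets:
        idx = rng.choice(len(all_targets), size=n_from_targets, replace=False)
        disease.extend(all_targets[i] for i in idx)
    remaining = sorted(set(proteins) - set(disease))
    n_rest = spec.n_disease_genes - len(disease)
    if n_rest > len(remaining):
        raise ValueError("cannot draw enough non-overlap disease genes")
    if n_rest:
        idx = rng.choice(len(remaining), size=n_rest, replace=False)
        disease.extend(remaining[i] for i in idx)
    disease = sorted(disease)

    # --- gene sets ------------------------------------------------------------
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    disease_set = set(disease)
    rho = spec.n_disease_genes / spec.n_proteins
    if spec.planted_term_enrichment == 1.0:
        idx = rng.choice(spec.n_proteins, size=spec.term_size, replace=False)
        planted = frozenset(proteins[idx])
    else:
        k_dis = int(round(spec.term_size * min(1.0, spec.planted_term_enrichment * rho)))
        k_dis = min(k_dis, len(disease))
        d_idx = rng.choice(len(disease), size=k_dis, replace=False)
        non_disease = sorted(set(proteins) - disease_set)
        n_idx = rng.choice(len(non_disease), size=spec.term_size - k_dis, replace=False)
        planted = frozenset([disease[i] for i in d_idx] + [non_disease[i] for i in n_idx])
    sets["PLANTED"] = ("planted enriched term", planted)
    tw = len(str(max(spec.n_terms, 1)))
    for t in range(1, spec.n_terms):
        idx = rng.choice(spec.n_proteins, size=spec.term_size, replace=False)
        sets[f"T{t:0{tw}d}"] = (f"random term {t}", frozenset(proteins[idx]))
    collection = GeneSetCollection(sets, frozenset(proteins))
    return MolecularData(
        ppi_edges=edges,
        annotations=tuple(annotations),
        compound_targets=compound_targets,
        disease_genes=tuple(disease),
        gene_sets=collection,
    )


def _preferential_attachment(n: int, m: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Barabási–Albert growth with ``m`` edges per arriving node."""
    m = max(1, min(m, n - 1))
    targets = list(range(m))
    repeated: list[int] = []
    pairs: list[tuple[int, int]] = []
    for v in range(m, n):
        for t in targets:
            pairs.append((min(v, t), max(v, t)))
        repeated.extend(targets)
        repeated.extend([v] * m)
        chosen: set[int] = set()
        while len(chosen) < m:
            chosen.add(repeated[rng.integers(0, len(repeated))])
        targets = sorted(chosen)
    return sorted(set(pairs))
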