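"""End-to-end pipeline: configuration, staged execution and provenance.

The pipeline chains the package's stages in their analytic order — cohort
input, co-prescription core extraction, relative-risk specificity screen,
association rules, molecular network assembly, dense-core detection, random
walk with restart, enrichment, core pathways, and multilevel Ward clustering
— and writes every stage's output plus a manifest recording the config hash,
seed and input checksums. Two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from . import cluster as _cluster
from . import cooccurrence as _cooc
from . import io as _io
from .enrich import EnrichmentResult, core_pathways as _core_pathways, enrich as _enrich_genes
from . import molnet as _molnet
from . import rules as _rules
from . import specificity as _spec

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

DEFAULT_CLUSTER_K = {"symptom": 4, "target": 3, "go": 4, "kegg": 4}


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs and thresholds of a pipeline run.

    Threshold defaults are the reference analysis settings: shell degree
    coefficient alpha = 2.4; RR > 1 with chi-square p < 0.05; rule thresholds
    support > 0.2 and confidence > 0.5; PPI confidence >= 0.9; restart
    probability 0.75; enrichment q < 0.05; cluster counts 4/3/4/4 for the
    symptom/target/GO/KEGG levels.
    """

    transactions: str
    ppi: str | None = None
    annotations: str | None = None
    compound_targets: str | None = None
    disease_genes: str | None = None
    gmt_kegg: str | None = None
    gmt_go: str | None = None

    alpha: float = 2.4
    max_layers: int | None = 3
    rr_min: float = 1.0
    p_max: float = 0.05
    min_support: float = 0.2
    min_confidence: float = 0.5
    rule_groups: int | None = None
    ppi_min_confidence: float = 0.9
    restart_prob: float = 0.75
    q_max: float = 0.05
    cluster_k: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CLUSTER_K))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        for name in ("p_max", "min_support", "min_confidence", "ppi_min_confidence", "q_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.restart_prob <= 1.0:
            raise ValueError("restart_prob must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cluster_k"] = dict(self.cluster_k)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    core_herbs: list[str]
    shell: _cooc.ShellResult
    specificity: list[_spec.SpecificityResult]
    rules: list[_rules.AssociationRule]
    rule_labels: list[int] | None
    complexes: list[_molnet.Complex]
    rwr_scores: _molnet.RWRScores | None
    core_compounds: list[tuple[str, float]]
    disease_enrichment: dict[str, list[EnrichmentResult]]
    core_pathways: dict[str, dict[str, frozenset[str]]]
    assignments: dict[str, dict[str, int]]
    manifest: dict[str, Any]

    @property
    def specific_herbs(self) -> list[str]:
        return [r.herb_id for r in self.specificity if r.selected]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every configured stage; optionally write the result bundle.

    Stages whose inputs are not configured (e.g. no PPI file) are skipped and
    their result fields left empty. Any stage failure is re-raised with the
    stage name prefixed.
    """
    inputs = {
        name: getattr(config, name)
        for name in (
            "transactions", "ppi", "annotations", "compound_targets",
            "disease_genes", "gmt_kegg", "gmt_go",
        )
        if getattr(config, name)
    }
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # annotate with the stage name
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    db = stage("read_transactions")(lambda: _io.read_transactions(config.transactions))

    def _core():
        net = _cooc.build_network(db, cohort_filter="case")
        shell = _cooc.extract_hierarchy(net, alpha=config.alpha, max_layers=config.max_layers)
        return shell

    shell = stage("core_extraction")(_core)
    core_herbs = sorted(shell.core_herbs)

    def _specificity():
        counts = db.cohort_counts()
        if counts["control"] == 0:
            return []
        return _spec.screen_specific_herbs(db, rr_min=config.rr_min, p_max=config.p_max)

    specificity = stage("specificity")(_specificity)

    def _mine():
        case_db = db.filter_cohort("case")
        return _rules.mine_rules(
            case_db,
            min_support=config.min_support,
            min_confidence=config.min_confidence,
        )

    rules = stage("association_rules")(_mine)
    rule_labels = None
    if config.rule_groups and len(rules) >= config.rule_groups:
        rule_labels = list(
            stage("rule_grouping")(
                lambda: _rules.group_rules(rules, k=config.rule_groups, seed=config.seed)
            )
        )

    complexes: list[_molnet.Complex] = []
    rwr_scores = None
    core_compounds: list[tuple[str, float]] = []
    disease_enrichment: dict[str, list[EnrichmentResult]] = {}
    core_paths: dict[str, dict[str, frozenset[str]]] = {}
    assignments: dict[str, dict[str, int]] = {}

    annotations = (
        stage("read_annotations")(lambda: _io.read_annotations(config.annotations))
        if config.annotations
        else []
    )
    disease = (
        stage("read_disease_genes")(lambda: _io.read_id_list(config.disease_genes))
        if config.disease_genes
        else []
    )

    if config.ppi and annotations and disease:
        def _network():
            edges = _io.read_edge_list(config.ppi, min_confidence=config.ppi_min_confidence)
            ct = (
                _io.read_compound_targets(config.compound_targets)
                if config.compound_targets
                else None
            )
            return _molnet.build_molecular_network(edges, annotations, disease, compound_targets=ct)

        net = stage("molecular_network")(_network)
        complexes = stage("mcode")(lambda: _molnet.mcode_cores(net.protein_view))

        def _rwr():
            seeds = [g for g in disease if g in net.graph]
            return _molnet.rwr(net, seeds, restart_prob=config.restart_prob)

        rwr_scores = stage("rwr")(_rwr)
        core_compounds = stage("core_compounds")(
            lambda: _molnet.retain_core_compounds(rwr_scores, net.compounds)
        )

    collections = {}
    if config.gmt_kegg:
        collections["kegg"] = stage("read_gmt_kegg")(lambda: _io.read_gmt(config.gmt_kegg))
    if config.gmt_go:
        collections["go"] = stage("read_gmt_go")(lambda: _io.read_gmt(config.gmt_go))

    per_level_features: dict[str, dict[str, object]] = {}
    if annotations:
        per_level_features["symptom"] = {a.herb_id: a.symptoms for a in annotations}
        per_level_features["target"] = {a.herb_id: a.targets for a in annotations}
    if disease and collections:
        for level, coll in collections.items():
            def _enr(coll=coll):
                dis = _enrich_genes(
                    [g for g in disease if g in coll.universe], coll, q_max=config.q_max
                )
                per_herb = {
                    a.herb_id: _enrich_genes(
                        [g for g in a.targets if g in coll.universe], coll, q_max=config.q_max
                    )
                    for a in annotations
                    if a.targets & coll.universe
                }
                return dis, per_herb

            dis_res, herb_res = stage(f"enrichment_{level}")(_enr)
            disease_enrichment[level] = dis_res
            core_paths[level] = stage(f"core_pathways_{level}")(
                lambda dis_res=dis_res, herb_res=herb_res: _core_pathways(herb_res, dis_res)
            )
            # pathway-level profiles use enriched-gene counts on core terms
            union_terms = set().union(*core_paths[level].values()) if core_paths[level] else set()
            feats: dict[str, object] = {}
            for herb, results in herb_res.items():
                k_of = {r.term_id: r.k for r in results}
                feats[herb] = {t: k_of.get(t, 0) for t in union_terms}
            per_level_features[level] = feats

    for level, feats in per_level_features.items():
        k = config.cluster_k.get(level)
        if not k:
            continue

        def _clust(feats=feats, level=level, k=k):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                profile = _cluster.build_profile(feats, level=level)
            state = _cluster.ward_cluster(profile)
            return state.assignment(min(k, len(profile.herbs)))

        try:
            assignments[level] = stage(f"cluster_{level}")(_clust)
        except RuntimeError as exc:
            if "at least two herbs" in str(exc):
                continue
            raise

    result = PipelineResult(
        core_herbs=core_herbs,
        shell=shell,
        specificity=specificity,
        rules=rules,
        rule_labels=rule_labels,
        complexes=complexes,
        rwr_scores=rwr_scores,
        core_compounds=core_compounds,
        disease_enrichment=disease_enrichment,
        core_pathways=core_paths,
        assignments=assignments,
        manifest=manifest,
    )
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def write_bundle(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage's output as plain text under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    _io.write_id_list(result.core_herbs, out / "core_herbs.txt")
    with (out / "shell_layers.tsv").open("w", encoding="utf-8") as fh:
        fh.write("layer\therb_a\therb_b\tweight\n")
        for i, layer in enumerate(result.shell.layers, start=1):
            for (a, b), w in layer.edges:
                fh.write(f"{i}\t{a}\t{b}\t{w}\n")

    with (out / "specificity.tsv").open("w", encoding="utf-8") as fh:
        fh.write("herb\tn_ij\tn_i\tn_j\tN\tRR\tchi2\tp\tselected\n")
        for r in sorted(result.specificity, key=lambda r: (-r.rr, r.herb_id)):
            t = r.table
            fh.write(
                f"{r.herb_id}\t{t.n_ij}\t{t.n_i}\t{t.n_j}\t{t.N}\t"
                f"{r.rr:.6g}\t{r.chi2:.6g}\t{r.p:.6g}\t{r.selected}\n"
            )

    with (out / "rules.tsv").open("w", encoding="utf-8") as fh:
        fh.write("LHS\tRHS\tSupport\tConfidence\tCoverage\tLift\tCount\tGroup\n")
        labels = result.rule_labels or [""] * len(result.rules)
        for r, lab in zip(result.rules, labels):
            fh.write(
                f"{','.join(sorted(r.lhs))}\t{','.join(sorted(r.rhs))}\t"
                f"{r.support:.3f}\t{r.confidence:.3f}\t{r.coverage:.3f}\t"
                f"{r.lift:.3f}\t{r.count}\t{lab}\n"
            )

    with (out / "complexes.tsv").open("w", encoding="utf-8") as fh:
        fh.write("rank\tscore\tdensity\tmembers\n")
        for i, c in enumerate(result.complexes, start=1):
            fh.write(f"{i}\t{c.score:.4f}\t{c.density:.4f}\t{','.join(sorted(c.nodes))}\n")

    if result.rwr_scores is not None:
        retained = {c for c, _ in result.core_compounds}
        with (out / "rwr_scores.tsv").open("w", encoding="utf-8") as fh:
            fh.write("node\tscore\tretained\n")
            for node, score in sorted(
                result.rwr_scores.scores.items(), key=lambda t: (-t[1], t[0])
            ):
                fh.write(f"{node}\t{score:.6e}\t{node in retained}\n")

    for level, results in result.disease_enrichment.items():
        with (out / f"enrichment_disease_{level}.tsv").open("w", encoding="utf-8") as fh:
            fh.write("term\tk\tK\tn\tM\tp\tq\tsignificant\tgenes\n")
            for r in results:
                fh.write(
                    f"{r.term_id}\t{r.k}\t{r.K}\t{r.n}\t{r.M}\t{r.p:.6e}\t"
                    f"{r.q:.6e}\t{r.significant}\t{','.join(sorted(r.enriched_genes))}\n"
                )
    for level, mapping in result.core_pathways.items():
        with (out / f"core_pathways_{level}.tsv").open("w", encoding="utf-8") as fh:
            fh.write("herb\tcore_terms\n")
            for herb in sorted(mapping):
                fh.write(f"{herb}\t{','.join(sorted(mapping[herb]))}\n")

    if result.assignments:
        summary = _cluster.multilevel_summary(result.assignments)
        summary.to_csv(out / "cluster_summary.tsv", sep="\t")
        for level, assign in result.assignments.items():
            with (out / f"cluster_{level}.tsv").open("w", encoding="utf-8") as fh:
                fh.write("herb\tcluster\n")
                for herb in sorted(assign):
                    fh.write(f"{herb}\t{assign[herb]}\n")

    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
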