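"""End-to-end orchestration: simulate/load -> filter -> featurize -> label ->
train -> threshold -> network -> modules -> validation, with one global seed
and a machine-readable run report.

The configuration is a nested mapping (usually loaded from YAML); unknown
keys are rejected so typos fail fast.  Every stage writes its artifact under
``outdir`` and the report is written last, so a complete report implies a
complete run.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clusterone, enrichment, io, network, preprocess, reference, scoring
from .features import MetricParams, build_pair_feature_table
from .simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_annotations,
    simulate_curated_studies,
    simulate_dataset,
    write_dataset,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

_DEFAULTS: dict[str, dict[str, Any]] = {
    "simulate": {
        "enabled": True,
        "n_genes": 300,
        "n_cell_lines": 40,
        "n_modules": 10,
        "module_size_range": [8, 12],
        "within_module_noise_sd": 0.3,
        "background_sd": 0.5,
        "essential_depth_mean": -1.0,
        "nonlinear_fraction": 0.2,
        "unexpressed_fraction": 0.1,
        "signal_scale": 1.0,
        "n_studies": 3,
        "coverage": 0.8,
        "fpr": 0.001,
        "n_noise_terms": 20,
    },
    "inputs": {
        "fitness": None,
        "expression": None,
        "studies": [],
        "annotations": None,
        "ontology": None,
    },
    "filters": {
        "min_tpm": 0.0,
        "min_lines": 1,
        "fitness_cutoff": -0.5,
        "mad_constant": 1.0,
    },
    "metrics": {
        "minkowski_order": 3.0,
        "mi_bins": 5,
        "binarize_cutoff": -0.5,
        "constant_vector_impute": 0.0,
    },
    "reference": {"min_support": 2, "neg_pos_ratio": 5.0},
    "cv": {"k": 5, "repeats": 10, "backends": list(scoring.BACKENDS)},
    "threshold": {"policy": "youden", "value": 0.02},
    "clusterone": {"p": 2.0, "min_size": 3, "min_density": 0.5, "merge_overlap": 0.8},
    "network": {"n_hubs": 8, "weighted_hits": True, "hits_tol": 1e-8,
                "hits_max_iter": 100_000},
    "enrichment": {"enabled": True},
}


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "cofitnet_run"
    sections: dict[str, dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged: dict[str, dict[str, Any]] = {}
        for section, defaults in _DEFAULTS.items():
            given = dict(self.sections.get(section, {}))
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(
                    f"unknown keys in config section {section!r}: {sorted(unknown)}"
                )
            merged[section] = {**defaults, **given}
        unknown_sections = set(self.sections) - set(_DEFAULTS)
        if unknown_sections:
            raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
        self.sections = merged

    def __getitem__(self, section: str) -> dict[str, Any]:
        return self.sections[section]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seed = raw.pop("seed", 1)
        outdir = raw.pop("outdir", "cofitnet_run")
        return cls(seed=seed, outdir=outdir, sections=raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = {"seed": self.seed, "outdir": self.outdir, **self.sections}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass
class RunReport:
    seed: int
    counts: dict[str, Any] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"seed": self.seed, "counts": self.counts,
                        "timings_s": self.timings_s}, indent=1, sort_keys=True) + "\n"
        )


class _StageTimer:
    def __init__(self, report: RunReport):
        self.report = report

    def __call__(self, name: str):
        report = self.report

        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                report.timings_s[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc_type is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Ctx()


def _load_inputs(cfg: RunConfig, outdir: Path):
    sim = cfg["simulate"]
    if sim["enabled"]:
        sconf = SimulationConfig(
            n_genes=sim["n_genes"],
            n_cell_lines=sim["n_cell_lines"],
            n_modules=sim["n_modules"],
            module_size_range=tuple(sim["module_size_range"]),
            within_module_noise_sd=sim["within_module_noise_sd"],
            background_sd=sim["background_sd"],
            essential_depth_mean=sim["essential_depth_mean"],
            nonlinear_fraction=sim["nonlinear_fraction"],
            unexpressed_fraction=sim["unexpressed_fraction"],
            signal_scale=sim["signal_scale"],
            seed=cfg.seed,
        )
        fitness, expression, truth = simulate_dataset(sconf)
        write_dataset(outdir, fitness, expression, truth)
        studies = simulate_curated_studies(
            truth,
            n_studies=sim["n_studies"],
            coverage=sim["coverage"],
            fpr=sim["fpr"],
            seed=cfg.seed,
            gene_universe=sorted(fitness.index),
        )
        for i, s in enumerate(studies, start=1):
            io.write_pair_list(s, outdir / f"study_{i}.tsv")
        annotations, ontology = simulate_annotations(
            truth, n_noise_terms=sim["n_noise_terms"], seed=cfg.seed,
            gene_universe=sorted(fitness.index),
        )
        io.write_gmt(io.annotations_to_gmt(annotations), outdir / "annotations.gmt")
        io.write_ontology(ontology, outdir / "ontology.tsv")
        return fitness, expression, studies, annotations, ontology, truth

    inp = cfg["inputs"]
    if not inp["fitness"] or not Path(inp["fitness"]).exists():
        raise FileNotFoundError(f"fitness matrix not found: {inp['fitness']!r}")
    if not inp["expression"] or not Path(inp["expression"]).exists():
        raise FileNotFoundError(f"expression matrix not found: {inp['expression']!r}")
    fitness = io.read_matrix(inp["fitness"])
    expression = io.read_matrix(inp["expression"])
    studies = [io.read_pair_list(p) for p in inp["studies"]]
    annotations: dict[str, set[str]] = {}
    if inp["annotations"]:
        for term, genes in io.read_gmt(inp["annotations"]).items():
            for g in genes:
                annotations.setdefault(g, set()).add(term)
    ontology = io.read_ontology(inp["ontology"]) if inp["ontology"] else None
    return fitness, expression, studies, annotations, ontology, None


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage and return (and write) the run report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=cfg.seed)
    stage = _StageTimer(report)

    with stage("inputs"):
        fitness, expression, studies, annotations, ontology, truth = _load_inputs(
            cfg, outdir
        )

    with stage("preprocess"):
        fp = cfg["filters"]
        filt = preprocess.select_candidate_genes(
            fitness,
            expression,
            preprocess.FilterParams(
                min_tpm=fp["min_tpm"],
                min_lines=fp["min_lines"],
                fitness_cutoff=fp["fitness_cutoff"],
                mad_constant=fp["mad_constant"],
            ),
        )
        (outdir / "filter_report.json").write_text(
            json.dumps(filt.to_dict(), indent=1) + "\n"
        )
        (outdir / "candidate_genes.txt").write_text(
            "".join(g + "\n" for g in filt.genes)
        )
        report.counts.update(
            n_genes_input=filt.n_input,
            n_genes_expressed=filt.n_expressed,
            n_genes_dependent=filt.n_dependent,
            n_candidate_genes=filt.n_variable,
        )
        genes = filt.genes
        if len(genes) < 2:
            raise ValueError("fewer than 2 candidate genes survive the filters")

    with stage("features"):
        mp = cfg["metrics"]
        params = MetricParams(
            minkowski_order=mp["minkowski_order"],
            mi_bins=mp["mi_bins"],
            binarize_cutoff=mp["binarize_cutoff"],
            constant_vector_impute=mp["constant_vector_impute"],
        )
        table = build_pair_feature_table(fitness, genes, params)
        table.to_csv(outdir / "pair_features.tsv", sep="\t", index=False,
                     float_format="%.8g")
        report.counts["n_pairs"] = len(table)

    with stage("reference"):
        rp = cfg["reference"]
        universe = {
            frozenset((a, b)) for a, b in zip(table["gene_a"], table["gene_b"])
        }
        positives_all = reference.build_positives(studies, rp["min_support"])
        positives = positives_all & universe
        labels = reference.build_negatives(universe, positives, annotations)
        labels.to_frame().to_csv(outdir / "labels.tsv", sep="\t", index=False)
        counts = labels.counts()
        report.counts.update(
            n_positives=counts[reference.POSITIVE],
            n_negatives=counts[reference.NEGATIVE],
            n_unlabeled=counts[reference.UNLABELED],
        )
        training = reference.assemble_training_table(
            table, labels, neg_pos_ratio=rp["neg_pos_ratio"], seed=cfg.seed
        )
        report.counts["n_training_rows"] = len(training.y)

    with stage("ml_scoring"):
        cv = cfg["cv"]
        cv_results: dict[str, scoring.CVResult] = {}
        for backend in cv["backends"]:
            spec = scoring.ScorerSpec.make(backend, seed=cfg.seed)
            cv_results[backend] = scoring.stratified_cv(
                spec, training, k=cv["k"], repeats=cv["repeats"], seed=cfg.seed
            )
        aurocs = {b: r.mean_auroc() for b, r in cv_results.items()}
        best_backend = max(sorted(aurocs), key=lambda b: aurocs[b])
        report.counts["cv_auroc"] = {b: round(a, 6) for b, a in aurocs.items()}
        report.counts["best_backend"] = best_backend

        pooled = cv_results[best_backend].pooled_scores()
        roc = scoring.roc_analysis(pooled, training.y)
        roc.to_frame().to_csv(outdir / "roc_curve.tsv", sep="\t", index=False,
                              float_format="%.8g")
        tp = cfg["threshold"]
        if tp["policy"] == "youden":
            cutoff, sens, spec_ = scoring.best_threshold(roc)
        elif tp["policy"] == "fixed":
            cutoff = float(tp["value"])
            idx = int(np.argmin(np.abs(roc.thresholds - cutoff)))
            sens, spec_ = float(roc.sensitivity[idx]), float(roc.specificity[idx])
        else:
            raise ValueError(f"unknown threshold policy {tp['policy']!r}")
        report.counts.update(
            pooled_auroc=round(roc.auroc, 6),
            threshold=cutoff,
            sensitivity=round(sens, 6),
            specificity=round(spec_, 6),
        )

        final_scorer = scoring.make_scorer(
            scoring.ScorerSpec.make(best_backend, seed=cfg.seed)
        )
        final_scorer.fit(training.X, training.y)
        scored = scoring.score_pairs(final_scorer, table, training)
        scored.to_csv(outdir / "pair_scores.tsv", sep="\t", index=False,
                      float_format="%.8g")
        edges = scoring.threshold_edges(scored, cutoff)
        io.write_edge_list(edges, outdir / "edges.tsv")
        report.counts["n_edges"] = len(edges)
        model_meta = {
            "backend": best_backend,
            "threshold": cutoff,
            "feature_means": [round(float(v), 10) for v in training.feature_means],
            "feature_sds": [round(float(v), 10) for v in training.feature_sds],
        }
        (outdir / "model.json").write_text(json.dumps(model_meta, indent=1) + "\n")

    with stage("network"):
        np_ = cfg["network"]
        if len(edges) == 0:
            raise ValueError("no edges above the threshold; network is empty")
        net = network.build_network(edges)
        stats = network.network_stats(net)
        hub_scores = network.hits_hub_scores(
            net, tol=np_["hits_tol"], max_iter=np_["hits_max_iter"],
            weighted=np_["weighted_hits"],
        )
        hubs = network.top_hubs(hub_scores, k=min(np_["n_hubs"], len(hub_scores)))
        network.hub_table(hub_scores).to_csv(
            outdir / "hub_scores.tsv", sep="\t", index=False, float_format="%.8g"
        )
        report.counts.update(
            n_network_nodes=stats["n_nodes"],
            n_network_components=stats["n_components"],
            top_hubs=hubs,
        )

    with stage("clusterone"):
        cp = cfg["clusterone"]
        modules = clusterone.detect_modules(
            net,
            p=cp["p"],
            min_size=cp["min_size"],
            min_density=cp["min_density"],
            merge_overlap=cp["merge_overlap"],
        )
        module_map = modules.as_dict()
        io.write_gmt(
            module_map,
            outdir / "modules.gmt",
            descriptions={
                mid: f"{c.cohesiveness:.6g}"
                for mid, c in zip(module_map, modules.clusters)
            },
        )
        report.counts["n_modules"] = len(modules)
        report.counts["module_sizes"] = sorted(
            (len(m) for m in module_map.values()), reverse=True
        )

    with stage("enrichment"):
        if cfg["enrichment"]["enabled"] and annotations:
            term_sets = io.annotations_to_gmt(annotations)
            universe_genes = set(net.nodes)
            enr = enrichment.module_enrichment_table(
                module_map, {"terms": term_sets}, universe_genes
            )
            enr.to_csv(outdir / "module_enrichment.tsv", sep="\t", index=False,
                       float_format="%.6g")
            report.counts["n_enriched_modules_q05"] = int(
                enr[enr["q"] < 0.05]["module"].nunique()
            )

    report.to_json(outdir / "run_report.json")
    return report
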