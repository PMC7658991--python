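"""End-to-end orchestration: QC → clustering → markers/DE → clinical stats,
crosstalk scoring, and external-cohort classification, from one config.

Every stage writes plain-text tables into the output directory along with a
JSON run manifest (config hash, seed, package version, chosen grid point)
so a run can be reproduced and audited.  A single seed drives every
stochastic stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as oio
from .io import TISSUES, ValidationError
from .classify import composition_table, train_subtype_model
from .cluster import ConsensusGrid
from .crosstalk import (NINE_DIRECTIONS, build_network, count_expressed_pairs,
                        crosstalk_genes, enrich_crosstalk_genes,
                        patient_matrix, select_high_pairs)
from .markers import differential_expression, find_markers
from .qc import cpm, filter_samples_by_depth, run_qc
from .simulate import CohortConfig, generate_cohort, generate_genesets, \
    generate_lr_database
from .stats import pairwise_trend_tests, patient_clinical, score_distributions


@dataclass
class PipelineConfig:
    """All stage parameters plus either input paths or synthetic settings."""

    outdir: str = "oasubtypes_out"
    seed: int = 0
    # inputs: per-tissue count paths + metadata/LR/geneset paths, or synthetic
    counts: dict = field(default_factory=dict)      # tissue -> path
    counts_format: str = "tsv"
    metadata: str | None = None
    lr_table: str | None = None
    genesets: str | None = None
    synthetic: dict | None = None                   # CohortConfig overrides
    # QC
    depth_low: int = 500_000
    depth_high: int = 2_000_000
    control_max_variance: float = 3.0
    min_cpm: float = 5.0
    min_samples: int = 15
    # clustering
    n_grid: tuple = (2500, 3000, 3500, 4000, 4500, 5000)
    k_grid: tuple = tuple(range(2, 9))
    force_k: int | None = None
    # markers / DE
    p_adj_max: float = 0.05
    auroc_min: float = 0.6
    fc_min: float = 4.0
    fdr_max: float = 0.05
    # crosstalk
    tau_expr: float = 1.0
    min_or_expressed: float = 0.5
    tau_or: float = 0.9
    # classifier
    n_trees: int = 500
    external: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("metadata", "lr_table", "genesets", "external"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"config {key}: file not found: {p}")
        for tissue, p in cfg.counts.items():
            if tissue not in TISSUES:
                raise ValidationError(f"config counts: unknown tissue {tissue!r}")
            if not Path(p).exists():
                raise ValidationError(f"config counts[{tissue}]: file not found: {p}")
        if not cfg.counts and cfg.synthetic is None:
            raise ValidationError("config must provide counts paths or synthetic settings")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_inputs(config: PipelineConfig):
    """Resolve inputs: read the referenced files or generate a synthetic cohort."""
    if config.synthetic is not None:
        cc = CohortConfig(**{"seed": config.seed, **config.synthetic})
        counts, meta, truth = generate_cohort(cc)
        lr = generate_lr_database(cc)
        gs = generate_genesets(cc)
        return counts, meta, lr, gs, truth
    counts = {t: oio.read_count_matrix(p, format=config.counts_format)
              for t, p in config.counts.items()}
    if config.metadata is None:
        raise ValidationError("metadata path required with real count inputs")
    meta = oio.read_sample_table(config.metadata)
    lr = oio.read_lr_table(config.lr_table) if config.lr_table else None
    gs = oio.read_gmt(config.genesets) if config.genesets else None
    return counts, meta, lr, gs, None


def _write_manifest(config: PipelineConfig, outdir: Path, extra: dict) -> None:
    manifest = {"config_digest": config.digest(), "seed": config.seed,
                "version": __version__, "config": asdict(config), **extra}
    oio.write_json(manifest, outdir / "manifest.json")


def run_discovery(config: PipelineConfig):
    """QC, consensus clustering, markers, DE and clinical stats on cartilage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, meta, lr, gs, truth = load_inputs(config)
    if "cartilage" not in counts:
        raise ValidationError("discovery requires cartilage counts")
    cart = counts["cartilage"]

    expr_oa, expr_ctrl = run_qc(
        cart, meta, depth_low=config.depth_low, depth_high=config.depth_high,
        control_max_variance=config.control_max_variance,
        min_cpm=config.min_cpm, min_samples=config.min_samples)

    grid = ConsensusGrid(n_grid=config.n_grid, k_grid=config.k_grid,
                         force_k=config.force_k,
                         random_state=config.seed).fit(expr_oa)
    labels = grid.labels_.map(lambda c: f"C{c}")
    labels.rename_axis("sample_id").to_frame().to_csv(
        outdir / "labels.tsv", sep="\t")
    grid.results_.to_csv(outdir / "grid_report.tsv", sep="\t", index=False)
    cons = pd.DataFrame(grid.best_model_.consensus_,
                        index=grid.best_model_.sample_ids_,
                        columns=grid.best_model_.sample_ids_)
    cons.to_csv(outdir / "consensus.tsv", sep="\t")

    markers = find_markers(expr_oa, labels, p_adj_max=config.p_adj_max,
                           auroc_min=config.auroc_min)
    markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)

    kept_counts = cart.loc[expr_oa.index, expr_oa.columns]
    de_results = {}
    for a, b in combinations(sorted(labels.unique()), 2):
        sa = labels.index[labels == a].tolist()
        sb = labels.index[labels == b].tolist()
        if len(sa) < 2 or len(sb) < 2:
            continue
        de = differential_expression(kept_counts, sa, sb, fc_min=config.fc_min,
                                     fdr_max=config.fdr_max, contrast=(a, b))
        de_results[f"{a}_vs_{b}"] = de
        de.table.to_csv(outdir / f"de_{a}_vs_{b}.tsv", sep="\t", index=False)

    clin = patient_clinical(meta, labels)
    dists = score_distributions(clin)
    for score, pct in dists.items():
        pct.to_csv(outdir / f"clinical_{score}_pct.tsv", sep="\t")
    trends = pairwise_trend_tests(clin)
    trends.to_csv(outdir / "clinical_trends.tsv", sep="\t", index=False)

    _write_manifest(config, outdir, {
        "stage": "discovery", "chosen_n_hvg": grid.best_n_,
        "chosen_k": grid.best_k_,
        "silhouette": grid.best_model_.silhouette_,
        "n_samples_clustered": int(expr_oa.shape[1]),
        "n_genes_post_qc": int(expr_oa.shape[0]),
    })
    return {"expr_oa": expr_oa, "expr_ctrl": expr_ctrl, "grid": grid,
            "labels": labels, "markers": markers, "de": de_results,
            "clinical": (dists, trends), "meta": meta, "counts": counts,
            "lr": lr, "genesets": gs, "truth": truth}


def run_crosstalk(config: PipelineConfig, labels: pd.Series | None = None,
                  inputs=None):
    """Occurrence-ratio crosstalk over all nine directions per subtype."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if inputs is None:
        counts, meta, lr, gs, _ = load_inputs(config)
    else:
        counts, meta, lr, gs = (inputs["counts"], inputs["meta"],
                                inputs["lr"], inputs["genesets"])
    if lr is None:
        raise ValidationError("crosstalk requires a ligand-receptor table")
    if labels is None:
        lab = pd.read_csv(outdir / "labels.tsv", sep="\t", index_col=0)
        labels = lab.iloc[:, 0]
    available = [t for t in TISSUES if t in counts]
    if len(available) < 1:
        raise ValidationError("crosstalk requires at least one tissue")

    exprs = {}
    for t in available:
        kept = filter_samples_by_depth(counts[t], config.depth_low,
                                       config.depth_high)
        exprs[t] = patient_matrix(cpm(kept), meta, t)

    by_sample = meta.set_index("sample_id")["patient_id"]
    patient_label = pd.Series(labels.values, index=by_sample.loc[labels.index].values) \
        if pd.Index(labels.index).isin(by_sample.index).all() else labels

    all_rows, net_rows, enrich_tables = [], [], {}
    background = set(counts[available[0]].index)
    for subtype in sorted(patient_label.unique()):
        patients = patient_label.index[patient_label == subtype].tolist()
        results = []
        for source, target in NINE_DIRECTIONS:
            if source not in exprs or target not in exprs:
                all_rows.append({"subtype": subtype, "source": source,
                                 "target": target, "status": "tissue_absent",
                                 "expressed_pairs": 0, "high_pairs": 0,
                                 "n_evaluable_patients": 0})
                continue
            res = count_expressed_pairs(
                exprs, patients, lr, source, target, subtype=subtype,
                tau_expr=config.tau_expr,
                min_or_expressed=config.min_or_expressed)
            res = select_high_pairs(res, tau_or=config.tau_or)
            results.append(res)
            res.table.to_csv(
                outdir / f"crosstalk_{subtype}_{source}_to_{target}.tsv",
                sep="\t", index=False)
            all_rows.append({
                "subtype": subtype, "source": source, "target": target,
                "status": "no_evaluable" if res.no_evaluable else "ok",
                "expressed_pairs": res.expressed_pairs,
                "high_pairs": res.high_pairs,
                "n_evaluable_patients": res.n_evaluable_patients})
        _, edges = build_network(results)
        edges.insert(0, "subtype", subtype)
        net_rows.append(edges)
        query = set().union(*(crosstalk_genes(r) for r in results)) if results else set()
        if gs and query:
            enr = enrich_crosstalk_genes(query, gs, background)
            enr.to_csv(outdir / f"crosstalk_enrichment_{subtype}.tsv",
                       sep="\t", index=False)
            enrich_tables[subtype] = enr

    summary = pd.DataFrame(all_rows)
    summary.to_csv(outdir / "crosstalk_summary.tsv", sep="\t", index=False)
    network = pd.concat(net_rows, ignore_index=True) if net_rows else pd.DataFrame()
    network.to_csv(outdir / "crosstalk_network.tsv", sep="\t", index=False)
    return {"summary": summary, "network": network, "enrichment": enrich_tables}


def run_classify(config: PipelineConfig, discovery=None,
                 external_expr: pd.DataFrame | None = None):
    """Train the subtype forest on the discovery cohort and label externals."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if discovery is None:
        discovery = run_discovery(config)
    if external_expr is None:
        if config.external is None:
            raise ValidationError("no external expression matrix provided")
        external_expr = oio.read_count_matrix(config.external,
                                              format=config.counts_format)
    if external_expr.shape[1] == 0:
        raise ValidationError("external expression matrix has no samples")
    model = train_subtype_model(discovery["expr_oa"], discovery["labels"],
                                discovery["markers"], seed=config.seed,
                                n_trees=config.n_trees)
    pred = model.predict(external_expr)
    comp = composition_table(pred, classes=model.classes_)
    pred.rename_axis("sample_id").to_frame().to_csv(
        outdir / "external_predictions.tsv", sep="\t")
    comp.to_csv(outdir / "external_composition.tsv", sep="\t", index=False,
                float_format="%.1f")
    return {"model": model, "predictions": pred, "composition": comp}
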