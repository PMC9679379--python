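"""End-to-end orchestration: simulate (or load) -> preprocess -> landscape
-> consensus clustering -> differential expression -> DMS -> survival ->
enrichment, with one config, structured per-stage logging and a manifest.

The stage graph is deliberately linear: each stage writes plain TSVs that
the next stage (and the user) can inspect, and the manifest records every
parameter, seed and row count so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import dea, dms, enrichment, landscape, preprocess, survival, syndata
from .io import (GeneSet, GeneSetCollection, read_clinical, read_cnv,
                 read_expression, read_gmt, read_maf, write_expression,
                 write_gmt, write_table)

logger = logging.getLogger("methscore")


@dataclass
class PipelineConfig:
    """All knobs of the full pipeline; YAML-loadable, CLI-overridable."""

    outdir: str = "methscore_results"
    seed: int = 0

    # inputs: either simulate a cohort or point at files
    simulate: bool = False
    sim: dict[str, Any] = field(default_factory=dict)   # SimulationConfig overrides
    expression_path: str | None = None
    clinical_path: str | None = None
    maf_path: str | None = None
    cnv_path: str | None = None
    gmt_path: str | None = None
    panel_path: str | None = None                        # one gene symbol per line

    # thresholds / parameters (defaults follow the study conventions)
    min_days: float = 30.0
    log2_offset: float | None = None
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    k: int | None = None                                 # override chosen k
    reps: int = 1000
    p_item: float = 0.8
    distance: str = "correlation"
    contrast: tuple[int, int] | None = None              # cluster labels to contrast
    deg_mode: str = "pairwise"                           # or "union"
    p_cut: float = 0.05
    lfc_cut: float = 1.0
    use_adjusted: bool = False
    cox_alpha: float = 0.05
    minprop: float = 0.1
    gsea_n_perm: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        if "contrast" in raw and raw["contrast"] is not None:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(**raw)

    def validate(self) -> None:
        for name, lo, hi in (("p_cut", 0, 1), ("lfc_cut", 0, np.inf),
                             ("cox_alpha", 0, 1), ("minprop", 0, 0.5),
                             ("p_item", 0, 1)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.min_days < 0 or self.reps < 1:
            raise ValueError("min_days must be >= 0 and reps >= 1")
        if not self.simulate and (self.expression_path is None
                                  or self.clinical_path is None):
            raise ValueError("need expression_path and clinical_path "
                             "(or simulate=True)")


def _read_panel(path: str | None) -> list[str]:
    if path is None:
        return list(landscape.DEFAULT_PANEL)
    genes = [line.strip() for line in Path(path).read_text().splitlines()
             if line.strip() and not line.startswith("#")]
    if not genes:
        raise ValueError(f"{path}: empty panel file")
    return genes


def _truth_gene_sets(cohort: syndata.SyntheticCohort,
                     rng: np.random.Generator) -> GeneSetCollection:
    """Gene sets for the enrichment stage of a simulated run: the planted
    DEG block plus random same-universe decoys (synthetic, not curated)."""
    truth = cohort.gene_truth
    degs = list(truth.index[truth["role"] == "deg"])
    universe = list(cohort.expression.index)
    sets = {}
    if degs:
        sets["planted_deg_block"] = GeneSet(
            "planted_deg_block", "genes with planted between-cluster shifts",
            tuple(degs))
    size = max(5, min(50, len(universe) // 20))
    for i in range(5):
        members = rng.choice(universe, size=size, replace=False)
        name = f"random_set_{i + 1}"
        sets[name] = GeneSet(name, "random decoy set (synthetic)", tuple(members))
    return GeneSetCollection(sets)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage in order; returns the manifest (also written as
    ``manifest.json`` in the output directory)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": _jsonable(dataclasses.asdict(config)),
        "stages": [],
    }

    def record(stage: str, **info: Any) -> None:
        manifest["stages"].append({"stage": stage, **_jsonable(info)})
        logger.info("stage %-10s %s", stage, info)

    # -- stage 1: simulate or load ------------------------------------------
    cohort = None
    if config.simulate:
        sim_cfg = syndata.SimulationConfig(seed=config.seed, **config.sim)
        cohort = syndata.simulate_cohort(sim_cfg)
        paths = cohort.write(outdir / "cohort")
        expression, clinical = cohort.expression, cohort.clinical
        mutations, cnv = cohort.mutations, cohort.cnv
        record("simulate", n_samples=expression.shape[1],
               n_genes=expression.shape[0], seed=config.seed,
               sim=dataclasses.asdict(sim_cfg),
               outputs=sorted(Path(p).name for p in paths.values()))
    else:
        expression, _ = read_expression(config.expression_path,
                                        log2_offset=config.log2_offset)
        clinical, _ = read_clinical(config.clinical_path)
        mutations = read_maf(config.maf_path)[0] if config.maf_path else None
        cnv = read_cnv(config.cnv_path)[0] if config.cnv_path else None
        record("load", n_samples=expression.shape[1],
               n_genes=expression.shape[0], n_clinical=len(clinical))

    # -- stage 2: preprocess -------------------------------------------------
    clinical_f, excl = preprocess.filter_clinical_samples(clinical,
                                                          config.min_days)
    expression_c = preprocess.collapse_duplicate_genes(expression)
    bundle = preprocess.align_cohort(expression_c, clinical_f)
    write_expression(bundle.expression, outdir / "expression_clean.tsv")
    write_table(bundle.clinical, outdir / "clinical_clean.tsv")
    record("preprocess", exclusions=excl, align=bundle.exclusion_log,
           n_samples=bundle.expression.shape[1],
           n_genes=bundle.expression.shape[0])

    panel = [g for g in _read_panel(config.panel_path)
             if g in bundle.expression.index]
    if len(panel) < 2:
        raise RuntimeError("stage landscape: fewer than 2 panel genes in matrix")

    # -- stage 3: landscape --------------------------------------------------
    info: dict[str, Any] = {"n_panel_genes": len(panel)}
    if mutations is not None and len(mutations):
        freq = landscape.mutation_frequency(
            mutations, list(bundle.expression.columns), panel)
        write_table(freq, outdir / "mutation_frequency.tsv")
        info["n_mutation_rows"] = len(mutations)
    if cnv is not None:
        cfreq = landscape.cnv_frequency(cnv[list(
            c for c in cnv.columns if c in set(bundle.expression.columns))], panel)
        write_table(cfreq, outdir / "cnv_frequency.tsv")
    r, p = landscape.correlation_matrix(bundle.expression, panel,
                                        method="spearman")
    write_table(r, outdir / "panel_correlation.tsv")
    record("landscape", **info)

    # -- stage 4: consensus clustering --------------------------------------
    k_range = tuple(k for k in config.k_range if k < bundle.expression.shape[1])
    result = cns.consensus_cluster(
        bundle.expression, panel, k_range=k_range, n_resamples=config.reps,
        p_item=config.p_item, distance=config.distance, seed=config.seed)
    chosen_k = config.k if config.k is not None else result.chosen_k
    clusters = result.assignments[chosen_k]
    write_table(clusters.to_frame("cluster"), outdir / "cluster_assignments.tsv")
    write_table(result.report(), outdir / "cluster_selection.tsv")
    for k in result.k_range:
        write_table(result.consensus[k], outdir / f"consensus_k{k}.tsv")
    record("cluster", chosen_k=chosen_k, recommended_k=result.chosen_k,
           low_confidence=result.low_confidence, reps=config.reps,
           seed=config.seed,
           cluster_sizes=clusters.value_counts().sort_index().to_dict())

    # -- stage 5: differential expression ------------------------------------
    if config.deg_mode == "union" and chosen_k > 2:
        deg_genes = dea.pairwise_union_degs(
            bundle.expression, clusters, config.p_cut, config.lfc_cut,
            config.use_adjusted)
        contrast = ("union", "union")
        deg_table = None
        counts = {"total": len(deg_genes)}
    else:
        contrast = config.contrast or ((2, 3) if chosen_k >= 3 else (1, 2))
        sub = clusters[clusters.isin(contrast)]
        deg_table = dea.moderated_t(bundle.expression[list(sub.index)], sub,
                                    contrast[0], contrast[1])
        call = dea.call_degs(deg_table, config.p_cut, config.lfc_cut,
                             config.use_adjusted)
        deg_genes = call.genes
        counts = call.counts
        write_table(deg_table, outdir / "deg_table.tsv")
    if not deg_genes:
        raise RuntimeError("stage deg: no DEGs pass the thresholds")
    pd.Series(deg_genes, name="gene").to_csv(outdir / "deg_genes.tsv",
                                             sep="\t", index=False)
    record("deg", contrast=list(contrast), **counts)

    # -- stage 6: DMS --------------------------------------------------------
    screen = dms.cox_screen(bundle.expression, bundle.clinical, deg_genes,
                            alpha=config.cox_alpha)
    write_table(screen, outdir / "cox_screen.tsv")
    model, scores = dms.fit_dms(bundle.expression, screen)
    write_table(model.to_frame(), outdir / "dms_model.tsv")
    record("score", n_screened=int(screen["kept"].sum()),
           n_candidates=len(screen), signs=list(model.signs),
           explained_variance=list(model.explained_variance_ratio))

    # -- stage 7: survival ---------------------------------------------------
    cut = survival.find_cutpoint(
        scores["dms"].to_numpy(), bundle.clinical["os_time"].to_numpy(),
        bundle.clinical["os_status"].to_numpy(), minprop=config.minprop)
    groups = cut.groups(scores["dms"], labels=("Low_DMS", "High_DMS"))
    scores = scores.assign(group=groups)
    write_table(scores, outdir / "dms_scores.tsv")
    write_table(cut.scan, outdir / "cutpoint_scan.tsv", index=False)

    chi2, df, p_lr = survival.logrank_test(
        bundle.clinical["os_time"], bundle.clinical["os_status"], groups)
    medians = {}
    km_frames = []
    for gname in ("Low_DMS", "High_DMS"):
        mask = (groups == gname).to_numpy()
        curve = survival.km_estimate(bundle.clinical["os_time"][mask],
                                     bundle.clinical["os_status"][mask])
        medians[gname] = survival.median_survival(curve)
        km_frames.append(curve.as_frame().assign(group=gname))
    write_table(pd.concat(km_frames, ignore_index=True),
                outdir / "km_curves.tsv", index=False)
    record("survival", cutpoint=cut.cutpoint, statistic=cut.statistic,
           logrank_chi2=chi2, logrank_p=p_lr, medians=medians,
           n_low=cut.n_low, n_high=cut.n_high,
           selection_biased=cut.selection_biased)

    # -- stage 8: enrichment -------------------------------------------------
    gene_sets = None
    if config.gmt_path:
        gene_sets = read_gmt(config.gmt_path)
    elif cohort is not None:
        gene_sets = _truth_gene_sets(cohort,
                                     np.random.default_rng(config.seed + 1))
        write_gmt(gene_sets, outdir / "gene_sets_synthetic.gmt")
    if gene_sets is not None and deg_table is not None:
        ranked = deg_table.sort_values("log2fc", ascending=False)
        gsea = enrichment.gsea_run(list(ranked.index),
                                   ranked["log2fc"].to_numpy(), gene_sets,
                                   n_perm=config.gsea_n_perm,
                                   seed=config.seed)
        write_table(gsea.table, outdir / "gsea.tsv")
        ora = enrichment.ora_hypergeometric(deg_genes, gene_sets,
                                            list(bundle.expression.index))
        write_table(ora, outdir / "ora.tsv")
        record("enrich", n_sets=len(gene_sets),
               n_perm=config.gsea_n_perm)
    else:
        record("enrich", skipped="no gene sets supplied")

    # group-transition crosstab (subtype x DMS group)
    crosstab = landscape.group_crosstab(clusters.rename("subtype"),
                                        groups.rename("dms_group"))
    write_table(crosstab, outdir / "group_crosstab.tsv", index=False)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                             + "\n")
    return manifest


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj
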