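"""End-to-end orchestration: detect -> specificity -> coexpress -> cluster
-> markers -> assign -> project -> enrich, with a machine-readable report.

The pipeline runs either on files (count/sample/cell/annotation paths) or
on the synthetic seed generated from a ``SimConfig``; when ground truth is
available the report additionally scores recovery (sensitivity/false-call
rate of specificity calls, module ARI, cluster ARI, assignment accuracy).
Every stage is timed, failures are recorded with the stage name, and
stages downstream of a failure are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .bulk import (CPM_DETECTION_THRESHOLD, detect_genes, detection_summary,
                   group_key, group_mean_cpm, compare_prevalence)
from .coexpression import CoexpressionConfig, build_modules, classify_module_spatial
from .enrichment import enrich_terms, top_terms
from .integration import (assign_clusters, cluster_subregion_correlation,
                          project_module, pseudobulk_vs_bulk)
from .io import (CountTable, read_counts, read_gmt, read_ortholog_map,
                 read_sample_table)
from .simulate import SimConfig, generate_all, pseudo_species_calls
from .single_nucleus import (CellMatrix, cluster_cells, find_markers,
                             marker_sets, normalize_cells, pseudobulk,
                             qc_filter_cells)
from .specificity import (call_specific_both_scopes, conserved_regional_tfs,
                          specific_sets)

log = logging.getLogger("seedatlas")

STAGE_ORDER = ("data", "detect", "specificity", "coexpress", "sn_cluster",
               "markers", "assign", "project", "enrich", "conserved_tfs")


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run.

    Threshold defaults are the study's stated ones: fivefold / FDR < 0.001
    specificity, marker filters log2FC >= 1, adjusted p < 0.05, min.pct
    0.25, and q < 0.05 for enrichment and assignment.
    """

    sim: SimConfig | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    cells_path: str | None = None
    gmt_path: str | None = None
    tf_path: str | None = None

    fold: float = 5.0
    fdr: float = 1e-3
    marker_min_pct: float = 0.25
    marker_lfc_min: float = 1.0
    marker_alpha: float = 0.05
    q_threshold: float = 0.05
    detection_cpm: float = CPM_DETECTION_THRESHOLD
    coexpr: CoexpressionConfig = field(default_factory=CoexpressionConfig)
    n_pcs: int = 30
    resolution: float = 1.0
    seed: int = 7
    outdir: str | None = None
    stages: tuple = STAGE_ORDER

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        if "coexpr" in raw and raw["coexpr"] is not None:
            raw["coexpr"] = CoexpressionConfig(**raw["coexpr"])
        return cls(**raw)

    def config_hash(self) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj
        payload = asdict(self)
        payload.pop("outdir", None)  # where results land is not provenance
        payload = json.dumps(_clean(payload), default=str, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj, key=str) if isinstance(obj, set)] \
            if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else str(f)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def _write_tsv(df: pd.DataFrame, path: Path, header: str):
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: RunConfig, return_state: bool = False):
    """Execute the full analysis; returns the report (and, on request, the
    in-memory stage products for tests and downstream work)."""
    t0 = time.time()
    report = {"version": __version__, "config_hash": config.config_hash(),
              "seed": config.seed, "stages": {}}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    header = (f"# seedatlas v{__version__} config_hash={config.config_hash()} "
              f"seed={config.seed}\n")
    state: dict = {}
    failed = False

    def _stage(name):
        def deco(fn):
            nonlocal failed
            if name not in config.stages:
                report["stages"][name] = {"status": "skipped", "reason": "not requested"}
                return
            if failed:
                report["stages"][name] = {"status": "skipped",
                                          "reason": "upstream failure"}
                return
            t = time.time()
            log.info("stage %s: start", name)
            try:
                summary = fn() or {}
                report["stages"][name] = {"status": "ok",
                                          "seconds": round(time.time() - t, 2),
                                          **summary}
            except Exception as exc:  # recorded, downstream skipped
                log.exception("stage %s failed", name)
                report["stages"][name] = {"status": "failed", "error": str(exc),
                                          "seconds": round(time.time() - t, 2)}
                failed = True
        return deco

    @_stage("data")
    def _data():
        if config.sim is not None:
            sim = generate_all(config.sim)
            state.update(sim)
            return {"source": "synthetic", "n_genes": sim["bulk_counts"].shape[0],
                    "n_bulk_samples": sim["bulk_counts"].shape[1],
                    "n_cells": sim["cells"].n_cells}
        if not (config.counts_path and config.samples_path):
            raise ValueError("either sim or counts_path+samples_path required")
        state["bulk_counts"] = read_counts(config.counts_path, "tsv")
        state["samples"] = read_sample_table(config.samples_path)
        state["truth"] = None
        if config.cells_path:
            state["cells"] = CellMatrix.from_count_table(
                read_counts(config.cells_path, "mtx_triplet"))
        if config.gmt_path:
            state["annotation"] = read_gmt(config.gmt_path)
        return {"source": "files", "n_genes": state["bulk_counts"].shape[0]}

    @_stage("detect")
    def _detect():
        counts, samples = state["bulk_counts"], state["samples"]
        calls = detect_genes(counts, samples, "all_replicates_nonzero")
        state["detection"] = calls
        state["profiles"] = group_mean_cpm(counts, samples)
        summary = detection_summary(calls)
        # whole-seed detection on the summed library, CPM-threshold rule
        total = counts.dense().sum(axis=1)
        whole_cpm = total / total.sum() * 1e6
        summary["whole_seed_count"] = int((whole_cpm > config.detection_cpm).sum())
        truth = state.get("truth")
        if truth is not None:
            summary["universal_recovered"] = int(
                sum(1 for g in truth.universal_genes
                    if bool(calls.loc[g].all())))
        tf = sorted(truth.tf_genes) if truth is not None else None
        if tf:
            groups = list(calls.columns)
            pvals = {g: compare_prevalence(state["profiles"], calls, tf, g)["p"]
                     for g in groups}
            summary["tf_prevalence_groups_ns"] = int(sum(p >= 0.05 for p in pvals.values()))
            summary["tf_prevalence_groups"] = len(groups)
        if outdir:
            _write_tsv(state["detection"].reset_index().rename(columns={"index": "gene_id"}),
                       outdir / "detection_calls.tsv", header)
        return summary

    @_stage("specificity")
    def _specificity():
        counts, samples = state["bulk_counts"], state["samples"]
        stages = sorted(samples.frame["stage"].unique())
        calls = {}
        summary = {}
        for stage in stages:
            both = call_specific_both_scopes(counts, samples, stage,
                                             fold=config.fold, fdr_max=config.fdr)
            calls[stage] = both
            summary[stage] = {scope: int(len(df)) for scope, df in both.items()}
        state["specificity"] = calls
        sub_all = pd.concat([calls[s]["subregion"] for s in stages])
        reg_all = pd.concat([calls[s]["regional"] for s in stages])
        state["calls_subregion"] = sub_all
        state["calls_regional"] = reg_all
        truth = state.get("truth")
        if truth is not None:
            perf = {}
            spec_truth = truth.specific_genes
            for stage in stages:
                for scope in ("subregion", "regional"):
                    df = calls[stage][scope]
                    called = set(zip(df["gene_id"], df["subregion"]))
                    t = spec_truth[spec_truth["stage"] == stage]
                    if scope == "subregion":
                        t = t[t["scope"] == "subregion"]
                    # score the genes planted *as* specific/regional; module
                    # members (lower planted fold) are tracked separately
                    dedicated = t[t["source"] != "module"]
                    ded_pairs = set(zip(dedicated["gene"], dedicated["subregion"]))
                    mod_pairs = set(zip(t.loc[t["source"] == "module", "gene"],
                                        t.loc[t["source"] == "module", "subregion"]))
                    planted_genes = truth.planted_genes(stage)
                    other = set(state["bulk_counts"].gene_ids) - planted_genes
                    false_genes = {g for g, _s in called if g not in planted_genes}
                    perf[f"{stage}:{scope}"] = {
                        "sensitivity": round(len(ded_pairs & called) / len(ded_pairs), 4)
                        if ded_pairs else None,
                        "sensitivity_module_members":
                            round(len(mod_pairs & called) / len(mod_pairs), 4)
                            if mod_pairs else None,
                        "false_call_rate": round(len(false_genes) / len(other), 5)}
            summary["recovery"] = perf
        if outdir:
            _write_tsv(pd.concat([sub_all, reg_all]),
                       outdir / "specificity_calls.tsv", header)
        return {"n_calls": summary}

    @_stage("coexpress")
    def _coexpress():
        detection = state["detection"]
        detected_any = detection.index[detection.any(axis=1)]
        expr = np.log2(state["profiles"].loc[detected_any] + 1.0)
        expr = expr.loc[expr.std(axis=1) > 0]
        result = build_modules(expr, config.coexpr)
        state["coexpression"] = result
        classes = {}
        for mid, module in result["modules"].items():
            cls = classify_module_spatial(
                module.member_gene_ids, module.eigengene,
                state["calls_subregion"], state["calls_regional"],
                config.coexpr.specific_fraction_threshold)
            module.spatial_class = cls["spatial_class"]
            module.focal_subregion = cls["focal_subregion"]
            module.fraction_members_specific = cls["fraction_members_specific"]
            classes[mid] = cls
        summary = {"power": result["power"], "fallback": result["fallback"],
                   "n_modules": len(result["modules"]),
                   "classes": classes}
        truth = state.get("truth")
        if truth is not None:
            planted_genes = [g for members in truth.module_members.values()
                             for g in members]
            truth_labels = {g: mid for mid, members in truth.module_members.items()
                            for g in members}
            labels = result["labels"]
            shared = [g for g in planted_genes if g in labels.index]
            ari = adjusted_rand_score([truth_labels[g] for g in shared],
                                      [labels[g] for g in shared])
            summary["module_ari"] = round(float(ari), 4)
        if outdir:
            _write_tsv(result["labels"].rename("module").reset_index()
                       .rename(columns={"index": "gene_id"}),
                       outdir / "module_labels.tsv", header)
        return summary

    @_stage("sn_cluster")
    def _sn_cluster():
        if "cells" not in state:
            raise ValueError("no single-nucleus input available")
        cells, qc_report = qc_filter_cells(state["cells"], min_counts=1)
        cells = normalize_cells(cells)
        labeling = cluster_cells(cells, n_pcs=config.n_pcs,
                                 resolution=config.resolution, seed=config.seed)
        state["cells_norm"] = cells
        state["labeling"] = labeling
        summary = {"n_cells": cells.n_cells, "n_removed": len(qc_report["removed"]),
                   "n_clusters": len(labeling.cluster_ids())}
        if state.get("true_cell_labels") is not None:
            true = state["true_cell_labels"].reindex(cells.barcodes)
            ari = adjusted_rand_score(true.to_numpy(), labeling.labels.to_numpy())
            summary["cluster_ari"] = round(float(ari), 4)
        return summary

    @_stage("markers")
    def _markers():
        markers = find_markers(state["cells_norm"], state["labeling"],
                               min_pct=config.marker_min_pct,
                               lfc_min=config.marker_lfc_min,
                               alpha=config.marker_alpha)
        state["markers"] = markers
        if outdir:
            _write_tsv(markers, outdir / "cluster_markers.tsv", header)
        return {"n_marker_records": int(len(markers)),
                "clusters_with_markers": int(markers["cluster"].nunique())}

    @_stage("assign")
    def _assign():
        cells = state["cells_norm"]
        detection = state["detection"]
        bulk_detected = set(detection.index[detection.any(axis=1)])
        expressed = {g for g, nz in zip(cells.gene_ids,
                                        np.asarray((cells.counts > 0).sum(axis=1)).ravel())
                     if nz > 0}
        background = bulk_detected & expressed
        spec_sets = specific_sets(state["calls_subregion"])
        msets = marker_sets(state["markers"])
        for cid in state["labeling"].cluster_ids():
            msets.setdefault(cid, set())  # no markers -> explicit unassigned
        assignments = assign_clusters(msets, spec_sets, background,
                                      q_threshold=config.q_threshold)
        state["assignments"] = assignments
        table = {cid: a.assigned_subregion for cid, a in assignments.items()}
        summary = {"assigned": table}
        truth = state.get("truth")
        if truth is not None and state.get("true_cell_labels") is not None:
            true = state["true_cell_labels"].reindex(cells.barcodes)
            correct, total = 0, 0
            ambiguous_ok = None
            for planted, sub in truth.cluster_identities.items():
                mask = (true == planted).to_numpy()
                if mask.sum() == 0:
                    continue
                detected = state["labeling"].labels[mask].mode().iloc[0]
                got = assignments.get(detected)
                got_sub = got.assigned_subregion if got else None
                if sub is None:
                    ambiguous_ok = got_sub is None
                else:
                    total += 1
                    correct += int(got_sub == sub)
            summary["assignment_accuracy"] = round(correct / total, 4) if total else None
            summary["ambiguous_unassigned"] = ambiguous_ok
        pb_clusters = pseudobulk(cells, state["labeling"])
        state["pseudobulk_clusters"] = pb_clusters
        corr = cluster_subregion_correlation(pb_clusters, state["profiles"])
        state["cluster_subregion_corr"] = corr
        pb_all = pseudobulk(cells)
        bulk = state["bulk_counts"]
        whole = CountTable(list(bulk.gene_ids), ["whole_seed"],
                           bulk.dense().sum(axis=1).astype(np.int64)[:, None])
        rho, _table = pseudobulk_vs_bulk(pb_all, whole)
        summary["pseudobulk_bulk_spearman"] = round(rho, 4)
        if outdir:
            rows = [{"cluster": cid, "subregion": a.assigned_subregion or "unassigned",
                     "confidence": a.confidence,
                     "secondary": ",".join(a.secondary_assignments)}
                    for cid, a in assignments.items()]
            _write_tsv(pd.DataFrame(rows), outdir / "cluster_assignments.tsv", header)
        return summary

    @_stage("project")
    def _project():
        if "coexpression" not in state:
            return {"skipped": "no modules"}
        cells, labeling = state["cells_norm"], state["labeling"]
        summary = {}
        projections = {}
        for mid, module in state["coexpression"]["modules"].items():
            proj = project_module(cells, module.member_gene_ids, labeling,
                                  module_id=mid)
            projections[mid] = proj
            best = max(proj.per_cluster_z, key=lambda c: proj.per_cluster_z[c])
            summary[mid] = {"max_z_cluster": best,
                            "max_z": round(proj.per_cluster_z[best], 3),
                            "enriched": proj.enriched_clusters}
        state["projections"] = projections
        return {"modules": summary}

    @_stage("enrich")
    def _enrich():
        if "annotation" not in state:
            return {"skipped": "no annotation"}
        detection = state["detection"]
        background = set(detection.index[detection.any(axis=1)])
        summary = {}
        for sub, genes in specific_sets(state["calls_subregion"]).items():
            query = set(genes) & background
            if not query:
                continue
            rows = enrich_terms(query, state["annotation"], background,
                                q_max=config.q_threshold)
            summary[sub] = list(top_terms(rows, 5)["term_id"])
        state["enrichment"] = summary
        return {"top_terms": summary}

    @_stage("conserved_tfs")
    def _conserved():
        truth = state.get("truth")
        if truth is None or truth.orthologs is None:
            return {"skipped": "no ortholog data"}
        samples = state["samples"]
        regions_a = samples.subregion_regions()
        pairing = {r: r for r in set(regions_a.values())}
        calls_b = pseudo_species_calls(truth)
        result = conserved_regional_tfs(
            state["calls_regional"], calls_b, truth.orthologs,
            sorted(truth.tf_genes), sorted(truth.tf_genes_b), pairing,
            state["profiles"].rename(columns=lambda c: c), regions_a,
            dict(regions_a), k=5)
        return {"pairs": {r: df["gene_a"].tolist() for r, df in result.items()}}

    report["total_seconds"] = round(time.time() - t0, 2)
    report = _jsonable(report)
    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
    state["report"] = report
    return (report, state) if return_state else report
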