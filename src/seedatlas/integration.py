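"""Integration of the single-nucleus and subregion (bulk) datasets.

Cluster marker sets are compared against subregion-specific mRNA sets by
hypergeometric overlap enrichment over an explicit background universe;
each cluster is assigned to the subregion with the highest enrichment
(q < 0.05), or left unassigned.  Coexpression modules are projected onto
the cell map as the per-cell mean normalized expression of module genes,
and cluster/subregion transcriptome agreement is measured by Spearman
correlation of log CPM profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, hypergeom_upper_tail, odds_ratio_2x2
from .bulk import cpm
from .io import CountTable
from .single_nucleus import CellMatrix, ClusterLabeling


@dataclass
class OverlapStat:
    set_a_size: int
    set_b_size: int
    background_size: int
    overlap: int
    odds_ratio: float
    p_value: float
    q_value: float | None = None


@dataclass
class ClusterAssignment:
    cluster_id: str
    assigned_subregion: str | None
    enrichment_table: dict  # subregion -> OverlapStat
    confidence: float
    secondary_assignments: list = field(default_factory=list)
    reason: str | None = None


def overlap_enrichment(set_a, set_b, background) -> OverlapStat:
    """Hypergeometric upper-tail enrichment of two gene sets on a background."""
    background = set(background)
    set_a, set_b = set(set_a), set(set_b)
    for name, s in (("set_a", set_a), ("set_b", set_b)):
        outside = s - background
        if outside:
            raise ValueError(f"{name} element outside background: {sorted(outside)[0]}")
    overlap = len(set_a & set_b)
    p = hypergeom_upper_tail(overlap, len(set_a), len(set_b), len(background))
    orat = odds_ratio_2x2(overlap, len(set_a), len(set_b), len(background))
    return OverlapStat(len(set_a), len(set_b), len(background), overlap, orat, p)


def assign_clusters(marker_sets: dict, specific_sets: dict, background,
                    q_threshold: float = 0.05) -> dict:
    """Assign each cluster to the subregion whose specific set its markers
    are most enriched for.

    Enrichment score = -log10 BH-q (BH across subregions within cluster),
    tie-broken by odds ratio then lexicographic subregion id.  Subregions
    with q < threshold beyond the winner are reported as secondary
    assignments.  Genes outside the background are ignored.
    """
    background = set(background)
    subregions = sorted(specific_sets)
    out = {}
    for cid in sorted(marker_sets):
        markers = set(marker_sets[cid]) & background
        if not markers:
            out[cid] = ClusterAssignment(cid, None, {}, 0.0,
                                         reason="empty marker set")
            continue
        table = {}
        for sub in subregions:
            table[sub] = overlap_enrichment(markers,
                                            set(specific_sets[sub]) & background,
                                            background)
        qs = bh_adjust([table[sub].p_value for sub in subregions])
        for sub, q in zip(subregions, qs):
            table[sub].q_value = float(q)
        qualifying = [s for s in subregions if table[s].q_value < q_threshold]
        if not qualifying:
            out[cid] = ClusterAssignment(cid, None, table, 0.0,
                                         reason="no subregion with q < threshold")
            continue
        def score(s):
            return (-np.log10(max(table[s].q_value, 1e-300)), table[s].odds_ratio)

        ranked = sorted(qualifying, key=lambda s: (-score(s)[0], -score(s)[1], s))
        best = ranked[0]
        if len(ranked) > 1:
            s1 = score(best)[0]
            s2 = score(ranked[1])[0]
            confidence = 1.0 if s1 == s2 else (s1 / s2 if s2 > 0 else float("inf"))
        else:
            confidence = float("inf")
        out[cid] = ClusterAssignment(cid, best, table, float(confidence),
                                     secondary_assignments=ranked[1:])
    return out


@dataclass
class ModuleProjection:
    module_id: str
    per_cell_score: pd.Series
    per_cluster_mean: dict
    per_cluster_z: dict
    enriched_clusters: list


def project_module(cells: CellMatrix, module_genes, labeling: ClusterLabeling,
                   module_id: str = "module", z_threshold: float = 1.5) -> ModuleProjection:
    """Per-cell mean normalized expression of module genes, summarized per
    cluster as a z-score against the overall per-cell score distribution."""
    if cells.normalized is None:
        raise ValueError("normalize_cells must run before project_module")
    present = [g for g in module_genes if g in set(cells.gene_ids)]
    missing = len(list(module_genes)) - len(present)
    if not present:
        raise ValueError("no module gene present in cell matrix")
    if missing:
        warnings.warn(f"{missing} module gene(s) absent from cell matrix")
    pos = {g: i for i, g in enumerate(cells.gene_ids)}
    idx = [pos[g] for g in present]
    score = np.asarray(cells.normalized[idx, :].mean(axis=0)).ravel()
    score = pd.Series(score, index=cells.barcodes, name="score")
    overall_mean = float(score.mean())
    overall_sd = float(score.std(ddof=0))
    labels = labeling.labels.reindex(cells.barcodes)
    means, zs = {}, {}
    for cid in labeling.cluster_ids():
        m = float(score[labels == cid].mean())
        means[cid] = m
        zs[cid] = (m - overall_mean) / overall_sd if overall_sd > 0 else 0.0
    enriched = sorted([c for c, z in zs.items() if z >= z_threshold],
                      key=lambda c: -zs[c])
    return ModuleProjection(module_id, score, means, zs, enriched)


def _log_cpm_frame(table: CountTable) -> pd.DataFrame:
    return np.log2(cpm(table) + 1.0)


def cluster_subregion_correlation(cluster_pseudobulk: CountTable,
                                  subregion_profiles: pd.DataFrame) -> pd.DataFrame:
    """Spearman rho of cluster pseudobulk vs subregion profiles.

    Computed over the shared gene set on log2(CPM+1); ``subregion_profiles``
    is a genes x group CPM frame.  Genes zero in both vectors of a pair are
    excluded from that pair.
    """
    pb = _log_cpm_frame(cluster_pseudobulk)
    prof = np.log2(subregion_profiles + 1.0)
    shared = [g for g in pb.index if g in prof.index]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes (< 10)")
    pb = pb.loc[shared]
    prof = prof.loc[shared]
    out = pd.DataFrame(index=pb.columns, columns=prof.columns, dtype=float)
    for c in pb.columns:
        x = pb[c].to_numpy()
        for s in prof.columns:
            y = prof[s].to_numpy()
            keep = ~((x == 0) & (y == 0))
            out.loc[c, s] = stats.spearmanr(x[keep], y[keep]).statistic
    return out


def pseudobulk_vs_bulk(pseudobulk_table: CountTable,
                       whole_seed_bulk: CountTable) -> tuple:
    """Global Spearman rho between pseudobulk snRNA and whole-seed bulk.

    Both are CPM-transformed and log2(x+1); returns (rho, per-gene table).
    """
    pb = _log_cpm_frame(pseudobulk_table).iloc[:, 0]
    bulk = _log_cpm_frame(whole_seed_bulk).iloc[:, 0]
    shared = [g for g in pb.index if g in bulk.index]
    if len(shared) < 100:
        raise ValueError(f"only {len(shared)} shared genes (< 100)")
    table = pd.DataFrame({"pseudobulk_log_cpm": pb.loc[shared],
                          "bulk_log_cpm": bulk.loc[shared]})
    rho = float(stats.spearmanr(table["pseudobulk_log_cpm"],
                                table["bulk_log_cpm"]).statistic)
    return rho, table
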