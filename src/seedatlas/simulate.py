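"""Synthetic miniature seed with full ground truth.

The generator states a small world with the structure the pipeline is
meant to recover: negative-binomial bulk counts over subregion x stage x
replicate groups with planted >= 5-fold subregion- and regional-specific
genes, planted coexpression modules whose genes share a subregion-localized
profile, and single-nucleus counts drawn multinomially from cluster
identities tied to subregion profiles plus planted cluster-exclusive
markers.  One cluster is "ambiguous": its cells carry the pure baseline
profile with no planted boosts, so it should stay unassigned.

Cells sample from the LATENT subregion mean profiles (not the realized
bulk counts), so genes without planted structure are exactly
exchangeable across clusters, which makes marker precision/recall well
defined.  All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .bulk import group_key
from .io import CountTable, GeneSetCollection, OrthologMap, SampleTable
from .single_nucleus import CellMatrix

DEFAULT_SUBREGIONS = {
    "EP": "embryo", "SUS": "embryo",
    "ES-ALE": "endosperm", "ES-PER": "endosperm",
    "SC-EPD": "seed_coat", "SC-OI": "seed_coat",
    "SC-II": "seed_coat", "SC-HIL": "seed_coat",
}
DEFAULT_CLUSTER_SUBREGIONS = ("EP", "SUS", "ES-ALE", "SC-EPD", "SC-OI", "SC-HIL")
DEFAULT_MODULE_SUBREGIONS = ("EP", "ES-ALE", "SC-EPD", "SC-OI", "SC-HIL")


@dataclass
class SimConfig:
    """Stated world of the standard synthetic seed (all sizes per spec of
    the fixture: 2000 genes, 8 subregions in 3 regions, 2 stages, 3
    replicates, NB dispersion 0.1, 6 identity clusters x 150 cells, seed 7)."""

    n_genes: int = 2000
    subregions: dict = field(default_factory=lambda: dict(DEFAULT_SUBREGIONS))
    stages: tuple = ("glob", "cot")
    replicates: int = 3
    nb_dispersion: float = 0.1
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    # planted specific/module/marker genes are abundant (specific mRNAs run
    # high in the real data) but capped so planted mass stays a small
    # fraction of each library: compositional CPM compression of the
    # planted folds then stays under ~10%
    planted_baseline_log2: tuple = (5.5, 7.5)
    bulk_library_size: int = 200_000
    n_universal: int = 100
    # planted folds carry ~3 sigma of margin over the 5x calling
    # threshold: the minimum over 7 pairwise comparisons of 3-replicate NB
    # group means (dispersion 0.1) dips ~0.5-1 log2 below the planted fold
    n_specific_per_subregion: int = 5   # per stage
    specific_fold: float = 12.0
    n_regional_per_region: int = 3      # per stage
    regional_fold: float = 12.0
    module_sizes: tuple = (40, 45, 50, 55, 60)
    module_subregions: tuple = DEFAULT_MODULE_SUBREGIONS
    module_fold: float = 8.0
    module_loading_jitter: float = 0.1
    # module members sit below the dedicated specific genes so five whole
    # modules do not dominate the focal subregion's library
    module_baseline_log2: tuple = (4.5, 6.0)
    cluster_subregions: tuple = DEFAULT_CLUSTER_SUBREGIONS
    cells_per_cluster: int = 150
    ambiguous_cluster: bool = True
    n_markers_per_cluster: int = 20
    marker_log2fc: float = 3.0
    cell_library_median: float = 4000.0
    cell_library_sigma: float = 0.3
    empty_fraction: float = 0.05
    n_tf_random: int = 100
    ortholog_fraction: float = 0.6
    n_decoy_terms: int = 30
    decoy_term_size: int = 20
    seed: int = 7

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_genes", "replicates", "bulk_library_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted structure: what a correct pipeline should recover."""

    specific_genes: pd.DataFrame  # gene, stage, subregion, scope, fold
    module_members: dict          # module_id -> list of genes
    module_focal: dict            # module_id -> focal subregion
    universal_genes: set
    tf_genes: set
    baseline_log2: pd.Series = None
    group_log2_mean: pd.DataFrame = None   # genes x group keys (latent)
    cluster_identities: dict = field(default_factory=dict)  # cluster -> subregion|None
    cluster_markers: dict = field(default_factory=dict)     # cluster -> list of genes
    cell_probs: pd.DataFrame = None        # genes x clusters sampling probabilities
    orthologs: OrthologMap = None
    tf_genes_b: set = field(default_factory=set)

    def specific_pairs(self, stage: str, scope: str) -> set:
        """(gene, subregion) pairs planted as specific at this stage/scope.

        Subregion-scope plants are nested inside the regional scope.
        """
        df = self.specific_genes[self.specific_genes["stage"] == stage]
        if scope == "subregion":
            df = df[df["scope"] == "subregion"]
        return set(zip(df["gene"], df["subregion"]))

    def planted_genes(self, stage: str) -> set:
        df = self.specific_genes[self.specific_genes["stage"] == stage]
        return set(df["gene"])

    def true_marker_lfc(self) -> pd.DataFrame:
        """Latent one-vs-rest log2FC per gene x cluster, on the same
        de-logged scale the marker caller uses."""
        probs = self.cell_probs
        out = {}
        # scale latent probabilities to expected counts at a nominal library
        lam = probs.to_numpy()
        lam = lam / lam.sum(axis=0, keepdims=True)
        nominal = 4000.0
        for j, cid in enumerate(probs.columns):
            mean_in = nominal * lam[:, j]
            mean_out = nominal * lam[:, [i for i in range(lam.shape[1]) if i != j]].mean(axis=1)
            out[cid] = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        return pd.DataFrame(out, index=probs.index)


def _gene_ids(n):
    return [f"g{i:04d}" for i in range(n)]


def generate_bulk(config: SimConfig):
    """Bulk counts + samples + planted truth.

    Returns (CountTable, SampleTable, SyntheticTruth).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    subs = sorted(config.subregions)
    regions = sorted(set(config.subregions.values()))
    stages = list(config.stages)
    group_keys = [group_key(s, t) for s in subs for t in stages]

    n_specific = config.n_specific_per_subregion * len(subs) * len(stages)
    n_regional = config.n_regional_per_region * len(regions) * len(stages)
    n_module = sum(config.module_sizes)
    n_clusters = len(config.cluster_subregions)
    n_markers = config.n_markers_per_cluster * n_clusters
    n_planted = config.n_universal + n_specific + n_regional + n_module + n_markers
    if n_planted > config.n_genes:
        raise ValueError(f"more planted genes ({n_planted}) than n_genes "
                         f"({config.n_genes})")

    order = rng.permutation(config.n_genes)
    cursor = 0

    def take(k):
        nonlocal cursor
        block = [genes[i] for i in order[cursor:cursor + k]]
        cursor += k
        return block

    universal = take(config.n_universal)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          config.n_genes)
    baseline = pd.Series(baseline, index=genes, name="baseline_log2")
    # universal genes sit high enough to be detected in every replicate
    baseline.loc[universal] = rng.uniform(7.5, 10.0, len(universal))

    def _abundant(block):
        # planted specific mRNAs and markers are relatively highly
        # expressed, mirroring the higher median abundance of
        # subregion-specific transcripts in dissected-subregion data
        baseline.loc[block] = rng.uniform(*config.planted_baseline_log2, len(block))
        return block

    boost = pd.DataFrame(0.0, index=genes, columns=group_keys)
    spec_rows = []
    for stage in stages:
        for sub in subs:
            for g in _abundant(take(config.n_specific_per_subregion)):
                boost.loc[g, group_key(sub, stage)] += np.log2(config.specific_fold)
                spec_rows.append({"gene": g, "stage": stage, "subregion": sub,
                                  "scope": "subregion", "fold": config.specific_fold,
                                  "source": "specific"})
        for region in regions:
            region_subs = [s for s in subs if config.subregions[s] == region]
            for g in _abundant(take(config.n_regional_per_region)):
                for sub in region_subs:
                    boost.loc[g, group_key(sub, stage)] += np.log2(config.regional_fold)
                    spec_rows.append({"gene": g, "stage": stage, "subregion": sub,
                                      "scope": "regional", "fold": config.regional_fold,
                                      "source": "regional"})

    module_members, module_focal = {}, {}
    for mi, (size, focal) in enumerate(zip(config.module_sizes,
                                           config.module_subregions), 1):
        mid = f"mod{mi}"
        members = take(size)
        baseline.loc[members] = rng.uniform(*config.module_baseline_log2, size)
        module_members[mid] = members
        module_focal[mid] = focal
        loadings = rng.uniform(1.0, 1.0 + config.module_loading_jitter, size)
        for g, w in zip(members, loadings):
            for stage in stages:
                boost.loc[g, group_key(focal, stage)] += w * np.log2(config.module_fold)
            # module genes are >= 5-fold up in their focal subregion at
            # every stage -> part of the subregion-specific truth
            for stage in stages:
                spec_rows.append({"gene": g, "stage": stage, "subregion": focal,
                                  "scope": "subregion",
                                  "fold": float(2 ** (w * np.log2(config.module_fold))),
                                  "source": "module"})

    cluster_markers = {}
    for ci, sub in enumerate(config.cluster_subregions):
        cluster_markers[f"c{ci}"] = _abundant(take(config.n_markers_per_cluster))

    tf_pool = [g for g in genes if g not in set(universal)]
    regional_genes = sorted({r["gene"] for r in spec_rows if r["scope"] == "regional"})
    random_tfs = list(rng.choice([g for g in tf_pool if g not in regional_genes],
                                 size=config.n_tf_random, replace=False))
    tf_genes = set(regional_genes) | set(random_tfs)

    latent = boost.add(baseline, axis=0)

    columns, meta_rows = [], []
    count_cols = []
    for sub in subs:
        for stage in stages:
            probs = (2.0 ** latent[group_key(sub, stage)]).to_numpy()
            probs = probs / probs.sum()
            mu = probs * config.bulk_library_size
            for rep in range(1, config.replicates + 1):
                cid = f"{sub}_{stage}_{rep}"
                columns.append(cid)
                meta_rows.append({"column_id": cid,
                                  "region": config.subregions[sub],
                                  "subregion": sub, "stage": stage,
                                  "replicate": rep})
                if config.nb_dispersion > 0:
                    r = 1.0 / config.nb_dispersion
                    draw = rng.negative_binomial(r, r / (r + mu))
                else:
                    draw = rng.poisson(mu)
                count_cols.append(draw)
    counts = CountTable(genes, columns, np.column_stack(count_cols))
    samples = SampleTable(pd.DataFrame(meta_rows))

    truth = SyntheticTruth(
        specific_genes=pd.DataFrame(spec_rows, columns=["gene", "stage", "subregion",
                                                        "scope", "fold", "source"]),
        module_members=module_members, module_focal=module_focal,
        universal_genes=set(universal), tf_genes=tf_genes,
        baseline_log2=baseline, group_log2_mean=latent,
        cluster_markers=cluster_markers)
    return counts, samples, truth


def generate_cells(config: SimConfig, truth: SyntheticTruth):
    """Single-nucleus counts from cluster identities tied to subregions.

    Returns (CellMatrix, true labels as a pandas Series, updated truth).
    Empty barcodes (``empty_fraction`` of cells) carry all-zero columns and
    the true label "empty".
    """
    rng = np.random.default_rng(config.seed + 1)
    genes = list(truth.group_log2_mean.index)
    cot_stage = config.stages[-1]

    probs = {}
    identities = {}
    for ci, sub in enumerate(config.cluster_subregions):
        cid = f"c{ci}"
        if sub not in config.subregions:
            raise ValueError(f"cluster subregion {sub} absent from bulk truth")
        lam = 2.0 ** truth.group_log2_mean[group_key(sub, cot_stage)].to_numpy()
        markers = truth.cluster_markers[cid]
        lam = lam.copy()
        gpos = {g: i for i, g in enumerate(genes)}
        for g in markers:
            lam[gpos[g]] *= 2.0 ** config.marker_log2fc
        probs[cid] = lam / lam.sum()
        identities[cid] = sub
    if config.ambiguous_cluster:
        lam = 2.0 ** truth.baseline_log2.to_numpy()
        probs["ambiguous"] = lam / lam.sum()
        identities["ambiguous"] = None

    barcodes, labels, cols = [], [], []
    for cid in probs:
        p = probs[cid]
        for i in range(config.cells_per_cluster):
            lib = int(max(100, round(rng.lognormal(np.log(config.cell_library_median),
                                                   config.cell_library_sigma))))
            cols.append(rng.multinomial(lib, p))
            barcodes.append(f"{cid}_cell{i:04d}")
            labels.append(cid)
    n_empty = int(round(config.empty_fraction * len(barcodes)))
    for i in range(n_empty):
        cols.append(np.zeros(len(genes), dtype=np.int64))
        barcodes.append(f"empty{i:04d}")
        labels.append("empty")

    counts = sparse.csr_matrix(np.column_stack(cols))
    cells = CellMatrix(genes, barcodes, counts)
    true_labels = pd.Series(labels, index=barcodes, name="true_cluster")
    truth.cluster_identities = identities
    truth.cell_probs = pd.DataFrame({cid: probs[cid] for cid in probs}, index=genes)
    return cells, true_labels, truth


def generate_annotation(config: SimConfig, truth: SyntheticTruth):
    """Gene sets (one true term per planted structure + decoys), ortholog
    map (identity pairs for a fraction of TFs) and the pseudo-species TF
    list.  Returns (GeneSetCollection, OrthologMap, tf_list_b)."""
    rng = np.random.default_rng(config.seed + 2)
    genes = list(truth.baseline_log2.index)
    sets = {}
    for mid, members in truth.module_members.items():
        sets[f"TERM:module:{mid}"] = (f"planted module {mid}", frozenset(members))
    spec = truth.specific_genes
    planted = spec[spec["scope"] == "subregion"]
    for (sub, stage), grp in planted.groupby(["subregion", "stage"]):
        core = sorted(set(grp["gene"]))
        if len(core) >= 3:
            sets[f"TERM:specific:{sub}:{stage}"] = (
                f"planted {sub} {stage} specific", frozenset(core))
    for i in range(config.n_decoy_terms):
        decoy = rng.choice(genes, size=config.decoy_term_size, replace=False)
        sets[f"TERM:decoy{i:02d}"] = (f"decoy {i}", frozenset(decoy))
    annotation = GeneSetCollection(sets)

    tfs = sorted(truth.tf_genes)
    n_orth = int(round(config.ortholog_fraction * len(tfs)))
    chosen = list(rng.choice(tfs, size=n_orth, replace=False))
    orthologs = OrthologMap(frozenset((g, f"AT_{g}") for g in chosen))
    truth.orthologs = orthologs
    truth.tf_genes_b = {f"AT_{g}" for g in chosen}
    return annotation, orthologs, sorted(truth.tf_genes_b)


def pseudo_species_calls(truth: SyntheticTruth) -> pd.DataFrame:
    """Regional-scope specificity calls of the pseudo-species: every
    ortholog-paired TF keeps its planted regional pattern under the
    identity region pairing ("AT_" prefix on genes and matching subregions)."""
    if truth.orthologs is None:
        raise ValueError("generate_annotation must run first")
    paired = {a for a, _ in truth.orthologs.pairs}
    df = truth.specific_genes
    df = df[(df["scope"] == "regional") & df["gene"].isin(paired)].copy()
    df["gene_id"] = "AT_" + df["gene"]
    out = df[["gene_id", "stage", "subregion"]].copy()
    out["scope"] = "regional"
    out["min_fold_change"] = df["fold"].to_numpy()
    out["max_fdr"] = 0.0
    return out.reset_index(drop=True)


def generate_all(config: SimConfig):
    """Bulk + cells + annotation in one deterministic call."""
    counts, samples, truth = generate_bulk(config)
    cells, true_labels, truth = generate_cells(config, truth)
    annotation, orthologs, tf_b = generate_annotation(config, truth)
    return {"bulk_counts": counts, "samples": samples, "truth": truth,
            "cells": cells, "true_cell_labels": true_labels,
            "annotation": annotation, "orthologs": orthologs,
            "tf_list_b": tf_b}
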