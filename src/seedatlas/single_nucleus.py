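"""Single-nucleus RNA processing: QC, normalization, clustering, markers.

Mirrors the standard droplet pipeline: median-library log normalization,
PCA on the top variable genes, a shared-nearest-neighbor (SNN) graph with
Jaccard edge weights, Leiden community detection at a fixed resolution and
seed, one-vs-rest Wilcoxon marker tests, and raw-count pseudobulk.

Marker records satisfy three filters exactly as emitted: log2FC >= 1
(computed on the de-logged scale as log2((mean expm1(in)+1) /
(mean expm1(out)+1))), BH-adjusted p < 0.05, and expression in >= 25% of
in-cluster cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._stats import EXACT_RANKSUM_MAX_N, bh_adjust, rank_sum_test, rank_sum_test_matrix
from .io import CountTable

SNN_K = 20
SNN_PRUNE = 1.0 / 15.0
N_HVG = 2000
SCALE_CLIP = 10.0


@dataclass
class CellMatrix:
    """Gene x cell counts with optional normalized layer (same shape)."""

    gene_ids: list
    barcodes: list
    counts: object  # sparse genes x cells
    normalized: object = None

    def __post_init__(self):
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicated barcodes")
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError("counts shape inconsistent with gene/barcode lists")

    @property
    def n_cells(self):
        return len(self.barcodes)

    @classmethod
    def from_count_table(cls, table: CountTable) -> "CellMatrix":
        counts = table.counts if sparse.issparse(table.counts) else sparse.csr_matrix(table.counts)
        return cls(list(table.gene_ids), list(table.column_ids), counts)


@dataclass
class ClusterLabeling:
    """barcode -> cluster id plus the parameters and embedding that made it."""

    labels: pd.Series  # index barcodes, values cluster-id strings
    n_pcs: int
    resolution: float
    seed: int
    embedding: np.ndarray = None  # cells x n_pcs, row order = labels.index

    def __post_init__(self):
        if (self.labels.astype(str) == "").any():
            raise ValueError("empty cluster id")
        self.labels = self.labels.astype(str)

    def cluster_ids(self):
        return sorted(self.labels.unique())

    def cells_of(self, cluster_id: str):
        return list(self.labels.index[self.labels == cluster_id])


# ---------------------------------------------------------------------------
# QC + normalization
# ---------------------------------------------------------------------------

def qc_filter_cells(cells: CellMatrix, min_genes: int = 1,
                    max_genes: int | None = None,
                    min_counts: int = 1) -> tuple:
    """Drop cells outside the detected-gene range or below ``min_counts``."""
    if min_genes < 0 or min_counts < 0 or (max_genes is not None and max_genes < 0):
        raise ValueError("QC thresholds must be non-negative")
    genes_per_cell = np.asarray((cells.counts > 0).sum(axis=0)).ravel()
    counts_per_cell = np.asarray(cells.counts.sum(axis=0)).ravel()
    keep = (genes_per_cell >= min_genes) & (counts_per_cell >= min_counts)
    if max_genes is not None:
        keep &= genes_per_cell <= max_genes
    if not keep.any():
        raise ValueError("QC removed all cells")
    kept = [b for b, k in zip(cells.barcodes, keep) if k]
    report = {"n_input": cells.n_cells, "n_kept": int(keep.sum()),
              "removed": [b for b, k in zip(cells.barcodes, keep) if not k]}
    out = CellMatrix(list(cells.gene_ids), kept, cells.counts[:, keep])
    return out, report


def normalize_cells(cells: CellMatrix) -> CellMatrix:
    """log1p(count / cell library x median library); zeros stay zero."""
    libs = np.asarray(cells.counts.sum(axis=0)).ravel().astype(float)
    if np.any(libs == 0):
        raise ValueError("zero-library cell(s) present: run qc_filter_cells first")
    median_lib = float(np.median(libs))
    scale = sparse.diags(median_lib / libs)
    norm = (cells.counts @ scale).tocsr()
    norm.data = np.log1p(norm.data)
    return CellMatrix(list(cells.gene_ids), list(cells.barcodes),
                      cells.counts, normalized=norm)


# ---------------------------------------------------------------------------
# embedding + clustering
# ---------------------------------------------------------------------------

def highly_variable_genes(cells: CellMatrix, n_top: int = N_HVG) -> np.ndarray:
    """Indices of the top-n genes by within-mean-bin standardized dispersion."""
    norm = cells.normalized.tocsc()
    mean = np.asarray(norm.mean(axis=1)).ravel()
    sq = norm.copy()
    sq.data **= 2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    n_bins = 20
    order = np.argsort(mean, kind="stable")
    z = np.zeros(len(mean))
    for chunk in np.array_split(order, n_bins):
        d = disp[chunk]
        sd = d.std()
        z[chunk] = (d - d.mean()) / sd if sd > 0 else 0.0
    ranked = np.lexsort((np.arange(len(z)), -z))
    return np.sort(ranked[:min(n_top, len(z))])


def _embed(cells: CellMatrix, n_pcs: int, seed: int,
           n_hvg: int = N_HVG) -> np.ndarray:
    hvg = highly_variable_genes(cells, n_hvg)
    x = np.asarray(cells.normalized[hvg, :].todense(), dtype=float).T  # cells x genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = np.clip((x - mu) / sd, -SCALE_CLIP, SCALE_CLIP)
    n_comp = min(n_pcs, z.shape[0] - 1, z.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    return pca.fit_transform(z)


def snn_graph(embedding: np.ndarray, k: int = SNN_K,
              prune: float = SNN_PRUNE) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard weights, pruned < 1/15.

    Every pair of cells sharing at least one member of their (k-neighbor +
    self) sets is a candidate edge, as in the usual droplet pipeline.
    """
    n = embedding.shape[0]
    if n <= k:
        raise ValueError(f"fewer cells ({n}) than k+1 ({k + 1})")
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    idx = nn.kneighbors(return_distance=False)
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([idx, np.arange(n)[:, None]], axis=1).ravel()
    m = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    m.data[:] = 1.0  # dedupe self already in knn
    shared = (m @ m.T).tocoo()
    keep = shared.row < shared.col
    size = np.asarray(m.sum(axis=1)).ravel()
    inter = shared.data[keep]
    union = size[shared.row[keep]] + size[shared.col[keep]] - inter
    jac = inter / union
    mask = jac >= prune
    edges = list(zip(shared.row[keep][mask].tolist(),
                     shared.col[keep][mask].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jac[mask].tolist()
    return g


def _leiden(graph: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        weights=graph.es["weight"] if graph.ecount() else None,
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    return np.asarray(part.membership)


def _relabel_by_size(membership: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(membership, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[m] for m in membership])


def cluster_cells(cells: CellMatrix, n_pcs: int = 30, resolution: float = 1.0,
                  seed: int = 0, k: int = SNN_K,
                  prune: float = SNN_PRUNE) -> ClusterLabeling:
    """PCA -> SNN -> Leiden clustering; labels are "0", "1", ... by size."""
    if cells.normalized is None:
        raise ValueError("normalize_cells must run before clustering")
    if cells.n_cells < n_pcs + 1:
        raise ValueError("need >= n_pcs + 1 cells")
    emb = _embed(cells, n_pcs, seed)
    if np.allclose(emb, emb[0], atol=1e-12):
        # degenerate: all cells identical in the embedding -> one cluster
        labels = pd.Series("0", index=cells.barcodes, name="cluster")
        return ClusterLabeling(labels, n_pcs=n_pcs, resolution=resolution,
                               seed=seed, embedding=emb)
    graph = snn_graph(emb, k=k, prune=prune)
    membership = _relabel_by_size(_leiden(graph, resolution, seed))
    labels = pd.Series([str(m) for m in membership], index=cells.barcodes,
                       name="cluster")
    return ClusterLabeling(labels, n_pcs=n_pcs, resolution=resolution,
                           seed=seed, embedding=emb)


def subcluster(cells: CellMatrix, labeling: ClusterLabeling, cluster_id: str,
               resolution: float = 0.5, seed: int = 0,
               k: int = SNN_K) -> ClusterLabeling:
    """Re-cluster one cluster's cells on the same embedding.

    Children are labeled "{id}a", "{id}b", ... in decreasing size order;
    all other labels are untouched.  A cluster that stays in one community
    is returned unchanged.
    """
    if cluster_id not in set(labeling.labels):
        raise ValueError(f"unknown cluster_id: {cluster_id}")
    mask = (labeling.labels == cluster_id).to_numpy()
    sub_emb = labeling.embedding[mask]
    k_eff = min(k, sub_emb.shape[0] - 1)
    graph = snn_graph(sub_emb, k=k_eff)
    membership = _relabel_by_size(_leiden(graph, resolution, seed))
    labels = labeling.labels.copy()
    if membership.max() == 0:
        return ClusterLabeling(labels, labeling.n_pcs, labeling.resolution,
                               labeling.seed, labeling.embedding)
    suffixes = "abcdefghijklmnopqrstuvwxyz"
    new = [f"{cluster_id}{suffixes[m]}" for m in membership]
    labels.loc[mask] = new
    return ClusterLabeling(labels, labeling.n_pcs, labeling.resolution,
                           labeling.seed, labeling.embedding)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def find_markers(cells: CellMatrix, labeling: ClusterLabeling,
                 min_pct: float = 0.25, lfc_min: float = 1.0,
                 alpha: float = 0.05) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker test per cluster, positive markers only.

    Genes expressed in >= ``min_pct`` of either group are tested; BH
    adjustment is per cluster over its tested genes; emitted rows satisfy
    log2FC >= ``lfc_min``, adj_p < ``alpha`` and pct_in >= ``min_pct``.
    """
    if cells.normalized is None:
        raise ValueError("normalize_cells must run before find_markers")
    clusters = labeling.cluster_ids()
    if len(clusters) < 2:
        raise ValueError("find_markers needs >= 2 clusters")
    norm = cells.normalized.tocsr()
    label_arr = labeling.labels.reindex(cells.barcodes).to_numpy()
    rows = []
    for cid in clusters:
        in_mask = label_arr == cid
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < 3:
            warnings.warn(f"cluster {cid} has < 3 cells: skipped")
            continue
        expr_in = norm[:, in_mask]
        expr_out = norm[:, ~in_mask]
        pct_in = np.asarray((expr_in > 0).sum(axis=1)).ravel() / n_in
        pct_out = np.asarray((expr_out > 0).sum(axis=1)).ravel() / n_out
        tested = np.where((pct_in >= min_pct) | (pct_out >= min_pct))[0]
        if len(tested) == 0:
            continue
        x = np.asarray(expr_in[tested].todense(), dtype=float)
        y = np.asarray(expr_out[tested].todense(), dtype=float)
        mean_in = np.expm1(x).mean(axis=1)
        mean_out = np.expm1(y).mean(axis=1)
        lfc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        if n_in + n_out <= EXACT_RANKSUM_MAX_N:
            pvals = np.array([rank_sum_test(xi, yi) for xi, yi in zip(x, y)])
        else:
            pvals = rank_sum_test_matrix(x, y)
        adj = bh_adjust(pvals)
        keep = (lfc >= lfc_min) & (adj < alpha) & (pct_in[tested] >= min_pct)
        for gi, ok in zip(range(len(tested)), keep):
            if not ok:
                continue
            g = tested[gi]
            rows.append({"cluster": cid, "gene": cells.gene_ids[g],
                         "log2FC": float(lfc[gi]),
                         "pct_in": float(pct_in[g]), "pct_out": float(pct_out[g]),
                         "p": float(pvals[gi]), "adj_p": float(adj[gi])})
    out = pd.DataFrame(rows, columns=["cluster", "gene", "log2FC", "pct_in",
                                      "pct_out", "p", "adj_p"])
    return out.sort_values(["cluster", "adj_p", "p", "gene"]).reset_index(drop=True)


def marker_sets(markers: pd.DataFrame) -> dict:
    return {cid: set(grp["gene"]) for cid, grp in markers.groupby("cluster")}


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

def pseudobulk(cells: CellMatrix, labeling: ClusterLabeling | None = None) -> CountTable:
    """Sum raw counts over all cells, or per cluster when labels are given."""
    if labeling is None:
        col = np.asarray(cells.counts.sum(axis=1)).ravel().astype(np.int64)
        return CountTable(list(cells.gene_ids), ["pseudobulk"], col[:, None])
    label_arr = labeling.labels.reindex(cells.barcodes)
    cols, names = [], []
    for cid in labeling.cluster_ids():
        mask = (label_arr == cid).to_numpy()
        if mask.sum() == 0:
            warnings.warn(f"empty cluster {cid}: zero pseudobulk column")
            cols.append(np.zeros(len(cells.gene_ids), dtype=np.int64))
        else:
            cols.append(np.asarray(cells.counts[:, mask].sum(axis=1)).ravel()
                        .astype(np.int64))
        names.append(str(cid))
    return CountTable(list(cells.gene_ids), names, np.column_stack(cols))
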