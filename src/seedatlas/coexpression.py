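"""Weighted gene coexpression network core, implemented from scratch.

The pipeline follows the WGCNA recipe: a soft-thresholded correlation
adjacency (power chosen by the scale-free topology criterion), the
topological overlap measure (TOM) as a smoothed similarity, average-linkage
hierarchical clustering of the TOM dissimilarity with a deterministic
tree-cut, module eigengenes (first principal component of the standardized
member submatrix), eigengene-correlation merging, and a spatial
classification of each module against the subregion-specificity calls.

Everything here is deterministic given the configuration: there are no
randomized steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

UNASSIGNED = "unassigned"


@dataclass
class CoexpressionConfig:
    power_grid: tuple = tuple(range(1, 21))
    r2_target: float = 0.8
    network_type: str = "unsigned"  # or "signed_hybrid"
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    # tree-cut internals: static cut at this merge-height quantile, then a
    # cohesion filter (median within-cluster dissimilarity / cut height)
    height_quantile: float = 0.99
    tightness: float = 0.9
    specific_fraction_threshold: float = 0.5

    def __post_init__(self):
        if any(p < 1 for p in self.power_grid):
            raise ValueError("powers must be >= 1")
        if not (0 < self.r2_target <= 1):
            raise ValueError("r2_target must be in (0, 1]")


@dataclass
class CoexpressionModule:
    module_id: str
    member_gene_ids: list
    eigengene: pd.Series
    spatial_class: str = "shared"
    focal_subregion: str | None = None
    fraction_members_specific: float = 0.0
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# adjacency / TOM
# ---------------------------------------------------------------------------

def adjacency(expr: pd.DataFrame, power: float,
              network_type: str = "unsigned") -> np.ndarray:
    """Soft-thresholded correlation adjacency (genes x genes, diagonal 1)."""
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    zero_var = list(expr.index[sd == 0])
    if zero_var:
        raise ValueError(f"zero-variance gene(s): {zero_var[:10]}")
    cor = np.corrcoef(values)
    if network_type == "unsigned":
        adj = np.abs(cor) ** power
    elif network_type == "signed_hybrid":
        adj = np.where(cor > 0, cor, 0.0) ** power
    else:
        raise ValueError(f"unknown network_type: {network_type}")
    np.fill_diagonal(adj, 1.0)
    return np.clip(adj, 0.0, 1.0)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij counts shared neighbors (sum over u != i,j of a_iu a_uj) and k_i is
    the connectivity sum over u != i of a_iu.  TOM_ii = 1.
    """
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if adj.min() < -1e-12 or adj.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # includes no i/j terms because the diagonal is zeroed
    k = a.sum(axis=1)
    min_k = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (min_k + 1.0 - a)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# soft threshold
# ---------------------------------------------------------------------------

def pick_soft_threshold(expr: pd.DataFrame,
                        config: CoexpressionConfig | None = None) -> dict:
    """Scale-free topology criterion over a power grid.

    For each power: adjacency, connectivity k_i, then a log10 p(k) on
    log10 k regression over >= 10 equal-width connectivity bins.  The
    signed R^2 is sign(-slope) * R^2.  The chosen power is the smallest one
    reaching ``r2_target``; if none does, the argmax R^2 with a fallback
    flag.  A network with (near-)constant connectivity is trivially
    scale-free-degenerate and scores R^2 = 1.
    """
    config = config or CoexpressionConfig()
    if expr.shape[1] < 8:
        raise ValueError("pick_soft_threshold needs >= 8 samples")
    rows = []
    for power in config.power_grid:
        adj = adjacency(expr, power, config.network_type)
        a = adj.copy()
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        rows.append({"power": power, **_scale_free_fit(k)})
    fit = pd.DataFrame(rows)
    passing = fit[fit["signed_r2"] >= config.r2_target]
    if len(passing):
        power = int(passing["power"].iloc[0])
        fallback = False
    else:
        power = int(fit.loc[fit["signed_r2"].idxmax(), "power"])
        fallback = True
    return {"power": power, "fit": fit, "fallback": fallback}


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> dict:
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 2 or (k.max() - k.min()) / max(k.max(), 1e-12) < 1e-6:
        # constant connectivity: degenerate scale-free, criterion met
        return {"signed_r2": 1.0, "slope": 0.0, "mean_k": float(k.mean()) if len(k) else 0.0}
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.sum() / len(k)))
    xs, ys = np.array(xs), np.array(ys)
    if len(xs) < 3 or np.ptp(xs) < 1e-12:
        return {"signed_r2": 1.0, "slope": 0.0, "mean_k": float(k.mean())}
    slope, intercept = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    signed_r2 = float(r ** 2 * (1.0 if slope < 0 else -1.0))
    return {"signed_r2": signed_r2, "slope": float(slope), "mean_k": float(k.mean())}


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def cut_modules(diss_tom: np.ndarray, gene_ids,
                min_module_size: int = 30, height_quantile: float = 0.99,
                cut_fraction: float = 0.9) -> pd.Series:
    """Deterministic module detection on a TOM dissimilarity.

    Average-linkage hierarchical clustering, then a flat cut at
    ``cut_fraction`` x the ``height_quantile`` quantile of merge heights:
    modules are the maximal branches that have fully merged below that
    height and hold >= ``min_module_size`` genes.  Coexpressed blocks join
    internally at low dissimilarity while unstructured genes only merge
    near the top of the dendrogram, so pure noise yields no module at all.
    Everything else is labeled ``unassigned``.
    """
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    if min_module_size > n:
        warnings.warn("min_module_size exceeds gene count: all genes unassigned")
        return pd.Series(UNASSIGNED, index=gene_ids, name="module")
    diss = np.asarray(diss_tom, dtype=float)
    condensed = squareform(np.round((diss + diss.T) / 2, 12), checks=True)
    link = hierarchy.linkage(condensed, method="average")
    heights = link[:, 2]
    cut_h = cut_fraction * float(np.quantile(heights, height_quantile))
    flat = hierarchy.fcluster(link, t=cut_h, criterion="distance")

    labels = pd.Series(UNASSIGNED, index=gene_ids, name="module")
    accepted = [(len(m), m) for m in
                (np.where(flat == cid)[0] for cid in np.unique(flat))
                if len(m) >= min_module_size]
    accepted.sort(key=lambda t: (-t[0], t[1][0]))
    for rank, (_, members) in enumerate(accepted, 1):
        labels.iloc[members] = f"M{rank}"
    return labels


def module_eigengene(expr: pd.DataFrame, members) -> pd.Series:
    """First-PC sample scores of the gene-standardized member submatrix.

    Unit variance; sign-oriented so the mean correlation with member
    profiles is non-negative.  Zero-variance members are excluded with a
    warning; fewer than 2 usable members is an error.
    """
    members = [g for g in members if g in expr.index]
    sub = expr.loc[members].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    usable = sd > 0
    if not np.all(usable):
        warnings.warn(f"excluding {int((~usable).sum())} zero-variance member(s)")
    sub = sub[usable]
    if sub.shape[0] < 2:
        raise ValueError("module_eigengene needs >= 2 usable members")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    eig = eig / eig.std(ddof=1)
    cors = np.array([np.corrcoef(eig, row)[0, 1] for row in z])
    if np.nanmean(cors) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns, name="eigengene")


def merge_modules(expr: pd.DataFrame, labels: pd.Series,
                  merge_cut_height: float = 0.25) -> pd.Series:
    """Iteratively merge the most-correlated eigengene pair while their
    correlation >= 1 - merge_cut_height; recompute eigengenes after each
    merge.  Merging the best pair first makes the result order-independent
    when pairwise correlations are distinct."""
    labels = labels.copy()
    threshold = 1.0 - merge_cut_height
    while True:
        module_ids = sorted(m for m in labels.unique() if m != UNASSIGNED)
        if len(module_ids) < 2:
            return labels
        eigs = {m: module_eigengene(expr, labels.index[labels == m])
                for m in module_ids}
        best = None
        for i, a in enumerate(module_ids):
            for b in module_ids[i + 1:]:
                c = float(np.corrcoef(eigs[a], eigs[b])[0, 1])
                if best is None or c > best[0] + 1e-15:
                    best = (c, a, b)
        if best is None or best[0] < threshold:
            return labels
        _, a, b = best
        labels[labels == b] = a


def classify_module_spatial(members, eigengene: pd.Series,
                            calls_subregion: pd.DataFrame,
                            calls_regional: pd.DataFrame,
                            fraction_threshold: float = 0.5) -> dict:
    """Spatial class of a module from its members' specificity calls.

    subregion_specific: >= ``fraction_threshold`` of members are
    subregion-specific for one common subregion AND that subregion carries
    the maximal mean eigengene value; regional: the same criterion at
    regional scope; otherwise shared.  Eigengene columns are
    "subregion:stage" group keys.
    """
    members = set(members)
    by_sub = eigengene.groupby(
        eigengene.index.to_series().str.split(":").str[0]).mean()
    top_sub = by_sub.sort_values(ascending=False, kind="stable").index[0]

    def _best(calls):
        if calls.empty:
            return None, 0.0
        hits = calls[calls["gene_id"].isin(members)]
        if hits.empty:
            return None, 0.0
        frac = (hits.groupby("subregion")["gene_id"].nunique() / len(members))
        frac = frac.sort_values(ascending=False, kind="stable")
        return frac.index[0], float(frac.iloc[0])

    sub_focal, sub_frac = _best(calls_subregion)
    if sub_focal is not None and sub_frac >= fraction_threshold and sub_focal == top_sub:
        return {"spatial_class": "subregion_specific", "focal_subregion": sub_focal,
                "fraction_members_specific": sub_frac}
    reg_focal, reg_frac = _best(calls_regional)
    if reg_focal is not None and reg_frac >= fraction_threshold and reg_focal == top_sub:
        return {"spatial_class": "regional", "focal_subregion": reg_focal,
                "fraction_members_specific": reg_frac}
    return {"spatial_class": "shared", "focal_subregion": None,
            "fraction_members_specific": max(sub_frac, reg_frac)}


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def build_modules(expr: pd.DataFrame,
                  config: CoexpressionConfig | None = None) -> dict:
    """Soft threshold -> adjacency -> TOM -> tree-cut -> merge -> eigengenes."""
    config = config or CoexpressionConfig()
    choice = pick_soft_threshold(expr, config)
    adj = adjacency(expr, choice["power"], config.network_type)
    tom = tom_similarity(adj)
    labels = cut_modules(1.0 - tom, expr.index, config.min_module_size,
                         config.height_quantile, config.tightness)
    labels = merge_modules(expr, labels, config.merge_cut_height)
    modules = {}
    for mid in sorted(m for m in labels.unique() if m != UNASSIGNED):
        members = list(labels.index[labels == mid])
        modules[mid] = CoexpressionModule(
            module_id=mid, member_gene_ids=members,
            eigengene=module_eigengene(expr, members))
    return {"power": choice["power"], "fit": choice["fit"],
            "fallback": choice["fallback"], "labels": labels, "modules": modules}
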