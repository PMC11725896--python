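"""Subregion- and regional-specific mRNA calling.

A transcript is *subregion-specific* at a stage when it accumulates at a
fivefold or higher level (FDR < 0.001) in one subregion relative to every
other subregion at the same stage; *regional-specific* relaxes the
comparison set to subregions of the other seed regions only, so every
subregion-specific call is also a regional-specific call.

The differential test is a negative-binomial exact test in the edgeR
tradition: replicate counts are scaled to a common (geometric-mean)
library, summed per group and rounded, and the split of the two group sums
is compared against its exact conditional null given per-gene dispersions.
Dispersions come from a method-of-moments estimate on within-group
residuals, shrunk toward a binned-mean dispersion trend with weight
proportional to the residual degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import nbinom

from ._stats import bh_adjust
from .bulk import cpm, group_key
from .io import CountTable, OrthologMap, SampleTable

DISPERSION_FLOOR = 1e-4
DEFAULT_PRIOR_DF = 10.0
FOLD_THRESHOLD = 5.0
FDR_THRESHOLD = 1e-3
LOGFC_PSEUDOCOUNT = 0.25  # CPM units

_CHUNK_FLAT = 2_000_000  # max flat pmf-array length per vectorized chunk


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _pseudo_counts(counts: CountTable, columns) -> pd.DataFrame:
    """Counts rescaled to the geometric-mean library size of ``columns``."""
    sub = counts.to_frame()[list(columns)]
    libs = sub.sum(axis=0).to_numpy(dtype=float)
    if np.any(libs == 0):
        bad = [c for c, l in zip(columns, libs) if l == 0]
        raise ValueError(f"zero-library column(s): {bad}")
    target = float(np.exp(np.mean(np.log(libs))))
    return sub * (target / libs)


def estimate_dispersion(counts: CountTable, groups: dict,
                        prior_df: float = DEFAULT_PRIOR_DF) -> pd.Series:
    """Per-gene NB dispersion (phi in var = mu + phi mu^2).

    ``groups`` maps group name -> list of column ids.  Groups with a single
    replicate contribute nothing; if no group has >= 2 replicates this is
    an error (use a fixed dispersion from config instead).
    """
    multi = {g: cols for g, cols in groups.items() if len(cols) >= 2}
    if not multi:
        raise ValueError("all groups single-replicate: supply a fixed dispersion "
                         "via configuration instead of estimating one")
    all_cols = [c for cols in multi.values() for c in cols]
    pseudo = _pseudo_counts(counts, all_cols)

    phi_num = np.zeros(len(pseudo))
    df_tot = 0.0
    for cols in multi.values():
        block = pseudo[cols].to_numpy()
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        df = len(cols) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = (v - m) / (m ** 2)
        phi_g = np.where(m > 0, np.clip(phi_g, 0.0, None), 0.0)
        phi_num += df * phi_g
        df_tot += df
    phi_raw = phi_num / df_tot

    # trended prior: running mean of phi_raw over 20 equal-count mean bins
    # (the moment estimator is right-skewed, so a median trend biases the
    # dispersion low and makes the exact test anticonservative)
    overall_mean = pseudo.to_numpy().mean(axis=1)
    log_mean = np.log(overall_mean + 0.5)
    order = np.argsort(log_mean, kind="stable")
    n_bins = min(20, max(1, len(order) // 10))
    splits = np.array_split(order, n_bins)
    centers = np.array([log_mean[idx].mean() for idx in splits])
    bin_means = np.array([phi_raw[idx].mean() for idx in splits])
    if len(centers) > 1:
        trend = np.interp(log_mean, centers, bin_means)
    else:
        trend = np.full(len(log_mean), bin_means[0])

    shrunk = (df_tot * phi_raw + prior_df * trend) / (df_tot + prior_df)
    shrunk = np.maximum(shrunk, DISPERSION_FLOOR)
    return pd.Series(shrunk, index=pseudo.index, name="dispersion")


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _exact_nb_pvalues(s_a: np.ndarray, s_b: np.ndarray, n_a: int, n_b: int,
                      phi: np.ndarray) -> np.ndarray:
    """Exact conditional p-values for the split (s_a, s_b) of NB group sums.

    Under H0 the common per-replicate mean is (s_a+s_b)/(n_a+n_b); the
    group sums are NB with sizes n_g/phi.  The p-value sums the
    probabilities of all splits no more likely than the observed one
    (edgeR's doubling-free convention), so a perfectly central split gives
    p = 1 exactly.
    """
    s_a = np.asarray(s_a, dtype=np.int64)
    s_b = np.asarray(s_b, dtype=np.int64)
    phi = np.maximum(np.asarray(phi, dtype=float), 1e-8)
    s = s_a + s_b
    mu = s / (n_a + n_b)
    r_a = n_a / phi
    r_b = n_b / phi
    p_a = r_a / (r_a + n_a * mu)
    p_b = r_b / (r_b + n_b * mu)

    pvals = np.ones(len(s))
    todo = np.where(s > 0)[0]
    start = 0
    while start < len(todo):
        # grow chunk until the flat enumeration arrays reach the cap
        end, flat = start, 0
        while end < len(todo) and flat + s[todo[end]] + 1 <= _CHUNK_FLAT:
            flat += s[todo[end]] + 1
            end += 1
        end = max(end, start + 1)
        idx = todo[start:end]
        sizes = s[idx] + 1
        offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        gidx = np.repeat(np.arange(len(idx)), sizes)
        ks = np.arange(sizes.sum()) - np.repeat(offsets, sizes)
        logf = (nbinom.logpmf(ks, r_a[idx][gidx], p_a[idx][gidx])
                + nbinom.logpmf(s[idx][gidx] - ks, r_b[idx][gidx], p_b[idx][gidx]))
        f = np.exp(logf)
        log_obs = logf[offsets + s_a[idx]]
        mask = logf <= log_obs[gidx] + 1e-8
        total = np.add.reduceat(f, offsets)
        num = np.add.reduceat(np.where(mask, f, 0.0), offsets)
        with np.errstate(invalid="ignore"):
            pvals[idx] = np.where(total > 0, num / total, 1.0)
        start = end
    return np.clip(pvals, 0.0, 1.0)


def pairwise_de(counts: CountTable, cols_a, cols_b, dispersion,
                pseudocount: float = LOGFC_PSEUDOCOUNT) -> pd.DataFrame:
    """NB exact test of group A vs group B (log2FC is A over B, CPM scale)."""
    cols_a, cols_b = list(cols_a), list(cols_b)
    if set(cols_a) & set(cols_b):
        raise ValueError("overlapping group membership")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need >= 2 replicates")
    pseudo = _pseudo_counts(counts, cols_a + cols_b)
    s_a = np.round(pseudo[cols_a].sum(axis=1).to_numpy()).astype(np.int64)
    s_b = np.round(pseudo[cols_b].sum(axis=1).to_numpy()).astype(np.int64)
    if np.isscalar(dispersion):
        phi = np.full(len(pseudo), float(dispersion))
    else:
        phi = pd.Series(dispersion).reindex(pseudo.index).to_numpy(dtype=float)
    pv = _exact_nb_pvalues(s_a, s_b, len(cols_a), len(cols_b), phi)

    mat = cpm(counts)
    mean_a = mat[cols_a].mean(axis=1).to_numpy()
    mean_b = mat[cols_b].mean(axis=1).to_numpy()
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))

    return pd.DataFrame({
        "log2_fold_change": lfc,
        "p_value": pv,
        "fdr": bh_adjust(pv),
    }, index=pseudo.index)


# ---------------------------------------------------------------------------
# specificity calls
# ---------------------------------------------------------------------------

def _comparison_sets(samples: SampleTable, stage: str, scope: str) -> dict:
    """focal subregion -> list of comparison subregions at this stage."""
    stage_df = samples.frame[samples.frame["stage"] == stage]
    subs = sorted(stage_df["subregion"].unique())
    if len(subs) < 2:
        raise ValueError(f"stage {stage} has fewer than 2 subregions")
    regions = samples.subregion_regions()
    out = {}
    for focal in subs:
        if scope == "subregion":
            comp = [t for t in subs if t != focal]
        elif scope == "regional":
            comp = [t for t in subs if regions[t] != regions[focal]]
        else:
            raise ValueError(f"unknown scope: {scope}")
        out[focal] = comp
    if scope == "regional" and len({regions[s] for s in subs}) < 2:
        raise ValueError(f"regional scope needs >= 2 regions at stage {stage}")
    return out


def call_specific(counts: CountTable, samples: SampleTable, stage: str,
                  scope: str = "subregion", fold: float = FOLD_THRESHOLD,
                  fdr_max: float = FDR_THRESHOLD, dispersion=None,
                  contrast: str = "all_pairwise",
                  _pair_cache: dict | None = None) -> pd.DataFrame:
    """Call subregion- or regional-specific mRNAs at one stage.

    A gene is called for focal subregion S iff, against EVERY comparison
    subregion, its fold change (S over other) is >= ``fold`` and the
    comparison's BH FDR is < ``fdr_max``.  ``contrast='pooled'`` instead
    compares S against all comparison subregions pooled as one group.
    Returns one row per call with the minimum fold change and maximum FDR
    across comparisons.  ``_pair_cache`` lets callers reuse pairwise
    results across scopes (the tests are symmetric in the pair).
    """
    comp_sets = _comparison_sets(samples, stage, scope)
    groups = samples.groups(stage=stage)
    group_cols = {sub: cols for (sub, _stg), cols in groups.items()}
    if any(not comps for comps in comp_sets.values()):
        empty = [f for f, c in comp_sets.items() if not c]
        raise ValueError(f"empty comparison set for subregion(s) {empty} "
                         f"at stage {stage} (scope={scope})")
    if dispersion is None:
        dispersion = estimate_dispersion(counts, {str(k): v for k, v in groups.items()})

    cache = _pair_cache if _pair_cache is not None else {}
    rows = []
    for focal, comps in sorted(comp_sets.items()):
        if contrast == "pooled":
            pooled_cols = [c for t in comps for c in group_cols[t]]
            res = pairwise_de(counts, group_cols[focal], pooled_cols, dispersion)
            passing = (res["log2_fold_change"] >= np.log2(fold)) & (res["fdr"] < fdr_max)
            min_fold = 2.0 ** res["log2_fold_change"]
            max_fdr = res["fdr"]
        else:
            fold_tab, fdr_tab = [], []
            for other in comps:
                key = tuple(sorted((focal, other)))
                if key not in cache:
                    cache[key] = pairwise_de(counts, group_cols[key[0]],
                                             group_cols[key[1]], dispersion)
                res = cache[key]
                sign = 1.0 if key[0] == focal else -1.0
                fold_tab.append(2.0 ** (sign * res["log2_fold_change"]))
                fdr_tab.append(res["fdr"])
            fold_tab = pd.concat(fold_tab, axis=1)
            fdr_tab = pd.concat(fdr_tab, axis=1)
            min_fold = fold_tab.min(axis=1)
            max_fdr = fdr_tab.max(axis=1)
            passing = (min_fold >= fold) & (max_fdr < fdr_max)
        for gene in min_fold.index[passing]:
            rows.append({"gene_id": gene, "stage": stage, "subregion": focal,
                         "scope": scope, "min_fold_change": float(min_fold[gene]),
                         "max_fdr": float(max_fdr[gene])})
    out = pd.DataFrame(rows, columns=["gene_id", "stage", "subregion", "scope",
                                      "min_fold_change", "max_fdr"])
    return out.sort_values(["subregion", "gene_id"]).reset_index(drop=True)


def call_specific_both_scopes(counts: CountTable, samples: SampleTable,
                              stage: str, **kwargs) -> dict:
    """Subregion- and regional-scope calls sharing one pairwise-DE cache."""
    cache: dict = {}
    return {scope: call_specific(counts, samples, stage, scope=scope,
                                 _pair_cache=cache, **kwargs)
            for scope in ("subregion", "regional")}


def specific_sets(calls: pd.DataFrame) -> dict:
    """subregion -> set of called genes (any stage present in ``calls``)."""
    out: dict = {}
    for sub, grp in calls.groupby("subregion"):
        out[sub] = set(grp["gene_id"])
    return out


# ---------------------------------------------------------------------------
# cross-species conserved regional-specific TFs
# ---------------------------------------------------------------------------

def conserved_regional_tfs(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                           orthologs: OrthologMap, tf_list_a, tf_list_b,
                           region_pairing: dict, profiles_a: pd.DataFrame,
                           regions_a: dict, regions_b: dict, k: int = 5) -> dict:
    """Top-k conserved regional-specific TF ortholog pairs per region.

    ``calls_*`` are regional-scope specificity calls; ``regions_*`` map
    subregions to regions; ``region_pairing`` maps species-a regions to
    species-b regions.  Pairs are ranked by gene_a's maximum CPM over the
    group columns of its focal subregion(s) in ``profiles_a``.
    """
    if len(orthologs) == 0:
        raise ValueError("empty ortholog map")
    tf_a, tf_b = set(tf_list_a), set(tf_list_b)
    pairs = orthologs.pairs

    def _tf_calls(calls, tfs, regions):
        df = calls[calls["gene_id"].isin(tfs)].copy()
        df["region"] = df["subregion"].map(regions)
        return df

    a_df = _tf_calls(calls_a, tf_a, regions_a)
    b_df = _tf_calls(calls_b, tf_b, regions_b)

    out = {}
    for region_a, region_b in sorted(region_pairing.items()):
        a_sub = a_df[a_df["region"] == region_a]
        b_genes = set(b_df.loc[b_df["region"] == region_b, "gene_id"])
        found = []
        for gene_a, grp in a_sub.groupby("gene_id"):
            partners = {b for (a, b) in pairs if a == gene_a} & b_genes
            if not partners:
                continue
            prevalence = 0.0
            for _, row in grp.iterrows():
                cols = [c for c in profiles_a.columns
                        if c.startswith(row["subregion"] + ":")]
                if cols and gene_a in profiles_a.index:
                    prevalence = max(prevalence, float(profiles_a.loc[gene_a, cols].max()))
            for gene_b in sorted(partners):
                found.append({"gene_a": gene_a, "gene_b": gene_b,
                              "prevalence": prevalence})
        found.sort(key=lambda r: (-r["prevalence"], r["gene_a"], r["gene_b"]))
        out[region_a] = pd.DataFrame(found[:k],
                                     columns=["gene_a", "gene_b", "prevalence"])
    return out
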