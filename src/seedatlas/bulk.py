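"""Detection calling and prevalence summaries for the bulk (LCM) data.

Two detection rules are supported, mirroring how dissected-subregion and
whole-seed libraries are treated: a transcript is *detected* in a subregion
group when every biological replicate has at least one raw count
(``all_replicates_nonzero``), and detected in a whole-seed library when its
mean CPM exceeds a threshold (default 0.0978 CPM, the average CPM
equivalent of a single raw count in the subregion libraries).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._stats import rank_sum_test
from .io import CountTable, SampleTable

CPM_DETECTION_THRESHOLD = 0.0978

GROUP_SEP = ":"


def group_key(subregion: str, stage: str) -> str:
    return f"{subregion}{GROUP_SEP}{stage}"


def cpm(counts: CountTable) -> pd.DataFrame:
    """Counts-per-million per column; each column sums to 1e6."""
    libs = counts.column_sums()
    zero = [c for c, l in zip(counts.column_ids, libs) if l == 0]
    if zero:
        raise ValueError(f"zero-library column(s): {zero}")
    values = counts.dense() / libs * 1e6
    return pd.DataFrame(values, index=counts.gene_ids, columns=counts.column_ids)


def group_mean_cpm(counts: CountTable, samples: SampleTable,
                   method: str = "mean_cpm") -> pd.DataFrame:
    """Group-level prevalence: genes x (subregion:stage) mean CPM.

    ``mean_cpm`` averages per-replicate CPM (replicates weighted equally);
    ``cpm_of_sums`` computes CPM of the summed raw counts instead.
    """
    samples.check_against(counts)
    groups = samples.groups()
    out = {}
    if method == "mean_cpm":
        mat = cpm(counts)
        for (sub, stg), cols in groups.items():
            out[group_key(sub, stg)] = mat[cols].mean(axis=1)
    elif method == "cpm_of_sums":
        dense = counts.to_frame()
        for (sub, stg), cols in groups.items():
            summed = dense[cols].sum(axis=1)
            out[group_key(sub, stg)] = summed / summed.sum() * 1e6
    else:
        raise ValueError(f"unknown method: {method}")
    return pd.DataFrame(out)


def detect_genes(counts: CountTable, samples: SampleTable,
                 rule: str = "all_replicates_nonzero",
                 threshold: float = CPM_DETECTION_THRESHOLD) -> pd.DataFrame:
    """Boolean detection calls, genes x (subregion:stage) groups.

    ``all_replicates_nonzero``: detected iff the minimum raw count over the
    group's replicates is >= 1.  ``cpm_threshold``: detected iff the mean
    CPM over replicates exceeds ``threshold``.
    """
    samples.check_against(counts)
    groups = samples.groups()
    if any(len(cols) == 0 for cols in groups.values()):
        raise ValueError("group with zero replicates")
    calls = {}
    if rule == "all_replicates_nonzero":
        dense = counts.to_frame()
        for (sub, stg), cols in groups.items():
            calls[group_key(sub, stg)] = dense[cols].min(axis=1) >= 1
    elif rule == "cpm_threshold":
        mat = cpm(counts)
        for (sub, stg), cols in groups.items():
            calls[group_key(sub, stg)] = mat[cols].mean(axis=1) > threshold
    else:
        raise ValueError(f"unknown detection rule: {rule}")
    out = pd.DataFrame(calls)
    out.attrs["rule"] = rule
    out.attrs["threshold"] = threshold
    return out


def detection_summary(calls: pd.DataFrame) -> dict:
    """Per-group detected counts plus mean/union/intersection over groups."""
    if calls.shape[1] == 0:
        raise ValueError("detection_summary requires >= 1 group")
    per_group = calls.sum(axis=0).astype(int)
    return {
        "per_group_count": per_group.to_dict(),
        "mean_over_groups": float(per_group.mean()),
        "union_count": int(calls.any(axis=1).sum()),
        "intersection_count": int(calls.all(axis=1).sum()),
    }


def compare_prevalence(profile: pd.DataFrame, calls: pd.DataFrame,
                       subset, group: str) -> dict:
    """Median prevalence of a gene subset (e.g. TFs) vs all detected genes.

    Restricted to genes detected in ``group``; p from a two-sided
    Mann-Whitney rank test of the subset against its complement on CPM.
    """
    detected = calls.index[calls[group]]
    subset = set(subset)
    sub_genes = [g for g in detected if g in subset]
    other = [g for g in detected if g not in subset]
    if not sub_genes:
        raise ValueError(f"subset empty after detection filter in group {group}")
    vals = profile[group]
    sub_vals = vals.loc[sub_genes].to_numpy()
    other_vals = vals.loc[other].to_numpy()
    p = rank_sum_test(sub_vals, other_vals) if len(other) else np.nan
    if not len(other):
        warnings.warn(f"subset covers all detected genes in {group}; p undefined")
    return {
        "median_subset": float(np.median(sub_vals)),
        "median_all": float(np.median(vals.loc[detected].to_numpy())),
        "n_subset": len(sub_genes),
        "n_detected": len(detected),
        "p": float(p),
    }
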