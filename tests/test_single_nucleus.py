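"""QC, normalization, clustering, subclustering, markers, pseudobulk."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from seedatlas.simulate import SimConfig, generate_bulk, generate_cells
from seedatlas.single_nucleus import (CellMatrix, ClusterLabeling,
                                      cluster_cells, find_markers,
                                      normalize_cells, pseudobulk,
                                      qc_filter_cells, subcluster)


def _cells(counts, genes=None, barcodes=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(counts.shape[1])]
    return CellMatrix(genes, barcodes, sparse.csr_matrix(counts))


@pytest.fixture(scope="module")
def three_population_world():
    """Three planted cell populations with disjoint marker blocks."""
    cfg = SimConfig(n_genes=600,
                    subregions={"A": "embryo", "B": "endosperm", "C": "seed_coat"},
                    stages=("cot",), replicates=3, n_universal=20,
                    n_specific_per_subregion=5, n_regional_per_region=0,
                    module_sizes=(), module_subregions=(),
                    cluster_subregions=("A", "B", "C"), cells_per_cluster=200,
                    ambiguous_cluster=False, n_markers_per_cluster=15,
                    n_tf_random=30, seed=21)
    _counts, _samples, truth = generate_bulk(cfg)
    cells, true_labels, truth = generate_cells(cfg, truth)
    cells, _ = qc_filter_cells(cells, min_counts=1)
    cells = normalize_cells(cells)
    return cfg, cells, true_labels.reindex(cells.barcodes), truth


class TestQc:
    def test_zero_count_cell_removed(self):
        cells = _cells([[0, 3], [0, 2]])
        kept, report = qc_filter_cells(cells, min_counts=1)
        assert kept.barcodes == ["c1"]
        assert report["removed"] == ["c0"]

    def test_identity_thresholds(self):
        cells = _cells([[1, 0], [0, 2]])
        kept, _ = qc_filter_cells(cells, min_genes=0, max_genes=None, min_counts=0)
        assert kept.barcodes == cells.barcodes

    def test_planted_empty_barcodes_exactly_removed(self, standard_config):
        _c, _s, truth = generate_bulk(standard_config)
        cells, true_labels, _ = generate_cells(standard_config, truth)
        kept, report = qc_filter_cells(cells, min_counts=1)
        empties = set(true_labels.index[true_labels == "empty"])
        assert set(report["removed"]) == empties
        assert len(empties) == int(round(0.05 * (cells.n_cells - len(empties))))

    def test_all_removed_errors(self):
        with pytest.raises(ValueError, match="all cells"):
            qc_filter_cells(_cells([[0, 0]]), min_counts=1)


class TestNormalize:
    def test_zero_stays_zero(self):
        cells = normalize_cells(_cells([[0, 4], [5, 1]]))
        assert cells.normalized[0, 0] == 0.0

    def test_equal_libraries_log1p(self):
        counts = np.array([[3, 1], [2, 4]])  # both libraries = 5
        cells = normalize_cells(_cells(counts))
        np.testing.assert_allclose(cells.normalized.todense(),
                                   np.log1p(counts), atol=1e-12)

    def test_doubling_cell_counts_invariant(self):
        # doubling one cell's counts cancels in the library rescaling
        # (median library pinned by the other cells)
        base = np.array([[3, 3, 1], [2, 2, 1], [5, 5, 2]])
        doubled = base.copy()
        doubled[:, 2] *= 2
        n1 = normalize_cells(_cells(base)).normalized.todense()
        n2 = normalize_cells(_cells(doubled)).normalized.todense()
        np.testing.assert_allclose(np.asarray(n1)[:, 2], np.asarray(n2)[:, 2],
                                   atol=1e-12)

    def test_zero_library_cell_errors(self):
        with pytest.raises(ValueError, match="zero-library"):
            normalize_cells(_cells([[1, 0], [2, 0]]))


class TestCluster:
    def test_three_planted_populations(self, three_population_world):
        _cfg, cells, true_labels, _truth = three_population_world
        labeling = cluster_cells(cells, n_pcs=20, resolution=1.0, seed=5)
        from sklearn.metrics import adjusted_rand_score
        ari = adjusted_rand_score(true_labels, labeling.labels)
        assert ari >= 0.95

    def test_deterministic_under_fixed_seed(self, three_population_world):
        _cfg, cells, _tl, _truth = three_population_world
        l1 = cluster_cells(cells, n_pcs=20, resolution=1.0, seed=5)
        l2 = cluster_cells(cells, n_pcs=20, resolution=1.0, seed=5)
        pd.testing.assert_series_equal(l1.labels, l2.labels)

    def test_identical_cells_single_cluster(self):
        counts = np.tile(np.array([[4], [1], [3]]), (1, 100))
        cells = normalize_cells(_cells(counts))
        labeling = cluster_cells(cells, n_pcs=2, resolution=1.0, seed=0)
        assert len(labeling.cluster_ids()) == 1

    def test_parameters_recorded(self, three_population_world):
        _cfg, cells, _tl, _truth = three_population_world
        labeling = cluster_cells(cells, n_pcs=15, resolution=0.8, seed=9)
        assert (labeling.n_pcs, labeling.resolution, labeling.seed) == (15, 0.8, 9)

    def test_too_few_cells_errors(self):
        cells = normalize_cells(_cells(np.ones((10, 5), dtype=int)))
        with pytest.raises(ValueError, match="n_pcs"):
            cluster_cells(cells, n_pcs=30)


class TestSubcluster:
    def test_merged_subtypes_split(self, three_population_world):
        _cfg, cells, true_labels, _truth = three_population_world
        labeling = cluster_cells(cells, n_pcs=20, resolution=1.0, seed=5)
        # force two true populations under one label, then subcluster it
        merged = labeling.labels.copy()
        ids = labeling.cluster_ids()
        a, b = ids[0], ids[1]
        merged[merged == b] = a
        forced = ClusterLabeling(merged, labeling.n_pcs, labeling.resolution,
                                 labeling.seed, labeling.embedding)
        out = subcluster(cells, forced, a, resolution=0.5, seed=5)
        children = {l for l in out.labels.unique() if l.startswith(a) and l != a}
        assert children == {f"{a}a", f"{a}b"}

    def test_labels_outside_cluster_untouched(self, three_population_world):
        _cfg, cells, _tl, _truth = three_population_world
        labeling = cluster_cells(cells, n_pcs=20, resolution=1.0, seed=5)
        target = labeling.cluster_ids()[0]
        out = subcluster(cells, labeling, target, resolution=0.5, seed=5)
        outside = labeling.labels != target
        pd.testing.assert_series_equal(labeling.labels[outside],
                                       out.labels[outside])

    def test_homogeneous_cluster_unchanged(self, three_population_world):
        _cfg, cells, _tl, _truth = three_population_world
        labeling = cluster_cells(cells, n_pcs=20, resolution=1.0, seed=5)
        target = labeling.cluster_ids()[0]
        out = subcluster(cells, labeling, target, resolution=0.01, seed=5)
        pd.testing.assert_series_equal(labeling.labels, out.labels)

    def test_unknown_cluster_errors(self, three_population_world):
        _cfg, cells, _tl, _truth = three_population_world
        labeling = cluster_cells(cells, n_pcs=20, resolution=1.0, seed=5)
        with pytest.raises(ValueError, match="unknown cluster"):
            subcluster(cells, labeling, "nope")


def _labeling(labels, barcodes):
    return ClusterLabeling(pd.Series(labels, index=barcodes),
                           n_pcs=0, resolution=1.0, seed=0)


class TestMarkers:
    def test_perfect_separation(self):
        rng = np.random.default_rng(1)
        n_in, n_out = 50, 450
        counts = rng.poisson(5, (3, n_in + n_out)) + 1
        counts[0, :n_in] = rng.poisson(20, n_in) + 1
        counts[0, n_in:] = 0
        cells = normalize_cells(_cells(counts))
        labels = _labeling(["A"] * n_in + ["B"] * n_out, cells.barcodes)
        markers = find_markers(cells, labels)
        row = markers[(markers["cluster"] == "A") & (markers["gene"] == "g0")]
        assert len(row) == 1
        assert row["pct_in"].iloc[0] == 1.0
        assert row["pct_out"].iloc[0] == 0.0

    def test_uniform_gene_no_record(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(5, (4, 200))
        cells = normalize_cells(_cells(counts))
        labels = _labeling(["A"] * 100 + ["B"] * 100, cells.barcodes)
        markers = find_markers(cells, labels)
        assert markers.empty

    def test_exact_p_matches_rank_split_enumeration(self):
        # 4-vs-4 cells: p from all C(8,4)=70 assignments
        counts = np.array([[9, 7, 8, 6, 1, 2, 0, 1],
                           [5, 5, 5, 5, 5, 5, 5, 5]])
        cells = normalize_cells(_cells(counts))
        labels = _labeling(list("AAAABBBB"), cells.barcodes)
        markers = find_markers(cells, labels, lfc_min=0.0, alpha=1.0)
        norm = np.asarray(cells.normalized.todense())[0]
        ranks = stats.rankdata(norm)
        w_obs = ranks[:4].sum()
        ws = [ranks[list(idx)].sum() for idx in combinations(range(8), 4)]
        lo = np.mean([w <= w_obs + 1e-9 for w in ws])
        hi = np.mean([w >= w_obs - 1e-9 for w in ws])
        expected = min(1.0, 2 * min(lo, hi))
        row = markers[(markers["cluster"] == "A") & (markers["gene"] == "g0")]
        assert row["p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_exact_p_matches_scipy_when_no_ties(self):
        from seedatlas._stats import rank_sum_test
        x = [3.1, 5.2, 0.4, 7.7]
        y = [1.0, 2.2, 9.9, 4.4, 6.1]
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="exact").pvalue
        assert rank_sum_test(x, y) == pytest.approx(expected, abs=1e-12)

    def test_log2fc_hand_computation(self):
        # equal libraries -> normalized = log1p(count); lfc on expm1 scale
        counts = np.array([[3, 3, 3, 0, 0, 0],
                           [2, 2, 2, 5, 5, 5]])
        cells = normalize_cells(_cells(counts))
        labels = _labeling(list("AAABBB"), cells.barcodes)
        markers = find_markers(cells, labels, lfc_min=0.0, alpha=1.0,
                               min_pct=0.0)
        row = markers[(markers["cluster"] == "A") & (markers["gene"] == "g0")]
        assert row["log2FC"].iloc[0] == pytest.approx(np.log2((3 + 1) / (0 + 1)))

    def test_emitted_rows_respect_all_filters(self, pipeline_state):
        _report, state = pipeline_state
        markers = state["markers"]
        assert (markers["log2FC"] >= 1.0).all()
        assert (markers["adj_p"] < 0.05).all()
        assert (markers["pct_in"] >= 0.25).all()

    def test_planted_marker_recovery(self, three_population_world):
        _cfg, cells, true_labels, truth = three_population_world
        labeling = _labeling(true_labels.tolist(), cells.barcodes)
        markers = find_markers(cells, labeling)
        lfc_truth = truth.true_marker_lfc()
        for cid in ("c0", "c1", "c2"):
            emitted = set(markers.loc[markers["cluster"] == cid, "gene"])
            planted = set(truth.cluster_markers[cid])
            recall = len(emitted & planted) / len(planted)
            genuine = set(lfc_truth.index[lfc_truth[cid] >= 0.5])
            precision = len(emitted & genuine) / len(emitted)
            assert recall >= 0.9
            assert precision >= 0.9

    def test_single_cluster_errors(self):
        cells = normalize_cells(_cells(np.ones((2, 10), dtype=int)))
        with pytest.raises(ValueError, match="2 clusters"):
            find_markers(cells, _labeling(["A"] * 10, cells.barcodes))


class TestPseudobulk:
    def test_global_sum(self):
        cells = _cells([[1, 3], [2, 4]])
        pb = pseudobulk(cells)
        np.testing.assert_array_equal(pb.dense().ravel(), [4, 6])

    def test_cluster_columns_sum_to_global(self, three_population_world):
        _cfg, cells, true_labels, _truth = three_population_world
        labeling = _labeling(true_labels.tolist(), cells.barcodes)
        per_cluster = pseudobulk(cells, labeling)
        total = pseudobulk(cells)
        np.testing.assert_array_equal(per_cluster.dense().sum(axis=1),
                                      total.dense().ravel())

    def test_empty_cluster_zero_column_with_warning(self):
        # cluster B's only cell was QC-filtered out of the matrix
        cells = _cells([[1, 2]], barcodes=["c0", "c1"])
        labeling = ClusterLabeling(
            pd.Series(["A", "A", "B"], index=["c0", "c1", "c_removed"]),
            0, 1.0, 0)
        with pytest.warns(UserWarning, match="empty cluster B"):
            pb = pseudobulk(cells, labeling)
        assert pb.column_ids == ["A", "B"]
        np.testing.assert_array_equal(pb.dense(), [[3, 0]])
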