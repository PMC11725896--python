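"""Adjacency, TOM, soft threshold, tree cut, eigengenes, merging, classes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from seedatlas.coexpression import (CoexpressionConfig, adjacency,
                                    classify_module_spatial, cut_modules,
                                    merge_modules, module_eigengene,
                                    pick_soft_threshold, tom_similarity)

GENES16 = [f"g{i}" for i in range(16)]


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes,
                        columns=[f"s{j}" for j in range(values.shape[1])])


def _block_expr(rng, sizes, n_samples=16, within_sd=0.2):
    """Planted correlation blocks: shared profile + small independent noise."""
    rows, labels = [], []
    for b, size in enumerate(sizes):
        profile = rng.normal(0, 1, n_samples)
        for _ in range(size):
            rows.append(profile + rng.normal(0, within_sd, n_samples))
            labels.append(f"block{b}")
    genes = [f"g{i}" for i in range(len(rows))]
    return _expr(np.array(rows), genes), pd.Series(labels, index=genes)


class TestAdjacency:
    def test_perfect_correlation_any_power(self):
        expr = _expr([[1, 2, 3, 4], [2, 4, 6, 8]])
        for power in (1, 6, 12):
            assert adjacency(expr, power)[0, 1] == pytest.approx(1.0)

    def test_hand_value_unsigned(self, rng):
        # build two genes with known correlation 0.5 via Cholesky
        z = rng.normal(size=(2, 4000))
        x = z[0]
        y = 0.5 * z[0] + np.sqrt(1 - 0.25) * z[1]
        expr = _expr(np.vstack([x, y]))
        a = adjacency(expr, 6)[0, 1]
        r = np.corrcoef(x, y)[0, 1]
        assert a == pytest.approx(abs(r) ** 6)
        assert a == pytest.approx(0.5 ** 6, rel=0.25)

    def test_signed_hybrid_zeroes_negative(self):
        expr = _expr([[1, 2, 3, 4], [4, 3, 2, 1]])
        assert adjacency(expr, 6, "signed_hybrid")[0, 1] == 0.0

    def test_zero_variance_gene_errors(self):
        expr = _expr([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency(expr, 6)


class TestTom:
    def test_three_node_hand_value(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        # l_12 = 0.25, k = 1.0 each: (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)

    def test_perfect_pair(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 1.0
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self, rng):
        n = 6
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        for i, j in itertools.combinations(range(n), 2):
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            k_i = sum(a[i, u] for u in range(n) if u != i)
            k_j = sum(a[j, u] for u in range(n) if u != j)
            expected = (l_ij + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
            assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_range_and_symmetry(self, rng):
        a = rng.uniform(0, 1, (20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert tom.min() >= 0 and tom.max() <= 1
        np.testing.assert_allclose(tom, tom.T)

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(np.array([[1.0, 0.2], [0.6, 1.0]]))
        with pytest.raises(ValueError, match="0, 1"):
            tom_similarity(np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestSoftThreshold:
    def test_degenerate_copies_choose_smallest_power(self, rng):
        profile = rng.normal(0, 1, 12)
        expr = _expr(np.array([profile + rng.normal(0, 1e-4, 12)
                               for _ in range(30)]))
        res = pick_soft_threshold(expr, CoexpressionConfig(power_grid=(2, 4, 6)))
        assert res["power"] == 2
        assert not res["fallback"]

    def test_noise_falls_back_to_argmax(self, rng):
        expr = _expr(rng.normal(size=(60, 12)))
        cfg = CoexpressionConfig(power_grid=tuple(range(1, 8)))
        res = pick_soft_threshold(expr, cfg)
        assert res["fallback"]
        assert res["power"] == int(res["fit"].loc[res["fit"]["signed_r2"].idxmax(),
                                                  "power"])

    def test_fit_table_covers_grid(self, rng):
        expr = _expr(rng.normal(size=(40, 10)))
        grid = (1, 3, 5, 9)
        res = pick_soft_threshold(expr, CoexpressionConfig(power_grid=grid))
        assert res["fit"]["power"].tolist() == list(grid)

    def test_too_few_samples_errors(self, rng):
        expr = _expr(rng.normal(size=(40, 7)))
        with pytest.raises(ValueError, match="8 samples"):
            pick_soft_threshold(expr)


class TestCutModules:
    def _diss(self, expr, power=6):
        return 1.0 - tom_similarity(adjacency(expr, power))

    def test_two_planted_blocks_recovered(self, rng):
        expr, labels = _block_expr(rng, [40, 40])
        got = cut_modules(self._diss(expr), expr.index, min_module_size=30)
        assert adjusted_rand_score(labels, got) == pytest.approx(1.0)
        assert got.nunique() == 2

    def test_noise_yields_no_modules(self, rng):
        expr = _expr(rng.normal(size=(150, 16)))
        got = cut_modules(self._diss(expr), expr.index, min_module_size=30)
        assert set(got) == {"unassigned"}

    def test_small_block_below_min_size(self, rng):
        expr, _ = _block_expr(rng, [10])
        noise = _expr(rng.normal(size=(50, 16)),
                      genes=[f"n{i}" for i in range(50)])
        both = pd.concat([expr, noise])
        got = cut_modules(self._diss(both), both.index, min_module_size=30)
        assert set(got) == {"unassigned"}

    def test_min_size_above_n_warns_all_unassigned(self, rng):
        expr = _expr(rng.normal(size=(5, 10)))
        with pytest.warns(UserWarning, match="unassigned"):
            got = cut_modules(self._diss(expr), expr.index, min_module_size=30)
        assert set(got) == {"unassigned"}


class TestEigengene:
    def test_identical_members_give_standardized_profile(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        expr = _expr(np.vstack([x, x, x]))
        eig = module_eigengene(expr, expr.index)
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(eig.to_numpy(), z, atol=1e-10)

    def test_sign_rule_on_mirrored_members(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = _expr(np.vstack([x, -x, x]))
        eig = module_eigengene(expr, expr.index)
        cors = [np.corrcoef(eig, row)[0, 1] for _, row in expr.iterrows()]
        assert np.mean(cors) >= 0
        assert abs(np.corrcoef(eig, x)[0, 1]) == pytest.approx(1.0)

    def test_matches_pca_oracle(self, rng):
        from sklearn.decomposition import PCA
        expr = _expr(rng.normal(size=(5, 12)))
        eig = module_eigengene(expr, expr.index).to_numpy()
        z = expr.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
        oracle = PCA(n_components=1).fit(z.T).transform(z.T).ravel()
        oracle = oracle / oracle.std(ddof=1)
        agreement = abs(np.corrcoef(eig, oracle)[0, 1])
        assert agreement == pytest.approx(1.0, abs=1e-9)

    def test_first_pc_optimality(self, rng):
        """Eigengene explains at least as much member variance as any
        single member's standardized profile."""
        expr = _expr(rng.normal(size=(6, 10)))
        eig = module_eigengene(expr, expr.index).to_numpy()
        z = expr.to_numpy()
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)

        def explained(v):
            v = v / np.linalg.norm(v)
            return float(np.sum((z @ v) ** 2))

        best_member = max(explained(row) for row in z)
        assert explained(eig) >= best_member - 1e-9

    def test_zero_variance_member_excluded(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = _expr(np.vstack([x, x * 2, np.ones(4)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            eig = module_eigengene(expr, expr.index)
        assert abs(np.corrcoef(eig, x)[0, 1]) == pytest.approx(1.0)

    def test_too_few_members_errors(self):
        expr = _expr([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match=">= 2"):
            module_eigengene(expr, expr.index)


class TestMerge:
    def _labeled_blocks(self, rng, profiles, size=10, sd=0.15):
        rows, labels = [], []
        for b, profile in enumerate(profiles):
            for _ in range(size):
                rows.append(profile + rng.normal(0, sd, len(profile)))
                labels.append(f"M{b + 1}")
        genes = [f"g{i}" for i in range(len(rows))]
        return (_expr(np.array(rows), genes), pd.Series(labels, index=genes))

    def test_highly_correlated_modules_merge(self, rng):
        base = rng.normal(0, 1, 12)
        expr, labels = self._labeled_blocks(rng, [base, base + rng.normal(0, 0.25, 12)])
        merged = merge_modules(expr, labels, merge_cut_height=0.25)
        if np.corrcoef(module_eigengene(expr, labels.index[labels == "M1"]),
                       module_eigengene(expr, labels.index[labels == "M2"]))[0, 1] >= 0.75:
            assert merged.nunique() == 1

    def test_uncorrelated_modules_stay(self, rng):
        expr, labels = self._labeled_blocks(rng, [rng.normal(0, 1, 12),
                                                  rng.normal(0, 1, 12)])
        merged = merge_modules(expr, labels, merge_cut_height=0.25)
        assert merged.nunique() == 2

    def test_merge_order_independent(self, rng):
        profiles = [rng.normal(0, 1, 12) for _ in range(3)]
        expr, labels = self._labeled_blocks(rng, profiles)
        results = []
        for order in itertools.permutations(["M1", "M2", "M3"]):
            relabeled = labels.map({m: o for m, o in zip(["M1", "M2", "M3"], order)})
            merged = merge_modules(expr, relabeled, merge_cut_height=0.6)
            # compare partitions, not label names
            part = tuple(sorted(tuple(sorted(merged.index[merged == m]))
                                for m in merged.unique()))
            results.append(part)
        assert len(set(results)) == 1


class TestClassify:
    def _eig(self, focal="S1", subs=("S1", "S2", "S3")):
        cols = [f"{s}:{t}" for s in subs for t in ("glob", "cot")]
        values = [3.0 if c.startswith(focal) else -1.0 for c in cols]
        return pd.Series(values, index=cols)

    def _calls(self, pairs, scope="subregion"):
        return pd.DataFrame([{"gene_id": g, "stage": "cot", "subregion": s,
                              "scope": scope, "min_fold_change": 8.0,
                              "max_fdr": 1e-5} for g, s in pairs])

    def test_majority_specific_module(self):
        members = [f"g{i}" for i in range(10)]
        calls = self._calls([(g, "S1") for g in members[:8]])
        res = classify_module_spatial(members, self._eig("S1"), calls,
                                      self._calls([], "regional"))
        assert res["spatial_class"] == "subregion_specific"
        assert res["focal_subregion"] == "S1"
        assert res["fraction_members_specific"] == pytest.approx(0.8)

    def test_members_split_across_regions_shared(self):
        members = [f"g{i}" for i in range(9)]
        pairs = [(g, s) for g, s in zip(members, ["S1", "S2", "S3"] * 3)]
        res = classify_module_spatial(members, self._eig("S1"),
                                      self._calls(pairs), self._calls(pairs, "regional"))
        assert res["spatial_class"] == "shared"

    def test_regional_fallback(self):
        members = [f"g{i}" for i in range(10)]
        reg = self._calls([(g, "S1") for g in members[:7]], "regional")
        res = classify_module_spatial(members, self._eig("S1"),
                                      self._calls([]), reg)
        assert res["spatial_class"] == "regional"
        assert res["focal_subregion"] == "S1"

    def test_fixture_modules_classified_to_planted_subregions(self, pipeline_state):
        report, state = pipeline_state
        truth = state["truth"]
        classes = report["stages"]["coexpress"]["classes"]
        planted_focal = set(truth.module_focal.values())
        got_focal = {c["focal_subregion"] for c in classes.values()
                     if c["spatial_class"] == "subregion_specific"}
        assert got_focal == planted_focal
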