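"""Clustering oracles: brute-force Ward agreement, hand-computed variance
ratio, k selection and the reference-null sub-structure check."""

import numpy as np
import pytest

from gaitclust.cluster import (
    distance_matrix,
    select_k,
    variance_ratio,
    ward_linkage,
)


def _greedy_ward_oracle(X):
    """Exhaustive greedy merging by minimal SSE increase.

    Independent of scipy: clusters are member-index sets; each step merges
    the pair with the smallest Delta-SSE = |A||B|/(|A|+|B|) * ||mA - mB||^2.
    """
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ma = X[list(a)].mean(axis=0)
                mb = X[list(b)].mean(axis=0)
                d = len(a) * len(b) / (len(a) + len(b)) * np.sum((ma - mb) ** 2)
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((frozenset([clusters[i], clusters[j]]), d))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    return merges


def _scipy_merge_sets(tree):
    n = len(tree.leaf_ids)
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for idx, (a, b, h, _) in enumerate(tree.merges):
        out.append((frozenset([members[a], members[b]]), h))
        members[n + idx] = members[a] | members[b]
    return out


class TestDistanceMatrix:
    def test_identical_rows_distance_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (2, 1))
        np.testing.assert_allclose(distance_matrix(X), 0, atol=1e-15)

    def test_three_four_five(self):
        X = np.zeros((2, 10))
        X[1, 0], X[1, 1] = 3.0, 4.0
        D = distance_matrix(X)
        assert D[0, 1] == pytest.approx(5.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        X = rng.normal(size=(10, 7))
        D = distance_matrix(X)
        for i in range(10):
            for j in range(10):
                expect = np.sqrt(np.sum((X[i] - X[j]) ** 2))
                assert D[i, j] == pytest.approx(expect, abs=1e-12)
        np.testing.assert_allclose(D, D.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(D), 0, atol=1e-15)

    def test_non_finite_rows_rejected(self):
        X = np.zeros((3, 2))
        X[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            distance_matrix(X)


class TestWardLinkage:
    def test_two_points_single_merge_height(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        tree = ward_linkage(X)
        assert len(tree.merges) == 1
        # Delta-SSE for two singletons = d^2 / 2
        assert tree.merges[0][2] == pytest.approx(12.5, abs=1e-10)

    def test_collinear_points_merge_closest_first(self):
        X = np.array([[0.0], [1.0], [10.0]])
        tree = ward_linkage(X)
        a, b, _, _ = tree.merges[0]
        assert {a, b} == {0, 1}

    def test_heights_non_decreasing(self, rng):
        tree = ward_linkage(rng.normal(size=(30, 5)))
        heights = [m[2] for m in tree.merges]
        assert (np.diff(heights) >= -1e-12).all()

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_merge_sequence_matches_greedy_sse_oracle(self, seed):
        X = np.random.default_rng(seed).normal(size=(8, 4))
        oracle = _greedy_ward_oracle(X)
        ours = _scipy_merge_sets(ward_linkage(X))
        for (o_pair, o_h), (s_pair, s_h) in zip(oracle, ours):
            assert o_pair == s_pair
            assert s_h == pytest.approx(o_h, rel=1e-8)

    def test_cut_produces_requested_cluster_count(self, rng):
        X = rng.normal(size=(25, 6))
        tree = ward_linkage(X)
        for k in range(1, 25):
            assert len(set(tree.cut(k))) == k

    def test_newick_export_parses(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        tree = ward_linkage(X, leaf_ids=["a", "b", "c", "d"])
        nwk = tree.to_newick()
        assert nwk.endswith(";")
        assert all(leaf in nwk for leaf in "abcd")


class TestVarianceRatio:
    def test_true_split_beats_random_split(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.1, size=(10, 3)), rng.normal(10, 0.1, size=(10, 3))]
        )
        true = np.array([0] * 10 + [1] * 10)
        random_split = np.array(([0, 1] * 10))
        assert variance_ratio(X, true) > variance_ratio(X, random_split)

    def test_zero_within_variance_is_infinite(self):
        X = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        labels = np.array([0, 0, 1, 1])
        assert variance_ratio(X, labels) == np.inf

    def test_hand_computed_scatter_traces_on_12_point_fixture(self):
        rng = np.random.default_rng(99)
        X = rng.normal(size=(12, 4))
        labels = np.array([0] * 4 + [1] * 4 + [2] * 4)
        # independent hand computation from scatter-trace definitions
        grand = X.mean(axis=0)
        tr_b = sum(
            4 * np.sum((X[labels == g].mean(axis=0) - grand) ** 2) for g in (0, 1, 2)
        )
        tr_w = sum(
            np.sum((X[labels == g] - X[labels == g].mean(axis=0)) ** 2)
            for g in (0, 1, 2)
        )
        expect = (tr_b / 2) / (tr_w / 9)
        assert variance_ratio(X, labels) == pytest.approx(expect, abs=1e-10)

    def test_matches_sklearn_calinski_harabasz(self, rng):
        from sklearn.metrics import calinski_harabasz_score

        X = rng.normal(size=(40, 6))
        labels = rng.integers(0, 3, size=40)
        assert variance_ratio(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels), rel=1e-10
        )

    def test_invalid_k_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValueError):
            variance_ratio(X, np.zeros(6, int))


class TestSelectK:
    def _blobs(self, centers, n_per, rng, d=5, sd=0.2):
        X = np.vstack(
            [rng.normal(c, sd, size=(n_per, d)) for c in centers]
        )
        return X

    def test_two_blobs_select_two(self, rng):
        X = self._blobs([0.0, 8.0], 15, rng)
        sol = select_k(X, ward_linkage(X), range(2, 8), n_null=0)
        assert sol.k_selected == 2

    def test_three_blobs_select_three(self, rng):
        X = self._blobs([0.0, 8.0, 16.0], 12, rng)
        sol = select_k(X, ward_linkage(X), range(2, 8), n_null=0)
        assert sol.k_selected == 3

    def test_labels_invariant_to_input_order(self, rng):
        from sklearn.metrics import adjusted_rand_score

        X = self._blobs([0.0, 6.0], 12, rng)
        ids = [f"S{i}" for i in range(len(X))]
        sol1 = select_k(X, ward_linkage(X, ids), range(2, 6), n_null=0)
        perm = rng.permutation(len(X))
        ids_p = [ids[i] for i in perm]
        sol2 = select_k(X[perm], ward_linkage(X[perm], ids_p), range(2, 6), n_null=0)
        l1 = [sol1.labels[s] for s in ids]
        l2 = [sol2.labels[s] for s in ids]
        assert adjusted_rand_score(l1, l2) == 1.0

    def test_single_gaussian_raises_no_substructure_flag(self):
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 8))
            sol = select_k(
                X, ward_linkage(X), range(2, 8), n_null=49, rng=rng
            )
            hits += sol.no_substructure
        assert hits / n_seeds >= 0.8

    def test_separated_blobs_pass_null_check(self, rng):
        X = self._blobs([0.0, 10.0], 20, rng)
        sol = select_k(X, ward_linkage(X), range(2, 6), n_null=49, rng=rng)
        assert not sol.no_substructure
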