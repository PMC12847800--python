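import math

import numpy as np
import pytest

from oracles import connectivity_brute, densities_brute
from rbfclust.hybrid_rbf import (
    AffinityState,
    RBFParams,
    SubClusterState,
    assign_isolated,
    build_affinity,
    compute_sigma,
    detect_subclusters,
    fit,
    merge_subclusters,
)
from rbfclust.synthetic import generate_feature_blobs
from rbfclust.validity import nmi


class TestRBFParams:
    def test_defaults_match_reference_settings(self):
        p = RBFParams()
        assert (p.p1, p.p2, p.p3) == (0.15, 1.0, 0.05)
        assert p.n_sigma_neighbors == 5
        assert p.tau_link == pytest.approx(math.exp(-0.5))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p1": 0.0},
            {"p1": 1.5},
            {"p2": 0.0},
            {"p3": -0.1},
            {"n_sigma_neighbors": 0},
            {"tau_link": 1.5},
            {"tau_merge": 0.0},
            {"merge_linkage": "median"},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            RBFParams(**kwargs)

    def test_inverted_thresholds_warn(self):
        with pytest.warns(UserWarning):
            RBFParams(tau_link=0.3, tau_merge=0.5)


class TestComputeSigma:
    def test_1d_line(self):
        # grand mean of mean-5NN distances over the integers 0..9:
        # endpoints 3.0, next-in 2.2, interior 1.8 -> 2.12
        x = np.arange(10.0)[:, None]
        assert compute_sigma(x, RBFParams()) == pytest.approx(2.12)

    def test_linear_in_p2(self, rng):
        x = rng.normal(size=(12, 3))
        s1 = compute_sigma(x, RBFParams(p2=1.0))
        s2 = compute_sigma(x, RBFParams(p2=2.0))
        assert s2 == pytest.approx(2 * s1)

    def test_coincident_pair_among_distinct(self):
        x = np.array([[0.0], [0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
        assert compute_sigma(x, RBFParams()) > 0

    def test_all_coincident_errors(self):
        x = np.zeros((7, 2))
        with pytest.raises(ValueError, match="degenerate"):
            compute_sigma(x, RBFParams())

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            compute_sigma(np.zeros((4, 2)), RBFParams(n_sigma_neighbors=5))


class TestBuildAffinity:
    def test_analytic_values(self):
        sigma = 1.7
        x = np.array([[0.0], [0.0], [sigma], [sigma * math.sqrt(2 * math.log(2))]])
        aff = build_affinity(x, sigma)
        assert aff.w[0, 1] == pytest.approx(1.0)  # d = 0
        assert aff.w[0, 2] == pytest.approx(math.exp(-0.5))  # d = sigma
        assert aff.w[0, 3] == pytest.approx(0.5)  # half-weight distance

    def test_symmetry_unit_diag_range(self, rng):
        x = rng.normal(size=(30, 4))
        aff = build_affinity(x, 1.0)
        assert np.array_equal(aff.w, aff.w.T)
        np.testing.assert_allclose(np.diag(aff.w), 1.0)
        assert np.all(aff.w > 0) and np.all(aff.w <= 1)

    def test_densities_match_brute_force(self, rng):
        x = rng.normal(size=(25, 3))
        aff = build_affinity(x, 0.8)
        np.testing.assert_allclose(aff.rho_raw, densities_brute(x, 0.8), atol=1e-10)
        np.testing.assert_allclose(aff.rho_norm, aff.rho_raw / 24, atol=1e-12)

    def test_nonfinite_rejected(self):
        x = np.array([[0.0], [np.nan]])
        with pytest.raises(ValueError):
            build_affinity(x, 1.0)

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            build_affinity(np.zeros((3, 1)), 0.0)


def _blob_outlier_data():
    return np.array(
        [[0, 0], [0, 0.1], [0.1, 0], [10, 10], [10, 10.1], [10.1, 10], [5, 5]], dtype=float
    )


class TestDetectSubclusters:
    def test_low_density_point_isolated(self):
        # Table-3 style thresholds: p1 - p3 = 0.10; rho_norm 0.05 is below it
        params = RBFParams(p1=0.15, p3=0.05)
        aff = build_affinity(_blob_outlier_data(), 0.5)
        assert aff.rho_norm[6] < 0.10
        state = detect_subclusters(aff, params)
        assert 6 in state.isolated

    def test_two_blobs_one_outlier(self):
        params = RBFParams(p1=0.15, p3=0.05, tau_link=0.5)
        aff = build_affinity(_blob_outlier_data(), 0.5)
        state = detect_subclusters(aff, params)
        assert state.isolated == [6]
        assert state.t == 2
        assert sorted(map(sorted, state.subclusters)) == [[0, 1, 2], [3, 4, 5]]

    def test_no_isolation_when_threshold_nonpositive(self):
        params = RBFParams(p1=0.05, p3=0.05, tau_link=0.01)
        aff = build_affinity(np.random.default_rng(0).normal(size=(8, 2)), 5.0)
        with pytest.warns(UserWarning):
            state = detect_subclusters(aff, params)
        assert state.isolated == []
        assert state.t == 1
        assert sorted(state.subclusters[0]) == list(range(8))

    def test_partition_invariant(self, rng):
        aff = build_affinity(rng.normal(size=(20, 2)), 1.0)
        state = detect_subclusters(aff, RBFParams())
        covered = sorted(state.isolated + [i for sc in state.subclusters for i in sc])
        assert covered == list(range(20))
        for i, sc in enumerate(state.subclusters):
            assert all(state.labels[j] == i + 1 for j in sc)
        assert all(state.labels[i] == 0 for i in state.isolated)

    def test_raising_p1_never_shrinks_s(self, rng):
        aff = build_affinity(rng.normal(size=(25, 2)), 0.7)
        prev = set()
        for p1 in (0.06, 0.15, 0.4, 0.9):
            state = detect_subclusters(aff, RBFParams(p1=p1, p3=0.05))
            cur = set(state.isolated)
            assert prev <= cur
            prev = cur


def _manual_three_subclusters(c12, c23, c13):
    """Six points in three 2-point subclusters with constant cross-blocks."""
    w = np.eye(6)
    blocks = {(0, 1): None, (0, 2): None, (1, 2): None}
    within = 0.95
    pairs = [(0, 1), (2, 3), (4, 5)]
    for a, b in pairs:
        w[a, b] = w[b, a] = within
    cross = {(0, 1): c12, (1, 2): c23, (0, 2): c13}
    groups = [[0, 1], [2, 3], [4, 5]]
    for (ga, gb), val in cross.items():
        for i in groups[ga]:
            for j in groups[gb]:
                w[i, j] = w[j, i] = val
    rho_raw = w.sum(axis=1) - 1
    aff = AffinityState(w=w, sigma=1.0, rho_raw=rho_raw, rho_norm=rho_raw / 5)
    labels = np.array([1, 1, 2, 2, 3, 3])
    state = SubClusterState(labels=labels, isolated=[], subclusters=groups, t=3)
    return aff, state


class TestMergeSubclusters:
    def test_selective_merge(self):
        aff, state = _manual_three_subclusters(0.8, 0.1, 0.05)
        res = merge_subclusters(state, aff, RBFParams(tau_merge=0.5))
        assert res.n_clusters == 2
        assert res.merge_log == [[1, 2], [3]]
        np.testing.assert_array_equal(res.final_labels, [1, 1, 1, 1, 2, 2])

    def test_transitive_closure(self):
        aff, state = _manual_three_subclusters(0.6, 0.6, 0.0)
        res = merge_subclusters(state, aff, RBFParams(tau_merge=0.5))
        assert res.n_clusters == 1
        assert res.merge_log == [[1, 2, 3]]

    def test_single_subcluster_identity(self):
        aff, state = _manual_three_subclusters(0.0, 0.0, 0.0)
        state = SubClusterState(
            labels=np.ones(6, dtype=int), isolated=[], subclusters=[list(range(6))], t=1
        )
        res = merge_subclusters(state, aff, RBFParams())
        assert res.n_clusters == 1

    def test_all_isolated_gives_k0(self):
        aff, _ = _manual_three_subclusters(0.0, 0.0, 0.0)
        state = SubClusterState(
            labels=np.zeros(6, dtype=int), isolated=list(range(6)), subclusters=[], t=0
        )
        res = merge_subclusters(state, aff, RBFParams())
        assert res.n_clusters == 0

    def test_connectivity_matches_brute_force(self, rng):
        aff = build_affinity(rng.normal(size=(15, 2)), 1.0)
        state = detect_subclusters(aff, RBFParams(tau_link=0.8))
        for a in range(state.t):
            for b in range(a + 1, state.t):
                expected = connectivity_brute(aff.w, state.subclusters[a], state.subclusters[b])
                block = aff.w[np.ix_(state.subclusters[a], state.subclusters[b])]
                assert block.mean() == pytest.approx(expected, abs=1e-10)

    def test_lower_tau_merge_never_increases_k(self, rng):
        aff = build_affinity(rng.normal(size=(30, 2)), 0.6)
        state = detect_subclusters(aff, RBFParams())
        ks = [
            merge_subclusters(state, aff, RBFParams(tau_merge=tm)).n_clusters
            for tm in (0.9, 0.5, 0.2, 0.05, 0.01)
        ]
        assert ks == sorted(ks, reverse=True)

    def test_max_linkage_option(self):
        aff, state = _manual_three_subclusters(0.4, 0.1, 0.05)
        mean_res = merge_subclusters(state, aff, RBFParams(tau_merge=0.45))
        with pytest.warns(UserWarning):
            params_max = RBFParams(tau_merge=0.45, tau_link=0.4, merge_linkage="max")
        max_res = merge_subclusters(state, aff, params_max)
        assert mean_res.n_clusters == 3
        assert max_res.n_clusters == 3  # max cross weight 0.4 < 0.45 too
        loose = merge_subclusters(state, aff, RBFParams(tau_merge=0.35, merge_linkage="max"))
        assert loose.n_clusters == 2


class TestAssignIsolated:
    def test_argmax_assignment(self):
        x = np.array([[0.0], [0.2], [10.0], [10.2], [1.0]])
        aff = build_affinity(x, 0.5)
        params = RBFParams(p1=0.15, p3=0.0, tau_link=0.5)  # only point 4 falls below 0.15
        state = detect_subclusters(aff, params)
        assert 4 in state.isolated
        res = assign_isolated(merge_subclusters(state, aff, params), state, aff)
        assert res.final_labels[4] == res.final_labels[0]
        assert res.isolated_assignments[4] == res.final_labels[0]

    def test_tie_goes_to_lowest_label(self):
        x = np.array([[0.0], [0.4], [10.0], [10.4], [5.2]])  # midpoint between blobs
        aff = build_affinity(x, 0.5)
        aff.w[4, :] = aff.w[:, 4] = 0.25  # exact symmetric weights to both blobs
        aff.w[4, 4] = 1.0
        state = SubClusterState(
            labels=np.array([1, 1, 2, 2, 0]), isolated=[4], subclusters=[[0, 1], [2, 3]], t=2
        )
        res = merge_subclusters(state, aff, RBFParams(tau_merge=0.9))
        res = assign_isolated(res, state, aff)
        assert res.final_labels[4] == 1

    def test_empty_s_identity(self, rng):
        aff = build_affinity(rng.normal(size=(10, 2)), 2.0)
        params = RBFParams(p1=0.01, p3=0.0, tau_link=0.3)
        state = detect_subclusters(aff, params)
        assert state.isolated == []
        before = merge_subclusters(state, aff, params)
        after = assign_isolated(before, state, aff)
        np.testing.assert_array_equal(before.final_labels, after.final_labels)

    def test_k0_errors(self):
        aff, _ = _manual_three_subclusters(0.0, 0.0, 0.0)
        state = SubClusterState(
            labels=np.zeros(6, dtype=int), isolated=list(range(6)), subclusters=[], t=0
        )
        res = merge_subclusters(state, aff, RBFParams())
        with pytest.raises(ValueError, match="no clusters"):
            assign_isolated(res, state, aff)


class TestFit:
    def test_recovers_planted_blobs(self):
        x, truth = generate_feature_blobs(2, 15, dims=3, center_spread=50, within_sd=0.5, seed=7)
        res = fit(x)
        assert res.n_clusters == 2
        assert nmi(res.final_labels, truth) == pytest.approx(1.0)

    def test_huge_sigma_single_cluster(self, rng):
        x = rng.normal(size=(12, 2))
        res = fit(x, RBFParams(p2=1e3))
        assert res.n_clusters == 1
        assert res.isolated_assignments == {}

    def test_tiny_sigma_all_isolated_errors(self, rng):
        x = rng.normal(size=(12, 2))
        with pytest.raises(ValueError, match="no clusters"):
            fit(x, RBFParams(p2=1e-6, p1=0.15, p3=0.05))

    def test_deterministic(self, rng):
        x = rng.normal(size=(20, 4))
        a = fit(x)
        b = fit(x)
        np.testing.assert_array_equal(a.final_labels, b.final_labels)
        assert a.merge_log == b.merge_log
        assert a.sigma == b.sigma

    def test_partition_total(self, rng):
        x, _ = generate_feature_blobs(3, 10, dims=2, center_spread=20, within_sd=0.4, n_outliers=2, seed=3)
        res = fit(x)
        assert np.all(res.final_labels >= 1)
        assert np.all(res.final_labels <= res.n_clusters)

    def test_permutation_equivariance(self, rng):
        x, _ = generate_feature_blobs(3, 8, dims=2, center_spread=30, within_sd=0.5, seed=5)
        perm = rng.permutation(x.shape[0])
        res = fit(x)
        res_p = fit(x[perm])
        assert nmi(res.final_labels[perm], res_p.final_labels) == pytest.approx(1.0)

    def test_scale_coupling(self, rng):
        x = rng.normal(size=(15, 3))
        sigma = compute_sigma(x, RBFParams())
        w1 = build_affinity(x, sigma).w
        w2 = build_affinity(x * 7.5, sigma * 7.5).w
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_fewer_than_two_points(self):
        with pytest.raises(ValueError):
            fit(np.zeros((1, 2)))
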