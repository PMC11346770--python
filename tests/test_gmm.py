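"""Mixture fitting, BIC selection, component merging, candidate breakpoints."""

import numpy as np
import pytest

from ascna.gmm_segmentation import (
    MixtureModel,
    candidate_breakpoints,
    fit_gmm,
    merge_components,
)

from conftest import make_bins, make_features


def three_cluster_features(rng, n_per=120, sd=0.02):
    centers = np.array([[0.5, 0.1], [1.0, 0.4], [1.5, 0.25]])
    pts = np.concatenate(
        [c + rng.normal(0, sd, size=(n_per, 2)) for c in centers]
    )
    rng.shuffle(pts)
    n_cells, m = 4, pts.shape[0] // 4
    return (
        make_features(pts[: n_cells * m, 0].reshape(n_cells, m),
                      pts[: n_cells * m, 1].reshape(n_cells, m)),
        centers,
    )


def simple_model(means, weights=None, assignments=None, cov=0.01):
    means = np.asarray(means, dtype=float)
    K = len(means)
    w = np.full(K, 1 / K) if weights is None else np.asarray(weights, float)
    return MixtureModel(
        weights=w,
        means=means,
        covariances=np.repeat((cov * np.eye(2))[None], K, axis=0),
        loglik=0.0,
        loglik_trace=[0.0],
        assignments=np.asarray(assignments) if assignments is not None else np.zeros((1, 1), int),
        n_points=100,
    )


class TestFitGmm:
    def test_bic_selects_three_well_separated_components(self, rng):
        feats, centers = three_cluster_features(rng)
        model = fit_gmm(feats, k_min=1, k_max=6, seed=0)
        assert model.K == 3
        got = model.means[np.argsort(model.means[:, 0])]
        np.testing.assert_allclose(got, centers, atol=0.02)

    def test_single_repeated_point_single_component(self):
        feats = make_features(np.full((1, 10), 1.2), np.full((1, 10), 0.4))
        model = fit_gmm(feats, k_min=1, k_max=1, seed=0)
        np.testing.assert_allclose(model.means[0], [1.2, 0.4], atol=1e-9)
        assert model.weights[0] == pytest.approx(1.0)

    def test_loglik_trace_is_monotone_nondecreasing(self, rng):
        feats, _ = three_cluster_features(rng, sd=0.05)
        for k in (2, 4, 6):
            model = fit_gmm(feats, k_min=k, k_max=k, seed=1)
            tr = model.loglik_trace
            assert all(
                b >= a - 1e-8 * (1 + abs(a)) for a, b in zip(tr, tr[1:])
            )

    def test_weights_sum_to_one_and_assignments_cover_unmasked(self, rng):
        feats, _ = three_cluster_features(rng)
        model = fit_gmm(feats, k_min=2, k_max=4, seed=0)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
        masked = feats.bin_table.masked
        assert (model.assignments[:, ~masked] >= 0).all()

    def test_matches_sklearn_reference_likelihood(self, rng):
        sklearn = pytest.importorskip("sklearn.mixture")
        feats, _ = three_cluster_features(rng, sd=0.05)
        pts, _, _ = feats.feature_points()
        ours = fit_gmm(feats, k_min=3, k_max=3, seed=0)
        ref = sklearn.GaussianMixture(
            3, covariance_type="full", n_init=5, random_state=0
        ).fit(pts)
        ref_ll = ref.score(pts) * len(pts)
        # same optimum within a small relative tolerance
        assert ours.loglik >= ref_ll - 1e-3 * abs(ref_ll)


class TestMergeComponents:
    def test_delta_zero_is_identity(self):
        model = simple_model([[1.0, 0.4], [1.02, 0.41]])
        merged = merge_components(model, delta=0.0)
        assert merged.K == 2
        np.testing.assert_array_equal(merged.means, model.means)

    def test_weighted_merge_of_close_pair(self):
        model = simple_model(
            [[1.00, 0.40], [1.05, 0.42]], weights=[0.6, 0.4]
        )
        merged = merge_components(model, delta=0.1, baf_weight=1.0)
        assert merged.K == 1
        np.testing.assert_allclose(merged.means[0], [1.02, 0.408], atol=1e-12)
        assert merged.weights[0] == pytest.approx(1.0)

    def test_distant_pair_not_merged(self):
        model = simple_model([[1.0, 0.4], [1.2, 0.4]])
        merged = merge_components(model, delta=0.1, baf_weight=1.0)
        assert merged.K == 2

    def test_baf_weight_downweights_mbaf_distance(self):
        # pure-mBAF separation of 0.12: merged at weight 0.5, kept at weight 1
        model = simple_model([[1.0, 0.30], [1.0, 0.42]])
        assert merge_components(model, delta=0.1, baf_weight=1.0).K == 2
        assert merge_components(model, delta=0.1, baf_weight=0.5).K == 1

    def test_weight_conservation_and_k_never_grows(self, rng):
        for _ in range(20):
            K = int(rng.integers(2, 8))
            means = np.column_stack(
                [rng.uniform(0, 2, K), rng.uniform(0, 0.5, K)]
            )
            w = rng.dirichlet(np.ones(K))
            model = simple_model(means, weights=w)
            merged = merge_components(model, delta=float(rng.uniform(0, 0.3)))
            assert merged.K <= K
            assert merged.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_moment_matched_covariance(self):
        model = simple_model([[1.0, 0.4], [1.06, 0.4]], weights=[0.5, 0.5])
        merged = merge_components(model, delta=0.1, baf_weight=1.0)
        # mixture of two identical covariances + between-mean scatter
        expected_var_x = 0.01 + 0.5 * 0.03**2 + 0.5 * 0.03**2
        assert merged.covariances[0, 0, 0] == pytest.approx(expected_var_x)
        assert merged.covariances[0, 1, 1] == pytest.approx(0.01)


class TestCandidateBreakpoints:
    def test_left_bin_convention(self):
        bt = make_bins(5)
        model = simple_model([[0, 0]], assignments=np.array([[1, 1, 2, 2, 2]]))
        bps = candidate_breakpoints(model, bt)
        np.testing.assert_array_equal(bps[0], [1])

    def test_constant_assignment_has_no_breakpoints(self):
        bt = make_bins(4)
        model = simple_model([[0, 0]], assignments=np.array([[3, 3, 3, 3]]))
        assert candidate_breakpoints(model, bt)[0].size == 0

    def test_every_change_reported(self):
        bt = make_bins(3)
        model = simple_model([[0, 0]], assignments=np.array([[1, 2, 1]]))
        np.testing.assert_array_equal(candidate_breakpoints(model, bt)[0], [0, 1])

    def test_chromosome_boundaries_never_produce_breakpoints(self):
        bt = make_bins(4, chrom=["chr1", "chr1", "chr2", "chr2"])
        model = simple_model([[0, 0]], assignments=np.array([[1, 1, 2, 2]]))
        assert candidate_breakpoints(model, bt)[0].size == 0

    def test_change_across_masked_gap_reported_at_left_unmasked_bin(self):
        bt = make_bins(5).with_mask(np.array([False, False, True, False, False]))
        model = simple_model([[0, 0]], assignments=np.array([[1, 1, -1, 2, 2]]))
        np.testing.assert_array_equal(candidate_breakpoints(model, bt)[0], [1])

    def test_per_cell_independence(self, rng):
        bt = make_bins(12)
        q = rng.integers(0, 3, size=(5, 12))
        model = simple_model([[0, 0]], assignments=q)
        joint = candidate_breakpoints(model, bt)
        for i in range(5):
            solo = simple_model([[0, 0]], assignments=q[i : i + 1])
            np.testing.assert_array_equal(
                candidate_breakpoints(solo, bt)[0], joint[i]
            )
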