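"""Site clustering, fold structure, confound regression, kernels, KRR,
nested cross-validation."""

import numpy as np
import pytest

from connpredict.containers import ConnectomeSet
from connpredict.prediction import (
    BatchedNestedCV,
    DEFAULT_LAMBDA_GRID,
    accuracy_metrics,
    aggregate_accuracy,
    build_site_clusters,
    correlation_kernel,
    enumerate_folds,
    fit_krr,
    krr_predict,
    nested_cv,
    regress_confounds,
    simplex_grid,
)
from conftest import small_cohort


class TestSiteClusters:
    def test_identity_when_sites_equal_clusters(self):
        sites = np.repeat([f"s{i}" for i in range(5)], 20)
        clusters, site_map = build_site_clusters(sites, n_clusters=5, min_size=10)
        assert len(set(site_map.values())) == 5
        # each cluster holds exactly one site
        sizes = np.bincount(clusters)
        np.testing.assert_array_equal(sizes, 20)

    def test_greedy_hand_trace(self):
        # sizes: a=300, b=200, c=180, d=160, e=150, f=150 into 3 clusters.
        # Greedy (descending size -> smallest cluster):
        #   a->0, b->1, c->2, d->1(360), wait: after a,b,c sizes=[300,200,180];
        #   d->2 (180+160=340), e->1 (200+150=350), f->0 (300+150=450)
        counts = {"a": 300, "b": 200, "c": 180, "d": 160, "e": 150, "f": 150}
        sites = np.concatenate([[k] * v for k, v in counts.items()])
        _, site_map = build_site_clusters(sites, n_clusters=3, min_size=150)
        assert site_map["a"] == 0
        assert site_map["b"] == 1
        assert site_map["c"] == 2
        assert site_map["d"] == 2
        assert site_map["e"] == 1
        assert site_map["f"] == 0

    def test_sites_never_split(self):
        sites = np.repeat([f"s{i}" for i in range(12)], 30)
        clusters, site_map = build_site_clusters(sites, n_clusters=4, min_size=60)
        for s in set(sites):
            assert len(set(clusters[sites == s])) == 1

    def test_small_clusters_warn(self):
        sites = np.repeat(["a", "b"], 5)
        with pytest.warns(UserWarning, match="relaxed"):
            build_site_clusters(sites, n_clusters=2, min_size=150)

    def test_too_few_sites_error(self):
        with pytest.raises(ValueError, match="split"):
            build_site_clusters(np.repeat(["a", "b"], 50), n_clusters=3)


class TestEnumerateFolds:
    def test_ten_choose_three_gives_120_folds(self):
        folds = enumerate_folds(10, 3)
        assert len(folds) == 120

    def test_each_cluster_in_36_test_sets(self):
        folds = enumerate_folds(10, 3)
        for c in range(10):
            assert sum(c in f.test_clusters for f in folds) == 36

    def test_two_choose_one(self):
        assert len(enumerate_folds(2, 1)) == 2

    def test_partition_property(self):
        for f in enumerate_folds(6, 2):
            assert not set(f.test_clusters) & set(f.train_clusters)
            assert sorted(f.test_clusters + f.train_clusters) == list(range(6))

    def test_invalid_k_test(self):
        with pytest.raises(ValueError):
            enumerate_folds(3, 3)


class TestRegressConfounds:
    def test_orthogonal_confound_leaves_y_centered(self, rng):
        n = 200
        c = rng.standard_normal(n)
        y = rng.standard_normal(n)
        tr, te = np.arange(150), np.arange(150, 200)
        # orthogonalize against the confound on the training subset
        y[tr] -= np.polyval(np.polyfit(c[tr], y[tr], 1), c[tr])
        ytr, yte, _ = regress_confounds(y, c, tr, te)
        np.testing.assert_allclose(ytr, y[tr] - y[tr].mean(), atol=1e-8)

    def test_motion_effect_removed_on_train(self, rng):
        n = 300
        fd = rng.standard_normal(n)
        y = 2.0 * fd + 0.1 * rng.standard_normal(n)
        tr, te = np.arange(200), np.arange(200, 300)
        ytr, _, coefs = regress_confounds(y, fd, tr, te)
        assert abs(np.corrcoef(ytr, fd[tr])[0, 1]) < 1e-10
        assert coefs[1] == pytest.approx(2.0, abs=0.05)

    def test_test_residuals_use_train_coefficients(self, rng):
        n = 100
        fd = rng.standard_normal(n)
        y = 1.5 * fd + rng.standard_normal(n)
        tr, te = np.arange(70), np.arange(70, 100)
        _, yte, coefs = regress_confounds(y, fd, tr, te)
        expected = y[te] - (coefs[0] + coefs[1] * fd[te])
        np.testing.assert_allclose(yte, expected)

    def test_zero_variance_confound_errors(self, rng):
        y = rng.standard_normal(50)
        with pytest.raises(ValueError, match="rank"):
            regress_confounds(y, np.ones(50), np.arange(40), np.arange(40, 50))


class TestCorrelationKernel:
    def test_single_participant_self_kernel(self, rng):
        K = correlation_kernel(rng.standard_normal((1, 30)))
        np.testing.assert_allclose(K, [[1.0]])

    def test_negated_shifted_vector_anticorrelates(self, rng):
        v = rng.standard_normal(40)
        K = correlation_kernel(np.stack([v, -v + 3.0]))
        assert K[0, 1] == pytest.approx(-1.0)

    def test_matches_pairwise_loop_oracle(self, rng):
        A = rng.standard_normal((5, 20))
        B = rng.standard_normal((4, 20))
        K = correlation_kernel(A, B)
        for i in range(5):
            for j in range(4):
                assert K[i, j] == pytest.approx(np.corrcoef(A[i], B[j])[0, 1])

    def test_zero_variance_row_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_kernel(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))


class TestFitKRR:
    def _toy(self, rng, n=6):
        X = rng.standard_normal((n, 15))
        K = correlation_kernel(X)
        y = rng.standard_normal(n)
        return K, y

    def test_interpolation_at_tiny_lambda(self, rng):
        K, y = self._toy(rng)
        alpha, mu = fit_krr(K, y, 1e-10)
        np.testing.assert_allclose(krr_predict(K, alpha, mu), y, atol=1e-4)

    def test_predicts_mean_at_huge_lambda(self, rng):
        K, y = self._toy(rng)
        alpha, mu = fit_krr(K, y, 1e10)
        np.testing.assert_allclose(krr_predict(K, alpha, mu), y.mean(), atol=1e-6)

    def test_matches_direct_linear_solve(self, rng):
        K, y = self._toy(rng)
        lam = 1.0
        alpha, mu = fit_krr(K, y, lam)
        jitter = 1e-8 * np.trace(K) / 6
        expected = np.linalg.solve(K + (lam + jitter) * np.eye(6), y - y.mean())
        np.testing.assert_allclose(alpha, expected, atol=1e-8)

    def test_negative_lambda_rejected(self, rng):
        K, y = self._toy(rng)
        with pytest.raises(ValueError):
            fit_krr(K, y, -1.0)

    def test_indefinite_kernel_rejected(self, rng):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="positive semidefinite"):
            fit_krr(K, np.array([0.0, 1.0]), 1e-6)


class TestSimplexGrid:
    def test_step_quarter_four_states_gives_35_vectors(self):
        grid = simplex_grid(4, 0.25)
        assert len(grid) == 35
        for w in grid:
            assert w.sum() == pytest.approx(1.0)
        vertices = [tuple(np.eye(4)[i]) for i in range(4)]
        assert all(any(tuple(w) == v for w in grid) for v in vertices)

    def test_step_one_gives_vertices_only(self):
        grid = simplex_grid(3, 1.0)
        assert len(grid) == 3


class TestAccuracyMetrics:
    def test_perfect_prediction(self):
        r, cod = accuracy_metrics([1.0, 2, 3, 4], [1.0, 2, 3, 4], 2.5)
        assert r == pytest.approx(1.0) and cod == pytest.approx(1.0)

    def test_constant_prediction_at_train_mean(self):
        obs = np.array([1.0, 2, 3, 4])
        r, cod = accuracy_metrics(obs, np.full(4, 2.5), 2.5)
        assert np.isnan(r)
        assert cod == pytest.approx(0.0)

    def test_hand_computed_five_points(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pred = np.array([1.5, 2.0, 2.5, 4.5, 4.0])
        r, cod = accuracy_metrics(obs, pred, 2.0)
        assert r == pytest.approx(np.corrcoef(obs, pred)[0, 1])
        expected_cod = 1 - np.sum((obs - pred) ** 2) / np.sum((obs - 2.0) ** 2)
        assert cod == pytest.approx(expected_cod)

    def test_too_few_points_missing(self):
        r, cod = accuracy_metrics([1.0, 2.0], [1.0, 2.0], 1.5)
        assert np.isnan(r) and np.isnan(cod)


class TestAggregateAccuracy:
    def test_equal_values_pass_through(self):
        assert aggregate_accuracy([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_fisher_mean_of_point_two_and_point_six(self):
        # independently computed: tanh((atanh .2 + atanh .6)/2) = 0.420204
        assert aggregate_accuracy([0.2, 0.6]) == pytest.approx(0.420204, abs=1e-5)

    def test_symmetric_values_cancel(self):
        assert aggregate_accuracy([-0.45, 0.45]) == pytest.approx(0.0, abs=1e-12)

    def test_missing_excluded_with_count(self):
        val, n = aggregate_accuracy([0.2, np.nan, 0.2], return_n=True)
        assert val == pytest.approx(0.2) and n == 2


def _mini_cv(seed=0, **overrides):
    conn, behavior, meta, truth = small_cohort(seed=seed, **overrides)
    clusters, _ = build_site_clusters(meta["site"], n_clusters=6, min_size=1)
    folds = enumerate_folds(6, 2)
    confounds = meta[["mean_fd", "mean_dvars"]].to_numpy()
    return conn, behavior, meta, truth, clusters, folds, confounds


class TestNestedCV:
    def test_no_leakage_and_no_site_splitting(self, cv_setup, cohort):
        clusters = cv_setup["clusters"]
        sites = cohort["meta"]["site"].to_numpy()
        for f in cv_setup["folds"]:
            tr = np.isin(clusters, f.train_clusters)
            te = np.isin(clusters, f.test_clusters)
            assert not np.any(tr & te)
            assert np.all(tr | te)
            for s in np.unique(sites):
                in_test = te[sites == s]
                assert in_test.all() or not in_test.any()

    def test_null_behavior_accuracy_near_zero(self, rng):
        conn, behavior, meta, truth, clusters, folds, conf = _mini_cv(seed=1)
        y = rng.standard_normal(conn.n_participants)
        res = nested_cv(conn, y, clusters, folds, family="single_kernel",
                        state="rest", confounds=conf)
        rs = np.asarray(res.r)
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 2.5 * se + 0.05

    def test_planted_signal_recovered(self):
        conn, behavior, meta, truth, clusters, folds, conf = _mini_cv(
            seed=2, n_participants=300, behavior_noise_sd=0.2, noise_sd=0.05
        )
        res = nested_cv(conn, behavior.y("cognition_01"), clusters, folds[:8],
                        family="single_kernel", state="rest", confounds=conf)
        assert res.mean_accuracy() > 0.5

    def test_participant_order_invariance(self):
        conn, behavior, meta, truth, clusters, folds, conf = _mini_cv(seed=3)
        y = behavior.y("cognition_01")
        res1 = nested_cv(conn, y, clusters, folds[:4], family="single_kernel",
                         state="rest", confounds=conf)
        perm = np.random.default_rng(0).permutation(conn.n_participants)
        conn2 = ConnectomeSet(
            participants=[conn.participants[i] for i in perm],
            states=list(conn.states), edges=conn.edges[perm],
            n_regions=conn.n_regions,
        )
        res2 = nested_cv(conn2, y[perm], clusters[perm], folds[:4],
                         family="single_kernel", state="rest", confounds=conf[perm])
        np.testing.assert_allclose(res1.r, res2.r, atol=1e-10)

    def test_affine_rescaling_of_behavior_leaves_r_unchanged(self):
        conn, behavior, meta, truth, clusters, folds, conf = _mini_cv(seed=4)
        y = behavior.y("cognition_01")
        res1 = nested_cv(conn, y, clusters, folds[:4], family="single_kernel",
                         state="rest")
        res2 = nested_cv(conn, 3.0 * y + 7.0, clusters, folds[:4],
                         family="single_kernel", state="rest")
        np.testing.assert_allclose(res1.r, res2.r, atol=1e-8)
        np.testing.assert_allclose(res1.cod, res2.cod, atol=1e-8)

    def test_multikernel_with_identical_kernels_matches_single(self):
        conn, behavior, meta, truth, clusters, folds, conf = _mini_cv(
            seed=5, state_modulation_sd=0.0
        )
        y = behavior.y("cognition_01")
        res_m = nested_cv(conn, y, clusters, folds[:4], family="multikernel",
                          weight_step=0.5, confounds=conf)
        res_s = nested_cv(conn, y, clusters, folds[:4], family="single_kernel",
                          state="rest", confounds=conf)
        for k in range(4):
            np.testing.assert_allclose(res_m.predicted[k], res_s.predicted[k],
                                       atol=1e-8)

    def test_mean_fc_with_identical_states_matches_single(self):
        conn, behavior, meta, truth, clusters, folds, conf = _mini_cv(
            seed=6, state_modulation_sd=0.0
        )
        y = behavior.y("cognition_01")
        res_m = nested_cv(conn, y, clusters, folds[:4], family="mean_fc",
                          confounds=conf)
        res_s = nested_cv(conn, y, clusters, folds[:4], family="single_kernel",
                          state="rest", confounds=conf)
        np.testing.assert_allclose(res_m.r, res_s.r, atol=1e-8)

    def test_linear_ridge_matches_kernel_trick(self):
        """Primal ridge on standardized edges equals its dual (linear-kernel)
        formulation, checked through the recovered primal weights."""
        conn, behavior, meta, truth, clusters, folds, conf = _mini_cv(seed=7)
        y = behavior.y("cognition_01")
        res = nested_cv(conn, y, clusters, folds[:2], family="linear_ridge",
                        state="rest", return_models=True)
        model = res.models[0]
        tr, te = model.train_idx, model.test_idx
        X = conn.state_edges("rest")
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        direct = Xte @ model.primal_weights + model.y_train_mean
        np.testing.assert_allclose(direct, res.predicted[0], atol=1e-6)

    def test_constant_behavior_in_fold_warns_and_skips(self):
        conn, behavior, meta, truth, clusters, folds, conf = _mini_cv(seed=8)
        y = np.zeros(conn.n_participants)
        with pytest.warns(UserWarning, match="constant"):
            res = nested_cv(conn, y, clusters, folds[:2], family="single_kernel",
                            state="rest")
        assert len(res.folds) == 0


class TestMultikernelSignal:
    def test_complementary_states_keep_multikernel_competitive(self):
        """When different states carry different planted signal, the
        inner-CV-selected multikernel keeps up with the best single state."""
        diffs = []
        for seed in range(5):
            conn, behavior, meta, truth, clusters, folds, conf = _mini_cv(
                seed=seed,
                n_participants=240,
                state_signal_profile={
                    "cognition": [1.6, 0.1, 0.1, 1.6],
                    "mental_health": [0.1, 1.6, 1.6, 0.1],
                },
            )
            y = behavior.y("cognition_01")
            singles = [
                nested_cv(conn, y, clusters, folds[:6], family="single_kernel",
                          state=s, confounds=conf).mean_accuracy()
                for s in conn.states
            ]
            multi = nested_cv(conn, y, clusters, folds[:6], family="multikernel",
                              weight_step=0.5, confounds=conf).mean_accuracy()
            diffs.append(multi - max(singles))
        assert np.median(diffs) >= -0.02


class TestBatchedEngine:
    def test_matches_sequential_nested_cv(self, cohort, cv_setup):
        conn = cohort["connectomes"]
        behavior = cohort["behavior"]
        folds = cv_setup["folds"][:10]
        clusters = cv_setup["clusters"]
        conf = cv_setup["confounds"]
        K = correlation_kernel(conn.state_edges("rest"))
        engine = BatchedNestedCV(K, clusters, folds, confounds=conf)
        measures = ["cognition_01", "noise_01"]
        batched = engine.evaluate(
            np.column_stack([behavior.y(m) for m in measures])
        )
        for j, m in enumerate(measures):
            res = nested_cv(conn, behavior.y(m), clusters, folds,
                            family="single_kernel", state="rest", confounds=conf)
            assert batched[j] == pytest.approx(res.mean_accuracy(), abs=1e-8)
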