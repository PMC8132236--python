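import numpy as np
import pytest

import jointfair as jf
from jointfair.penalties import (
    GroupMeans,
    build_penalty_operator,
    build_shared_penalty_operator,
    compute_group_means,
    eval_penalties,
    project_linf,
    smoothed_gradient,
    smoothed_penalty,
    spectral_norm,
)

from conftest import random_instance


class TestGroupMeans:
    def test_columnwise_means_with_leading_one(self):
        data = jf.GroupedDataset(
            X=[np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([[5.0, -1.0], [0.0, 0.0]])],
            y=[np.array([0.0, 1.0]), np.array([1.0, 0.0])],
            labels=["a", "b"],
        )
        means = compute_group_means(data)
        np.testing.assert_array_equal(means.xbar[0][0], [1.0, 1.0, 2.0])
        np.testing.assert_array_equal(means.xbar[0][1], [1.0, 3.0, 4.0])
        np.testing.assert_array_equal(means.xbar[1][1], [1.0, 5.0, -1.0])

    def test_standard_normal_means_concentrate_under_null(self):
        # with null coefficients the outcome is independent of X, so the
        # class-conditional means of N(0,1) features concentrate at zero
        # (informative coefficients shift them along beta)
        data = random_instance(7, p=5, n=(400, 300), prevalence_beta_scale=0.0)
        means = compute_group_means(data)
        for k in range(2):
            for cls in (0, 1):
                m = len(data.class_indices(k, cls))
                assert np.all(np.abs(means.xbar[k][cls][1:]) < 3.0 / np.sqrt(m))


def _uniform_means(K, p, c=0.5):
    vec = np.concatenate(([1.0], np.full(p, c)))
    return GroupMeans(xbar=[{0: vec.copy(), 1: vec.copy()} for _ in range(K)])


class TestPenaltyOperator:
    def test_k2_p1_explicit_rows(self):
        means = _uniform_means(2, 1, c=0.7)
        hyper = jf.Hyperparameters(lambda_f=1.0, lambda_sim=1.0)
        op = build_penalty_operator(means, hyper)
        D = np.asarray(op.D)
        assert D.shape == (3, 4)
        np.testing.assert_allclose(D[0], [1.0, 0.7, -1.0, -0.7])
        np.testing.assert_allclose(D[1], [1.0, 0.7, -1.0, -0.7])
        np.testing.assert_allclose(D[2], [0.0, 1.0, 0.0, -1.0])

    def test_zero_lambdas_zero_operator(self):
        means = _uniform_means(2, 3)
        op = build_penalty_operator(means, jf.Hyperparameters())
        assert np.all(np.asarray(op.D) == 0)
        assert op.spectral_norm == 0.0
        assert op.nnz_rows == 0

    def test_k3_all_pairs_and_svd(self):
        data = random_instance(3, K=3, p=2, n=(30, 25, 20))
        means = compute_group_means(data)
        hyper = jf.Hyperparameters(lambda_f=0.8, lambda_sim=1.3)
        op = build_penalty_operator(means, hyper)
        # 3 pairs: 6 fairness rows + 3 pairs * 2 coords similarity rows
        assert op.M == 6 + 6
        kinds = [m[0] for m in op.row_meta]
        assert kinds.count("fairness") == 6
        assert kinds.count("similarity") == 6
        exact = np.linalg.svd(np.asarray(op.D), compute_uv=False)[0]
        assert abs(op.spectral_norm - exact) <= 1e-6 * exact

    def test_intercepts_absent_from_similarity_rows(self):
        data = random_instance(5, K=2, p=3)
        op = build_penalty_operator(compute_group_means(data), jf.Hyperparameters(lambda_sim=2.0))
        D = np.asarray(op.D)
        for i, meta in enumerate(op.row_meta):
            if meta[0] == "similarity":
                assert D[i, 0] == 0.0 and D[i, 4] == 0.0

    def test_requires_two_groups(self):
        means = _uniform_means(1, 2)
        with pytest.raises(ValueError):
            build_penalty_operator(means, jf.Hyperparameters())

    def test_shared_operator_shape(self):
        data = random_instance(9, K=3, p=4, n=(30, 25, 20))
        op = build_shared_penalty_operator(
            compute_group_means(data), jf.Hyperparameters(lambda_f=1.0)
        )
        assert np.asarray(op.D).shape == (6, 5)


class TestEvalPenalties:
    def test_identical_groups_zero(self):
        means = _uniform_means(2, 3)
        beta = jf.CoefficientSet(betas=[[1.0, 2.0, 3.0]] * 2, intercepts=[0.5, 0.5])
        p_f, p_sim, _ = eval_penalties(beta, means, jf.Hyperparameters(lambda_f=1, lambda_sim=1))
        assert p_f == pytest.approx(0.0)
        assert p_sim == pytest.approx(0.0)

    def test_hand_similarity_value(self):
        means = _uniform_means(2, 1)
        beta = jf.CoefficientSet(betas=[[1.0], [-1.0]], intercepts=[0.0, 0.0])
        _, p_sim, _ = eval_penalties(beta, means, jf.Hyperparameters(lambda_sim=2.0))
        assert p_sim == pytest.approx(4.0)

    def test_matches_operator_l1_norm(self):
        rng = np.random.default_rng(4)
        data = random_instance(4, K=3, p=4, n=(30, 25, 20))
        means = compute_group_means(data)
        hyper = jf.Hyperparameters(lambda_f=0.7, lambda_sim=1.1, lambda_sp=0.3)
        op = build_penalty_operator(means, hyper)
        for _ in range(5):
            beta = jf.CoefficientSet(
                betas=rng.standard_normal((3, 4)), intercepts=rng.standard_normal(3)
            )
            p_f, p_sim, _ = eval_penalties(beta, means, hyper)
            l1 = np.abs(op.matvec(beta.augmented())).sum()
            assert p_f + p_sim == pytest.approx(l1, abs=1e-10)

    def test_homogeneity_in_lambdas(self):
        data = random_instance(6, p=3)
        means = compute_group_means(data)
        beta = jf.CoefficientSet(betas=[[1.0, -2.0, 0.5], [0.0, 1.0, 2.0]], intercepts=[0.1, -0.2])
        h1 = jf.Hyperparameters(lambda_f=0.4, lambda_sim=0.9)
        h2 = jf.Hyperparameters(lambda_f=1.2, lambda_sim=2.7)
        p1 = sum(eval_penalties(beta, means, h1)[:2])
        p2 = sum(eval_penalties(beta, means, h2)[:2])
        assert p2 == pytest.approx(3.0 * p1, rel=1e-12)


class TestProjectLinf:
    def test_clips_componentwise(self):
        np.testing.assert_array_equal(
            project_linf(np.array([0.5, -2.0, 1.7])), [0.5, -1.0, 1.0]
        )

    def test_identity_inside_ball(self):
        x = np.array([0.3, -0.9, 1.0])
        np.testing.assert_array_equal(project_linf(x), x)

    def test_result_in_ball(self):
        rng = np.random.default_rng(0)
        x = 10 * rng.standard_normal(50)
        assert np.max(np.abs(project_linf(x))) <= 1.0


class TestSmoothing:
    def _setup(self, seed=2):
        data = random_instance(seed, p=4)
        means = compute_group_means(data)
        hyper = jf.Hyperparameters(lambda_f=0.6, lambda_sim=0.8)
        return build_penalty_operator(means, hyper)

    def test_zero_beta_zero_value(self):
        op = self._setup()
        val, alpha = smoothed_penalty(np.zeros(10), op, mu=0.5)
        assert val == 0.0
        assert np.all(alpha == 0)

    def test_single_row_hand_value(self):
        from jointfair.penalties import PenaltyOperator

        D = np.array([[3.0, 0.0]])
        op = PenaltyOperator(D=D, row_meta=[("similarity", (0, 1), 0)], spectral_norm=3.0,
                             K=2, p=0, n_blocks=2)
        val, alpha = smoothed_penalty(np.array([1.0, 0.0]), op, mu=1.0)
        assert alpha[0] == 1.0
        assert val == pytest.approx(2.5)

    def test_sandwich_bound(self):
        op = self._setup()
        rng = np.random.default_rng(8)
        for _ in range(200):
            beta = rng.standard_normal(10) * rng.uniform(0.1, 5)
            mu = 10 ** rng.uniform(-6, 1)
            exact = np.abs(op.matvec(beta)).sum()
            val, _ = smoothed_penalty(beta, op, mu)
            assert val <= exact + 1e-10
            assert exact - val <= mu * op.M / 2 + 1e-10

    def test_tiny_mu_tight(self):
        op = self._setup()
        rng = np.random.default_rng(3)
        beta = rng.standard_normal(10)
        mu = 1e-6
        exact = np.abs(op.matvec(beta)).sum()
        val, _ = smoothed_penalty(beta, op, mu)
        assert exact - val <= mu * op.M / 2 + 1e-12

    def test_convexity_on_random_triples(self):
        op = self._setup()
        rng = np.random.default_rng(5)
        for _ in range(50):
            b1, b2 = rng.standard_normal((2, 10))
            t = rng.uniform()
            mu = 0.3
            f = lambda b: smoothed_penalty(b, op, mu)[0]  # noqa: E731
            assert f(t * b1 + (1 - t) * b2) <= t * f(b1) + (1 - t) * f(b2) + 1e-10

    def test_gradient_matches_finite_differences(self):
        op = self._setup()
        rng = np.random.default_rng(11)
        mu = 0.2
        h = 1e-6
        for _ in range(20):
            beta = rng.standard_normal(10)
            g = smoothed_gradient(beta, op, mu)
            fd = np.empty_like(g)
            for i in range(beta.size):
                e = np.zeros_like(beta)
                e[i] = h
                fp, _ = smoothed_penalty(beta + e, op, mu)
                fm, _ = smoothed_penalty(beta - e, op, mu)
                fd[i] = (fp - fm) / (2 * h)
            np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-5)

    def test_gradient_lipschitz_bound(self):
        op = self._setup()
        rng = np.random.default_rng(13)
        mu = 0.15
        L = op.spectral_norm**2 / mu
        for _ in range(100):
            b1, b2 = rng.standard_normal((2, 10))
            g1 = smoothed_gradient(b1, op, mu)
            g2 = smoothed_gradient(b2, op, mu)
            assert np.linalg.norm(g1 - g2) <= L * np.linalg.norm(b1 - b2) * (1 + 1e-9)

    def test_nonpositive_mu_rejected(self):
        op = self._setup()
        with pytest.raises(ValueError):
            smoothed_penalty(np.zeros(10), op, mu=0.0)


def test_spectral_norm_matches_svd_on_random_matrices():
    rng = np.random.default_rng(21)
    for shape in [(3, 5), (8, 4), (10, 10)]:
        A = rng.standard_normal(shape)
        exact = np.linalg.svd(A, compute_uv=False)[0]
        assert spectral_norm(A) == pytest.approx(exact, rel=1e-6)


def test_sigmoid_difference_bounded_by_linear_difference():
    """Mean sigmoid gaps between groups are at most 1/4 of mean linear gaps.

    Monte-Carlo on random coefficient pairs with standard-normal features;
    three MC standard errors of slack on the quarter bound.
    """
    rng = np.random.default_rng(17)
    n_mc = 4000
    for _ in range(200):
        p = rng.integers(1, 6)
        bj = rng.standard_normal(p) * rng.uniform(0.2, 2)
        bk = rng.standard_normal(p) * rng.uniform(0.2, 2)
        Xj = rng.standard_normal((n_mc, p))
        Xk = rng.standard_normal((n_mc, p))
        lj, lk = Xj @ bj, Xk @ bk
        sj, sk = 1 / (1 + np.exp(-lj)), 1 / (1 + np.exp(-lk))
        lhs = abs(sj.mean() - sk.mean())
        rhs = 0.25 * abs(lj.mean() - lk.mean())
        se = np.sqrt(sj.var() / n_mc + sk.var() / n_mc) + 0.25 * np.sqrt(
            lj.var() / n_mc + lk.var() / n_mc
        )
        assert lhs <= rhs + 3 * se
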