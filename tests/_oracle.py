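"""Independent convex solver used as a test oracle.

Solves  min_b  loss(b) + ||D b||_1 + sum_j t_j |b_j|  by exact variable
splitting: each absolute value gets an epigraph auxiliary bounded below by
+/- its linear form, giving a smooth objective with linear inequality
constraints, handed to scipy's trust-region constrained solver.  This path
shares no code with the package's proximal-gradient implementation.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, minimize


def oracle_solve(loss_value, loss_grad, D, thresholds, x0, gtol=1e-10, maxiter=3000):
    """Return (b_opt, F_opt) for the composite nonsmooth convex problem."""
    D = np.asarray(D.toarray() if sp.issparse(D) else D, dtype=float)
    t = np.asarray(thresholds, dtype=float)
    q = x0.size
    M = D.shape[0]

    def obj(z):
        b, u, v = z[:q], z[q : q + M], z[q + M :]
        return loss_value(b) + u.sum() + t @ v

    def grad(z):
        b = z[:q]
        return np.concatenate([loss_grad(b), np.ones(M), t])

    Iq = np.eye(q)
    blocks = []
    if M:
        blocks.append(np.hstack([-D, np.eye(M), np.zeros((M, q))]))  # u - Db >= 0
        blocks.append(np.hstack([D, np.eye(M), np.zeros((M, q))]))  # u + Db >= 0
    blocks.append(np.hstack([-Iq, np.zeros((q, M)), Iq]))  # v - b >= 0
    blocks.append(np.hstack([Iq, np.zeros((q, M)), Iq]))  # v + b >= 0
    A = np.vstack(blocks)

    z0 = np.concatenate([x0, np.abs(D @ x0) + 1.0 if M else np.zeros(0), np.abs(x0) + 1.0])
    res = minimize(
        obj,
        z0,
        jac=grad,
        method="trust-constr",
        constraints=[LinearConstraint(A, 0.0, np.inf)],
        options={"gtol": gtol, "xtol": 1e-14, "maxiter": maxiter, "verbose": 0},
    )
    b = res.x[:q]
    F = loss_value(b) + np.abs(D @ b).sum() + t @ np.abs(b)
    return b, float(F)


def oracle_jfm(data, hyper, gtol=1e-10):
    """Exact-objective JFM solve on a small instance via oracle_solve."""
    from jointfair.optimizer import _augment, _sigmoid, _softplus
    from jointfair.penalties import build_penalty_operator, compute_group_means

    means = compute_group_means(data)
    op = build_penalty_operator(means, hyper)
    K, p = data.K, data.p
    q = (p + 1) * K
    Xaug = [_augment(Xk) for Xk in data.X]
    sp_per_group = hyper.sparsity_per_group(data.n_per_group)
    thr = np.zeros(q)
    for k in range(K):
        thr[k * (p + 1) + 1 : (k + 1) * (p + 1)] = sp_per_group[k]

    def loss_value(b):
        blocks = b.reshape(K, p + 1)
        return sum(
            float(np.mean(_softplus(Xa @ blk) - yk * (Xa @ blk)))
            for Xa, yk, blk in zip(Xaug, data.y, blocks)
        )

    def loss_grad(b):
        blocks = b.reshape(K, p + 1)
        out = np.empty((K, p + 1))
        for k in range(K):
            eta = Xaug[k] @ blocks[k]
            out[k] = Xaug[k].T @ ((_sigmoid(eta) - data.y[k]) / eta.shape[0])
        return out.reshape(-1)

    return oracle_solve(loss_value, loss_grad, op.D, thr, np.zeros(q), gtol=gtol)


def oracle_sfm(data, hyper, gtol=1e-10):
    """Exact-objective single-fairness-model solve via oracle_solve."""
    from jointfair.optimizer import _augment, _sigmoid, _softplus
    from jointfair.penalties import build_shared_penalty_operator, compute_group_means

    means = compute_group_means(data)
    op = build_shared_penalty_operator(means, hyper)
    p = data.p
    q = p + 1
    Xaug = [_augment(Xk) for Xk in data.X]

    def loss_value(b):
        return sum(
            float(np.sum(_softplus(Xa @ b) - yk * (Xa @ b))) for Xa, yk in zip(Xaug, data.y)
        )

    def loss_grad(b):
        g = np.zeros(q)
        for Xa, yk in zip(Xaug, data.y):
            g += Xa.T @ (_sigmoid(Xa @ b) - yk)
        return g

    lam = float(np.atleast_1d(np.asarray(hyper.lambda_sp, float))[0])
    thr = np.full(q, lam)
    thr[0] = 0.0
    return oracle_solve(loss_value, loss_grad, op.D, thr, np.zeros(q), gtol=gtol)
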