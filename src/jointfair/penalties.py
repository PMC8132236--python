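"""Fairness, similarity and sparsity penalties and their smooth surrogate.

The fairness penalty compares the class-conditional mean linear predictors
between every pair of groups (an equalized-odds surrogate): for each outcome
class y and pair j < k it charges ``lambda_f * |X̄_jyᵀβ̃_j − X̄_kyᵀβ̃_k|``,
where β̃ is the intercept-augmented coefficient block and X̄_ky the mean
feature vector of group k's class-y subjects (with a leading 1 matching the
intercept).  The similarity penalty is a generalized fused lasso
``lambda_sim * Σ_{j<k} ||β_j − β_k||₁`` on slopes only.  Both are absolute
values of linear forms, so their sum equals ``||D β̃||₁`` for a stacked
operator D; this module builds D, and provides the Nesterov smooth
approximation

    f_mu(β) = max{ αᵀDβ̃ − (mu/2)||α||₂² : ||α||_∞ ≤ 1 }

whose maximizer is the L∞-ball projection α* = S_∞(Dβ̃ / mu), together with
its gradient Dᵀα* (Lipschitz with constant ||D||₂² / mu).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.sparse as sp

from .data_model import CoefficientSet, GroupedDataset, Hyperparameters

__all__ = [
    "GroupMeans",
    "PenaltyOperator",
    "compute_group_means",
    "build_penalty_operator",
    "build_shared_penalty_operator",
    "eval_penalties",
    "project_linf",
    "smoothed_penalty",
    "smoothed_gradient",
    "spectral_norm",
]

_DENSE_ENTRY_LIMIT = 10**5


@dataclass
class GroupMeans:
    """Intercept-augmented class-conditional feature means X̄_ky.

    ``xbar[k][y]`` is the length-(p+1) mean of group k's class-y rows with a
    leading exact 1 for the intercept coordinate.
    """

    xbar: list  # K entries, each {0: vector, 1: vector}

    @property
    def K(self) -> int:
        return len(self.xbar)

    @property
    def p(self) -> int:
        return len(self.xbar[0][0]) - 1


def compute_group_means(data: GroupedDataset) -> GroupMeans:
    """Columnwise means of each group's class-0 and class-1 rows."""
    xbar = []
    for k in range(data.K):
        entry = {}
        for cls in (0, 1):
            idx = data.class_indices(k, cls)
            if idx.size == 0:
                raise ValueError(f"group {data.labels[k]} lacks outcome class {cls}")
            entry[cls] = np.concatenate(([1.0], data.X[k][idx].mean(axis=0)))
        xbar.append(entry)
    return GroupMeans(xbar=xbar)


def project_linf(x: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the unit L∞ ball: componentwise clip."""
    return np.clip(x, -1.0, 1.0)


def spectral_norm(D, seed: int = 0, tol: float = 1e-8, max_iter: int = 10**4) -> float:
    """Largest singular value of D by power iteration on DᵀD.

    Deterministic fixed-seed start vector; exact SVD is reserved for tests.
    """
    m, q = D.shape
    if m == 0 or q == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(q)
    nv = np.linalg.norm(v)
    if nv == 0:
        return 0.0
    v /= nv
    sigma = 0.0
    for _ in range(max_iter):
        w = D.T @ (D @ v)
        nw = np.linalg.norm(w)
        if nw == 0:
            return 0.0
        v_new = w / nw
        sigma_new = np.sqrt(nw)
        if abs(sigma_new - sigma) <= tol * max(sigma_new, 1.0):
            return float(sigma_new)
        sigma, v = sigma_new, v_new
    return float(sigma)


@dataclass
class PenaltyOperator:
    """The stacked, λ-scaled linear operator D with row metadata.

    Rows are, in order: fairness rows for outcome class 0 over all pairs
    j < k, fairness rows for class 1, then similarity rows (pair, coordinate).
    ``D`` acts on the intercept-augmented stacked coefficient vector of
    length ``(p+1)K`` (``p+1`` for the shared-coefficient variant).
    """

    D: object  # scipy sparse or dense ndarray
    row_meta: list
    spectral_norm: float
    K: int
    p: int
    n_blocks: int  # K for group-specific operators, 1 for the shared variant

    @property
    def M(self) -> int:
        return self.D.shape[0]

    @property
    def nnz_rows(self) -> int:
        """Rows with any nonzero entry; only these contribute smoothing gap."""
        if sp.issparse(self.D):
            return int(np.count_nonzero(np.diff(self.D.indptr)))
        return int(np.count_nonzero(np.abs(self.D).sum(axis=1)))

    def matvec(self, beta_aug: np.ndarray) -> np.ndarray:
        return np.asarray(self.D @ beta_aug).ravel()

    def rmatvec(self, alpha: np.ndarray) -> np.ndarray:
        return np.asarray(self.D.T @ alpha).ravel()


def _finalize_operator(rows, meta, K, p, n_blocks, q) -> PenaltyOperator:
    if not rows:
        D = np.zeros((0, q))
    else:
        dense = np.vstack(rows)
        # dense matvecs win at small sizes; sparse storage above the cutoff
        D = dense if dense.size <= _DENSE_ENTRY_LIMIT else sp.csr_matrix(dense)
    norm = spectral_norm(D)
    return PenaltyOperator(D=D, row_meta=meta, spectral_norm=norm, K=K, p=p, n_blocks=n_blocks)


def build_penalty_operator(means: GroupMeans, hyper: Hyperparameters) -> PenaltyOperator:
    """Stack λ_F·D₀, λ_F·D₁ and λ_Sim·F for group-specific coefficients.

    All pairs j < k are enumerated for both the fairness and the similarity
    rows, matching the penalty sums exactly (for K = 2 this coincides with a
    consecutive-pair chain).  Similarity rows are zero on every intercept
    coordinate; fairness rows include it through the leading 1 of X̄_ky.
    """
    K, p = means.K, means.p
    if K < 2:
        raise ValueError("penalty operator requires K >= 2 groups")
    q = (p + 1) * K
    rows, meta = [], []
    pairs = list(combinations(range(K), 2))
    for cls in (0, 1):
        for j, k in pairs:
            row = np.zeros(q)
            row[j * (p + 1) : (j + 1) * (p + 1)] = hyper.lambda_f * means.xbar[j][cls]
            row[k * (p + 1) : (k + 1) * (p + 1)] = -hyper.lambda_f * means.xbar[k][cls]
            rows.append(row)
            meta.append(("fairness", cls, (j, k)))
    for j, k in pairs:
        for l in range(p):
            row = np.zeros(q)
            row[j * (p + 1) + 1 + l] = hyper.lambda_sim
            row[k * (p + 1) + 1 + l] = -hyper.lambda_sim
            rows.append(row)
            meta.append(("similarity", (j, k), l))
    return _finalize_operator(rows, meta, K, p, K, q)


def build_shared_penalty_operator(means: GroupMeans, hyper: Hyperparameters) -> PenaltyOperator:
    """Fairness operator for a single shared coefficient vector.

    Used by the single fairness model: each row is
    λ_F·(X̄_jy − X̄_ky) acting on the one (p+1)-block; there is no
    similarity term because there is only one coefficient vector.
    """
    K, p = means.K, means.p
    if K < 2:
        raise ValueError("shared penalty operator requires K >= 2 groups")
    q = p + 1
    rows, meta = [], []
    for cls in (0, 1):
        for j, k in combinations(range(K), 2):
            rows.append(hyper.lambda_f * (means.xbar[j][cls] - means.xbar[k][cls]))
            meta.append(("fairness", cls, (j, k)))
    return _finalize_operator(rows, meta, K, p, 1, q)


def eval_penalties(
    beta: CoefficientSet, means: GroupMeans, hyper: Hyperparameters
) -> tuple[float, float, float]:
    """Exact (unsmoothed) fairness, similarity and sparsity penalty values.

    Returns (P_F, P_Sim, P_Sp) where P_Sp uses per-group weights resolved
    from ``hyper.lambda_sp`` taken verbatim if a sequence, or the scalar
    applied uniformly (no dataset present here to tie by sample size).
    """
    K = beta.K
    aug = np.column_stack([beta.intercepts, beta.betas])  # K x (p+1)
    p_f = 0.0
    p_sim = 0.0
    for j, k in combinations(range(K), 2):
        for cls in (0, 1):
            p_f += abs(means.xbar[j][cls] @ aug[j] - means.xbar[k][cls] @ aug[k])
        p_sim += np.abs(beta.betas[j] - beta.betas[k]).sum()
    sp_w = np.atleast_1d(np.asarray(hyper.lambda_sp, dtype=float))
    if sp_w.size == 1:
        sp_w = np.full(K, sp_w[0])
    p_sp = float(sum(w * np.abs(b).sum() for w, b in zip(sp_w, beta.betas)))
    return hyper.lambda_f * p_f, hyper.lambda_sim * p_sim, p_sp


def smoothed_penalty(beta_aug: np.ndarray, op: PenaltyOperator, mu: float):
    """Nesterov smooth surrogate of ||Dβ̃||₁ and its maximizing dual α*.

    ``f_mu(β) = α*ᵀDβ̃ − (mu/2)||α*||₂²`` with α* = S_∞(Dβ̃/mu).  Always
    underestimates ||Dβ̃||₁, by at most mu·M/2 (M = number of rows of D).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if op.M == 0:
        return 0.0, np.zeros(0)
    z = op.matvec(beta_aug)
    alpha = project_linf(z / mu)
    value = float(alpha @ z - 0.5 * mu * (alpha @ alpha))
    return value, alpha


def smoothed_gradient(beta_aug: np.ndarray, op: PenaltyOperator, mu: float) -> np.ndarray:
    """Gradient Dᵀα* of the smooth surrogate; Lipschitz constant ||D||₂²/mu."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if op.M == 0:
        return np.zeros_like(beta_aug)
    alpha = project_linf(op.matvec(beta_aug) / mu)
    return op.rmatvec(alpha)
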