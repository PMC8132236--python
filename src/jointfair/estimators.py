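"""The four estimators compared throughout the package.

jfm
    Group-specific sparse logistic regressions estimated jointly under the
    equalized-odds fairness penalty and the fused-lasso similarity penalty;
    the group log-likelihoods are weighted by 1/n_k so small groups are not
    drowned out.
sfm
    Single fairness model: one shared coefficient vector under the fairness
    penalty, with an unweighted pooled log-likelihood (a weighted variant is
    available as an ablation flag).
separate
    Independent per-group lasso logistic regressions.
ignorant
    One pooled lasso logistic regression with K−1 group-indicator columns
    (reference coding on the first group); the indicators are penalized like
    any other feature.

All four route through the same accelerated proximal gradient core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    CoefficientSet,
    FitResult,
    GroupedDataset,
    Hyperparameters,
    Standardizer,
)
from .optimizer import (
    SolverOptions,
    _augment,
    _sigmoid,
    _softplus,
    aspg_fit,
    choose_mu,
    run_aspg,
)
from .penalties import (
    build_shared_penalty_operator,
    compute_group_means,
    spectral_norm,
    PenaltyOperator,
)

__all__ = [
    "ModelSpec",
    "fit_jfm",
    "fit_sfm",
    "fit_separate",
    "fit_ignorant",
    "fit_model",
    "predict_proba",
    "result_to_json",
    "result_from_json",
]

KINDS = ("jfm", "sfm", "separate", "ignorant")


@dataclass
class ModelSpec:
    kind: str = "jfm"
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; expected one of {KINDS}")


def fit_jfm(data: GroupedDataset, spec: ModelSpec) -> FitResult:
    """Joint fairness model: delegates to the ASPG solver."""
    return aspg_fit(data, spec.hyper, spec.options)


def _empty_operator(q: int) -> PenaltyOperator:
    return PenaltyOperator(
        D=np.zeros((0, q)), row_meta=[], spectral_norm=0.0, K=1, p=q - 1, n_blocks=1
    )


def _scalar_sp(hyper: Hyperparameters) -> float:
    sp = np.atleast_1d(np.asarray(hyper.lambda_sp, dtype=float))
    if sp.size != 1:
        raise ValueError("this estimator takes a single scalar sparsity weight")
    return float(sp[0])


def fit_sfm(data: GroupedDataset, spec: ModelSpec, weight_by_group: bool = False) -> FitResult:
    """Single fairness model: one shared coefficient vector.

    Minimizes −Σ_k ℓ(β; X_k, y_k) + λ_F Σ_{j<k,y} |X̄_jyᵀβ̃ − X̄_kyᵀβ̃| +
    λ_Sp‖β‖₁.  The likelihood is an unweighted sum over groups;
    ``weight_by_group=True`` switches to the 1/n_k weighting used by the
    joint model, for ablation.
    """
    hyper, opts = spec.hyper, spec.options
    means = compute_group_means(data)
    op = build_shared_penalty_operator(means, hyper)
    mu = hyper.mu if hyper.mu is not None else choose_mu(opts.delta, op)

    Xaug = [_augment(Xk) for Xk in data.X]
    weights = [1.0 / Xk.shape[0] if weight_by_group else 1.0 for Xk in data.X]
    p = data.p
    q = p + 1

    def loss_value(b):
        return sum(
            w * float(np.sum(_softplus(Xa @ b) - yk * (Xa @ b)))
            for w, Xa, yk in zip(weights, Xaug, data.y)
        )

    def loss_gradient(b):
        g = np.zeros(q)
        for w, Xa, yk in zip(weights, Xaug, data.y):
            g += w * (Xa.T @ (_sigmoid(Xa @ b) - yk))
        return g

    L_loss = sum(w * spectral_norm(Xa) ** 2 / 4.0 for w, Xa in zip(weights, Xaug))

    lam_sp = _scalar_sp(hyper)
    thr = np.full(q, lam_sp)
    thr[0] = 0.0

    prev = np.clip(np.concatenate(data.y).mean(), 1e-3, 1 - 1e-3)
    b0 = np.zeros(q)
    b0[0] = np.log(prev / (1 - prev))

    beta_aug, trace, converged, iters = run_aspg(
        loss_value, loss_gradient, L_loss, op, mu, thr, b0, opts
    )
    coef = CoefficientSet.from_augmented(beta_aug, 1)
    # exact objective: swap the smoothed fairness term for the true L1 form
    fair = float(np.abs(np.asarray(op.D @ beta_aug)).sum()) if op.M else 0.0
    final = loss_value(beta_aug) + fair + lam_sp * float(np.abs(coef.betas[0]).sum())
    return FitResult(
        coefficients=coef,
        objective_trace=trace,
        converged=converged,
        iterations=iters,
        final_objective=final,
        kind="sfm",
        labels=list(data.labels),
        feature_names=list(data.feature_names),
        standardizer=data.standardizer,
        hyper=hyper,
    )


def _lasso_logistic(X, y, lam, opts):
    """Mean-loss lasso logistic via the shared proximal-gradient core."""
    Xa = _augment(X)
    n, q = Xa.shape

    def loss_value(b):
        eta = Xa @ b
        return float(np.mean(_softplus(eta) - y * eta))

    def loss_gradient(b):
        eta = Xa @ b
        return Xa.T @ ((_sigmoid(eta) - y) / n)

    L_loss = spectral_norm(Xa) ** 2 / (4.0 * n)
    thr = np.full(q, lam)
    thr[0] = 0.0
    prev = np.clip(y.mean(), 1e-3, 1 - 1e-3)
    b0 = np.zeros(q)
    b0[0] = np.log(prev / (1 - prev))
    return run_aspg(loss_value, loss_gradient, L_loss, _empty_operator(q), 1.0, thr, b0, opts)


def fit_separate(data: GroupedDataset, spec: ModelSpec) -> FitResult:
    """Independent per-group lasso logistic regressions."""
    opts = spec.options
    sp_per_group = spec.hyper.sparsity_per_group(data.n_per_group)
    betas, intercepts, traces = [], [], []
    converged_all, iters_total, final = True, 0, 0.0
    for k in range(data.K):
        b, trace, conv, iters = _lasso_logistic(data.X[k], data.y[k], sp_per_group[k], opts)
        intercepts.append(b[0])
        betas.append(b[1:])
        traces.append(trace)
        converged_all &= conv
        iters_total += iters
        eta = data.X[k] @ b[1:] + b[0]
        final += float(np.mean(_softplus(eta) - data.y[k] * eta)) + sp_per_group[k] * float(
            np.abs(b[1:]).sum()
        )
    # traces are per-group; concatenate for diagnostics, keep count honest
    trace = [sum(t[min(i, len(t) - 1)] for t in traces) for i in range(max(map(len, traces)))]
    return FitResult(
        coefficients=CoefficientSet(betas=np.vstack(betas), intercepts=np.asarray(intercepts)),
        objective_trace=trace,
        converged=converged_all,
        iterations=len(trace) - 1,
        final_objective=final,
        kind="separate",
        labels=list(data.labels),
        feature_names=list(data.feature_names),
        standardizer=data.standardizer,
        hyper=spec.hyper,
    )


def _indicator_matrix(n_per_group: list) -> np.ndarray:
    """Reference-coded group indicators for pooled rows (first group = 0s)."""
    K = len(n_per_group)
    blocks = []
    for k, nk in enumerate(n_per_group):
        Z = np.zeros((nk, K - 1))
        if k > 0:
            Z[:, k - 1] = 1.0
        blocks.append(Z)
    return np.vstack(blocks)


def fit_ignorant(data: GroupedDataset, spec: ModelSpec) -> FitResult:
    """Pooled lasso logistic with penalized group-indicator covariates."""
    X_pool = np.vstack(data.X)
    y_pool = np.concatenate(data.y)
    Z = _indicator_matrix(data.n_per_group)
    X_full = np.hstack([X_pool, Z])
    lam = _scalar_sp(spec.hyper)
    b, trace, conv, iters = _lasso_logistic(X_full, y_pool, lam, spec.options)
    coef = CoefficientSet(betas=b[1:][None, :], intercepts=[b[0]])
    eta = X_full @ b[1:] + b[0]
    final = float(np.mean(_softplus(eta) - y_pool * eta)) + lam * float(np.abs(b[1:]).sum())
    ind_names = [f"group[{lab}]" for lab in data.labels[1:]]
    return FitResult(
        coefficients=coef,
        objective_trace=trace,
        converged=conv,
        iterations=iters,
        final_objective=final,
        kind="ignorant",
        labels=list(data.labels),
        feature_names=list(data.feature_names) + ind_names,
        standardizer=data.standardizer,
        hyper=spec.hyper,
    )


_FITTERS = {"jfm": fit_jfm, "sfm": fit_sfm, "separate": fit_separate, "ignorant": fit_ignorant}


def fit_model(data: GroupedDataset, spec: ModelSpec) -> FitResult:
    """Dispatch to the estimator named by ``spec.kind``."""
    return _FITTERS[spec.kind](data, spec)


def predict_proba(fit: FitResult, X: np.ndarray, groups, standardize: bool = True) -> np.ndarray:
    """Predicted event probabilities σ(intercept + xβ) for new rows.

    ``groups`` gives each row's group label; group-specific models use the
    matching coefficient block, the shared models use their single block
    (the group-ignorant model additionally activates the row's indicator).
    Stored standardization statistics are applied to the features unless
    ``standardize=False`` (for rows already on the training scale).
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray([str(g) for g in np.atleast_1d(groups)])
    if groups.size == 1 and X.shape[0] > 1:
        groups = np.repeat(groups, X.shape[0])
    unknown = set(groups) - set(fit.labels)
    if unknown:
        raise ValueError(f"unseen group label(s): {sorted(unknown)}")
    if standardize and fit.standardizer is not None:
        X = fit.standardizer.transform(X)

    if fit.kind in ("jfm", "separate"):
        idx = np.array([fit.labels.index(g) for g in groups])
        eta = np.einsum("ij,ij->i", X, fit.coefficients.betas[idx]) + fit.coefficients.intercepts[
            idx
        ]
    elif fit.kind == "sfm":
        eta = X @ fit.coefficients.betas[0] + fit.coefficients.intercepts[0]
    else:  # ignorant: append reference-coded indicators
        K = len(fit.labels)
        Z = np.zeros((X.shape[0], K - 1))
        for j, lab in enumerate(fit.labels[1:]):
            Z[groups == lab, j] = 1.0
        eta = np.hstack([X, Z]) @ fit.coefficients.betas[0] + fit.coefficients.intercepts[0]
    return _sigmoid(eta)


def result_to_json(fit: FitResult) -> str:
    """Serialize a fitted model (coefficients, labels, scaling, diagnostics)."""
    doc = {
        "kind": fit.kind,
        "labels": fit.labels,
        "feature_names": fit.feature_names,
        "intercepts": fit.coefficients.intercepts.tolist(),
        "betas": fit.coefficients.betas.tolist(),
        "converged": bool(fit.converged),
        "iterations": int(fit.iterations),
        "final_objective": float(fit.final_objective),
        "standardizer": fit.standardizer.to_dict() if fit.standardizer else None,
        "hyper": None
        if fit.hyper is None
        else {
            "lambda_f": fit.hyper.lambda_f,
            "lambda_sim": fit.hyper.lambda_sim,
            "lambda_sp": np.atleast_1d(np.asarray(fit.hyper.lambda_sp, float)).tolist(),
            "mu": fit.hyper.mu,
            "delta": fit.hyper.delta,
        },
    }
    return json.dumps(doc, sort_keys=True, indent=1)


def result_from_json(text: str) -> FitResult:
    doc = json.loads(text)
    hyper = None
    if doc["hyper"] is not None:
        h = doc["hyper"]
        hyper = Hyperparameters(
            lambda_f=h["lambda_f"],
            lambda_sim=h["lambda_sim"],
            lambda_sp=tuple(h["lambda_sp"]),
            mu=h["mu"],
            delta=h["delta"],
        )
    return FitResult(
        coefficients=CoefficientSet(betas=doc["betas"], intercepts=doc["intercepts"]),
        objective_trace=[doc["final_objective"]],
        converged=doc["converged"],
        iterations=0,
        kind=doc["kind"],
        final_objective=doc["final_objective"],
        labels=doc["labels"],
        feature_names=doc["feature_names"],
        standardizer=Standardizer.from_dict(doc["standardizer"]) if doc["standardizer"] else None,
        hyper=hyper,
    )
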