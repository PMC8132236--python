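"""Synthetic two-group benchmark scenarios and the replicate experiment runner.

The generators emulate the benchmark design used throughout the package's
evaluation: standard-normal features, Bernoulli outcomes from group-specific
logistic models, 40% of coefficients non-zero with value 3, a controllable
fraction of the non-zero support shared between the two groups, intercepts
calibrated so each group hits its target baseline event prevalence, and
unbalanced sample sizes (an over-represented group 1 and an under-represented
group 2).

Three scenario presets:

1. ``scenario_1`` — varies the proportion of shared non-zero coefficients
   (0%–100%) at n = (500, 200), p = 100, prevalences (50%, 30%).
2. ``scenario_2`` — varies the under-represented group's sample size
   (50–300) at 50% sharing, n₁ = 500, p = 100.
3. ``scenario_3`` — varies dimensionality p (50–2000) with either a fixed
   40-coordinate support or one proportional to p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_model import CoefficientSet, GroupedDataset
from .estimators import ModelSpec, fit_model, predict_proba
from .metrics import auc, brier, coef_mse, confusion_rates, disparity, selection_rates
from .model_selection import CVConfig, cv_select

__all__ = [
    "ScenarioSpec",
    "scenario_1",
    "scenario_2",
    "scenario_3",
    "make_coefficients",
    "calibrate_intercept",
    "generate_dataset",
    "run_experiment",
]

logger = logging.getLogger(__name__)

_CALIBRATION_DRAWS = 200_000


@dataclass
class ScenarioSpec:
    scenario: int = 1
    p: int = 100
    n: tuple = (500, 200)  # (over-represented, under-represented)
    n_nonzero: int = 40
    shared_fraction: float = 0.5
    coef_value: float = 3.0
    prevalences: tuple = (0.5, 0.3)  # group 1 then group 2
    test_n: int = 1000
    replicates: int = 20
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.n_nonzero > self.p:
            raise ValueError("n_nonzero cannot exceed p")
        if not all(0.0 < q < 1.0 for q in self.prevalences):
            raise ValueError("prevalences must lie in (0, 1)")
        if len(self.n) != 2 or len(self.prevalences) != 2:
            raise ValueError("scenario presets are two-group designs")


def scenario_1(shared_fraction: float = 1.0, **overrides) -> ScenarioSpec:
    """Difference in true model: sweep the shared-support fraction."""
    return replace(ScenarioSpec(scenario=1, shared_fraction=shared_fraction), **overrides)


def scenario_2(n_under: int = 50, **overrides) -> ScenarioSpec:
    """Difference in sample size: sweep the under-represented group's n."""
    return replace(ScenarioSpec(scenario=2, n=(500, n_under)), **overrides)


def scenario_3(p: int = 200, proportional: bool = False, **overrides) -> ScenarioSpec:
    """High dimensionality: sweep p with fixed (40) or proportional support."""
    n_nonzero = max(1, int(round(0.4 * p))) if proportional else 40
    return replace(ScenarioSpec(scenario=3, p=p, n_nonzero=n_nonzero), **overrides)


def make_coefficients(spec: ScenarioSpec) -> tuple[CoefficientSet, list]:
    """True slope vectors for the two groups.

    Group 1's support is the first ``n_nonzero`` coordinates; group 2 shares
    ``round(shared_fraction · n_nonzero)`` of them and takes fresh
    coordinates for the rest.  All non-zero values equal ``coef_value``.
    Support placement is deterministic: with exchangeable standard-normal
    features it is statistically equivalent to random placement but keeps
    truth metadata stable across replicates.  Intercepts are zero here;
    calibration fills them in.
    """
    m = spec.n_nonzero
    shared = int(round(spec.shared_fraction * m))
    fresh = m - shared
    if m + fresh > spec.p:
        raise ValueError(
            f"p={spec.p} too small for {m} non-zeros with {fresh} group-specific coordinates"
        )
    support1 = list(range(m))
    support2 = list(range(shared)) + list(range(m, m + fresh))
    betas = np.zeros((2, spec.p))
    betas[0, support1] = spec.coef_value
    betas[1, support2] = spec.coef_value
    return CoefficientSet(betas=betas, intercepts=np.zeros(2)), [support1, support2]


def calibrate_intercept(beta_k: np.ndarray, target_prev: float, seed: int = 0) -> float:
    """Intercept b with E_X[σ(b + Xβ)] = target under standard-normal X.

    With X ~ N(0, I), the linear term Xβ is N(0, ‖β‖₂²); the expectation is
    continuous and strictly increasing in b from 0 to 1, so bisection on a
    fixed Monte-Carlo sample always brackets.  ``β = 0`` returns the exact
    logit of the target.
    """
    if not 0.0 < target_prev < 1.0:
        raise ValueError("target prevalence must lie in (0, 1)")
    norm = float(np.linalg.norm(beta_k))
    if norm == 0.0:
        return float(np.log(target_prev / (1 - target_prev)))
    rng = np.random.default_rng(seed)
    eta0 = norm * rng.standard_normal(_CALIBRATION_DRAWS)

    def gap(b):
        return np.mean(1.0 / (1.0 + np.exp(-(b + eta0)))) - target_prev

    lo, hi = -60.0, 60.0
    return float(brentq(gap, lo, hi, xtol=1e-10))


def _simulate_group(rng, n, p, beta, intercept):
    X = rng.standard_normal((n, p))
    prob = 1.0 / (1.0 + np.exp(-(intercept + X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    return X, y


def generate_dataset(
    spec: ScenarioSpec, replicate_seed: int
) -> tuple[GroupedDataset, GroupedDataset, CoefficientSet]:
    """One train/test replicate: (train, test, truth).

    Features are iid N(0,1); outcomes Bernoulli(σ(b_k + Xβ_k)) with b_k
    calibrated to the group's target prevalence.  If a generated group
    misses an outcome class the draw is retried once, then an error is
    raised (vanishingly rare at the preset sizes).
    """
    truth, _ = make_coefficients(spec)
    intercepts = np.array(
        [
            calibrate_intercept(truth.betas[k], spec.prevalences[k], seed=spec.seed)
            for k in range(2)
        ]
    )
    truth = CoefficientSet(betas=truth.betas, intercepts=intercepts)
    rng = np.random.default_rng(replicate_seed)
    labels = ["group1", "group2"]

    def draw(sizes):
        for _attempt in range(2):
            Xs, ys = [], []
            for k, nk in enumerate(sizes):
                Xk, yk = _simulate_group(rng, nk, spec.p, truth.betas[k], intercepts[k])
                Xs.append(Xk)
                ys.append(yk)
            if all(np.any(yk == 0) and np.any(yk == 1) for yk in ys):
                return GroupedDataset(X=Xs, y=ys, labels=labels)
        raise RuntimeError("a simulated group repeatedly missed an outcome class")

    train = draw(spec.n)
    test = draw((spec.test_n, spec.test_n))
    return train, test, truth


def _evaluate(fit, test: GroupedDataset, truth: CoefficientSet) -> list:
    """Per-group metric rows for one fitted model on the test set."""
    rows = []
    group_aucs = []
    for k, lab in enumerate(test.labels):
        probs = predict_proba(fit, test.X[k], [lab] * len(test.y[k]), standardize=False)
        group_aucs.append(auc(probs, test.y[k]))
    # shared-coefficient models are scored against each group's truth
    if fit.coefficients.K == len(test.labels):
        est = fit.coefficients
    else:
        shared = fit.coefficients.betas[0][: truth.p]
        est = CoefficientSet(
            betas=np.vstack([shared] * len(test.labels)),
            intercepts=np.repeat(fit.coefficients.intercepts[0], len(test.labels)),
        )
    mses = coef_mse(est, truth)
    sel = selection_rates(est, truth)
    auc_disp = disparity(group_aucs)
    for k, lab in enumerate(test.labels):
        probs = predict_proba(fit, test.X[k], [lab] * len(test.y[k]), standardize=False)
        fpr, fnr, tpr, tnr, bal = confusion_rates(probs, test.y[k])
        rows.append(
            {
                "group": lab,
                "auc": group_aucs[k],
                "auc_disparity": auc_disp,
                "fpr": fpr,
                "fnr": fnr,
                "balanced_accuracy": bal,
                "brier": brier(probs, test.y[k]),
                "coef_mse": float(mses[k]),
                "sel_tpr": float(sel[k, 0]),
                "sel_tnr": float(sel[k, 1]),
            }
        )
    return rows


# per-estimator CV criteria: fairness-aware models use the group-robust
# harmonic AUC; vanilla comparators tune their single lasso penalty by AUC
_DEFAULT_CRITERIA = {
    "jfm": "group-harmonic-AUC",
    "sfm": "group-harmonic-AUC",
    "separate": "group-arithmetic-AUC",
    "ignorant": "overall-AUC",
}


def run_experiment(
    spec: ScenarioSpec,
    estimators: tuple = ("jfm", "sfm", "separate", "ignorant"),
    cvconfig: CVConfig | None = None,
    criteria_by_kind: dict | None = None,
    final_options=None,
    grids_by_kind: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate experiment: generate → CV-select → fit → evaluate.

    Returns ``(tidy, summary)``: one tidy row per estimator × group ×
    replicate, and a median/IQR summary per estimator × group.  Failed
    replicates are excluded from aggregation and counted in the log.
    ``final_options`` lets the full-training refit run tighter solver
    settings than the fold fits (default: same as CV); ``grids_by_kind``
    overrides the CV grids per estimator (the comparators' sparsity weights
    live on different scales than the joint model's tied-by-sqrt(n) ones).
    """
    cvconfig = cvconfig or CVConfig()
    final_options = final_options or cvconfig.options
    grids_by_kind = grids_by_kind or {}
    criteria = dict(_DEFAULT_CRITERIA, **(criteria_by_kind or {}))
    records = []
    failures = 0
    for r in range(spec.replicates):
        rep_seed = (spec.seed + 1000003 * (r + 1)) % (2**31)
        try:
            train, test, truth = generate_dataset(spec, rep_seed)
            for kind in estimators:
                cfg = replace(
                    cvconfig,
                    criterion=criteria[kind],
                    seed=rep_seed % (2**31),
                    grids=grids_by_kind.get(kind, cvconfig.grids),
                )
                best, _table = cv_select(train, kind, cfg)
                fit = fit_model(train, ModelSpec(kind=kind, hyper=best, options=final_options))
                for row in _evaluate(fit, test, truth):
                    records.append({"replicate": r, "estimator": kind, **row})
        except Exception as exc:  # noqa: BLE001 — replicate isolation
            failures += 1
            logger.warning("replicate %d failed: %s", r, exc)
    if failures:
        logger.warning("%d/%d replicates failed and were excluded", failures, spec.replicates)
    tidy = pd.DataFrame(records)
    if tidy.empty:
        raise RuntimeError("all replicates failed")
    metric_cols = [
        c for c in tidy.columns if c not in ("replicate", "estimator", "group")
    ]
    grouped = tidy.groupby(["estimator", "group"])[metric_cols]
    summary = grouped.median().add_suffix("_median").join(
        (grouped.quantile(0.75) - grouped.quantile(0.25)).add_suffix("_iqr")
    ).reset_index()
    return tidy, summary
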