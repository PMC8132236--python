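"""Cross-validated hyperparameter selection.

Folds are stratified jointly on group and outcome class so that every
training split keeps both classes in every group (a requirement of the
fairness penalty) and held-out AUCs are defined per group.  The default
selection criterion is the harmonic mean of groupwise held-out AUCs, which
is robust when group sample sizes are unbalanced; alternatives include the
arithmetic group mean, the overall AUC, the (negated) harmonic mean of
groupwise Brier scores, and group-mean AUC minus its disparity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .data_model import GroupedDataset, Hyperparameters
from .estimators import ModelSpec, fit_model, predict_proba
from .metrics import auc, brier, disparity, harmonic_mean
from .optimizer import SolverOptions

__all__ = ["CVConfig", "stratified_group_folds", "cv_select", "default_grid"]

logger = logging.getLogger(__name__)

CRITERIA = (
    "group-harmonic-AUC",
    "group-arithmetic-AUC",
    "overall-AUC",
    "group-harmonic-Brier",
    "AUC-minus-disparity",
)


def default_grid() -> list:
    """{0} ∪ 7-point log grid from 1e-3 to 10."""
    return [0.0] + list(np.logspace(-3, 1, 7))


@dataclass
class CVConfig:
    folds: int = 5
    grids: dict = field(default_factory=dict)  # keys among lambda_f/lambda_sim/lambda_sp
    criterion: str = "group-harmonic-AUC"
    seed: int = 0
    options: SolverOptions = field(default_factory=SolverOptions)
    # score pooled out-of-fold predictions rather than averaging per-fold
    # scores: one AUC per group from all held-out rows is far less noisy
    # when the under-represented group leaves only a handful of rows per fold
    pool_folds: bool = True

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("need at least 2 folds")
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        for key, vals in self.grids.items():
            if len(vals) == 0:
                raise ValueError(f"empty grid for {key}")


# hyperparameters each estimator actually tunes
_ACTIVE = {
    "jfm": ("lambda_f", "lambda_sim", "lambda_sp"),
    "sfm": ("lambda_f", "lambda_sp"),
    "separate": ("lambda_sp",),
    "ignorant": ("lambda_sp",),
}


def stratified_group_folds(data: GroupedDataset, folds: int, seed: int) -> list:
    """Per-group fold-id arrays, stratified on outcome within each group.

    If some group×class cell has fewer members than ``folds`` the fold count
    is reduced (with a warning) so every fold still sees both classes of
    every group.  Deterministic given ``seed``.
    """
    min_cell = min(
        int((data.y[k] == cls).sum()) for k in range(data.K) for cls in (0, 1)
    )
    if min_cell == 0:
        raise ValueError("a group lacks an outcome class")
    eff_folds = folds
    if min_cell < folds:
        eff_folds = min_cell
        warnings.warn(
            f"reducing folds from {folds} to {eff_folds}: smallest group×class cell"
        )
    rng = np.random.default_rng(seed)
    assignment = []
    for k in range(data.K):
        fold_id = np.empty(data.X[k].shape[0], dtype=int)
        for cls in (0, 1):
            idx = np.flatnonzero(data.y[k] == cls)
            idx = rng.permutation(idx)
            fold_id[idx] = np.arange(idx.size) % eff_folds
        assignment.append(fold_id)
    return assignment


def _criterion_score(criterion: str, group_scores: dict) -> float:
    """Score one fold from per-group (probabilities, outcomes)."""
    aucs = {g: auc(s, y) for g, (s, y) in group_scores.items()}
    if criterion == "group-harmonic-AUC":
        return harmonic_mean(list(aucs.values()))
    if criterion == "group-arithmetic-AUC":
        return float(np.mean(list(aucs.values())))
    if criterion == "overall-AUC":
        s = np.concatenate([v[0] for v in group_scores.values()])
        y = np.concatenate([v[1] for v in group_scores.values()])
        return auc(s, y)
    if criterion == "group-harmonic-Brier":
        briers = [brier(s, y) for s, y in group_scores.values()]
        return -harmonic_mean(briers)
    if criterion == "AUC-minus-disparity":
        vals = list(aucs.values())
        return float(np.mean(vals)) - disparity(vals)
    raise ValueError(criterion)


def cv_select(data: GroupedDataset, kind: str, config: CVConfig):
    """Grid-search hyperparameters by K-fold cross-validation.

    Returns ``(best, table)``: the winning :class:`Hyperparameters` and a
    score table with one row per grid point.  By default each grid point is
    scored once from its pooled out-of-fold predictions per group; with
    ``pool_folds=False`` per-fold scores are averaged instead.  Ties break
    toward the smallest lambda_f, then lambda_sim, then lambda_sp.  Grid
    points whose fits all fail score −inf.
    """
    active = _ACTIVE[kind]
    grids = {key: sorted(config.grids.get(key, default_grid())) for key in active}
    assignment = stratified_group_folds(data, config.folds, config.seed)
    eff_folds = max(int(a.max()) for a in assignment) + 1

    # grid enumerated in ascending (lambda_f, lambda_sim, lambda_sp) order so
    # the first strict maximum realizes the tie-break rule
    keys = list(grids)
    points = [dict(zip(keys, vals)) for vals in product(*(grids[k] for k in keys))]
    points.sort(key=lambda d: tuple(d.get(k, 0.0) for k in ("lambda_f", "lambda_sim", "lambda_sp")))

    rows = []
    best_score, best_point = -np.inf, None
    for point in points:
        hyper = Hyperparameters(**point, delta=config.options.delta)
        fold_scores = []
        oof = {lab: ([], []) for lab in data.labels}
        ok_folds = 0
        for f in range(eff_folds):
            train_idx = [np.flatnonzero(a != f) for a in assignment]
            test_idx = [np.flatnonzero(a == f) for a in assignment]
            try:
                fit = fit_model(
                    data.subset(train_idx), ModelSpec(kind=kind, hyper=hyper, options=config.options)
                )
                group_scores = {}
                for k, lab in enumerate(data.labels):
                    Xte = data.X[k][test_idx[k]]
                    yte = data.y[k][test_idx[k]]
                    probs = predict_proba(fit, Xte, [lab] * len(yte), standardize=False)
                    group_scores[lab] = (probs, yte)
                    oof[lab][0].append(probs)
                    oof[lab][1].append(yte)
                fold_scores.append(_criterion_score(config.criterion, group_scores))
                ok_folds += 1
            except (ValueError, FloatingPointError) as exc:  # pragma: no cover
                logger.warning("fold %d failed at %s: %s", f, point, exc)
        if not fold_scores:
            score = -np.inf
            logger.warning("all folds failed at grid point %s; scored -inf", point)
        elif config.pool_folds:
            pooled = {
                lab: (np.concatenate(s), np.concatenate(y)) for lab, (s, y) in oof.items()
            }
            score = _criterion_score(config.criterion, pooled)
        else:
            score = float(np.mean(fold_scores))
        rows.append({**{k: point.get(k, 0.0) for k in active}, "score": score,
                     "n_folds": ok_folds})
        if score > best_score:
            best_score, best_point = score, point
    table = pd.DataFrame(rows)
    if best_point is None:
        raise RuntimeError("every grid point failed")
    return Hyperparameters(**best_point, delta=config.options.delta), table
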