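"""Evaluation metrics: discrimination, fairness disparity, estimation and
variable-selection performance."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .data_model import CoefficientSet

__all__ = [
    "auc",
    "confusion_rates",
    "disparity",
    "coef_mse",
    "selection_rates",
    "brier",
    "harmonic_mean",
]


def auc(scores, y) -> float:
    """Mann–Whitney AUC: P(score⁺ > score⁻) + ½·P(tie), via midranks."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: only one outcome class present")
    ranks = rankdata(scores)  # midranks give half credit to ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_rates(scores, y, cutoff: float = 0.5):
    """FPR, FNR, TPR, TNR and balanced accuracy at a probability cutoff.

    Predictions are ŷ = 1 iff score ≥ cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    yhat = (scores >= cutoff).astype(float)
    n_pos = (y == 1).sum()
    n_neg = (y == 0).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("confusion rates undefined: only one outcome class present")
    fpr = float(((yhat == 1) & (y == 0)).sum() / n_neg)
    fnr = float(((yhat == 0) & (y == 1)).sum() / n_pos)
    tpr, tnr = 1.0 - fnr, 1.0 - fpr
    return fpr, fnr, tpr, tnr, 0.5 * (tpr + tnr)


def disparity(values) -> float:
    """Between-group spread of a metric: |v₁−v₂| for two groups, max−min otherwise."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("disparity needs at least two groups")
    return float(values.max() - values.min())


def coef_mse(est: CoefficientSet, truth: CoefficientSet) -> np.ndarray:
    """Per-group mean squared coefficient error (1/p)‖β̂_k − β_k‖₂², slopes only."""
    if est.betas.shape != truth.betas.shape:
        raise ValueError("coefficient shapes disagree")
    return ((est.betas - truth.betas) ** 2).mean(axis=1)


def selection_rates(est: CoefficientSet, truth: CoefficientSet, zero_tol: float = 1e-8):
    """Per-group support-recovery (TPR, TNR).

    TPR: fraction of truly non-zero coordinates with |β̂| > zero_tol;
    TNR: fraction of truly zero coordinates with |β̂| ≤ zero_tol.
    Returns an array of shape (K, 2); a group with no true positives (or no
    true zeros) reports NaN for the undefined rate.
    """
    out = np.full((est.K, 2), np.nan)
    for k in range(est.K):
        true_nz = np.abs(truth.betas[k]) > zero_tol
        est_nz = np.abs(est.betas[k]) > zero_tol
        if true_nz.any():
            out[k, 0] = float(est_nz[true_nz].mean())
        if (~true_nz).any():
            out[k, 1] = float((~est_nz[~true_nz]).mean())
    return out


def brier(scores, y) -> float:
    """Mean squared difference between predicted probability and outcome.

    Normalized by n so that folds of unequal size are comparable; the
    un-normalized sum differs only by a constant factor per fold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean((scores - y) ** 2))


def harmonic_mean(values) -> float:
    """Harmonic mean K / Σ(1/v_k); ≤ arithmetic mean, equal iff all equal."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("harmonic mean requires positive values")
    return float(values.size / np.sum(1.0 / values))
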