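"""Core data containers for grouped binary-outcome regression.

The joint fairness model operates on ``K >= 2`` groups of observations that
share one feature space: group ``k`` contributes an ``n_k x p`` feature matrix
``X_k`` and a binary outcome vector ``y_k``.  Both outcome classes must be
present in every group, because the equalized-odds fairness penalty is built
from the class-conditional feature means ``X̄_ky`` and is undefined when a
group lacks a class.

Intercepts are handled specially throughout the package: they are estimated
but never penalized by the sparsity or similarity penalties, while they *do*
enter each group's linear predictor and therefore the fairness penalty.
Internally this is realised by augmenting ``X`` with a leading constant-1
column; :class:`CoefficientSet` keeps intercepts separate from the slope
vectors in its public API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupedDataset",
    "CoefficientSet",
    "Hyperparameters",
    "FitResult",
    "Standardizer",
    "validate_dataset",
    "read_csv_dataset",
]


@dataclass
class Standardizer:
    """Per-feature zero-mean unit-variance transform with stored statistics."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)  # constant columns pass through
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        return cls(mean=np.asarray(d["mean"], float), scale=np.asarray(d["scale"], float))


@dataclass
class GroupedDataset:
    """K groups of (features, binary outcomes) sharing one feature space.

    Attributes
    ----------
    X : list of ndarray
        Per-group feature matrices, each ``n_k x p``.
    y : list of ndarray
        Per-group binary outcome vectors (values in {0, 1}).
    labels : list of str
        Group labels in first-appearance order; all pairwise penalties use
        this fixed order.
    feature_names : list of str
    standardizer : Standardizer or None
        Present when features were standardized; reused at prediction time.
    """

    X: list
    y: list
    labels: list
    feature_names: list = field(default_factory=list)
    standardizer: Standardizer | None = None

    def __post_init__(self):
        self.X = [np.asarray(Xk, dtype=float) for Xk in self.X]
        self.y = [np.asarray(yk, dtype=float) for yk in self.y]
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(self.p)]
        self._validate()

    def _validate(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.labels):
            raise ValueError("X, y and labels must have equal length")
        if self.K < 2:
            raise ValueError(f"need at least 2 groups, got {self.K}")
        p = self.X[0].shape[1] if self.X[0].ndim == 2 else -1
        if p < 1:
            raise ValueError("p = 0: no feature columns")
        for lab, Xk, yk in zip(self.labels, self.X, self.y):
            if Xk.ndim != 2 or Xk.shape[1] != p:
                raise ValueError(f"group {lab}: feature dimension mismatch (expected p={p})")
            if Xk.shape[0] != yk.shape[0]:
                raise ValueError(f"group {lab}: X and y row counts differ")
            if Xk.shape[0] < 1:
                raise ValueError(f"group {lab}: empty group")
            if not np.all(np.isfinite(Xk)):
                raise ValueError(f"group {lab}: non-finite feature values")
            vals = np.unique(yk)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError(f"group {lab}: outcomes must be binary 0/1, got {vals}")
            for cls in (0, 1):
                if not np.any(yk == cls):
                    raise ValueError(
                        f"group {lab} lacks outcome class {cls}; "
                        "the fairness penalty is undefined"
                    )

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def p(self) -> int:
        return self.X[0].shape[1]

    @property
    def n_per_group(self) -> list:
        return [Xk.shape[0] for Xk in self.X]

    @property
    def n(self) -> int:
        return sum(self.n_per_group)

    def class_indices(self, k: int, cls: int) -> np.ndarray:
        """Index set S_ky = {i : y_ki = y} within group k."""
        return np.flatnonzero(self.y[k] == cls)

    def subset(self, row_indices: list) -> "GroupedDataset":
        """New dataset keeping ``row_indices[k]`` rows of each group."""
        return GroupedDataset(
            X=[self.X[k][idx] for k, idx in enumerate(row_indices)],
            y=[self.y[k][idx] for k, idx in enumerate(row_indices)],
            labels=list(self.labels),
            feature_names=list(self.feature_names),
            standardizer=self.standardizer,
        )


@dataclass
class CoefficientSet:
    """Per-group slope vectors plus unpenalized intercepts.

    ``betas`` is a ``K x p`` array (row k = β_k); ``intercepts`` has length K.
    The stacked view is the length-``pK`` vector (β_1, …, β_K) in group-block
    order; stacking and unstacking are exact inverses.
    """

    betas: np.ndarray
    intercepts: np.ndarray

    def __post_init__(self):
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        self.intercepts = np.atleast_1d(np.asarray(self.intercepts, dtype=float))
        if self.betas.shape[0] != self.intercepts.shape[0]:
            raise ValueError("betas and intercepts disagree on group count")

    @property
    def K(self) -> int:
        return self.betas.shape[0]

    @property
    def p(self) -> int:
        return self.betas.shape[1]

    def stacked(self) -> np.ndarray:
        """Length-pK vector in group-block order, intercepts excluded."""
        return self.betas.reshape(-1).copy()

    @classmethod
    def from_stacked(cls, beta: np.ndarray, K: int, intercepts=None) -> "CoefficientSet":
        beta = np.asarray(beta, dtype=float)
        if beta.size % K:
            raise ValueError("stacked length not divisible by K")
        if intercepts is None:
            intercepts = np.zeros(K)
        return cls(betas=beta.reshape(K, -1), intercepts=intercepts)

    def augmented(self) -> np.ndarray:
        """Length-(p+1)K vector with the intercept leading each block."""
        return np.hstack([np.column_stack([self.intercepts, self.betas]).reshape(-1)])

    @classmethod
    def from_augmented(cls, beta_aug: np.ndarray, K: int) -> "CoefficientSet":
        blocks = np.asarray(beta_aug, dtype=float).reshape(K, -1)
        return cls(betas=blocks[:, 1:], intercepts=blocks[:, 0])


@dataclass
class Hyperparameters:
    """Penalty weights and smoothing controls for the joint objective.

    lambda_f
        Weight of the equalized-odds fairness penalty.
    lambda_sim
        Weight of the fused-lasso similarity penalty on pairwise slope
        differences.
    lambda_sp
        Either a scalar (tied across groups as ``lambda_sp / sqrt(n_k)``
        when fits resolve it against a dataset) or a length-K sequence of
        per-group L1 weights.
    mu
        Nesterov smoothing parameter; when None it is chosen as
        ``delta / M`` from the target accuracy ``delta`` (M = penalty rows).
    delta
        Target accuracy of the smoothed solution relative to the exact one.
    """

    lambda_f: float = 0.0
    lambda_sim: float = 0.0
    lambda_sp: float | tuple = 0.0
    mu: float | None = None
    delta: float = 1e-4

    def __post_init__(self):
        if self.lambda_f < 0 or self.lambda_sim < 0:
            raise ValueError("penalty weights must be nonnegative")
        sp = np.atleast_1d(np.asarray(self.lambda_sp, dtype=float))
        if np.any(sp < 0):
            raise ValueError("sparsity weights must be nonnegative")
        if self.mu is not None and self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.delta <= 0:
            raise ValueError("delta must be positive")

    def sparsity_per_group(self, n_per_group: list) -> np.ndarray:
        """Resolve lambda_sp to one weight per group.

        A scalar is tied across groups as ``lambda_sp / sqrt(n_k)`` so that
        sparsity pressure is inversely related to group sample size; a
        sequence is taken verbatim.
        """
        sp = np.atleast_1d(np.asarray(self.lambda_sp, dtype=float))
        K = len(n_per_group)
        if sp.size == 1:
            return sp[0] / np.sqrt(np.asarray(n_per_group, dtype=float))
        if sp.size != K:
            raise ValueError(f"lambda_sp has {sp.size} entries for {K} groups")
        return sp


@dataclass
class FitResult:
    """Outcome of an optimizer run."""

    coefficients: CoefficientSet
    objective_trace: list
    converged: bool
    iterations: int
    final_objective: float
    kind: str = "jfm"
    labels: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)
    standardizer: Standardizer | None = None
    hyper: Hyperparameters | None = None

    def __post_init__(self):
        if len(self.objective_trace) == 0:
            raise ValueError("objective trace must be non-empty")
        if self.iterations != len(self.objective_trace) - 1:
            raise ValueError("iterations must equal len(trace) - 1")


def validate_dataset(
    raw: pd.DataFrame,
    outcome_col: str,
    group_col: str,
    feature_cols: list | None = None,
    standardize: bool = False,
) -> GroupedDataset:
    """Partition a flat table into a validated :class:`GroupedDataset`.

    Group order is first-appearance order in the table.  The outcome column
    must hold exactly two distinct values; they are mapped to {0, 1} by sorted
    order.  All remaining numeric columns are features unless ``feature_cols``
    names them explicitly.
    """
    if isinstance(raw, GroupedDataset):  # idempotent on our own output
        return raw
    for col in (outcome_col, group_col):
        if col not in raw.columns:
            raise ValueError(f"column {col!r} not in table")
        if raw[col].isna().any():
            raise ValueError(f"column {col!r} contains missing values")

    if feature_cols is None:
        feature_cols = [
            c
            for c in raw.columns
            if c not in (outcome_col, group_col)
            and pd.api.types.is_numeric_dtype(raw[c])
        ]
    if len(feature_cols) == 0:
        raise ValueError("p = 0: no numeric feature columns found")
    for c in feature_cols:
        if raw[c].isna().any():
            raise ValueError(f"feature column {c!r} contains missing values")

    outcome_vals = sorted(pd.unique(raw[outcome_col]))
    if len(outcome_vals) != 2:
        raise ValueError(
            f"outcome column {outcome_col!r} must have exactly 2 levels, got {len(outcome_vals)}"
        )
    y_all = (raw[outcome_col] == outcome_vals[1]).to_numpy(dtype=float)

    labels = list(pd.unique(raw[group_col].astype(str)))
    if len(labels) < 2:
        raise ValueError("group column must have at least 2 levels")

    X_all = raw[feature_cols].to_numpy(dtype=float)
    standardizer = None
    if standardize:
        standardizer = Standardizer.fit(X_all)
        X_all = standardizer.transform(X_all)

    groups_X, groups_y = [], []
    group_series = raw[group_col].astype(str).to_numpy()
    for lab in labels:
        mask = group_series == lab
        yk = y_all[mask]
        for cls in (0, 1):
            if not np.any(yk == cls):
                raise ValueError(f"group {lab} lacks outcome class {cls}")
        groups_X.append(X_all[mask])
        groups_y.append(yk)

    return GroupedDataset(
        X=groups_X,
        y=groups_y,
        labels=labels,
        feature_names=list(feature_cols),
        standardizer=standardizer,
    )


def read_csv_dataset(
    path,
    outcome_col: str,
    group_col: str,
    standardize: bool = False,
) -> GroupedDataset:
    """Read a headered CSV and validate it into a :class:`GroupedDataset`."""
    raw = pd.read_csv(path)
    return validate_dataset(raw, outcome_col, group_col, standardize=standardize)
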