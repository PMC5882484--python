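"""Sparse linear support-vector regression for endpoint and error models.

The learner is L2-regularized epsilon-insensitive regression with a linear
kernel (liblinear-style, via scikit-learn's ``LinearSVR``).  Two
hyperparameters are tuned: the error penalty ``cost`` (C) and the
termination tolerance ``epsilon`` of the solver.  The epsilon-insensitive
tube width is a separate, fixed configuration (default 0.1) and is not part
of the tuning surface.  Features enter as raw occurrence counts with no
scaling or centering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.svm import LinearSVR

from .errors import DegenerateDataError
from .evaluation import q2
from .signatures import FeatureVector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SvrParams:
    """Hyperparameters of the linear SVR.

    cost : error penalty C (> 0).
    epsilon : termination tolerance of the solver (> 0).  This is the
        tuned "epsilon", not the tube width.
    tube : epsilon-insensitive tube width (fixed, not tuned).
    seed : RNG seed for the solver.
    """

    cost: float = 1.0
    epsilon: float = 1e-4
    tube: float = 0.1
    seed: int = 42

    def __post_init__(self):
        if self.cost <= 0 or self.epsilon <= 0:
            raise ValueError("cost and epsilon must be positive")


@dataclass
class LinearModel:
    """A fitted sparse linear model: prediction = bias + sum_j w_j x_j."""

    weights: dict[int, float]
    bias: float
    params: SvrParams
    n_features: int

    def to_dict(self) -> dict:
        idx = sorted(self.weights)
        return {
            "bias": self.bias,
            "n_features": self.n_features,
            "indices": idx,
            "values": [self.weights[j] for j in idx],
            "params": {
                "cost": self.params.cost,
                "epsilon": self.params.epsilon,
                "tube": self.params.tube,
                "seed": self.params.seed,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            weights=dict(zip(d["indices"], d["values"])),
            bias=d["bias"],
            params=SvrParams(**d["params"]),
            n_features=d["n_features"],
        )


def vectors_to_csr(
    X: list[FeatureVector] | sparse.spmatrix | np.ndarray,
    n_features: int | None = None,
) -> sparse.csr_matrix:
    """Stack feature vectors into a CSR matrix."""
    if sparse.issparse(X):
        return X.tocsr()
    if isinstance(X, np.ndarray):
        return sparse.csr_matrix(X)
    if n_features is None:
        n_features = 1 + max(
            (j for fv in X for j in fv.counts), default=-1
        )
    rows, cols, vals = [], [], []
    for i, fv in enumerate(X):
        for j, c in fv.counts.items():
            if j < n_features:
                rows.append(i)
                cols.append(j)
                vals.append(c)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(X), n_features), dtype=np.float64
    )


def fit_svr(X, y, params: SvrParams = SvrParams(),
            n_features: int | None = None) -> LinearModel:
    """Fit the linear SVR and return a sparse :class:`LinearModel`.

    Deterministic given ``params.seed``.  Raises
    :class:`DegenerateDataError` when all labels are identical or no sample
    has a nonzero feature.
    """
    Xm = vectors_to_csr(X, n_features)
    y = np.asarray(y, dtype=np.float64)
    if Xm.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if Xm.shape[0] < 2:
        raise DegenerateDataError("need at least two training samples")
    if np.ptp(y) == 0:
        raise DegenerateDataError("all target values identical")
    if Xm.nnz == 0:
        raise DegenerateDataError("all feature vectors are empty")

    svr = LinearSVR(
        C=params.cost,
        tol=params.epsilon,
        epsilon=params.tube,
        loss="epsilon_insensitive",
        dual=True,
        max_iter=200000,
        random_state=params.seed,
    )
    svr.fit(Xm, y)
    coef = np.ravel(svr.coef_)
    weights = {int(j): float(coef[j]) for j in np.flatnonzero(coef)}
    return LinearModel(
        weights=weights,
        bias=float(np.ravel(svr.intercept_)[0]),
        params=params,
        n_features=Xm.shape[1],
    )


def predict(model: LinearModel, x: FeatureVector | dict[int, float]) -> float:
    """Sparse dot product plus bias; indices absent from the model (or the
    vector) contribute zero."""
    counts = x.counts if isinstance(x, FeatureVector) else x
    w = model.weights
    return model.bias + sum(
        w[j] * c for j, c in counts.items() if j in w
    )


def predict_many(model: LinearModel, X) -> np.ndarray:
    """Vectorized prediction over a CSR matrix or list of feature vectors."""
    Xm = vectors_to_csr(X, model.n_features)
    w = np.zeros(model.n_features)
    for j, v in model.weights.items():
        w[j] = v
    return model.bias + Xm @ w


@dataclass
class GridSearchResult:
    table: "object"  # pandas.DataFrame: cost, epsilon, q2
    best: SvrParams


def grid_search(
    X_train, y_train, X_holdout, y_holdout,
    cost_grid, epsilon_grid,
    tube: float = 0.1, seed: int = 42,
) -> GridSearchResult:
    """Fit one model per (cost, epsilon) cell and score Q^2 on the holdout.

    Ties on Q^2 prefer the simpler model: lower cost, then larger epsilon.
    Cells whose fit fails are reported with a missing Q^2 and a warning.
    """
    import pandas as pd

    if not len(cost_grid) or not len(epsilon_grid):
        raise ValueError("empty hyperparameter grid")
    rows = []
    y_holdout = np.asarray(y_holdout, dtype=float)
    for cost in cost_grid:
        for eps in epsilon_grid:
            params = SvrParams(cost=cost, epsilon=eps, tube=tube, seed=seed)
            try:
                model = fit_svr(X_train, y_train, params)
                score = q2(y_holdout, predict_many(model, X_holdout))
            except DegenerateDataError as exc:
                logger.warning("grid cell (cost=%g, eps=%g) failed: %s",
                               cost, eps, exc)
                score = math.nan
            rows.append({"cost": cost, "epsilon": eps, "q2": score})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["q2"])
    if valid.empty:
        raise DegenerateDataError("every grid cell failed to fit")
    best_q2 = valid["q2"].max()
    ties = valid[valid["q2"] == best_q2]
    ties = ties.sort_values(["cost", "epsilon"], ascending=[True, False])
    top = ties.iloc[0]
    return GridSearchResult(
        table=table,
        best=SvrParams(cost=float(top["cost"]), epsilon=float(top["epsilon"]),
                       tube=tube, seed=seed),
    )
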