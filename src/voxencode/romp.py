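"""Regularized orthogonal matching pursuit (ROMP) for sparse linear encoding.

The per-voxel encoding model is ``y = X w + eps`` with an intercept column
appended to the design and a sparsity budget K on the number of nonzero
feature weights.  Because the number of feature dimensions far exceeds the
number of training stimuli, the least-squares problem is ill-posed and the
weight vector is found greedily: at each step the residual is correlated
with every unused column, a *regularized* group of comparable-magnitude
correlations is selected (largest-to-smallest, keeping a contiguous run
whose largest magnitude is at most twice its smallest, maximizing the run's
energy), the group joins the support, and the weights are refit by least
squares on the support plus intercept.

Following the published regularized pursuit, the support may *overshoot*
the sparsity budget K during iteration (the published analysis allows up to
2K; here the exploration cap defaults to min(3K, m - 2, n), which is what
the greedy group selection needs in practice to cover the true support on
small designs).  When the pursuit stops — residual below tolerance or cap
reached — an overfull support is truncated to the K largest-magnitude
refit weights and refit once more, so a fit on a sufficiently informative
design returns exactly K nonzero coefficients.

The intercept is always part of the refit and never counts toward K.
Columns are standardized (mean 0, sd 1 on the training rows) before the
pursuit, because the correlation-based selection is scale-sensitive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DataShapeError

logger = logging.getLogger(__name__)

#: Regularization factor of the group selection: the largest magnitude in the
#: accepted group is at most RATIO_BOUND times the smallest.
RATIO_BOUND = 2.0


@dataclass
class DesignMatrix:
    """Standardized design with a trailing constant column.

    ``values`` is samples × (dims + 1); the last column is all ones.  The
    column statistics are those of the *training* rows and are reused to
    transform held-out rows, so train and test live on the same scale.
    """

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray

    @classmethod
    def from_training(cls, X: np.ndarray, standardize: bool = True) -> "DesignMatrix":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise DataShapeError("design must be 2-D")
        if standardize:
            means = X.mean(axis=0)
            sds = X.std(axis=0)
            sds = np.where(sds > 0, sds, 1.0)  # constant columns stay centred
        else:
            means = np.zeros(X.shape[1])
            sds = np.ones(X.shape[1])
        Z = (X - means) / sds
        vals = np.hstack([Z, np.ones((X.shape[0], 1))])
        return cls(vals, means, sds)

    def transform(self, X_new: np.ndarray) -> "DesignMatrix":
        """Apply the training column statistics to new rows."""
        X_new = np.asarray(X_new, dtype=np.float64)
        if X_new.shape[1] != self.n_features:
            raise DataShapeError(
                f"expected {self.n_features} columns, got {X_new.shape[1]}"
            )
        Z = (X_new - self.column_means) / self.column_sds
        vals = np.hstack([Z, np.ones((X_new.shape[0], 1))])
        return DesignMatrix(vals, self.column_means, self.column_sds)

    @property
    def n_features(self) -> int:
        return self.values.shape[1] - 1

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class SparseLinearModel:
    """A sparse weight vector with explicit support plus an intercept.

    ``weights[i]`` multiplies the standardized feature column
    ``support[i]``; the least-squares refit guarantees the weights are
    optimal given the support.
    """

    support: np.ndarray
    weights: np.ndarray
    intercept: float
    residual_norm: float
    n_iterations: int
    residual_history: list[float] = field(default_factory=list)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    def dense_weights(self, n_features: int) -> np.ndarray:
        """Zero-padded weight vector of length ``n_features``."""
        w = np.zeros(n_features)
        w[self.support] = self.weights
        return w


def regularized_select(correlations: np.ndarray, max_pick: int) -> np.ndarray:
    """Select a comparable-magnitude group among the largest correlations.

    Among the ``max_pick`` largest-magnitude entries (zeros excluded), finds
    every contiguous run (in descending magnitude order) whose maximum
    magnitude is at most ``RATIO_BOUND`` times its minimum, and returns the
    run with the largest energy (sum of squares).  Ties prefer the run
    containing the overall largest magnitude, then the earliest run; entries
    of equal magnitude are ordered by ascending index, which makes the
    choice deterministic.

    Returns an ascending index array; empty if all correlations are zero.
    """
    u = np.asarray(correlations, dtype=np.float64)
    if not np.all(np.isfinite(u)):
        raise DataShapeError("correlations must be finite")
    if max_pick < 1:
        raise ConfigurationError("max_pick must be >= 1")
    mags = np.abs(u)
    if not np.any(mags > 0):
        return np.array([], dtype=np.intp)
    # descending magnitude, ascending index on ties
    order = np.lexsort((np.arange(u.size), -mags))[:max_pick]
    cand = order[mags[order] > 0]
    m = mags[cand]
    best_energy = -1.0
    best: tuple[int, int] | None = None
    j = 0
    for i in range(m.size):
        if j < i:
            j = i
        # extend run while the ratio bound holds (m is non-increasing)
        while j + 1 < m.size and m[i] <= RATIO_BOUND * m[j + 1]:
            j += 1
        energy = float(np.sum(m[i : j + 1] ** 2))
        if energy > best_energy:  # strict: earliest run wins ties
            best_energy = energy
            best = (i, j)
    assert best is not None
    lo, hi = best
    return np.sort(cand[lo : hi + 1])


def _refit(
    A_cols: np.ndarray, ones: np.ndarray, y: np.ndarray, support: list[int]
) -> tuple[np.ndarray, float, np.ndarray, int]:
    A = np.column_stack([A_cols[:, support], ones])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(np.linalg.norm(resid)), resid, int(rank)


def romp_fit(
    X: DesignMatrix,
    y: np.ndarray,
    K: int,
    tol: float | None = None,
    support_cap: int | None = None,
) -> SparseLinearModel:
    """Fit one voxel's sparse linear model by regularized pursuit.

    Parameters
    ----------
    X
        Training design (standardized, trailing ones column).
    y
        Response vector, one entry per training row of ``X``.
    K
        Sparsity budget: maximum (and, on informative designs, exact)
        number of supported feature columns.  The intercept is extra.
    tol
        Residual-norm stopping tolerance; defaults to ``1e-6 * ||y||``.
    support_cap
        Exploration bound on the intermediate support before the final
        truncation to K; defaults to ``min(3K, m - 2, n)``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.size != X.n_samples:
        raise DataShapeError(f"{y.size} responses but {X.n_samples} design rows")
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    if K > X.n_features:
        raise ConfigurationError(
            f"sparsity K={K} exceeds {X.n_features} feature columns"
        )
    if tol is None:
        tol = 1e-6 * float(np.linalg.norm(y))
    if support_cap is None:
        support_cap = min(3 * K, max(X.n_samples - 2, 1), X.n_features)
    support_cap = max(support_cap, K)

    cols = X.values[:, :-1]
    ones = X.values[:, -1]
    support: list[int] = []
    # intercept-only start
    coef = np.array([y.mean()])
    resid = y - coef[-1]
    resid_norm = float(np.linalg.norm(resid))
    history = [resid_norm]
    n_iter = 0

    while len(support) < support_cap and resid_norm > tol:
        n_iter += 1
        u = cols.T @ resid
        if support:
            u[support] = 0.0
        picked = regularized_select(u, max_pick=min(K, support_cap - len(support)))
        if picked.size == 0:
            break
        support.extend(int(i) for i in picked)
        coef, resid_norm, resid, rank = _refit(cols, ones, y, support)
        while rank < len(support) + 1 and support:
            dropped = support.pop()  # most recently added column
            warnings.warn(
                f"rank-deficient refit; dropping column {dropped}",
                RuntimeWarning,
                stacklevel=2,
            )
            coef, resid_norm, resid, rank = _refit(cols, ones, y, support)
        history.append(resid_norm)

    if len(support) > K:
        # cap the final nonzero count at exactly K: keep the K largest
        # magnitude refit weights, then refit on the kept support
        keep = np.argsort(-np.abs(coef[:-1]), kind="stable")[:K]
        support = [support[i] for i in sorted(keep)]
    if support:
        coef, resid_norm, resid, _ = _refit(cols, ones, y, support)
        weights = coef[:-1]
        intercept = float(coef[-1])
    else:
        weights = np.array([])
        intercept = float(y.mean())

    return SparseLinearModel(
        support=np.asarray(support, dtype=np.intp),
        weights=np.asarray(weights, dtype=np.float64),
        intercept=intercept,
        residual_norm=resid_norm,
        n_iterations=n_iter,
        residual_history=history,
    )


def predict(model: SparseLinearModel, X_new: DesignMatrix) -> np.ndarray:
    """Forward map ``X w + intercept`` restricted to the model's support.

    ``X_new`` must have been standardized with the *training* column
    statistics (use :meth:`DesignMatrix.transform`).
    """
    if model.support.size and model.support.max() >= X_new.n_features:
        raise DataShapeError(
            f"support index {int(model.support.max())} out of range for "
            f"{X_new.n_features} feature columns"
        )
    if model.support.size == 0:
        return np.full(X_new.n_samples, model.intercept)
    return X_new.values[:, model.support] @ model.weights + model.intercept
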