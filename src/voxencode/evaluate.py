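"""Prediction scoring, permutation nulls, model comparison, trend tests.

Prediction accuracy is the Pearson correlation r between predicted and
measured voxel responses over the held-out stimuli.  Two permutation
procedures calibrate significance:

* per-voxel accuracy — the pairing between predicted and measured rows is
  shuffled ``n_perm`` times and r recomputed, giving an empirical null per
  voxel; a voxel is significant when its observed r exceeds the null's
  (1 - alpha) quantile.  For a 500-stimulus test set and alpha = 0.001 the
  threshold sits near z_{0.999} / sqrt(n - 1) ~ 0.14.
* model advantage — each voxel's pair of accuracies (model A vs model B) is
  swapped with probability 1/2, and the advantage (percentage of voxels A
  wins, ties split evenly) recomputed, giving a null centred at 50% with
  binomial spread 50 / sqrt(N); at alpha = 0.05 the critical advantage is
  about 50 + 1.645 * 50 / sqrt(N) percent.

A tie-corrected Mann-Kendall test checks monotone trends, e.g. "does the
best encoding layer deepen along the sequence of ROIs".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LayerSpec
from .exceptions import ConfigurationError, DataShapeError
from .encoding import VoxelEncodingModel

logger = logging.getLogger(__name__)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation; defined as 0 for constant input.

    The zero convention (with a logged warning) keeps permutation loops
    well-defined when a shuffled pairing happens to involve a constant
    vector.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise DataShapeError(f"length mismatch: {a.size} vs {b.size}")
    da = a - a.mean()
    db = b - b.mean()
    denom = float(np.linalg.norm(da) * np.linalg.norm(db))
    if denom == 0.0:
        logger.warning("pearson_r on constant input; returning 0")
        return 0.0
    return float(np.dot(da, db) / denom)


def _zscore_columns(M: np.ndarray) -> np.ndarray:
    """Column z-scores with constant columns mapped to zero."""
    d = M - M.mean(axis=0)
    sd = d.std(axis=0)
    out = np.zeros_like(d)
    np.divide(d, sd, out=out, where=sd > 0)
    return out


def pearson_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations of two equal-shaped matrices."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape:
        raise DataShapeError(f"shape mismatch: {A.shape} vs {B.shape}")
    return (_zscore_columns(A) * _zscore_columns(B)).mean(axis=0)


@dataclass
class PredictionResult:
    """Predicted vs measured responses with per-voxel accuracy."""

    predicted: np.ndarray
    measured: np.ndarray
    voxel_ids: list[str] = field(default_factory=list)
    accuracy: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=np.float64)
        self.measured = np.asarray(self.measured, dtype=np.float64)
        if self.predicted.ndim == 1:  # single voxel given as a vector
            self.predicted = self.predicted[:, None]
        if self.measured.ndim == 1:
            self.measured = self.measured[:, None]
        if self.predicted.shape != self.measured.shape:
            raise DataShapeError(
                f"predicted {self.predicted.shape} vs measured {self.measured.shape}"
            )
        if not self.voxel_ids:
            self.voxel_ids = [f"v{i:04d}" for i in range(self.predicted.shape[1])]
        if len(self.voxel_ids) != self.predicted.shape[1]:
            raise DataShapeError("voxel_ids do not match matrix width")
        self.accuracy = pearson_columns(self.predicted, self.measured)


@dataclass
class SignificanceResult:
    """Permutation-null summary for voxel accuracies or a model advantage."""

    n_permutations: int
    alpha: float
    correlation_threshold: float = float("nan")
    null_quantiles: np.ndarray | None = None  # per-voxel thresholds
    significant: np.ndarray | None = None
    advantage: float = float("nan")  # percent, advantage test only
    advantage_threshold: float = float("nan")  # percent
    p_value: float = float("nan")


def voxel_significance(
    result: PredictionResult,
    n_perm: int = 1000,
    alpha: float = 0.001,
    seed: int | np.random.Generator | None = None,
    pooled: bool = False,
) -> SignificanceResult:
    """Permutation test of per-voxel prediction accuracy.

    Shuffles the pairing between predicted and measured rows ``n_perm``
    times, recomputing every voxel's correlation each time.  Per-voxel
    thresholds are the empirical (1 - alpha) null quantiles; with
    ``pooled=True`` a single threshold is taken from the null correlations
    pooled across voxels (one number for the whole map).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if alpha * n_perm < 1:
        logger.warning(
            "alpha*n_perm = %.3g < 1: the quantile is the sample maximum",
            alpha * n_perm,
        )
    rng = np.random.default_rng(seed)
    Zp = _zscore_columns(result.predicted)
    Zm = _zscore_columns(result.measured)
    n = Zp.shape[0]
    null = np.empty((n_perm, Zp.shape[1]))
    for t in range(n_perm):
        perm = rng.permutation(n)
        null[t] = (Zp[perm] * Zm).mean(axis=0)
    per_voxel = np.quantile(null, 1.0 - alpha, axis=0)
    threshold = float(np.quantile(null.ravel(), 1.0 - alpha)) if pooled else float(
        per_voxel.mean()
    )
    significant = result.accuracy > (threshold if pooled else per_voxel)
    return SignificanceResult(
        n_permutations=n_perm,
        alpha=alpha,
        correlation_threshold=threshold,
        null_quantiles=per_voxel,
        significant=significant,
    )


def _advantage_percent(diff: np.ndarray) -> float:
    """Percent of voxels won by A; exact ties contribute half a win each."""
    wins = np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)
    return 100.0 * wins / diff.size


def advantage_test(
    acc_a: np.ndarray,
    acc_b: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> SignificanceResult:
    """Sign-flip permutation test of one model's advantage over another.

    The advantage is the percentage of voxels where model A's accuracy
    exceeds model B's (ties split evenly).  The null swaps each voxel's
    pair with probability 1/2; the critical advantage is the (1 - alpha)
    null quantile.
    """
    a = np.asarray(acc_a, dtype=np.float64).ravel()
    b = np.asarray(acc_b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise DataShapeError("accuracy vectors differ in length")
    if a.size < 10:
        raise ConfigurationError("advantage test needs at least 10 voxels")
    rng = np.random.default_rng(seed)
    diff = a - b
    observed = _advantage_percent(diff)
    flips = rng.random((n_perm, diff.size)) < 0.5
    signed = np.where(flips, -diff, diff)
    wins = (signed > 0).sum(axis=1) + 0.5 * (signed == 0).sum(axis=1)
    null = 100.0 * wins / diff.size
    threshold = float(np.quantile(null, 1.0 - alpha))
    p = float((1 + np.count_nonzero(null >= observed)) / (1 + n_perm))
    if np.all(diff == 0):
        significant = np.array([False])
    else:
        significant = np.array([observed > threshold])
    return SignificanceResult(
        n_permutations=n_perm,
        alpha=alpha,
        advantage=observed,
        advantage_threshold=threshold,
        p_value=p,
        significant=significant,
    )


def compare_models(
    results: Mapping[str, PredictionResult],
    roi_labels: Mapping[str, str],
    threshold: float = 0.13,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pairwise per-ROI model comparison over above-threshold voxels.

    For every model pair and ROI, restricts to voxels where at least one
    model predicts above ``threshold`` (default the study's 0.13 critical
    correlation), reports the fraction won by each model (ties split), and
    the sign-flip advantage test.  Returns one tidy row per
    (roi, model_a, model_b).
    """
    names = list(results)
    base = results[names[0]]
    for name in names[1:]:
        if results[name].voxel_ids != base.voxel_ids:
            raise DataShapeError(f"voxel sets differ between models ({name})")
    rng = np.random.default_rng(seed)
    rois = sorted({roi_labels[v] for v in base.voxel_ids})
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :] if len(names) > 1 else [na]:
            acc_a = results[na].accuracy
            acc_b = results[nb].accuracy
            for roi in rois:
                mask = np.array([roi_labels[v] == roi for v in base.voxel_ids])
                above = mask & ((acc_a > threshold) | (acc_b > threshold))
                n_vox = int(above.sum())
                if n_vox == 0:
                    logger.warning(
                        "%s vs %s in %s: no voxel above threshold %.3g",
                        na, nb, roi, threshold,
                    )
                    rows.append(
                        dict(roi=roi, model_a=na, model_b=nb, n_voxels=0,
                             frac_a=np.nan, frac_b=np.nan, advantage_pct=np.nan,
                             advantage_threshold_pct=np.nan, p_value=np.nan,
                             significant=False)
                    )
                    continue
                da, db = acc_a[above], acc_b[above]
                frac_a = _advantage_percent(da - db) / 100.0
                if n_vox >= 10:
                    adv = advantage_test(da, db, n_perm=n_perm, alpha=alpha, seed=rng)
                    adv_pct, adv_thr = adv.advantage, adv.advantage_threshold
                    p, sig = adv.p_value, bool(adv.significant[0])
                else:
                    adv_pct, adv_thr, p, sig = 100 * frac_a, np.nan, np.nan, False
                rows.append(
                    dict(roi=roi, model_a=na, model_b=nb, n_voxels=n_vox,
                         frac_a=frac_a, frac_b=1.0 - frac_a, advantage_pct=adv_pct,
                         advantage_threshold_pct=adv_thr, p_value=p,
                         significant=sig)
                )
    return pd.DataFrame(rows)


def layer_contribution(
    model: VoxelEncodingModel, roi_labels: Mapping[str, str]
) -> pd.DataFrame:
    """Fraction of voxels per ROI whose best layer is each trained layer.

    Rows are ROIs, columns are layer labels in (network, depth) order;
    each row sums to 1.  Empty ROIs are omitted with a warning.
    """
    layers = sorted(model.layer_fits, key=lambda s: (s.network_id, s.layer_index))
    rois: list[str] = []
    for v in model.voxel_ids:
        r = roi_labels.get(v)
        if r is not None and r not in rois:
            rois.append(r)
    missing = set(roi_labels.values()) - set(rois)
    for roi in sorted(missing):
        logger.warning("ROI %s has no fitted voxels; omitted", roi)
    table = np.zeros((len(rois), len(layers)))
    ridx = {r: i for i, r in enumerate(rois)}
    lidx = {s: j for j, s in enumerate(layers)}
    for v in model.voxel_ids:
        roi = roi_labels.get(v)
        if roi is None:
            continue
        table[ridx[roi], lidx[model.voxels[v].best_layer]] += 1
    table /= table.sum(axis=1, keepdims=True)
    return pd.DataFrame(table, index=pd.Index(rois, name="roi"),
                        columns=[str(s) for s in layers])


class MannKendallResult(NamedTuple):
    S: int
    z: float
    p_value: float


def mann_kendall(sequence: np.ndarray) -> MannKendallResult:
    """Tie-corrected Mann-Kendall monotone-trend test.

    ``S = sum_{i<j} sign(x_j - x_i)``; the variance uses the tie correction
    ``[n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18`` and the z score applies a
    continuity correction.  The p value is two-sided normal.
    """
    x = np.asarray(sequence, dtype=np.float64).ravel()
    n = x.size
    if n < 4:
        raise ConfigurationError("Mann-Kendall needs at least 4 observations")
    diff_signs = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diff_signs, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var == 0 or S == 0:
        z = 0.0
    else:
        z = (S - math.copysign(1, S)) / math.sqrt(var)
    p = 1.0 if z == 0.0 else 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return MannKendallResult(S=S, z=float(z), p_value=float(p))
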