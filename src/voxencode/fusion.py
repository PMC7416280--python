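"""Decodability-ranked feature selection and the fused encoding model.

The fusion stage inverts the encoding direction: each feature dimension is
regressed *from* the voxel responses (same sparse ROMP machinery, design
and target swapped), predicted on held-out stimuli, and scored by the
correlation between predicted and real feature values — its *decodability*.
Within every layer of every network, dimensions are ranked by decodability
and the top fraction (default 10%, ceiling-rounded so a nonempty layer
always keeps at least one dimension) is retained.  Encoding is then re-run
on the retained dimensions of all layers of both networks, and each voxel
again picks its best layer — now possibly from either network — giving the
fused-feature encoding model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureMatrixSet, LayerSpec, VoxelResponseMatrix
from .encoding import LayerFit, VoxelEncodingModel, fit_layerwise, select_best_layer
from .exceptions import ConfigurationError
from .romp import DesignMatrix, SparseLinearModel, predict, romp_fit

logger = logging.getLogger(__name__)

DEFAULT_FRACTION = 0.10  # study default: keep the top 10% per layer


@dataclass
class DecoderFit:
    """Per-dimension decoding models for one layer (responses → features)."""

    layer: LayerSpec
    design: DesignMatrix  # training voxel responses, standardized + constant
    models: dict[int, SparseLinearModel]  # keyed by feature dimension

    def predict_matrix(self, R_raw: np.ndarray) -> np.ndarray:
        """Stimuli × dims predicted feature values on new response rows."""
        dm = self.design.transform(R_raw)
        dims = sorted(self.models)
        return np.column_stack([predict(self.models[d], dm) for d in dims])


@dataclass
class DecodabilityRanking:
    """Per-(layer, dimension) decodability with ranks and selection flags."""

    table: pd.DataFrame  # columns: network, layer_index, dim, decode_correlation, rank, selected
    fraction: float
    layers: list[LayerSpec]

    def selected_dims(self, layer: LayerSpec) -> np.ndarray:
        t = self.table
        mask = (
            (t["network"] == layer.network_id)
            & (t["layer_index"] == layer.layer_index)
            & t["selected"]
        )
        return np.sort(t.loc[mask, "dim"].to_numpy(dtype=np.intp))

    def selection(self) -> dict[LayerSpec, np.ndarray]:
        return {spec: self.selected_dims(spec) for spec in self.layers}


def fit_decoders(
    responses: VoxelResponseMatrix,
    features: FeatureMatrixSet,
    train_ids: Sequence[str],
    K: int,
    tol: float | None = None,
) -> dict[LayerSpec, DecoderFit]:
    """Fit one sparse decoder per feature dimension of every layer.

    The design matrix is the training voxel-response matrix (standardized,
    constant column appended); the target is one feature dimension.
    """
    r_train = responses.subset_stimuli(train_ids)
    f_train = features.subset_stimuli(train_ids)
    dm = DesignMatrix.from_training(r_train.values)
    out: dict[LayerSpec, DecoderFit] = {}
    for spec in features.layers:
        F = f_train[spec]
        models: dict[int, SparseLinearModel] = {}
        for d in range(F.shape[1]):
            try:
                models[d] = romp_fit(dm, F[:, d], K=K, tol=tol)
            except Exception as exc:
                raise type(exc)(f"layer {spec}, dimension {d}: {exc}") from exc
        out[spec] = DecoderFit(layer=spec, design=dm, models=models)
        logger.info("fitted %d decoders on %s", len(models), spec)
    return out


def rank_and_select(
    decoders: Mapping[LayerSpec, DecoderFit],
    responses: VoxelResponseMatrix,
    features: FeatureMatrixSet,
    eval_ids: Sequence[str],
    fraction: float = DEFAULT_FRACTION,
) -> DecodabilityRanking:
    """Rank dimensions by decodability per layer; keep the top fraction.

    Within each layer, dimensions are sorted by decreasing correlation
    between predicted and real feature values on ``eval_ids`` (ties by
    ascending dimension index); the first ``ceil(fraction * n_dims)`` are
    selected.  Constant dimensions score 0 and rank last.
    """
    from .evaluate import pearson_columns

    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    r_eval = responses.subset_stimuli(eval_ids)
    f_eval = features.subset_stimuli(eval_ids)
    layers = sorted(decoders, key=lambda s: (s.network_id, s.layer_index))
    rows = []
    for spec in layers:
        pred = decoders[spec].predict_matrix(r_eval.values)
        real = f_eval[spec]
        corr = pearson_columns(pred, real)
        n_const = int(np.count_nonzero(real.std(axis=0) == 0))
        if n_const:
            logger.warning("%s: %d constant feature dimensions scored 0", spec, n_const)
        order = np.lexsort((np.arange(corr.size), -corr))
        ranks = np.empty(corr.size, dtype=int)
        ranks[order] = np.arange(1, corr.size + 1)
        n_keep = math.ceil(fraction * corr.size)
        for d in range(corr.size):
            rows.append(
                dict(network=spec.network_id, layer_index=spec.layer_index,
                     dim=d, decode_correlation=corr[d], rank=int(ranks[d]),
                     selected=bool(ranks[d] <= n_keep))
            )
    return DecodabilityRanking(
        table=pd.DataFrame(rows), fraction=fraction, layers=layers
    )


def fused_encode(
    features: FeatureMatrixSet,
    responses: VoxelResponseMatrix,
    ranking: DecodabilityRanking,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    K: int,
    tol: float | None = None,
) -> VoxelEncodingModel:
    """Encode on the selected dimensions of every layer of both networks.

    Layers whose selection came out empty are excluded with a warning (the
    default ceiling rounding never empties a nonempty layer).
    """
    selection = ranking.selection()
    for spec in list(selection):
        if selection[spec].size == 0:
            logger.warning("layer %s has no selected dimensions; excluded", spec)
            del selection[spec]
    restricted = features.restrict_dims(selection)
    fits = fit_layerwise(restricted, responses, train_ids, K=K, tol=tol)
    model = select_best_layer(fits, restricted, responses, test_ids)
    model.dim_selection = {s: np.asarray(c, dtype=np.intp) for s, c in selection.items()}
    return model


def selection_sweep(
    fractions: Sequence[float],
    features: FeatureMatrixSet,
    responses: VoxelResponseMatrix,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    K_encode: int,
    K_decode: int | None = None,
    tol: float | None = None,
) -> pd.DataFrame:
    """Mean fused-model accuracy per ROI across selection fractions.

    Decoders are fit once; ranking, selection and fused encoding are
    re-run per fraction.  Returns a tidy table with one row per
    (fraction, roi).
    """
    if len(fractions) == 0:
        raise ConfigurationError("fractions must be non-empty")
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ConfigurationError(f"fraction {f} outside (0, 1]")
    if K_decode is None:
        K_decode = K_encode
    decoders = fit_decoders(responses, features, train_ids, K=K_decode, tol=tol)
    rows = []
    for frac in fractions:
        ranking = rank_and_select(decoders, responses, features, test_ids, frac)
        model = fused_encode(
            features, responses, ranking, train_ids, test_ids, K=K_encode, tol=tol
        )
        acc = {v: model.voxels[v].test_accuracy for v in model.voxel_ids}
        for roi in responses.rois:
            vox = responses.voxels_in(roi)
            rows.append(
                dict(fraction=frac, roi=roi,
                     mean_accuracy=float(np.mean([acc[v] for v in vox])),
                     n_voxels=len(vox))
            )
        logger.info("sweep fraction %.3g done", frac)
    return pd.DataFrame(rows)
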