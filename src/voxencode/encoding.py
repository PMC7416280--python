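"""Per-layer voxel-wise encoding models and best-layer selection.

Each network layer's feature matrix is mapped to every voxel by a sparse
ROMP regression; on held-out stimuli the layer whose prediction correlates
best with the measured response is taken as that voxel's best feature
layer, and the assembly of (best layer, sparse model) pairs is the
voxel-wise encoding model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import FeatureMatrixSet, LayerSpec, VoxelResponseMatrix
from .exceptions import ConfigurationError, InputDataError
from .romp import DesignMatrix, SparseLinearModel, predict, romp_fit

logger = logging.getLogger(__name__)

DEFAULT_TEST_SIZE = 500  # held-out stimuli in the study's 5254-image split


def split_stimuli(
    stimulus_ids: Sequence[str],
    test_size: int = DEFAULT_TEST_SIZE,
    seed: int | np.random.Generator | None = 0,
) -> tuple[list[str], list[str]]:
    """Random, seed-deterministic train/test partition of stimulus ids.

    The default test size of 500 mirrors the study's split of 5254 images
    into 4754 training and 500 test stimuli.  Both groups preserve the
    original id order.
    """
    ids = [str(s) for s in stimulus_ids]
    if len(set(ids)) != len(ids):
        raise InputDataError("duplicate stimulus ids in split")
    if not 0 < test_size < len(ids):
        raise ConfigurationError(
            f"test_size {test_size} must be in 1..{len(ids) - 1}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    test_rows = np.sort(perm[:test_size])
    train_rows = np.sort(perm[test_size:])
    return [ids[i] for i in train_rows], [ids[i] for i in test_rows]


@dataclass
class LayerFit:
    """All voxel models trained on one layer, plus the training scaler."""

    layer: LayerSpec
    design: DesignMatrix  # training design; carries column means/sds
    models: dict[str, SparseLinearModel]

    def predict_matrix(self, X_raw: np.ndarray, voxel_ids: Sequence[str]) -> np.ndarray:
        """Stimuli × voxels predictions on new (raw) feature rows."""
        dm = self.design.transform(X_raw)
        return np.column_stack([predict(self.models[v], dm) for v in voxel_ids])


@dataclass
class VoxelFit:
    best_layer: LayerSpec
    model: SparseLinearModel
    test_accuracy: float


@dataclass
class VoxelEncodingModel:
    """Per-voxel (best layer, sparse model) assembly."""

    voxels: dict[str, VoxelFit]
    layer_fits: dict[LayerSpec, LayerFit]
    #: per voxel, the evaluation accuracy of every candidate layer
    layer_accuracies: dict[str, dict[LayerSpec, float]] = field(default_factory=dict)
    #: columns of the raw feature matrices the fits were trained on
    #: (set by the fusion stage; None means all columns)
    dim_selection: dict[LayerSpec, np.ndarray] | None = None

    @property
    def voxel_ids(self) -> list[str]:
        return list(self.voxels)

    def accuracies(self) -> np.ndarray:
        return np.array([self.voxels[v].test_accuracy for v in self.voxels])

    def predict(
        self, features: FeatureMatrixSet, stimulus_ids: Sequence[str]
    ) -> np.ndarray:
        """Stimuli × voxels predictions using each voxel's best layer."""
        sub = features.subset_stimuli(stimulus_ids)
        cols = []
        for v, fit in self.voxels.items():
            lf = self.layer_fits[fit.best_layer]
            X = sub[fit.best_layer]
            if self.dim_selection is not None and fit.best_layer in self.dim_selection:
                if X.shape[1] != lf.design.n_features:
                    X = X[:, self.dim_selection[fit.best_layer]]
            dm = lf.design.transform(X)
            cols.append(predict(fit.model, dm))
        return np.column_stack(cols)


def fit_layerwise(
    features: FeatureMatrixSet,
    responses: VoxelResponseMatrix,
    train_ids: Sequence[str],
    K: int,
    tol: float | None = None,
) -> dict[LayerSpec, LayerFit]:
    """Fit one ROMP model per (layer, voxel) on the training stimuli."""
    f_train = features.subset_stimuli(train_ids)
    r_train = responses.subset_stimuli(train_ids)
    fits: dict[LayerSpec, LayerFit] = {}
    for spec in features.layers:
        dm = DesignMatrix.from_training(f_train[spec])
        K_eff = min(K, dm.n_features)  # narrow layers (e.g. after selection)
        if K_eff < K:
            logger.info("%s: clamping K from %d to %d columns", spec, K, K_eff)
        models: dict[str, SparseLinearModel] = {}
        for v in responses.voxel_ids:
            try:
                models[v] = romp_fit(dm, r_train.column(v), K=K_eff, tol=tol)
            except Exception as exc:
                raise type(exc)(f"layer {spec}, voxel {v}: {exc}") from exc
        fits[spec] = LayerFit(layer=spec, design=dm, models=models)
        logger.info("fitted %d voxel models on %s", len(models), spec)
    return fits


def select_best_layer(
    fits: Mapping[LayerSpec, LayerFit],
    features: FeatureMatrixSet,
    responses: VoxelResponseMatrix,
    eval_ids: Sequence[str],
) -> VoxelEncodingModel:
    """Pick, per voxel, the layer with the highest evaluation correlation.

    Ties break toward the lowest (network, layer index); a constant
    prediction or measurement scores 0 (logged).
    """
    from .evaluate import pearson_r  # local import avoids a cycle

    layers = sorted(fits, key=lambda s: (s.network_id, s.layer_index))
    f_eval = features.subset_stimuli(eval_ids)
    r_eval = responses.subset_stimuli(eval_ids)

    # predictions per layer: stimuli × voxels
    preds = {
        spec: fits[spec].predict_matrix(f_eval[spec], responses.voxel_ids)
        for spec in layers
    }
    voxels: dict[str, VoxelFit] = {}
    per_layer_acc: dict[str, dict[LayerSpec, float]] = {}
    for j, v in enumerate(responses.voxel_ids):
        measured = r_eval.values[:, j]
        accs: dict[LayerSpec, float] = {}
        for spec in layers:
            accs[spec] = pearson_r(preds[spec][:, j], measured)
        best = max(layers, key=lambda s: accs[s])  # max() keeps first on ties
        voxels[v] = VoxelFit(
            best_layer=best, model=fits[best].models[v], test_accuracy=accs[best]
        )
        per_layer_acc[v] = accs
    return VoxelEncodingModel(
        voxels=voxels, layer_fits=dict(fits), layer_accuracies=per_layer_acc
    )
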