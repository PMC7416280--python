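"""Synthetic stimuli features and voxel responses with known ground truth.

The generator emulates the statistical structure the encoding analysis
assumes: layer-indexed feature matrices whose adjacent layers are
correlated (a hierarchy, like consecutive CNN layers), and per-voxel
responses that are sparse linear functions of exactly one feature layer
plus i.i.d. Gaussian noise.  Every draw is governed by a single seed split
into named substreams in a fixed order, so identical configurations give
bit-identical data and every downstream stage can be tested against the
returned ground truth without downloading anything.

Feature hierarchy.  Layer 1 of each network is i.i.d. standard normal.
Layer l > 1 is ``alpha * (layer_{l-1} @ M_l) + sqrt(1 - alpha^2) * fresh``
with M_l a fixed random mixing matrix scaled to preserve unit variance, so
adjacent layers share ``alpha**2`` of their variance and the correlation
decays geometrically with layer distance.

Responses.  Each voxel draws a true layer, a support of ``true_sparsity``
dimensions and signed weights with magnitudes in [0.5, 2] (well separated
from zero, the standard regime for sparse-recovery benchmarks).  The noise
standard deviation is set from the realized signal standard deviation so
that the empirical signal-to-noise variance ratio matches ``snr``; the
population R^2 of the true model is ``snr / (1 + snr)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .containers import (
    DEFAULT_ROIS,
    FeatureMatrixSet,
    GroundTruth,
    LayerSpec,
    VoxelResponseMatrix,
)
from .exceptions import ConfigurationError, DataShapeError

#: Fraction of amplitude shared between adjacent layers (25% of variance).
DEFAULT_LAYER_MIXING = 0.5


def _default_rois() -> dict[str, int]:
    return {roi: 50 for roi in DEFAULT_ROIS}


@dataclass
class SyntheticConfig:
    """Shape and noise parameters of one synthetic study.

    Defaults are the desk-scale study conditions: 300 train / 100 test
    stimuli, 4 layers of 200 dimensions per network, 50 voxels in each of
    the five ROIs, 10-sparse ground truth at a signal-to-noise variance
    ratio of 4 (true-model R^2 = 0.8).
    """

    n_train: int = 300
    n_test: int = 100
    layers_per_network: int = 4
    dims_per_layer: int = 200
    n_networks: int = 1
    voxels_per_roi: Mapping[str, int] = field(default_factory=_default_rois)
    true_sparsity: int = 10
    snr: float = 4.0
    seed: int = 0
    layer_mixing: float = DEFAULT_LAYER_MIXING
    #: optional ROI -> layer_index map forcing every voxel of an ROI onto one
    #: true layer (first network); None draws each voxel's layer uniformly.
    roi_true_layer: Mapping[str, int] | None = None
    #: fraction of each layer's dimensions eligible to carry signal; 1.0
    #: spreads supports over the whole layer, smaller values concentrate
    #: them in the leading dimensions (the regime feature selection targets)
    support_pool_fraction: float = 1.0

    def __post_init__(self) -> None:
        counts = {
            "n_train": self.n_train,
            "n_test": self.n_test,
            "layers_per_network": self.layers_per_network,
            "dims_per_layer": self.dims_per_layer,
            "n_networks": self.n_networks,
            "true_sparsity": self.true_sparsity,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.n_networks not in (1, 2):
            raise ConfigurationError("n_networks must be 1 or 2")
        if not self.voxels_per_roi:
            raise ConfigurationError("voxels_per_roi must be non-empty")
        for roi, n in self.voxels_per_roi.items():
            if int(n) != n or n < 1:
                raise ConfigurationError(f"voxels_per_roi[{roi!r}] must be positive")
        if not self.snr > 0:
            raise ConfigurationError("snr must be > 0")
        if self.true_sparsity > self.dims_per_layer:
            raise ConfigurationError("true_sparsity cannot exceed dims_per_layer")
        if not 0.0 <= self.layer_mixing < 1.0:
            raise ConfigurationError("layer_mixing must be in [0, 1)")
        if not 0.0 < self.support_pool_fraction <= 1.0:
            raise ConfigurationError("support_pool_fraction must be in (0, 1]")
        if math.ceil(self.support_pool_fraction * self.dims_per_layer) < self.true_sparsity:
            raise ConfigurationError(
                "support pool smaller than true_sparsity"
            )
        if self.roi_true_layer is not None:
            for roi, li in self.roi_true_layer.items():
                if not 1 <= li <= self.layers_per_network:
                    raise ConfigurationError(
                        f"roi_true_layer[{roi!r}]={li} outside 1..{self.layers_per_network}"
                    )

    @property
    def n_stimuli(self) -> int:
        return self.n_train + self.n_test

    @property
    def n_voxels(self) -> int:
        return sum(self.voxels_per_roi.values())

    def network_ids(self) -> list[str]:
        return ["netA", "netB"][: self.n_networks]


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named substreams in a fixed, documented order."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("features", "mixing", "ground_truth", "noise")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_features(cfg: SyntheticConfig) -> FeatureMatrixSet:
    """Generate the layer-indexed feature matrices for every network.

    Deterministic given ``cfg`` (including the seed).  Each layer matrix is
    unit-variance marginally; adjacent layers within a network share
    ``cfg.layer_mixing ** 2`` of their variance.
    """
    rngs = _substreams(cfg.seed)
    rng_f, rng_m = rngs["features"], rngs["mixing"]
    n, d = cfg.n_stimuli, cfg.dims_per_layer
    alpha = cfg.layer_mixing
    stimulus_ids = [f"stim{i:05d}" for i in range(n)]

    entries: dict[LayerSpec, np.ndarray] = {}
    for net in cfg.network_ids():
        prev: np.ndarray | None = None
        for li in range(1, cfg.layers_per_network + 1):
            fresh = rng_f.standard_normal((n, d))
            if prev is None or alpha == 0.0:
                layer = fresh
            else:
                M = rng_m.standard_normal((d, d)) / math.sqrt(d)
                layer = alpha * (prev @ M) + math.sqrt(1.0 - alpha**2) * fresh
            spec = LayerSpec(network_id=net, layer_index=li, layer_name=f"conv{li}")
            entries[spec] = layer
            prev = layer
    return FeatureMatrixSet(entries, stimulus_ids)


def generate_responses(
    features: FeatureMatrixSet, cfg: SyntheticConfig
) -> tuple[VoxelResponseMatrix, dict[str, GroundTruth]]:
    """Generate voxel responses as sparse linear functions of one layer.

    Returns the response matrix (all stimuli, train + test) and the
    per-voxel ground truth used by recovery tests.
    """
    if features.n_stimuli != cfg.n_stimuli:
        raise DataShapeError(
            f"feature set has {features.n_stimuli} stimuli, config expects "
            f"{cfg.n_stimuli}"
        )
    rngs = _substreams(cfg.seed)
    rng_g, rng_n = rngs["ground_truth"], rngs["noise"]
    layers = features.layers
    by_index = {(s.network_id, s.layer_index): s for s in layers}

    voxel_ids: list[str] = []
    roi_labels: dict[str, str] = {}
    truths: dict[str, GroundTruth] = {}
    columns: list[np.ndarray] = []
    noiseless = math.isinf(cfg.snr)

    for roi, count in cfg.voxels_per_roi.items():
        for j in range(count):
            vid = f"{roi}_v{j:04d}"
            voxel_ids.append(vid)
            roi_labels[vid] = roi
            if cfg.roi_true_layer is not None:
                spec = by_index[(features.networks[0], cfg.roi_true_layer[roi])]
            else:
                spec = layers[rng_g.integers(len(layers))]
            X = features[spec]
            pool = math.ceil(cfg.support_pool_fraction * X.shape[1])
            support = np.sort(
                rng_g.choice(pool, size=cfg.true_sparsity, replace=False)
            )
            mags = rng_g.uniform(0.5, 2.0, size=cfg.true_sparsity)
            signs = rng_g.choice([-1.0, 1.0], size=cfg.true_sparsity)
            w = mags * signs
            signal = X[:, support] @ w
            sig_sd = float(signal.std())
            noise_sd = 0.0 if noiseless else sig_sd / math.sqrt(cfg.snr)
            y = signal if noiseless else signal + rng_n.normal(0.0, noise_sd, X.shape[0])
            columns.append(y)
            truths[vid] = GroundTruth(
                true_layer=spec,
                true_support=support,
                true_weights=w,
                noise_sd=noise_sd,
            )

    responses = VoxelResponseMatrix(
        np.column_stack(columns), voxel_ids, roi_labels, features.stimulus_ids
    )
    return responses, truths


def generate_study(
    cfg: SyntheticConfig,
) -> tuple[FeatureMatrixSet, VoxelResponseMatrix, dict[str, GroundTruth]]:
    """Convenience: features plus responses plus ground truth in one call."""
    features = generate_features(cfg)
    responses, truths = generate_responses(features, cfg)
    return features, responses, truths
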