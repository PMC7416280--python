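"""In-memory containers for layer-indexed features and voxel responses.

The two central objects are :class:`FeatureMatrixSet` — a mapping from
:class:`LayerSpec` (one network layer) to a stimuli × dimensions feature
matrix — and :class:`VoxelResponseMatrix`, a stimuli × voxels response
matrix with a region-of-interest (ROI) label per voxel.  Both carry ordered
stimulus identifiers so that rows can be aligned and subset by id rather
than by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import DataShapeError, InputDataError

#: ROI labels used by the study's dataset (five human visual areas).
DEFAULT_ROIS = ("EarlyVis", "LOC", "OPA", "PPA", "RSC")


@dataclass(frozen=True, order=True)
class LayerSpec:
    """Identifies one layer of one feature-extraction network.

    Parameters
    ----------
    network_id
        Label of the network the layer belongs to, e.g. ``"classification"``
        / ``"segmentation"`` for real extractors or ``"netA"`` / ``"netB"``
        for synthetic ones.
    layer_index
        1-based depth index of the layer (1..16 covers the VGG16 / FCN32s
        hierarchies: conv1..conv13 followed by fc1..fc3 or conv14..conv16).
    layer_name
        Human-readable layer name (``"conv3"``, ``"fc1"``, ...).
    pooled, pool_factor
        Whether spatial max-pooling was applied before flattening, and the
        block size used.
    """

    network_id: str
    layer_index: int
    layer_name: str = ""
    pooled: bool = False
    pool_factor: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.layer_index <= 16:
            raise DataShapeError(
                f"layer_index must be in 1..16, got {self.layer_index}"
            )
        if self.pool_factor < 1:
            raise DataShapeError("pool_factor must be >= 1")

    def __str__(self) -> str:  # used in table columns and log lines
        name = self.layer_name or f"layer{self.layer_index}"
        return f"{self.network_id}/L{self.layer_index:02d}_{name}"


def _check_finite(a: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(a)):
        raise InputDataError(f"{what} contains non-finite entries")


class FeatureMatrixSet:
    """Layer-indexed feature matrices sharing one ordered stimulus list.

    ``entries[spec]`` is a float array of shape (n_stimuli, n_dims); all
    entries share the same row count and row order (``stimulus_ids``).
    """

    def __init__(
        self,
        entries: Mapping[LayerSpec, np.ndarray],
        stimulus_ids: Sequence[str],
    ) -> None:
        if len(entries) == 0:
            raise InputDataError("FeatureMatrixSet requires at least one layer")
        ids = [str(s) for s in stimulus_ids]
        if len(set(ids)) != len(ids):
            raise InputDataError("duplicate stimulus ids")
        self.stimulus_ids: list[str] = ids
        self._row: dict[str, int] = {s: i for i, s in enumerate(ids)}
        ents: dict[LayerSpec, np.ndarray] = {}
        for spec, mat in entries.items():
            arr = np.asarray(mat, dtype=np.float64)
            if arr.ndim != 2:
                raise DataShapeError(f"{spec}: feature matrix must be 2-D")
            if arr.shape[0] != len(ids):
                raise DataShapeError(
                    f"{spec}: {arr.shape[0]} rows but {len(ids)} stimulus ids"
                )
            _check_finite(arr, f"feature matrix {spec}")
            ents[spec] = arr
        self.entries = ents

    # -- mapping-like access -------------------------------------------------
    def __getitem__(self, spec: LayerSpec) -> np.ndarray:
        return self.entries[spec]

    def __contains__(self, spec: LayerSpec) -> bool:
        return spec in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def layers(self) -> list[LayerSpec]:
        """Layer specs sorted by (network, depth) — the canonical order."""
        return sorted(self.entries, key=lambda s: (s.network_id, s.layer_index))

    @property
    def networks(self) -> list[str]:
        return sorted({s.network_id for s in self.entries})

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    def rows_for(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._row[s] for s in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise InputDataError(f"unknown stimulus id {exc.args[0]!r}") from exc

    def subset_stimuli(self, ids: Sequence[str]) -> "FeatureMatrixSet":
        """Row-subset (and reorder) every layer to the given stimulus ids."""
        rows = self.rows_for(ids)
        return FeatureMatrixSet(
            {spec: mat[rows] for spec, mat in self.entries.items()}, list(ids)
        )

    def restrict_dims(
        self, selection: Mapping[LayerSpec, np.ndarray]
    ) -> "FeatureMatrixSet":
        """Keep only the selected columns per layer; layers absent from
        ``selection`` (or selected empty) are dropped."""
        ents = {}
        for spec, cols in selection.items():
            cols = np.asarray(cols, dtype=np.intp)
            if cols.size == 0:
                continue
            ents[spec] = self.entries[spec][:, cols]
        if not ents:
            raise InputDataError("dimension selection removed every layer")
        return FeatureMatrixSet(ents, self.stimulus_ids)


class VoxelResponseMatrix:
    """Stimuli × voxels response matrix with per-voxel ROI labels."""

    def __init__(
        self,
        values: np.ndarray,
        voxel_ids: Sequence[str],
        roi_labels: Mapping[str, str],
        stimulus_ids: Sequence[str],
    ) -> None:
        arr = np.asarray(values, dtype=np.float64)
        if arr.ndim != 2:
            raise DataShapeError("response matrix must be 2-D")
        _check_finite(arr, "response matrix")
        vox = [str(v) for v in voxel_ids]
        stim = [str(s) for s in stimulus_ids]
        if arr.shape != (len(stim), len(vox)):
            raise DataShapeError(
                f"response matrix {arr.shape} does not match "
                f"{len(stim)} stimuli x {len(vox)} voxels"
            )
        missing = [v for v in vox if v not in roi_labels]
        if missing:
            raise InputDataError(f"ROI label missing for voxels {missing[:5]}")
        self.values = arr
        self.voxel_ids: list[str] = vox
        self.stimulus_ids: list[str] = stim
        self.roi_labels: dict[str, str] = {v: str(roi_labels[v]) for v in vox}
        self._vcol = {v: i for i, v in enumerate(vox)}
        self._srow = {s: i for i, s in enumerate(stim)}

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    @property
    def rois(self) -> list[str]:
        seen: list[str] = []
        for v in self.voxel_ids:
            r = self.roi_labels[v]
            if r not in seen:
                seen.append(r)
        return seen

    def column(self, voxel_id: str) -> np.ndarray:
        return self.values[:, self._vcol[voxel_id]]

    def voxels_in(self, roi: str) -> list[str]:
        return [v for v in self.voxel_ids if self.roi_labels[v] == roi]

    def subset_stimuli(self, ids: Sequence[str]) -> "VoxelResponseMatrix":
        try:
            rows = np.array([self._srow[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise InputDataError(f"unknown stimulus id {exc.args[0]!r}") from exc
        return VoxelResponseMatrix(
            self.values[rows], self.voxel_ids, self.roi_labels, list(ids)
        )


@dataclass
class GroundTruth:
    """Generative truth for one synthetic voxel (used by recovery tests)."""

    true_layer: LayerSpec
    true_support: np.ndarray
    true_weights: np.ndarray
    noise_sd: float
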