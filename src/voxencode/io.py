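"""Readers and writers for the on-disk interchange formats.

Features travel as HDF5 (one group per network, one dataset per layer
named ``L{index:02d}_{layer_name}``, with flattening order and pooling
recorded as attributes); responses as delimited text (header row of voxel
ids, index column of stimulus ids) or HDF5; ROI labels as a two-column
delimited table.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .containers import FeatureMatrixSet, LayerSpec, VoxelResponseMatrix
from .exceptions import InputDataError
from .features import FLATTEN_ORDER

_DSET_RE = re.compile(r"^L(\d{2})_(.*)$")


def write_features_hdf5(features: FeatureMatrixSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["flatten_order"] = FLATTEN_ORDER
        f.create_dataset(
            "stimulus_ids",
            data=np.array(features.stimulus_ids, dtype=h5py.string_dtype()),
        )
        for spec in features.layers:
            grp = f.require_group(spec.network_id)
            name = f"L{spec.layer_index:02d}_{spec.layer_name or 'layer'}"
            ds = grp.create_dataset(name, data=features[spec])
            ds.attrs["layer_index"] = spec.layer_index
            ds.attrs["layer_name"] = spec.layer_name
            ds.attrs["pooled"] = spec.pooled
            ds.attrs["pool_factor"] = spec.pool_factor


def read_features_hdf5(path: str | Path) -> FeatureMatrixSet:
    with h5py.File(path, "r") as f:
        if "stimulus_ids" not in f:
            raise InputDataError(f"{path}: missing stimulus_ids dataset")
        ids = [s.decode() if isinstance(s, bytes) else str(s)
               for s in f["stimulus_ids"][()]]
        entries: dict[LayerSpec, np.ndarray] = {}
        for net in f:
            if net == "stimulus_ids":
                continue
            grp = f[net]
            for name in grp:
                m = _DSET_RE.match(name)
                if not m:
                    raise InputDataError(f"{path}: unexpected dataset {net}/{name}")
                ds = grp[name]
                spec = LayerSpec(
                    network_id=net,
                    layer_index=int(ds.attrs.get("layer_index", int(m.group(1)))),
                    layer_name=str(ds.attrs.get("layer_name", m.group(2))),
                    pooled=bool(ds.attrs.get("pooled", False)),
                    pool_factor=int(ds.attrs.get("pool_factor", 1)),
                )
                entries[spec] = ds[()]
    return FeatureMatrixSet(entries, ids)


def write_responses_text(
    responses: VoxelResponseMatrix, path: str | Path, sep: str = "\t"
) -> None:
    df = pd.DataFrame(
        responses.values,
        index=pd.Index(responses.stimulus_ids, name="stimulus_id"),
        columns=responses.voxel_ids,
    )
    df.to_csv(path, sep=sep, float_format="%.6g")


def write_roi_table(
    roi_labels: Mapping[str, str], path: str | Path, sep: str = "\t"
) -> None:
    pd.DataFrame(
        {"voxel_id": list(roi_labels), "roi": list(roi_labels.values())}
    ).to_csv(path, sep=sep, index=False)


def read_roi_table(path: str | Path, sep: str = "\t") -> dict[str, str]:
    df = pd.read_csv(path, sep=sep)
    if not {"voxel_id", "roi"} <= set(df.columns):
        raise InputDataError(f"{path}: expected columns voxel_id, roi")
    return dict(zip(df["voxel_id"].astype(str), df["roi"].astype(str)))


def read_responses_text(
    path: str | Path, roi_path: str | Path, sep: str = "\t",
    average_repeats: bool = True,
) -> VoxelResponseMatrix:
    """Read a delimited response table plus its ROI label table.

    Rows sharing a stimulus id (repeated presentations) are averaged by
    default.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if average_repeats and df.index.has_duplicates:
        df = df.groupby(level=0, sort=False).mean()
    roi = read_roi_table(roi_path, sep=sep)
    return VoxelResponseMatrix(
        df.to_numpy(dtype=np.float64),
        [str(c) for c in df.columns],
        roi,
        list(df.index),
    )


def write_responses_hdf5(responses: VoxelResponseMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=responses.values)
        sd = h5py.string_dtype()
        f.create_dataset("stimulus_ids",
                         data=np.array(responses.stimulus_ids, dtype=sd))
        f.create_dataset("voxel_ids", data=np.array(responses.voxel_ids, dtype=sd))
        f.create_dataset(
            "roi_labels",
            data=np.array([responses.roi_labels[v] for v in responses.voxel_ids],
                          dtype=sd),
        )


def read_responses_hdf5(path: str | Path) -> VoxelResponseMatrix:
    with h5py.File(path, "r") as f:
        dec = lambda arr: [s.decode() if isinstance(s, bytes) else str(s)
                           for s in arr[()]]
        vox = dec(f["voxel_ids"])
        rois = dec(f["roi_labels"])
        return VoxelResponseMatrix(
            f["responses"][()], vox, dict(zip(vox, rois)), dec(f["stimulus_ids"])
        )
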