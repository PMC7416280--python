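"""Layer-indexed feature extraction: a toy hierarchy and an adapter.

Two routes produce a :class:`~voxencode.containers.FeatureMatrixSet` from
stimulus images:

* :func:`extract_toy_features` — a small, fixed convolution + rectification
  + max-pooling stack whose kernels are seed-determined constants.  It
  exists so the pipeline can be exercised end-to-end on images without any
  pretrained network, and mirrors the depth structure (conv → ReLU → pool)
  of the real extractors.
* :func:`adapt_external_features` — consumes per-layer arrays exported by
  any external extractor (e.g. a pretrained classification or segmentation
  network), validates them against the stimulus list, optionally applies
  spatial max-pooling, and flattens feature maps in a fixed
  (channel, row, column) row-major order so handoffs are reproducible.

Flattening is bijective (:func:`unflatten_map` inverts :func:`flatten_map`)
and pooling acts per stimulus, so reordering stimuli commutes with both.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy.signal import correlate2d

from .containers import FeatureMatrixSet, LayerSpec
from .exceptions import DataShapeError, InputDataError

FLATTEN_ORDER = "channel,row,column"

_TOY_KERNEL_SEED = 1729  # fixed: the toy stack is a constant of the package
_TOY_CHANNELS = 4
_TOY_KERNEL = 2


def load_images(paths: Iterable[str | Path]) -> list[np.ndarray]:
    """Load images as 2-D grayscale float arrays in [0, 1]."""
    out = []
    for p in paths:
        try:
            with Image.open(p) as im:
                out.append(np.asarray(im.convert("L"), dtype=np.float64) / 255.0)
        except (OSError, UnidentifiedImageError) as exc:
            raise InputDataError(f"cannot read image {p}: {exc}") from exc
    return out


def flatten_map(fmap: np.ndarray) -> np.ndarray:
    """Flatten a (channels, rows, cols) map row-major into one vector."""
    if fmap.ndim == 2:
        fmap = fmap[None]
    if fmap.ndim != 3:
        raise DataShapeError("feature map must be 2-D or 3-D")
    return fmap.reshape(-1)


def unflatten_map(vec: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`flatten_map` for a known (C, H, W) shape."""
    return np.asarray(vec).reshape(shape)


def max_pool(fmap: np.ndarray, factor: int) -> np.ndarray:
    """Block maxima over the spatial axes of a (C, H, W) or (H, W) map.

    Trailing rows/columns that do not fill a block are dropped, as in
    standard valid-mode pooling.
    """
    if factor < 1:
        raise DataShapeError("pool factor must be >= 1")
    if factor == 1:
        return fmap
    squeeze = fmap.ndim == 2
    if squeeze:
        fmap = fmap[None]
    c, h, w = fmap.shape
    hh, ww = h // factor, w // factor
    if hh == 0 or ww == 0:
        raise DataShapeError(f"map {h}x{w} smaller than pool factor {factor}")
    blocks = fmap[:, : hh * factor, : ww * factor].reshape(
        c, hh, factor, ww, factor
    )
    pooled = blocks.max(axis=(2, 4))
    return pooled[0] if squeeze else pooled


def toy_kernels(n_layers: int, seed: int = _TOY_KERNEL_SEED) -> list[np.ndarray]:
    """The fixed per-layer kernel banks of the toy hierarchy."""
    rng = np.random.default_rng(seed)
    banks = []
    in_ch = 1
    for _ in range(n_layers):
        banks.append(
            rng.standard_normal((_TOY_CHANNELS, in_ch, _TOY_KERNEL, _TOY_KERNEL))
        )
        in_ch = _TOY_CHANNELS
    return banks


def _conv_relu_pool(stack: np.ndarray, bank: np.ndarray, pool: int = 2) -> np.ndarray:
    """One toy layer: valid cross-correlation, ReLU, then 2x2 max-pool
    (skipped when the map is too small)."""
    out_ch = bank.shape[0]
    h = stack.shape[1] - bank.shape[2] + 1
    w = stack.shape[2] - bank.shape[3] + 1
    if h < 1 or w < 1:
        raise DataShapeError("image too small for the toy kernel stack")
    out = np.zeros((out_ch, h, w))
    for o in range(out_ch):
        for i in range(stack.shape[0]):
            out[o] += correlate2d(stack[i], bank[o, i], mode="valid")
    out = np.maximum(out, 0.0)
    if out.shape[1] >= pool and out.shape[2] >= pool:
        out = max_pool(out, pool)
    return out


def extract_toy_features(
    images: Sequence[np.ndarray] | Sequence[str | Path],
    n_layers: int = 4,
    stimulus_ids: Sequence[str] | None = None,
    kernels: Sequence[np.ndarray] | None = None,
    network_id: str = "toy",
) -> FeatureMatrixSet:
    """Run the fixed toy hierarchy and return per-layer feature matrices.

    ``images`` may be 2-D arrays (grayscale) or paths; all must share one
    spatial size.  ``kernels`` overrides the seed-determined banks (one
    (out_ch, in_ch, k, k) array per layer) — useful for hand-checkable
    fixtures.
    """
    if images and not isinstance(images[0], np.ndarray):
        arrays = load_images(images)  # type: ignore[arg-type]
    else:
        arrays = [np.asarray(a, dtype=np.float64) for a in images]  # type: ignore[union-attr]
    if not arrays:
        raise InputDataError("no images given")
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.ndim != 2:
            raise InputDataError(f"image {i} is not a 2-D grayscale array")
        if a.shape != shape:
            raise InputDataError(
                f"image {i} has size {a.shape}, expected {shape}"
            )
    banks = list(kernels) if kernels is not None else toy_kernels(n_layers)
    if len(banks) != n_layers:
        raise DataShapeError(f"{len(banks)} kernel banks for {n_layers} layers")
    if stimulus_ids is None:
        stimulus_ids = [f"stim{i:05d}" for i in range(len(arrays))]

    per_layer_rows: list[list[np.ndarray]] = [[] for _ in range(n_layers)]
    for a in arrays:
        stack = a[None]
        for li, bank in enumerate(banks):
            stack = _conv_relu_pool(stack, bank)
            per_layer_rows[li].append(flatten_map(stack))
    entries = {
        LayerSpec(network_id=network_id, layer_index=li + 1, layer_name=f"conv{li + 1}"):
            np.vstack(rows)
        for li, rows in enumerate(per_layer_rows)
    }
    return FeatureMatrixSet(entries, stimulus_ids)


def adapt_external_features(
    raw: Sequence[np.ndarray],
    specs: Sequence[LayerSpec],
    stimulus_ids: Sequence[str],
) -> FeatureMatrixSet:
    """Validate, optionally pool, and flatten externally extracted arrays.

    ``raw[i]`` holds layer ``specs[i]`` for all stimuli: either an already
    flat (stimuli × dims) matrix or a (stimuli, channels, rows, cols) map
    stack.  When ``specs[i].pooled`` is set, spatial max-pooling with
    ``pool_factor`` is applied before flattening.  This function never
    invokes a network itself.
    """
    if len(raw) != len(specs):
        raise DataShapeError(f"{len(raw)} arrays but {len(specs)} layer specs")
    entries: dict[LayerSpec, np.ndarray] = {}
    n = len(stimulus_ids)
    for arr, spec in zip(raw, specs):
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape[0] != n:
            raise DataShapeError(
                f"{spec}: {arr.shape[0]} rows but {n} stimulus ids"
            )
        if arr.ndim == 2:
            flat = arr
        elif arr.ndim == 4:
            if spec.pooled:
                arr = np.stack([max_pool(m, spec.pool_factor) for m in arr])
            flat = arr.reshape(n, -1)
        else:
            raise DataShapeError(
                f"{spec}: expected 2-D (flat) or 4-D (stimuli,C,H,W) array, "
                f"got ndim={arr.ndim}"
            )
        entries[spec] = flat
    return FeatureMatrixSet(entries, stimulus_ids)
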