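"""End-to-end study orchestration: data → encoding → fusion → evaluation.

:func:`run_study` runs the whole analysis and writes a result bundle to
disk: the feature container (HDF5), per-model accuracy tables, pairwise
model comparisons, per-ROI layer-contribution tables with a monotone-trend
test, an optional selection-fraction sweep, and a provenance file
recording every parameter and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .containers import DEFAULT_ROIS, FeatureMatrixSet, VoxelResponseMatrix
from .encoding import VoxelEncodingModel, fit_layerwise, select_best_layer, split_stimuli
from .evaluate import (
    PredictionResult,
    advantage_test,
    compare_models,
    layer_contribution,
    mann_kendall,
    voxel_significance,
)
from .exceptions import ConfigurationError, VoxencodeError
from .fusion import DEFAULT_FRACTION, fit_decoders, fused_encode, rank_and_select, selection_sweep
from .io import (
    read_features_hdf5,
    read_responses_text,
    write_features_hdf5,
    write_responses_text,
    write_roi_table,
)
from .synthetic import SyntheticConfig, generate_study

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Parameters of one study run.

    The statistical defaults are the study's: sparsity K = 100, a
    500-stimulus test set, top-10% feature selection, 1000 permutations,
    alpha 0.001 for voxel significance and 0.05 for model advantage,
    correlation threshold 0.13 for the comparison scatter.
    """

    out_dir: str | Path = "results/run"
    synthetic: bool = True
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    features_path: str | Path | None = None
    responses_path: str | Path | None = None
    roi_path: str | Path | None = None
    K: int = 100
    K_decode: int | None = None
    test_size: int = 500
    fraction: float = DEFAULT_FRACTION
    n_perm: int = 1000
    alpha_voxel: float = 0.001
    alpha_advantage: float = 0.05
    comparison_threshold: float = 0.13
    sweep_fractions: tuple[float, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if not self.synthetic:
            missing = [
                n for n, p in [("features_path", self.features_path),
                               ("responses_path", self.responses_path),
                               ("roi_path", self.roi_path)]
                if p is None
            ]
            if missing:
                raise ConfigurationError(
                    f"non-synthetic run requires {', '.join(missing)}"
                )
        if self.K < 1:
            raise ConfigurationError("K must be >= 1")
        if not 0 < self.fraction <= 1:
            raise ConfigurationError("fraction must be in (0, 1]")


def _load_inputs(cfg: RunConfig) -> tuple[FeatureMatrixSet, VoxelResponseMatrix, int]:
    """Returns (features, responses, test_size)."""
    if cfg.synthetic:
        synth = dataclasses.replace(cfg.synth, seed=cfg.seed)
        features, responses, _ = generate_study(synth)
        return features, responses, synth.n_test
    features = read_features_hdf5(cfg.features_path)
    responses = read_responses_text(cfg.responses_path, cfg.roi_path)
    return features, responses, cfg.test_size


def _network_subset(features: FeatureMatrixSet, network: str) -> FeatureMatrixSet:
    return FeatureMatrixSet(
        {s: features[s] for s in features.layers if s.network_id == network},
        features.stimulus_ids,
    )


def _accuracy_table(
    name: str,
    model: VoxelEncodingModel,
    responses: VoxelResponseMatrix,
    significant: np.ndarray,
) -> pd.DataFrame:
    rows = []
    for i, v in enumerate(model.voxel_ids):
        fit = model.voxels[v]
        rows.append(
            dict(voxel_id=v, roi=responses.roi_labels[v], model=name,
                 best_layer=str(fit.best_layer), accuracy=fit.test_accuracy,
                 significant=bool(significant[i]))
        )
    return pd.DataFrame(rows)


def _layer_trend(model: VoxelEncodingModel, responses: VoxelResponseMatrix) -> dict:
    """Mean best-layer depth per ROI (canonical ROI order) plus the
    Mann-Kendall trend along that sequence."""
    rois = [r for r in DEFAULT_ROIS if r in responses.rois]
    rois += [r for r in responses.rois if r not in rois]
    means = []
    for roi in rois:
        vox = responses.voxels_in(roi)
        means.append(
            float(np.mean([model.voxels[v].best_layer.layer_index for v in vox]))
        )
    out = {"rois": rois, "mean_best_layer": means}
    if len(means) >= 4:
        mk = mann_kendall(np.asarray(means))
        out.update({"mk_S": mk.S, "mk_z": mk.z, "mk_p": mk.p_value})
    return out


def run_study(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a summary dict and writes the bundle.

    Any stage failure aborts with an error naming the stage; files written
    before the failure are left in place and listed as partial in the log.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("voxencode")
    root.addHandler(handler)
    stage = "setup"
    try:
        stage = "data"
        features, responses, test_size = _load_inputs(cfg)
        write_features_hdf5(features, out / "features.h5")
        write_responses_text(responses, out / "responses.tsv")
        write_roi_table(responses.roi_labels, out / "roi_labels.tsv")

        stage = "split"
        train_ids, test_ids = split_stimuli(
            features.stimulus_ids, test_size=test_size, seed=cfg.seed
        )
        r_test = responses.subset_stimuli(test_ids)

        stage = "encode"
        rng = np.random.default_rng(cfg.seed + 1)
        models: dict[str, VoxelEncodingModel] = {}
        for net in features.networks:
            sub = _network_subset(features, net)
            fits = fit_layerwise(sub, responses, train_ids, K=cfg.K)
            models[net] = select_best_layer(fits, sub, responses, test_ids)
            logger.info("encoded network %s", net)

        stage = "fuse"
        decoders = fit_decoders(
            responses, features, train_ids, K=cfg.K_decode or cfg.K
        )
        ranking = rank_and_select(
            decoders, responses, features, test_ids, fraction=cfg.fraction
        )
        models["fused"] = fused_encode(
            features, responses, ranking, train_ids, test_ids, K=cfg.K
        )
        ranking.table.to_csv(out / "decodability.tsv", sep="\t", index=False,
                             float_format=FLOAT_FORMAT)

        stage = "evaluate"
        results: dict[str, PredictionResult] = {}
        acc_tables = []
        trends = {}
        for name, model in models.items():
            pred = model.predict(features, test_ids)
            res = PredictionResult(pred, r_test.values, voxel_ids=responses.voxel_ids)
            results[name] = res
            sig = voxel_significance(
                res, n_perm=cfg.n_perm, alpha=cfg.alpha_voxel, seed=rng
            )
            acc_tables.append(_accuracy_table(name, model, responses, sig.significant))
            layer_contribution(model, responses.roi_labels).to_csv(
                out / f"layer_contribution_{name}.tsv", sep="\t",
                float_format=FLOAT_FORMAT,
            )
            trends[name] = _layer_trend(model, responses)
        acc = pd.concat(acc_tables, ignore_index=True)
        acc.to_csv(out / "accuracy.tsv", sep="\t", index=False,
                   float_format=FLOAT_FORMAT)
        for name in models:
            acc[acc["model"] == name].to_csv(
                out / f"accuracy_{name}.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
        comparison = compare_models(
            results, responses.roi_labels, threshold=cfg.comparison_threshold,
            n_perm=cfg.n_perm, alpha=cfg.alpha_advantage, seed=rng,
        )
        comparison.to_csv(out / "comparison.tsv", sep="\t", index=False,
                          float_format=FLOAT_FORMAT)

        sweep_table = None
        if cfg.sweep_fractions:
            stage = "sweep"
            sweep_table = selection_sweep(
                list(cfg.sweep_fractions), features, responses, train_ids,
                test_ids, K_encode=cfg.K, K_decode=cfg.K_decode or cfg.K,
            )
            sweep_table.to_csv(out / "sweep.tsv", sep="\t", index=False,
                               float_format=FLOAT_FORMAT)

        stage = "provenance"
        prov = {
            "package_version": __version__,
            "config": _config_dict(cfg),
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "networks": features.networks,
            "models": list(models),
            "layer_trends": trends,
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2))
        logger.info("study complete: %s", out)
        return {
            "models": models,
            "results": results,
            "comparison": comparison,
            "accuracy": acc,
            "trends": trends,
            "sweep": sweep_table,
            "out_dir": out,
        }
    except Exception as exc:
        logger.error("stage %r failed: %s (partial outputs in %s)", stage, exc, out)
        raise VoxencodeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["out_dir"] = str(d["out_dir"])
    for key in ("features_path", "responses_path", "roi_path"):
        if d[key] is not None:
            d[key] = str(d[key])
    d["synth"]["voxels_per_roi"] = dict(d["synth"]["voxels_per_roi"])
    d["sweep_fractions"] = list(d["sweep_fractions"])
    return d
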