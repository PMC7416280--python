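"""Decodability ranking, top-fraction selection, fused encoding, sweep."""

import dataclasses
import math

import numpy as np
import pytest

from voxencode.containers import FeatureMatrixSet, VoxelResponseMatrix
from voxencode.encoding import fit_layerwise, select_best_layer
from voxencode.exceptions import ConfigurationError
from voxencode.fusion import (
    fit_decoders,
    fused_encode,
    rank_and_select,
    selection_sweep,
)
from voxencode.synthetic import SyntheticConfig, generate_features


def _shared_support_responses(feats, specs_and_dims, n_per_roi, snr, rng,
                              rois=("EarlyVis", "PPA")):
    """Voxels whose true signal lives in a fixed, shared set of dimensions
    of one layer each — the decodable-subset scenario."""
    voxel_ids, roi_labels, cols = [], {}, []
    for roi, (spec, dims) in zip(rois, specs_and_dims):
        for j in range(n_per_roi):
            vid = f"{roi}_v{j:03d}"
            voxel_ids.append(vid)
            roi_labels[vid] = roi
            w = rng.uniform(0.5, 2.0, len(dims)) * rng.choice([-1.0, 1.0], len(dims))
            signal = feats[spec][:, dims] @ w
            noise = rng.normal(0, signal.std() / math.sqrt(snr), len(signal))
            cols.append(signal + noise)
    return VoxelResponseMatrix(
        np.column_stack(cols), voxel_ids, roi_labels, feats.stimulus_ids
    )


class TestDecoders:
    def test_noiseless_copy_dimension_is_perfectly_decodable(self):
        cfg = SyntheticConfig(n_train=60, n_test=20, layers_per_network=1,
                              dims_per_layer=8, voxels_per_roi={"LOC": 5},
                              true_sparsity=1, seed=2)
        feats = generate_features(cfg)
        spec = feats.layers[0]
        # voxel 0 IS feature dimension 3 (plus nothing else)
        vals = np.column_stack([feats[spec][:, 3],
                                np.random.default_rng(0).standard_normal(80)])
        resp = VoxelResponseMatrix(vals, ["v0", "v1"],
                                   {"v0": "LOC", "v1": "LOC"},
                                   feats.stimulus_ids)
        decs = fit_decoders(resp, feats, feats.stimulus_ids[:60], K=1)
        model = decs[spec].models[3]
        assert model.residual_norm < 1e-6

    def test_decoder_cardinality_is_layers_times_dims(self, two_net_study):
        feats, resp, _ = two_net_study
        train = feats.stimulus_ids[:100]
        decs = fit_decoders(resp, feats, train, K=2)
        assert len(decs) == 4
        assert all(len(d.models) == 30 for d in decs.values())

    def test_planted_voxel_dependence_support_recovered(self):
        """A feature dimension built from two voxels is decoded on exactly
        those voxels (checked against the exhaustive 2-subset oracle)."""
        from tests.test_romp import exhaustive_support

        rng = np.random.default_rng(8)
        cfg = SyntheticConfig(n_train=80, n_test=20, layers_per_network=1,
                              dims_per_layer=4, voxels_per_roi={"OPA": 12},
                              true_sparsity=1, seed=8)
        feats = generate_features(cfg)
        spec = feats.layers[0]
        resp_vals = rng.standard_normal((100, 12))
        F = feats[spec].copy()
        F[:, 0] = 1.3 * resp_vals[:, 2] - 0.9 * resp_vals[:, 7]
        feats2 = FeatureMatrixSet({spec: F}, feats.stimulus_ids)
        resp = VoxelResponseMatrix(
            resp_vals, [f"v{i}" for i in range(12)],
            {f"v{i}": "OPA" for i in range(12)}, feats.stimulus_ids,
        )
        train = feats.stimulus_ids[:80]
        decs = fit_decoders(resp, feats2, train, K=2)
        model = decs[spec].models[0]
        Z = decs[spec].design.values[:, :-1]
        y = F[:80, 0]
        assert set(model.support.tolist()) == {2, 7}
        assert set(model.support.tolist()) == exhaustive_support(Z, y, 2)


class TestRankAndSelect:
    def _tiny_ranking(self, n_dims, fraction, n_vox=6, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(50)]
        spec = next(iter(generate_features(
            SyntheticConfig(n_train=40, n_test=10, layers_per_network=1,
                            dims_per_layer=4, voxels_per_roi={"LOC": 1},
                            true_sparsity=1)
        ).layers))
        feats = FeatureMatrixSet({spec: rng.standard_normal((50, n_dims))}, ids)
        resp = VoxelResponseMatrix(
            rng.standard_normal((50, n_vox)), [f"v{i}" for i in range(n_vox)],
            {f"v{i}": "LOC" for i in range(n_vox)}, ids,
        )
        decs = fit_decoders(resp, feats, ids[:40], K=1)
        return rank_and_select(decs, resp, feats, ids[40:], fraction)

    @pytest.mark.parametrize("n_dims,fraction,expected",
                             [(40, 0.10, 4), (25, 0.10, 3), (7, 0.10, 1),
                              (40, 1.0, 40)])
    def test_selected_count_is_ceiling_of_fraction(self, n_dims, fraction, expected):
        ranking = self._tiny_ranking(n_dims, fraction)
        (spec,) = ranking.layers
        assert ranking.selected_dims(spec).size == expected

    def test_ranks_are_a_permutation_ordered_by_correlation(self):
        ranking = self._tiny_ranking(20, 0.25)
        t = ranking.table.sort_values("rank")
        assert sorted(t["rank"]) == list(range(1, 21))
        corr = t["decode_correlation"].to_numpy()
        assert np.all(np.diff(corr) <= 1e-12)

    def test_selection_is_monotone_in_fraction(self):
        r_small = self._tiny_ranking(30, 0.1, seed=4)
        r_big = self._tiny_ranking(30, 0.5, seed=4)
        (spec,) = r_small.layers
        assert set(r_small.selected_dims(spec)) <= set(r_big.selected_dims(spec))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            self._tiny_ranking(10, 0.0)

    def test_planted_decodable_dims_outrank_noise(self):
        """Dimensions that drive voxel responses are ranked above pure-noise
        dimensions in >=95% of cases over 20 seeds (snr = 4)."""
        top_hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            cfg = SyntheticConfig(n_train=120, n_test=60, layers_per_network=1,
                                  dims_per_layer=30, voxels_per_roi={"LOC": 10},
                                  true_sparsity=1, seed=seed)
            feats = generate_features(cfg)
            spec = feats.layers[0]
            planted = [0, 1, 2, 3, 4]
            resp = _shared_support_responses(
                feats, [(spec, planted)], 10, 4.0, rng, rois=("LOC",)
            )
            train = feats.stimulus_ids[:120]
            test = feats.stimulus_ids[120:]
            decs = fit_decoders(resp, feats, train, K=3)
            ranking = rank_and_select(decs, resp, feats, test, 5 / 30)
            selected = set(ranking.selected_dims(spec).tolist())
            top_hits += len(selected & set(planted))
            total += len(planted)
        assert top_hits / total >= 0.95


class TestFusedEncode:
    def test_full_selection_reduces_to_plain_encoding(self, two_net_study):
        feats, resp, _ = two_net_study
        train = feats.stimulus_ids[:100]
        test = feats.stimulus_ids[100:]
        decs = fit_decoders(resp, feats, train, K=2)
        ranking = rank_and_select(decs, resp, feats, test, fraction=1.0)
        fused = fused_encode(feats, resp, ranking, train, test, K=3)
        plain_fits = fit_layerwise(feats, resp, train, K=3)
        plain = select_best_layer(plain_fits, feats, resp, test)
        for v in resp.voxel_ids:
            assert fused.voxels[v].best_layer == plain.voxels[v].best_layer
            assert fused.voxels[v].test_accuracy == pytest.approx(
                plain.voxels[v].test_accuracy
            )
            assert np.array_equal(
                np.sort(fused.voxels[v].model.support),
                np.sort(plain.voxels[v].model.support),
            )

    def test_single_network_fusion_stays_within_that_network(self, small_study):
        feats, resp, _ = small_study
        train = feats.stimulus_ids[:100]
        test = feats.stimulus_ids[100:]
        decs = fit_decoders(resp, feats, train, K=2)
        ranking = rank_and_select(decs, resp, feats, test, fraction=0.5)
        fused = fused_encode(feats, resp, ranking, train, test, K=3)
        assert {f.best_layer.network_id for f in fused.voxels.values()} == {"netA"}

    def test_fused_model_tracks_the_better_single_network(self):
        """With shared decodable supports in both networks, the fused model's
        accuracy stays within 0.05 (median) of the better single network."""
        cfg = SyntheticConfig(n_train=150, n_test=80, layers_per_network=2,
                              dims_per_layer=40, n_networks=2,
                              voxels_per_roi={"EarlyVis": 10, "PPA": 10},
                              true_sparsity=4, seed=13)
        feats = generate_features(cfg)
        rng = np.random.default_rng(13)
        specA = [s for s in feats.layers if s.network_id == "netA"][1]
        specB = [s for s in feats.layers if s.network_id == "netB"][0]
        resp = _shared_support_responses(
            feats, [(specA, [0, 1, 2, 3]), (specB, [5, 6, 7, 8])], 10, 4.0, rng
        )
        train = feats.stimulus_ids[:150]
        test = feats.stimulus_ids[150:]
        singles = {}
        for net in ("netA", "netB"):
            sub = FeatureMatrixSet(
                {s: feats[s] for s in feats.layers if s.network_id == net},
                feats.stimulus_ids,
            )
            fits = fit_layerwise(sub, resp, train, K=4)
            singles[net] = select_best_layer(fits, sub, resp, test)
        decs = fit_decoders(resp, feats, train, K=4)
        ranking = rank_and_select(decs, resp, feats, test, fraction=0.10)
        fused = fused_encode(feats, resp, ranking, train, test, K=4)
        gaps = [
            max(singles["netA"].voxels[v].test_accuracy,
                singles["netB"].voxels[v].test_accuracy)
            - fused.voxels[v].test_accuracy
            for v in resp.voxel_ids
        ]
        assert np.median(gaps) <= 0.05


class TestSelectionSweep:
    def _sweep_inputs(self, seed):
        cfg = SyntheticConfig(n_train=120, n_test=60, layers_per_network=2,
                              dims_per_layer=50, voxels_per_roi={"LOC": 10},
                              true_sparsity=5, seed=seed)
        feats = generate_features(cfg)
        rng = np.random.default_rng(1000 + seed)
        # 10% of dimensions informative per layer (shared across voxels)
        resp = _shared_support_responses(
            feats, [(feats.layers[0], [0, 1, 2, 3, 4]),
                    (feats.layers[1], [10, 11, 12, 13, 14])],
            5, 4.0, rng, rois=("LOC", "LOC2"),
        )
        return feats, resp

    def test_single_fraction_yields_one_row_per_roi(self):
        feats, resp = self._sweep_inputs(0)
        train, test = feats.stimulus_ids[:120], feats.stimulus_ids[120:]
        table = selection_sweep([0.2], feats, resp, train, test, K_encode=5)
        assert len(table) == len(resp.rois)
        assert set(table.columns) >= {"fraction", "roi", "mean_accuracy"}

    def test_sweep_is_deterministic(self):
        feats, resp = self._sweep_inputs(1)
        train, test = feats.stimulus_ids[:120], feats.stimulus_ids[120:]
        t1 = selection_sweep([0.1, 0.5], feats, resp, train, test, K_encode=5)
        t2 = selection_sweep([0.1, 0.5], feats, resp, train, test, K_encode=5)
        assert t1.equals(t2)

    def test_empty_fraction_list_rejected(self, small_study):
        feats, resp, _ = small_study
        with pytest.raises(ConfigurationError):
            selection_sweep([], feats, resp, feats.stimulus_ids[:100],
                            feats.stimulus_ids[100:], K_encode=3)

    def test_matched_fraction_beats_too_few_and_too_many(self):
        """With 10% informative dimensions, selecting 10% outperforms both
        1% (information lost) and 100% (noise added), averaged over seeds."""
        accs = {0.02: [], 0.1: [], 1.0: []}
        for seed in range(6):
            feats, resp = self._sweep_inputs(seed)
            train, test = feats.stimulus_ids[:120], feats.stimulus_ids[120:]
            table = selection_sweep(list(accs), feats, resp, train, test,
                                    K_encode=5)
            for frac in accs:
                accs[frac].append(
                    table[table["fraction"] == frac]["mean_accuracy"].mean()
                )
        assert np.mean(accs[0.1]) >= np.mean(accs[0.02])
        assert np.mean(accs[0.1]) >= np.mean(accs[1.0])
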