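import numpy as np
import pytest

from voxencode.synthetic import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """One-network study small enough for fast unit tests."""
    return SyntheticConfig(
        n_train=150,
        n_test=60,
        layers_per_network=3,
        dims_per_layer=40,
        n_networks=1,
        voxels_per_roi={"EarlyVis": 8, "PPA": 8},
        true_sparsity=4,
        snr=4.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_study(small_cfg)


@pytest.fixture(scope="session")
def two_net_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        n_train=150,
        n_test=60,
        layers_per_network=2,
        dims_per_layer=30,
        n_networks=2,
        voxels_per_roi={"EarlyVis": 6, "LOC": 6},
        true_sparsity=3,
        snr=4.0,
        seed=21,
    )


@pytest.fixture(scope="session")
def two_net_study(two_net_cfg):
    return generate_study(two_net_cfg)


def split_by_count(stimulus_ids, n_train):
    """Deterministic first-n/rest split used where randomness is irrelevant."""
    return list(stimulus_ids[:n_train]), list(stimulus_ids[n_train:])
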