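"""Shared configuration of the desk-scale synthetic study.

All drivers regenerate the same data deterministically from this config,
so each script can be run on its own; outputs land under ``results/``.
"""

from pathlib import Path

from voxencode.synthetic import SyntheticConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: two networks x 4 layers x 200 dims, 250 voxels, 10-sparse truth, snr 4
STUDY = SyntheticConfig(
    n_train=300,
    n_test=100,
    layers_per_network=4,
    dims_per_layer=200,
    n_networks=2,
    true_sparsity=10,
    snr=4.0,
    seed=2026,
)

K_SPARSITY = 10  # encoding / decoding sparsity budget at this scale
N_PERM = 1000
SWEEP_FRACTIONS = (0.02, 0.05, 0.10, 0.30, 1.00)
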