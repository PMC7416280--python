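#!/usr/bin/env python
"""Model comparison, layer contributions and the hierarchy trend test.

Re-runs the full study (both single-network models plus the fused model),
compares them pairwise with the sign-flip advantage permutation test over
above-threshold voxels, tabulates which layer each ROI's voxels prefer,
and tests the ROI sequence for a monotone trend in best-layer depth.
"""

import pandas as pd

from study_config import K_SPARSITY, N_PERM, RESULTS, STUDY
from voxencode.pipeline import FLOAT_FORMAT, RunConfig, run_study


def main() -> None:
    cfg = RunConfig(
        out_dir=RESULTS / "study",
        synth=STUDY,
        K=K_SPARSITY,
        n_perm=N_PERM,
        seed=STUDY.seed,
    )
    bundle = run_study(cfg)

    comparison = bundle["comparison"]
    print("pairwise advantages over above-threshold voxels:")
    for _, row in comparison.iterrows():
        tag = "SIGNIFICANT" if row["significant"] else "n.s."
        print(f"  {row['roi']:>9}: {row['model_a']} vs {row['model_b']}: "
              f"{row['advantage_pct']:.1f}% (critical "
              f"{row['advantage_threshold_pct']:.1f}%, p={row['p_value']:.3f}, {tag})")

    print("\nmean best-layer depth per ROI (Mann-Kendall trend):")
    for name, trend in bundle["trends"].items():
        seq = ", ".join(f"{r}:{m:.2f}"
                        for r, m in zip(trend["rois"], trend["mean_best_layer"]))
        mk = (f"S={trend['mk_S']}, p={trend['mk_p']:.3f}"
              if "mk_S" in trend else "n/a")
        print(f"  {name}: {seq}  ({mk})")
    print(f"\nbundle written to {RESULTS / 'study'}")


if __name__ == "__main__":
    main()
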