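# Methods

## The model

`voxencode` implements voxel-wise *linearized encoding* of visual stimuli:
a fixed nonlinear feature transform (the layers of a convolutional
network) followed by a learned linear map from one layer's features to
each fMRI voxel's response. For voxel responses `y` over `m` training
stimuli and an `m × (n+1)` design `X` (one layer's features plus a
constant column),

    y = X w + ε,

with `n ≫ m`, so the least-squares problem is ill-posed and `w` is
constrained to be sparse: `min ‖w‖₀ subject to Xw = y`, approximated
greedily. The package covers five stages:

1. **Sparse fit (ROMP).** Regularized orthogonal matching pursuit per
   voxel and layer (see below).
2. **Best-layer selection.** Every layer is fit separately; on held-out
   stimuli the layer whose prediction has the highest Pearson correlation
   with the measured response becomes that voxel's *best feature layer*
   (ties go to the shallower layer). The per-voxel (best layer, sparse
   model) pairs form the voxel-wise encoding model.
3. **Decodability-based fusion.** The regression is inverted — each
   feature dimension is regressed from the voxel responses with the same
   sparse machinery — and dimensions are ranked per layer by the
   correlation between decoded and real values on held-out stimuli
   (*decodability*). The top `ceil(fraction · n_ℓ)` dimensions of every
   layer of both networks (default fraction 0.10) are retained and the
   encoding re-run on the union, letting each voxel choose its best layer
   across networks.
4. **Permutation statistics.** Per-voxel significance: the pairing of
   predicted and measured test responses is shuffled (default 1000 times)
   and the observed correlation compared with the empirical
   `1 − α` null quantile (α = 0.001). For a 500-stimulus test set this
   critical value sits near `z₀.₉₉₉/√(n−1) ≈ 0.138`. Model advantage: the
   percentage of voxels one model wins (ties split evenly), tested by
   flipping each voxel's pair with probability ½; the α = 0.05 critical
   advantage follows the binomial closed form `50 + z₀.₉₅·50/√N` percent
   (≈ 53% at N ≈ 750).
5. **Layer-contribution trends.** Per ROI, the fraction of voxels whose
   best layer is each network depth, plus a tie-corrected Mann-Kendall
   test of monotone trend in mean best-layer depth along the ROI sequence
   EarlyVis → LOC → OPA → PPA → RSC.

## The ROMP implementation

Columns are standardized to mean 0, sd 1 on the training rows (selection
by correlation is scale-sensitive); the same statistics transform held-out
rows. The intercept is always refit and never counts toward the sparsity
budget `K`.

Each iteration correlates the residual with all unused columns, sorts the
top-`K` magnitudes, and keeps the contiguous *comparable* run — largest
magnitude at most twice the smallest — with maximal energy (ties prefer
the run containing the overall largest magnitude, then the earliest run;
equal magnitudes order by ascending column index). The run joins the
support and the weights are refit by least squares.

Stopping and the final cap: the pursuit runs until the residual norm falls
below `tol` (default `1e-6·‖y‖`) or the support reaches an exploration cap
of `min(3K, m − 2, n)`. Group selection needs room beyond `K`: capping the
support at exactly `K` lets one comparable group fill the budget with
spurious columns before refitting can correct them, and on noiseless
3-sparse Gaussian designs with m = 20 that variant agrees with the
exhaustive-subset oracle in only ~21% of instances. With exploration to
`3K` agreement is 99%, and the rate is flat out to `6K`, so the bound is
not delicate (the published analysis of the algorithm similarly lets the
support exceed the sparsity level before truncation). If the final support
exceeds `K`, the `K` largest-magnitude refit weights are kept and refit
once more, so a sufficiently informative design yields exactly `K` nonzero
coefficients — with the study default `K = 100`, exactly 100.

Rank-deficient refits drop the most recently added column with a warning.
A constant response yields an empty support and an intercept-only model.
Residual norms are non-increasing across pursuit iterations (the final
truncation refit may sit above the last exploration residual; the history
records both).

## Synthetic data

The generator produces the statistical structure the analysis assumes,
with known ground truth, so every stage is testable offline:

- **Features.** Layer 1 of each network is i.i.d. standard normal
  (stimuli × dims). Layer ℓ>1 is `α·(Xℓ₋₁M) + √(1−α²)·fresh` with a fixed
  random mixing matrix `M` scaled to preserve unit variance. Adjacent
  layers therefore share `α² = 25%` of their variance (default mixing
  α = 0.5), giving a hierarchy in which layer confusion is possible but
  the true layer remains identifiable — loosely mimicking the correlation
  between consecutive CNN layers without claiming image statistics.
- **Responses.** Each voxel draws one true layer (uniformly, or per a
  fixed ROI→layer map), a support of `true_sparsity` dimensions (default
  10) and signed weights with magnitudes uniform in [0.5, 2] — well
  separated from zero, the standard sparse-recovery benchmark regime.
  Noise is i.i.d. Gaussian with sd set from the realized signal sd so the
  signal-to-noise variance ratio equals `snr` (default 4; the true model's
  R² is `snr/(1+snr) = 0.8`). The i.i.d. Gaussian noise model is an
  assumption: real fMRI noise is temporally and spatially correlated.
- **Seeding.** One seed, split into named substreams (`features`,
  `mixing`, `ground_truth`, `noise`) in that fixed order; identical
  configurations are bit-identical.
- `support_pool_fraction` < 1 concentrates every support in the leading
  fraction of each layer's dimensions — the regime in which feature
  selection helps, used by the selection-sweep analysis.

What passing on this generator does **not** show: robustness to
correlated/non-Gaussian noise, to repeated-stimulus structure, to real CNN
feature statistics (heavy tails, strong within-layer correlation), or to
the far larger dimensionalities of real feature layers.

## Problem sizes and defaults

The statistical defaults mirror the study design: a 500-stimulus held-out
set from 5254 (`split_stimuli`), sparsity `K = 100`, top-10% selection,
1000 permutations, α = 0.001 (voxel) and 0.05 (advantage), comparison
threshold r = 0.13. The synthetic study itself is run desk-scale as the
package's own choice: 300 train / 100 test stimuli, 4 layers × 200
dimensions per network, 50 voxels in each of 5 ROIs, `K = 10` — large
enough for stable correlations and layer recovery, small enough that the
full analysis and test suite run in seconds to minutes on one CPU.

## Feature extraction

Real pretrained networks are deliberately outside the tested core. The
`features` module provides (a) a fixed toy hierarchy (seeded constant
kernels, valid cross-correlation → ReLU → 2×2 max-pool per layer) so the
pipeline can run end-to-end on images, and (b) an adapter that validates,
optionally max-pools (explicit, default off, recorded in the layer spec)
and flattens per-layer arrays exported by any external extractor.
Flattening order is fixed as (channel, row, column) row-major and is
bijective; pooling commutes with stimulus reordering.

## Numerical and design choices

- Best-layer selection uses the test set, replicating the study's
  procedure; this optimistically biases the reported accuracy of the
  *selection* step, which is why recovery tests score against ground truth
  rather than against that accuracy.
- Decodability is likewise computed on the held-out set.
- Pearson correlation of a constant vector is defined as 0 (logged), which
  keeps permutation loops total.
- Advantage ties contribute half a win to each model.
- Mann-Kendall uses the tie-corrected variance and a continuity-corrected
  two-sided normal approximation.
- No multiple-testing correction across voxels is applied by default,
  matching the study; per-voxel null quantiles are the default and a
  pooled-across-voxels null is available (one threshold for the map).
- Selection uses ceiling rounding so any nonempty layer keeps at least one
  dimension; a layer whose selection still comes out empty is excluded
  with a warning.
- `fit_layerwise` clamps `K` to a layer's width so aggressive selection
  fractions remain runnable.

## Known limitations

- The permutation threshold from 1000 shuffles at α = 0.001 interpolates
  between the two most extreme null values and is therefore noisy
  (roughly ±0.02 at n = 500); more permutations sharpen it.
- The greedy pursuit has no recovery guarantee at these undersampling
  ratios; the 99% oracle agreement is empirical, on Gaussian designs with
  well-separated weights.
- The toy feature hierarchy is a plumbing stand-in, not a model of any
  real network's representations.
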