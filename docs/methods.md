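# Methods

## The model

`landclust` performs cluster-level inference on statistical brain maps
without a cluster-forming threshold. The analysis operates on an
*activation landscape*: a 3D grid of `-log10(p)` values derived
voxel-wise from a statistical map (here a one-sample t-map across
subjects' contrast images). Three stages follow:

1. **Recursive decomposition.** The highest in-mask local maximum seeds
   a cluster that grows outward, never doubling back toward the peak
   (each step must strictly increase the Euclidean distance to the
   peak, in mm). Along each path the growth stops where the slope —
   the raw value difference per step — becomes *strictly more positive*
   than the previous step's slope: dropping off one hill's flank, the
   landscape must eventually turn upward toward the next hill, and that
   turning point is the cluster edge. Claimed voxels are removed; the
   procedure repeats from the next-highest remaining local maximum
   until no strict local maxima remain.

2. **Combination.** Secondary local maxima split one hill into a
   dominant cluster plus satellites. Two adjacent clusters, oriented
   (lower peak, higher peak), merge when

       PeaksDifference / (PeaksDifference + SmallerPeakToConnectingEdge)
           >= 1 - ProportionConnected

   with all three quantities measured on the lower-peaked cluster:
   the fraction of its edge voxels touching that specific neighbor,
   the absolute peak difference, and its peak height above the mean
   value of its edge voxels adjacent to the neighbor. A fully
   surrounded cluster always merges; a bump whose peak barely rises
   above its connecting flank merges easily; two peaks separated by a
   deep valley with little contact do not.

3. **Max-score permutation test.** Each cluster's *activation score* is
   the sum of its landscape values (height and extent jointly). Under
   the one-sample null, each subject's whole volume is multiplied by
   -1 with probability 0.5 — preserving spatial covariance while
   destroying any systematic group-level direction — and the entire
   pipeline is rerun; the whole-brain *maximum* cluster score is
   recorded per permutation. The significance criterion is the
   smallest observed null maximum with fewer than `alpha` of the null
   maxima above it; observed clusters scoring strictly above it are
   significant with family-wise error control at `alpha`. Corrected
   per-cluster p-values use the add-one estimator
   `(1 + #{null max >= score}) / (1 + n_permutations)`; at the boundary
   order statistic the strict score rule is authoritative.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `connectivity` | 26 | voxel neighborhood (6/18/26) for maxima, growth, edges, adjacency, and baseline components |
| `pre_threshold` | `None` | optional liberal p-value threshold restricting decomposition to supra-threshold voxels (see below) |
| `normalize_slope` | off | divide slopes by physical step length (mm); the default uses the raw per-step value difference |
| `tie_epsilon` | 0 | value differences below this count as ties in the local-maximum test (guard for quantized maps) |
| `two_sided` | on | contrast maps can be negative; one-sided maps are available |
| log base | 10 | fixed package-wide; cluster membership is invariant to the base (monotone), activation scores are not |
| `alpha` | 0.05 | family-wise error level of the max-score test |

Slope at the peak is defined as 0, so a first step is accepted iff
non-positive (neighbors of a strict maximum always are). "More
positive" is strict: constant slopes never stop growth. Equal-distance
neighbors are never visited (strict distance increase). The growth
frontier is ordered by (distance from peak, linear index) and each
voxel is decided once, at its first evaluation — this makes the
procedure fully deterministic; identical inputs give identical cluster
sets, and all pipelines are byte-reproducible under fixed seeds.

## The role of the liberal pre-threshold

With no pre-threshold the decomposition tiles the *entire* mask: every
in-mask voxel ends up in some cluster, because after each cluster is
removed the remaining available region exposes new local maxima. On a
fully tiled smoothed-noise landscape the combination criterion then
cascades: tiny floor clusters are fully surrounded (always absorbed),
absorption inflates the connected proportion of their neighbors, and a
much higher-peaked neighbor absorbs any moderately connected lower
cluster because a large peak difference drives the left-hand side of
the inequality toward 1. The measured fixed point on a 48^3 smoothed
noise map is a single whole-brain cluster — the "whole floor combined"
failure mode, under which cluster scores lose all spatial specificity.

A liberal pre-threshold (p = 0.05, i.e. landscape values above
`-log10(0.05) ~ 1.3`) changes the dynamics qualitatively rather than
just the cost: clusters become islands in unclaimed floor, most island
edge voxels border no other cluster, the connected proportion stays
small, and combination only merges genuine flank bumps within an
island. All simulation-study defaults therefore run with
`pre_threshold = 0.05`, applied *identically* to observed and permuted
maps (so the permutation null is exact); the core API default remains
fully threshold-free for landscapes whose structure supports it.
This threshold restricts where clusters may live but — unlike a
cluster-forming threshold — the clusters themselves are still defined
by the landscape's shape, and the statistic still pools height and
extent.

## The synthetic validation design

`SimulationScenario` defaults emulate a planted-effect group study: 32
subjects on a 48x48x48 grid of 2 mm voxels; per subject, white Gaussian
noise smoothed at 4 mm FWHM (sigma = FWHM / 2sqrt(2 ln 2) per axis),
standardized per volume to mean 0 / SD 1, plus a constant effect of 0.8
(contrast in noise-SD units, exact by construction thanks to the
rescale; `rescale_noise=False` reproduces the un-rescaled variant)
added over a fixed ellipsoidal region of 221 voxels (semi-axes 4.0,
3.8, 3.4 voxels) — the scale of a human amygdala, standing in for an
atlas-defined region so no atlas files are needed. The effect is added
*after* smoothing: the effect region is sharp-edged, only the noise is
smooth.

What this emulates — and what it does not: spatially correlated noise
with a contiguous homogeneous effect, one group, no inter-subject
anatomical variability, no physiological noise structure, stationary
smoothness, and a whole-grid mask about half the volume of a real 2 mm
brain mask. Passing tests therefore demonstrate the method's operating
characteristics (detection, specificity, family-wise error control)
under idealized fMRI-like conditions, not performance on any real
dataset.

The evaluation metrics pool over simulations: detection rate (>= 1
significant cluster containing >= 1 true-region voxel), cluster
specificity (fraction of pooled significant clusters intersecting the
region; the >= 1-voxel rule is the weakest reading, and per-cluster
overlap fractions are logged so stricter rules can be recomputed), and
voxel overlap (fraction of pooled significant-cluster voxels inside
the region). When no significant cluster exists the two specificity
metrics are reported missing, never 0.

### The fixed-threshold baseline

The comparison rule declares significant every connected component of
voxels with p < 0.005 and extent >= 20 voxels, with no whole-brain
correction. It thresholds a *one-sided* (positive contrast) p-map by
default — the convention in which this rule is applied to directional
t-contrasts (t > 2.74 at df 31); `baseline_two_sided=True` switches to
the two-sided map. Its false-positive content scales with search
volume and noise smoothness: on this 48^3 grid with 2-voxel-FWHM noise
it produces ~0.4 false components per simulation. The original
full-brain study this design emulates reported markedly lower baseline
specificity (52% of clusters, 67% of voxels in-region), implying ~1
false cluster per simulation with ~100 false voxels; reproducing that
false-positive *volume* requires the larger search volume and smoother
effective noise of a full-brain simulation, so at desk scale the
baseline's voxel overlap stays high even though its cluster
specificity clearly drops below the landscape method's. This is a
property of the scaled-down conditions, not of either method's
implementation.

## Numerical and design choices

* **Neighborhood:** the local-maximum definition ("all neighbors
  lower") is stated in-plane as 8 neighbors; for 3D grids the natural
  reading is the full 26-neighborhood, used everywhere by default and
  configurable to 6/18.
* **Distances** are physical (mm, via voxel size), compared as squared
  values; anisotropic voxels are respected.
* **Tie-breaks:** maxima are processed by (value desc, linear index
  asc); the growth frontier by (distance, linear index) with
  first-queued-parent-wins; merge passes process lower clusters by
  ascending peak (ties by ascending label), and among simultaneously
  qualifying neighbors the most connected wins (ties: higher peak,
  then smaller label). Each merge decision sees the updated labeling;
  passes repeat to a fixed point (each merge reduces the cluster count,
  so at most K-1 merges happen).
* **Zero-variance voxels** get t = 0 (flagged), never +/-inf: they
  carry no evidence and must not seed clusters. p-values are clipped at
  1e-300 so landscape values stay finite.
* **Degenerate combination case** (equal peaks meeting at peak level,
  0/0): merge — there is zero separation.
* **Identity permutation** is not forced into the null (flip vectors
  are i.i.d.); `include_identity=True` is available. The criterion uses
  the "fewer than alpha above" rule evaluated over observed null
  maxima; with n = 100 and alpha = 0.05 on distinct scores this sits at
  the 96th order statistic.
* **Permutation shortcut:** sign-flipping leaves squared data
  unchanged, so per-permutation t-maps are computed from a single
  matrix-vector product plus precomputed sums of squares; the test
  suite verifies exact agreement (to roundoff) with the naive
  flip-then-t route.
* **F-maps:** any non-negative `-log10(p)` grid can be supplied as a
  `StatLandscape`; only the one-sample t route is computed natively,
  and only the sign-flip permutation scheme is implemented.

## Problem sizes used in validation

The simulation studies in the test suite and acceptance script run 25
planted-effect simulations and 100 global-null simulations, each with
100 permutations at 48^3 — the study design at reduced simulation
count, chosen so the complete validation executes on a single CPU in
minutes. The oracle-equivalence checks run 1000 randomized landscapes
up to 7x7x3 against literal-rule reference implementations, and the
significance-criterion rule is checked against a brute-force scan on
10,000 random score vectors.

## Known limitations

* The threshold-free configuration is unsuitable for fully tiled noisy
  landscapes (see the pre-threshold section); it is intended for maps
  with genuine zero-floor structure or as a component in variations of
  the method.
* Only one-sample (sign-flip) permutation is built in; other designs
  require supplying per-permutation landscapes externally.
* Plateaus (exactly equal neighboring values) yield no strict local
  maxima; with continuous statistics this is measure-zero, and
  `tie_epsilon` exists for quantized maps.
* Scores depend on the log base (fixed at 10); inference validity does
  not, since the permutation null uses the same base.
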