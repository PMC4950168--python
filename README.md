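# landclust

Threshold-free, landscape-based cluster analysis for statistical brain
maps, with sign-flip permutation inference.

## The problem

Whole-brain voxel-wise testing of group fMRI contrasts faces a massive
multiple-comparisons problem; correcting per voxel devastates power.
Cluster-based methods test spatially contiguous sets of voxels instead,
but classically require the researcher to pick a cluster-forming
threshold — a choice that can strongly affect the results and invites
method-snooping. `landclust` defines clusters purely from the *shape*
of the activation landscape and controls the family-wise error rate by
permutation, so no cluster-forming threshold is ever chosen.

## The method

Given per-subject contrast maps, the voxel-wise one-sample t-map is
converted to an activation landscape `v(x) = -log10 p(x)`. Then:

1. **Recursive decomposition** — from the highest local maximum, a
   cluster grows outward (strictly away from the peak, in mm) and
   stops along each path where the slope turns upward: for a step
   u → w following prev → u, w joins iff
   `v(w) - v(u) <= v(u) - v(prev)`. Claimed voxels are removed and the
   next-highest remaining maximum seeds the next cluster.
2. **Combination** — adjacent clusters (lower, higher) merge when

   `PD / (PD + SP) >= 1 - PC`

   where, on the lower cluster: `PC` = fraction of its edge voxels
   touching that neighbor, `PD` = peak difference, `SP` = its peak
   height above the mean value of the edge voxels adjoining the
   neighbor. Bumps on a larger hill's flank are absorbed; genuinely
   separate peaks are not.
3. **Permutation test** — each cluster's activation score is the sum of
   its landscape values. Each subject's volume is sign-flipped with
   probability 0.5 (spatial covariance preserved, group effect
   destroyed), the pipeline reruns, and the whole-brain *maximum*
   score is recorded per permutation. Observed clusters scoring above
   the level exceeded by fewer than 5% of null maxima are significant
   with family-wise error control.

See `docs/methods.md` for assumptions, parameter details, and known
limitations — including why simulation-scale noise landscapes are run
with the liberal p = 0.05 pre-threshold.

## A worked example

`examples/02_group_inference.py` simulates 16 subjects on a 20x20x16
grid of 2 mm voxels with a spherical planted effect (effect size 1.2),
then runs the full analysis with 100 permutations:

```
clusters found: 78
significance criterion (5% of null max scores above): 89.6
 cluster  peak_x  peak_y  peak_z  peak_value  size      score  corrected_p  significant
       1      10       8       9    7.203979    41 170.546641     0.009901         True
       2      12      10       7    6.523044    53 201.682438     0.009901         True
significant voxels inside the planted region: 81 of 94
```

Of 78 landscape clusters, only the two covering the planted sphere
score above the permutation criterion (89.6); their corrected p-values
are 0.0099 = 1/(1+100), the smallest value 100 permutations can
resolve. 81 of their 94 voxels lie inside the true region.

The other examples show the decomposition/combination stages on a toy
landscape (`01_decompose_toy_landscape.py`) and a miniature
method-comparison study (`03_simulation_study.py`).

### Command line

```sh
landclust run --subjects subjects_4d.nii.gz --mask mask.nii.gz \
    --perms 100 --alpha 0.05 --seed 1 --pre-threshold 0.05 --out results/
landclust simulate --config scenario.yaml --out study/ --baseline
```

`run` writes the landscape, cluster-label map and significance mask as
NIfTI (input geometry preserved), plus the cluster table, null
distribution, and resolved configuration. `simulate` runs a planted-
effect simulation study from a YAML scenario.

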