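"""One-sample group analysis with sign-flip permutation inference.

Simulates a small 16-subject experiment with a planted spherical effect
(effect size 1.2 in noise-SD units), builds the -log10(p) landscape
from the one-sample t-map, and tests cluster activation scores against
the permutation null of the whole-brain maximum score.
"""

import numpy as np

from landclust import (
    ClusteringConfig,
    SimulationScenario,
    infer,
    make_region,
    simulate_stack,
)

shape = (20, 20, 16)
scenario = SimulationScenario(
    grid_shape=shape,
    voxel_size=(2.0, 2.0, 2.0),
    region=make_region(shape, radii=(2.5, 2.5, 2.5)),
    n_subjects=16,
    effect_size=1.2,
    fwhm=4.0,
    seed=42,
)
stack = simulate_stack(scenario)

result = infer(
    stack,
    n_permutations=100,
    seed=7,
    alpha=0.05,
    config=ClusteringConfig(connectivity=26, pre_threshold=0.05),
)

print(f"clusters found: {result.cluster_set.n_clusters}")
print(f"significance criterion (5% of null max scores above): {result.criterion:.1f}")
table = result.cluster_table()
print(table[table.significant].to_string(index=False))
n_in = scenario.region[result.significance_mask].sum() if result.significant.any() else 0
print(
    f"significant voxels inside the planted region: {n_in} of {int(result.significance_mask.sum())}\n"
    "A cluster is significant when its activation score (sum of -log10 p\n"
    "over its voxels) exceeds the criterion from the sign-flip null of the\n"
    "whole-brain maximum score - family-wise error control at 5% without\n"
    "any cluster-forming threshold."
)
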