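"""Merging adjacent clusters that are bumps on a larger hill's flank.

Depending on the smoothness of the map, the recursive decomposition can
split one hill into a dominant cluster plus small satellite clusters
around secondary local maxima. Two adjacent clusters, oriented as
(lower peak, higher peak), are merged when

    PeaksDifference / (PeaksDifference + SmallerPeakToConnectingEdge)
        >= 1 - ProportionConnected

where, always measured on the lower-peaked cluster:

* ProportionConnected — fraction of its edge voxels adjacent to the
  specific neighboring cluster;
* PeaksDifference — absolute difference of the two peak values;
* SmallerPeakToConnectingEdge — its peak value minus the mean landscape
  value over its edge voxels adjacent to that neighbor.

A fully surrounded cluster (ProportionConnected = 1) always merges; a
bump whose peak barely rises above the connecting flank merges easily;
two well-separated peaks joined by a deep valley do not. Without this
step a threshold-free decomposition would also have to keep every
shallow wiggle of the landscape "floor" as its own cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from . import _core
from .clustering import ClusterSet

__all__ = ["CombinationMetrics", "compute_metrics", "should_combine", "combine_all"]


@dataclass(frozen=True)
class CombinationMetrics:
    """The three quantities entering the combination inequality."""

    proportion_connected: float
    peaks_difference: float
    smaller_peak_to_connecting_edge: float


def compute_metrics(cs: ClusterSet, lower_label: int, higher_label: int) -> CombinationMetrics:
    """Combination metrics for the pair (lower, higher), measured on the
    lower-peaked cluster.

    If the clusters are not adjacent, ``proportion_connected`` is 0 and
    the connecting-edge term is NaN (no decision needed).
    """
    offs = _core.neighborhood_offsets(cs.config.connectivity)
    edge = cs.edge_voxels(lower_label)
    n_edge = edge.shape[0]
    shape = cs.label_grid.shape
    connecting = np.zeros(n_edge, dtype=bool)
    for off in offs:
        nb = edge + off
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        idx = tuple(nb[ok].T)
        hit = cs.landscape.mask[idx] & (cs.label_grid[idx] == higher_label)
        connecting[np.flatnonzero(ok)[hit]] = True
    n_conn = int(connecting.sum())
    peak_lo = float(cs.peak_values[lower_label - 1])
    peak_hi = float(cs.peak_values[higher_label - 1])
    if n_conn == 0:
        return CombinationMetrics(0.0, abs(peak_hi - peak_lo), math.nan)
    vals = cs.landscape.values[tuple(edge[connecting].T)]
    return CombinationMetrics(
        proportion_connected=n_conn / n_edge,
        peaks_difference=abs(peak_hi - peak_lo),
        smaller_peak_to_connecting_edge=peak_lo - float(vals.mean()),
    )


def should_combine(m: CombinationMetrics) -> bool:
    """Evaluate the combination inequality.

    Requires an actual contact (``proportion_connected > 0``); without
    one there is no decision to make and the answer is False. The
    degenerate case of equal peaks meeting at peak level (0/0) merges:
    there is zero separation.
    """
    if m.proportion_connected <= 0.0:
        return False
    denom = m.peaks_difference + m.smaller_peak_to_connecting_edge
    if denom == 0.0:
        return True
    return m.peaks_difference / denom >= 1.0 - m.proportion_connected


def combine_all(cs: ClusterSet) -> ClusterSet:
    """Merge clusters to the fixed point of the combination criterion.

    Candidate pairs are processed by ascending lower-peak value (the
    weakest bumps are absorbed first); after every merge, adjacency and
    metrics reflect the updated labeling. If several neighbors of one
    lower cluster qualify simultaneously, the most-connected one wins
    (ties: higher neighbor peak, then smaller label). Passes repeat
    until a full pass makes no merge; each merge reduces the cluster
    count by one, so termination is guaranteed. Surviving clusters are
    renumbered 1..K' preserving the decomposition's descending-peak
    order, with scores equal to the sums over their merged voxel sets.
    """
    if cs.n_clusters <= 1:
        return cs
    ids = np.arange(1, cs.n_clusters + 1)
    order = ids[np.lexsort((ids, cs.peak_values))].astype(np.int64)
    labels = cs.label_grid.copy()
    peak_val = np.concatenate(([0.0], np.asarray(cs.peak_values, dtype=np.float64)))
    peak_lin = np.concatenate(([0], cs.peak_lin)).astype(np.int64)
    offs = _core.neighborhood_offsets(cs.config.connectivity)
    _core.combine_kernel(
        cs.landscape.values, labels, cs.landscape.mask, offs, peak_val, peak_lin, order
    )
    roots = np.unique(labels[labels > 0])
    lut = np.zeros(cs.n_clusters + 1, dtype=np.int32)
    lut[roots] = np.arange(1, roots.size + 1, dtype=np.int32)
    return ClusterSet(lut[labels], cs.landscape, cs.config, peak_lin[roots])
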