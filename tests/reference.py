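"""Naive reference implementations used as independent oracles.

Everything here literally re-evaluates the stated rules — distance and
slope conditions along explicit paths, "fewer than alpha above" scans,
flood fills — with plain Python data structures and linear scans, never
sharing code with the production kernels. Deliberately slow; use only
on small grids.
"""

from __future__ import annotations

import math

import numpy as np


def offsets(connectivity: int):
    out = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity, order) in ((6, 2), (6, 3), (18, 3)):
                    continue
                out.append((dx, dy, dz))
    return out


def _neighbors(v, shape, conn):
    for off in offsets(conn):
        w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
        if all(0 <= w[i] < shape[i] for i in range(3)):
            yield w


def ref_local_maxima(values, available, conn=26, eps=0.0):
    """All voxels strictly above every available neighbor, sorted by
    (value desc, linear index asc)."""
    shape = values.shape
    maxima = []
    for v in zip(*np.nonzero(available)):
        if all(
            not available[w] or values[w] < values[v] - eps
            for w in _neighbors(v, shape, conn)
        ):
            lin = (v[0] * shape[1] + v[1]) * shape[2] + v[2]
            maxima.append((-values[v], lin, v))
    maxima.sort()
    return [m[2] for m in maxima]


def ref_grow(values, available, peak, voxel_size=(1.0, 1.0, 1.0), conn=26, normalize=False):
    """Grow one cluster from ``peak`` by the literal distance and slope
    rules, picking the next frontier entry by a linear scan."""
    shape = values.shape
    vsz = tuple(float(v) for v in voxel_size)

    def dist(v):
        return math.sqrt(sum(((v[i] - peak[i]) * vsz[i]) ** 2 for i in range(3)))

    def lin(v):
        return (v[0] * shape[1] + v[1]) * shape[2] + v[2]

    members = {tuple(peak)}
    queued = {tuple(peak)}
    # candidate entries: (voxel, parent, slope into parent)
    cands = []

    def queue_neighbors(u, slope_in):
        for w in _neighbors(u, shape, conn):
            if available[w] and w not in queued and dist(w) > dist(u):
                queued.add(w)
                cands.append((w, u, slope_in))

    queue_neighbors(tuple(peak), 0.0)
    while cands:
        best = 0
        for i in range(1, len(cands)):  # linear scan: min (distance, linear index)
            v_i, v_b = cands[i][0], cands[best][0]
            if (dist(v_i), lin(v_i)) < (dist(v_b), lin(v_b)):
                best = i
        v, u, slope_in = cands.pop(best)
        slope = values[v] - values[u]
        if normalize:
            step = math.sqrt(sum(((v[i] - u[i]) * vsz[i]) ** 2 for i in range(3)))
            slope /= step
        if slope > slope_in:
            continue  # upward turn: boundary non-member
        members.add(v)
        queue_neighbors(v, slope)
    return members


def ref_decompose(values, mask, voxel_size=(1.0, 1.0, 1.0), conn=26):
    """Iterate: highest available local maximum, grow, remove; returns a
    list of (peak, member set) in discovery order."""
    available = mask.copy()
    clusters = []
    while True:
        maxima = ref_local_maxima(values, available, conn)
        if not maxima:
            break
        peak = maxima[0]
        members = ref_grow(values, available, peak, voxel_size, conn)
        clusters.append((peak, members))
        for v in members:
            available[v] = False
    return clusters


def ref_combine(values, mask, clusters, conn=26):
    """Fixed-point combination on (peak, member-set) clusters.

    Mirrors the documented ordering: passes process lower clusters by
    ascending peak value (ties by ascending label), each decision uses
    current adjacency, the most-connected qualifying higher neighbor
    absorbs the lower cluster (ties: higher peak, then smaller label).
    Returns a dict label -> member set of the surviving clusters.
    """
    shape = values.shape
    peaks = {k: values[p] for k, (p, _) in enumerate(clusters, start=1)}
    members = {k: set(m) for k, (_, m) in enumerate(clusters, start=1)}
    owner = {}
    for k, m in members.items():
        for v in m:
            owner[v] = k
    order = sorted(peaks, key=lambda k: (peaks[k], k))
    rank = {k: i for i, k in enumerate(order)}

    def is_lower(c, r):
        return (peaks[c], rank[c]) < (peaks[r], rank[r])

    merged = True
    while merged:
        merged = False
        for c in order:
            if c not in members:
                continue
            edge = []
            contacts: dict[int, list] = {}
            for v in members[c]:
                roots = set()
                is_edge = False
                for w in _neighbors(v, shape, conn):
                    if not mask[w]:
                        continue
                    r = owner.get(w, 0)
                    if r != c:
                        is_edge = True
                        if r:
                            roots.add(r)
                if is_edge:
                    edge.append(v)
                    for r in roots:
                        contacts.setdefault(r, []).append(values[v])
            best, best_key = None, None
            for r, vals in contacts.items():
                if not is_lower(c, r):
                    continue
                pc = len(vals) / len(edge)
                pd = abs(peaks[r] - peaks[c])
                sp = peaks[c] - sum(vals) / len(vals)
                ok = (pd + sp == 0) or (pd / (pd + sp) >= 1 - pc)
                if ok:
                    key = (pc, peaks[r], -r)
                    if best is None or key > best_key:
                        best, best_key = r, key
            if best is not None:
                members[best] |= members.pop(c)
                for v in members[best]:
                    owner[v] = best
                merged = True
    return members


def ref_criterion(scores, alpha):
    """Smallest observed score c with #{scores > c}/n < alpha."""
    n = len(scores)
    for c in sorted(scores):
        if sum(s > c for s in scores) / n < alpha:
            return c
    raise AssertionError("unreachable: the maximum always qualifies")


def ref_components(supra, conn=26, min_size=1):
    """Connected components of a boolean grid by explicit flood fill."""
    shape = supra.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    for v in zip(*np.nonzero(supra)):
        if seen[v]:
            continue
        comp = set()
        frontier = [v]
        seen[v] = True
        while frontier:
            u = frontier.pop()
            comp.add(u)
            for w in _neighbors(u, shape, conn):
                if supra[w] and not seen[w]:
                    seen[w] = True
                    frontier.append(w)
        if len(comp) >= min_size:
            comps.append(comp)
    return comps
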