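"""Numba kernels for landscape decomposition and cluster combination.

These kernels implement the inner loops that run once per permutation:
growing clusters outward from local maxima until the downhill slope
turns upward, and merging adjacent clusters under the peak-separation
criterion. Everything here is deterministic: ties are broken by linear
voxel index (C order), and the growth frontier is a binary heap keyed
by (squared distance from the peak in mm, linear index).

Traversal semantics (shared with the pure-Python reference used in the
test suite):

* a voxel is queued at most once per growth, by the first accepted
  neighbor that reaches it; the frontier is ordered by (distance from
  the peak, linear index), so the first queuing is also the first —
  and only — evaluation of that voxel;
* a queued voxel v with queuing parent u is accepted iff
  ``value(v) - value(u) <= slope_in(u)`` where ``slope_in`` of the peak
  is 0; otherwise v is marked as a boundary non-member for this growth;
* neighbors are only queued if strictly farther (Euclidean, in mm) from
  the peak than the voxel queuing them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "neighborhood_offsets",
    "local_maxima_kernel",
    "grow_kernel",
    "decompose_kernel",
    "combine_kernel",
]


def neighborhood_offsets(connectivity: int) -> np.ndarray:
    """Offset table for a 6-, 18- or 26-neighborhood, sorted for determinism."""
    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18 or 26; got {connectivity}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.array(offs, dtype=np.int64)


# ---------------------------------------------------------------------------
# binary min-heap on parallel (float64 key, int64 tiebreak) arrays
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _less(d1, l1, d2, l2):
    return d1 < d2 or (d1 == d2 and l1 < l2)


@njit(cache=True)
def _heap_push(hd, hl, n, d, l):
    i = n
    hd[i] = d
    hl[i] = l
    while i > 0:
        p = (i - 1) >> 1
        if _less(hd[i], hl[i], hd[p], hl[p]):
            hd[i], hd[p] = hd[p], hd[i]
            hl[i], hl[p] = hl[p], hl[i]
            i = p
        else:
            break
    return n + 1


@njit(cache=True)
def _heap_pop(hd, hl, n):
    d = hd[0]
    l = hl[0]
    n -= 1
    hd[0] = hd[n]
    hl[0] = hl[n]
    i = 0
    while True:
        c = 2 * i + 1
        if c >= n:
            break
        if c + 1 < n and _less(hd[c + 1], hl[c + 1], hd[c], hl[c]):
            c += 1
        if _less(hd[c], hl[c], hd[i], hl[i]):
            hd[i], hd[c] = hd[c], hd[i]
            hl[i], hl[c] = hl[c], hl[i]
            i = c
        else:
            break
    return d, l, n


# ---------------------------------------------------------------------------
# local maxima
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _is_local_max(values, avail, offs, x, y, z, eps):
    # strict maximum; with eps > 0 near-ties also block maximality
    nx, ny, nz = values.shape
    v = values[x, y, z]
    for k in range(offs.shape[0]):
        xx = x + offs[k, 0]
        yy = y + offs[k, 1]
        zz = z + offs[k, 2]
        if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
            if avail[xx, yy, zz] != 0 and values[xx, yy, zz] >= v - eps:
                return False
    return True


@njit(cache=True)
def local_maxima_kernel(values, avail, offs, eps):
    """Linear indices of strict local maxima of the available region."""
    nx, ny, nz = values.shape
    out = np.empty(nx * ny * nz, np.int64)
    m = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if avail[x, y, z] != 0 and _is_local_max(values, avail, offs, x, y, z, eps):
                    out[m] = (x * ny + y) * nz + z
                    m += 1
    return out[:m]


# ---------------------------------------------------------------------------
# cluster growth
# ---------------------------------------------------------------------------


@njit(cache=True)
def grow_kernel(
    values,
    labels,
    mask,
    offs,
    off_len,
    vsz,
    gid,
    px,
    py,
    pz,
    stamp,
    pslope,
    pval,
    pstep,
    hd,
    hl,
    members,
    normalize_slope,
):
    """Grow one cluster labelled ``gid`` from peak (px, py, pz) in place.

    ``labels`` holds 0 for available voxels; any nonzero value means
    unavailable. ``stamp``/``pslope``/``pval``/``pstep`` are V-length
    scratch arrays (``stamp`` must contain no ``gid`` entries on entry);
    ``hd``/``hl`` are heap scratch; ``off_len`` gives the mm length of
    each neighbor step for the optional per-mm slope normalization
    (``normalize_slope`` true divides each slope by its step length).
    Accepted linear indices are written to ``members``; returns their
    count.
    """
    nx, ny, nz = values.shape
    vx, vy, vz = vsz[0], vsz[1], vsz[2]
    labels[px, py, pz] = gid
    plin = (px * ny + py) * nz + pz
    stamp[plin] = gid
    members[0] = plin
    n_acc = 1
    hn = 0
    # queue the peak's neighbors (parent slope at the peak is 0)
    for k in range(offs.shape[0]):
        xx = px + offs[k, 0]
        yy = py + offs[k, 1]
        zz = pz + offs[k, 2]
        if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
            if mask[xx, yy, zz] and labels[xx, yy, zz] == 0:
                lin = (xx * ny + yy) * nz + zz
                if stamp[lin] != gid:
                    stamp[lin] = gid
                    pslope[lin] = 0.0
                    pval[lin] = values[px, py, pz]
                    pstep[lin] = off_len[k]
                    dx = (xx - px) * vx
                    dy = (yy - py) * vy
                    dz = (zz - pz) * vz
                    hn = _heap_push(hd, hl, hn, dx * dx + dy * dy + dz * dz, lin)
    while hn > 0:
        d, lin, hn = _heap_pop(hd, hl, hn)
        z = lin % nz
        y = (lin // nz) % ny
        x = lin // (ny * nz)
        slope = values[x, y, z] - pval[lin]
        if normalize_slope:
            slope = slope / pstep[lin]
        if slope > pslope[lin]:
            continue  # slope turned upward: boundary non-member, decided
        labels[x, y, z] = gid
        members[n_acc] = lin
        n_acc += 1
        for k in range(offs.shape[0]):
            xx = x + offs[k, 0]
            yy = y + offs[k, 1]
            zz = z + offs[k, 2]
            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                if mask[xx, yy, zz] and labels[xx, yy, zz] == 0:
                    nlin = (xx * ny + yy) * nz + zz
                    if stamp[nlin] != gid:
                        dx = (xx - px) * vx
                        dy = (yy - py) * vy
                        dz = (zz - pz) * vz
                        nd = dx * dx + dy * dy + dz * dz
                        if nd > d:  # only move away from the peak
                            stamp[nlin] = gid
                            pslope[nlin] = slope
                            pval[nlin] = values[x, y, z]
                            pstep[nlin] = off_len[k]
                            hn = _heap_push(hd, hl, hn, nd, nlin)
    return n_acc


@njit(cache=True)
def decompose_kernel(values, mask, offs, off_len, vsz, eps, normalize_slope):
    """Full landscape decomposition: highest peak first, until none remain.

    Returns ``(labels, peak_lin)`` where labels is an int32 grid
    (0 = never claimed / out of mask) and ``peak_lin[k]`` is the linear
    index of the peak that seeded cluster ``k+1``.
    """
    nx, ny, nz = values.shape
    V = nx * ny * nz
    labels = np.zeros((nx, ny, nz), np.int32)
    stamp = np.zeros(V, np.int64)
    pslope = np.empty(V, np.float64)
    pval = np.empty(V, np.float64)
    pstep = np.empty(V, np.float64)
    hd = np.empty(V + 1, np.float64)
    hl = np.empty(V + 1, np.int64)
    members = np.empty(V, np.int64)
    avail = np.empty((nx, ny, nz), np.uint8)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                avail[x, y, z] = 1 if mask[x, y, z] else 0
    # lazily validated candidate heap of potential maxima, keyed by
    # (-value, linear index) so the highest peak pops first
    cap = 27 * V + 64
    chd = np.empty(cap, np.float64)
    chl = np.empty(cap, np.int64)
    cn = 0
    init = local_maxima_kernel(values, avail, offs, eps)
    for i in range(init.shape[0]):
        lin = init[i]
        z = lin % nz
        y = (lin // nz) % ny
        x = lin // (ny * nz)
        cn = _heap_push(chd, chl, cn, -values[x, y, z], lin)
    cand_stamp = np.full(V, -1, np.int64)
    peak_lin = np.empty(V, np.int64)
    gid = 0
    while cn > 0:
        _, lin, cn = _heap_pop(chd, chl, cn)
        z = lin % nz
        y = (lin // nz) % ny
        x = lin // (ny * nz)
        if labels[x, y, z] != 0:
            continue
        if not _is_local_max(values, avail, offs, x, y, z, eps):
            continue  # stale candidate; re-queued if it ever qualifies
        gid += 1
        peak_lin[gid - 1] = lin
        n_acc = grow_kernel(
            values,
            labels,
            mask,
            offs,
            off_len,
            vsz,
            gid,
            x,
            y,
            z,
            stamp,
            pslope,
            pval,
            pstep,
            hd,
            hl,
            members,
            normalize_slope,
        )
        # claimed voxels leave the available region; only their available
        # neighbors can newly become local maxima, so queue exactly those
        for i in range(n_acc):
            mlin = members[i]
            mz = mlin % nz
            my = (mlin // nz) % ny
            mx = mlin // (ny * nz)
            avail[mx, my, mz] = 0
        for i in range(n_acc):
            mlin = members[i]
            mz = mlin % nz
            my = (mlin // nz) % ny
            mx = mlin // (ny * nz)
            for k in range(offs.shape[0]):
                xx = mx + offs[k, 0]
                yy = my + offs[k, 1]
                zz = mz + offs[k, 2]
                if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                    if avail[xx, yy, zz] != 0:
                        nlin = (xx * ny + yy) * nz + zz
                        if cand_stamp[nlin] != gid:
                            cand_stamp[nlin] = gid
                            cn = _heap_push(chd, chl, cn, -values[xx, yy, zz], nlin)
    return labels, peak_lin[:gid]


# ---------------------------------------------------------------------------
# cluster combination
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _find(parent, c):
    root = c
    while parent[root] != root:
        root = parent[root]
    while parent[c] != root:  # path compression
        parent[c], c = root, parent[c]
    return root


@njit(cache=True)
def combine_kernel(values, labels, mask, offs, peak_val, peak_lin, order):
    """Merge clusters to the fixed point of the combination criterion.

    ``labels`` is the decomposition label grid (modified in place to
    hold root labels on exit); ``peak_val``/``peak_lin`` are 1-indexed
    per-cluster arrays; ``order`` lists cluster ids by ascending peak
    value (ties by ascending id), defining both the processing order of
    each pass and the lower/higher orientation of equal-peak pairs.
    Returns the union-find parent array mapping each original cluster id
    to its surviving root.

    Pairs are always oriented (lower, higher); the metrics — the share
    of the lower cluster's edge voxels touching the specific neighbor
    (ProportionConnected), the peak difference, and the lower peak's
    height above the mean value of its connecting edge voxels — are
    measured on the lower cluster. A pass processes lower clusters by
    ascending peak (weakest bumps absorbed first); within one decision,
    if several neighbors qualify the one with the largest connected
    proportion wins (ties: higher neighbor peak, then smaller id).
    Passes repeat until none merges.
    """
    nx, ny, nz = values.shape
    K = peak_val.shape[0] - 1  # ids are 1..K
    parent = np.empty(K + 1, np.int32)
    for c in range(K + 1):
        parent[c] = c
    # per-cluster voxel chains (linked lists over linear indices)
    V = nx * ny * nz
    head = np.full(K + 1, -1, np.int64)
    tail = np.full(K + 1, -1, np.int64)
    nxt = np.full(V, -1, np.int64)
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                c = labels[x, y, z]
                if c > 0:
                    lin = (x * ny + y) * nz + z
                    if head[c] < 0:
                        head[c] = lin
                    else:
                        nxt[tail[c]] = lin
                    tail[c] = lin
    # rank of each cluster in `order` (position = lower-ness)
    rank = np.empty(K + 1, np.int64)
    for i in range(K):
        rank[order[i]] = i
    contact_cnt = np.zeros(K + 1, np.int64)
    contact_sum = np.zeros(K + 1, np.float64)
    touched = np.empty(K + 1, np.int64)
    local_roots = np.empty(32, np.int64)
    merged_any = True
    while merged_any:
        merged_any = False
        for oi in range(K):
            c = order[oi]
            if _find(parent, c) != c:
                continue  # absorbed earlier
            # scan c's voxels: edge voxels and per-neighbor contacts
            n_edge = 0
            n_touch = 0
            lin = head[c]
            while lin >= 0:
                z = lin % nz
                y = (lin // nz) % ny
                x = lin // (ny * nz)
                is_edge = False
                n_local = 0
                for k in range(offs.shape[0]):
                    xx = x + offs[k, 0]
                    yy = y + offs[k, 1]
                    zz = z + offs[k, 2]
                    if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and mask[xx, yy, zz]:
                        lab = labels[xx, yy, zz]
                        r = _find(parent, lab) if lab > 0 else 0
                        if r != c:
                            is_edge = True
                            if r > 0:
                                dup = False
                                for j in range(n_local):
                                    if local_roots[j] == r:
                                        dup = True
                                        break
                                if not dup:
                                    local_roots[n_local] = r
                                    n_local += 1
                if is_edge:
                    n_edge += 1
                    for j in range(n_local):
                        r = local_roots[j]
                        if contact_cnt[r] == 0:
                            touched[n_touch] = r
                            n_touch += 1
                        contact_cnt[r] += 1
                        contact_sum[r] += values[x, y, z]
                lin = nxt[lin]
            # decide: among higher-peaked neighbors satisfying the
            # criterion, absorb into the most-connected one
            best = -1
            best_pc = -1.0
            for j in range(n_touch):
                r = touched[j]
                # c must be the lower of the pair: smaller peak, ties by
                # the processing order (earlier rank = lower)
                if not (
                    peak_val[r] > peak_val[c]
                    or (peak_val[r] == peak_val[c] and rank[r] > rank[c])
                ):
                    continue
                pc = contact_cnt[r] / n_edge
                pd = peak_val[r] - peak_val[c]
                if pd < 0.0:
                    pd = -pd
                sp = peak_val[c] - contact_sum[r] / contact_cnt[r]
                denom = pd + sp
                ok = True if denom == 0.0 else (pd / denom >= 1.0 - pc)
                if ok:
                    better = False
                    if pc > best_pc:
                        better = True
                    elif pc == best_pc and best > 0:
                        if peak_val[r] > peak_val[best]:
                            better = True
                        elif peak_val[r] == peak_val[best] and r < best:
                            better = True
                    if better:
                        best = r
                        best_pc = pc
            for j in range(n_touch):  # reset scratch
                r = touched[j]
                contact_cnt[r] = 0
                contact_sum[r] = 0.0
            if best > 0:
                parent[c] = best
                nxt[tail[best]] = head[c]
                tail[best] = tail[c]
                merged_any = True
    # rewrite the grid to root labels
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                c = labels[x, y, z]
                if c > 0:
                    labels[x, y, z] = _find(parent, c)
    for c in range(1, K + 1):
        parent[c] = _find(parent, c)
    return parent
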