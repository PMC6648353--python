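"""Numba kernel for threshold-free cluster enhancement on masked grids.

The discrete TFCE transform of a non-negative statistic map is

    TFCE(v) = sum_{k=1..n_steps} e(h_k, v)^E * h_k^H * dh,
    h_k = k * dh,  dh = max(stat) / n_steps,

where e(h, v) is the voxel count of the connected component containing v
among voxels with stat >= h.  A naive implementation labels the
suprathreshold set once per step; here components are maintained
incrementally with a union-find over voxels processed in descending value
order, and the per-component running sums are carried through merges with
potential offsets, giving O(V alpha(V) + n_steps * n_components) per map.
This is what makes max-statistic permutation nulls with hundreds of
flips-per-cohort affordable; tests verify exact agreement with a
brute-force per-threshold labelling oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["neighbor_table", "tfce_compact"]

_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def _offsets(connectivity: int):
    if connectivity == 6:
        return _OFFSETS_6
    offs = [(i, j, k)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)]
    if connectivity == 18:
        offs = [o for o in offs if sum(abs(x) for x in o) <= 2]
    elif connectivity != 26:
        raise ValueError("connectivity must be 6, 18 or 26")
    return offs


def neighbor_table(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """(V, n_offsets) table of compact neighbor indices inside ``mask`` (-1 pad).

    Build once per mask; reuse across the many statistic maps of a
    permutation run.
    """
    mask = np.asarray(mask, dtype=bool)
    compact = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    compact[mask] = np.arange(len(coords))
    offs = _offsets(connectivity)
    table = -np.ones((len(coords), len(offs)), dtype=np.int64)
    shape = mask.shape
    for oi, (di, dj, dk) in enumerate(offs):
        shifted = coords + np.array([di, dj, dk])
        ok = np.all((shifted >= 0) & (shifted < np.array(shape)), axis=1)
        idx = shifted[ok]
        table[ok, oi] = compact[idx[:, 0], idx[:, 1], idx[:, 2]]
    return table


@njit(cache=True)
def _find(parent, off, x):
    # locate root
    r = x
    while parent[r] != r:
        r = parent[r]
    # accumulate total potential from x to root
    s = 0.0
    u = x
    while parent[u] != u:
        s += off[u]
        u = parent[u]
    # path compression, re-basing each offset directly onto the root
    u = x
    while parent[u] != u:
        nxt = parent[u]
        o = off[u]
        parent[u] = r
        off[u] = s
        s -= o
        u = nxt
    return r


@njit(cache=True)
def tfce_compact(values, neighbors, n_steps, e_power, h_power):
    """TFCE of a compact (masked) value vector; non-positive values get 0."""
    nv = values.shape[0]
    out = np.zeros(nv)
    vmax = 0.0
    for i in range(nv):
        if values[i] > vmax:
            vmax = values[i]
    if vmax <= 0.0:
        return out
    dh = vmax / n_steps
    # tie slack: voxels within 1e-12 (relative) of a threshold count as
    # suprathreshold, so that exact c*map rescaling (rounding ~1e-16)
    # resolves threshold ties identically and c^(H+1) homogeneity is exact
    tie_eps = 1e-12 * vmax

    order = np.argsort(values)[::-1]
    parent = np.full(nv, -1, dtype=np.int64)
    size = np.zeros(nv, dtype=np.int64)
    acc = np.zeros(nv)
    off = np.zeros(nv)
    root_list = np.empty(nv, dtype=np.int64)
    n_roots = 0
    ptr = 0

    for k in range(n_steps, 0, -1):
        h = k * dh
        # activate voxels reaching this threshold and merge with active neighbors
        while ptr < nv and values[order[ptr]] >= h - tie_eps:
            v = order[ptr]
            parent[v] = v
            size[v] = 1
            acc[v] = 0.0
            off[v] = 0.0
            root_list[n_roots] = v
            n_roots += 1
            for ni in range(neighbors.shape[1]):
                nb = neighbors[v, ni]
                if nb >= 0 and parent[nb] >= 0:
                    ra = _find(parent, off, v)
                    rb = _find(parent, off, nb)
                    if ra != rb:
                        if size[ra] < size[rb]:
                            ra, rb = rb, ra
                        # attach rb under ra, preserving accumulated sums
                        parent[rb] = ra
                        off[rb] = acc[rb] - acc[ra]
                        size[ra] += size[rb]
            ptr += 1
        # add this threshold's contribution to every live component
        inc = (h ** h_power) * dh
        w = 0
        for ri in range(n_roots):
            r = root_list[ri]
            if parent[r] == r:
                acc[r] += (size[r] ** e_power) * inc
                root_list[w] = r
                w += 1
        n_roots = w

    for v in range(nv):
        if parent[v] >= 0:
            s = 0.0
            u = v
            while parent[u] != u:
                s += off[u]
                u = parent[u]
            out[v] = acc[u] + s
    return out
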