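"""Independent brute-force oracles used to certify the library's algorithms.

Everything here is deliberately naive and self-contained (pure Python flood
fill, union-find, set arithmetic) so it shares no code path with the
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _offsets(connectivity: int):
    if connectivity == 26:
        return _OFFSETS_26
    if connectivity == 18:
        return [o for o in _OFFSETS_26 if sum(map(abs, o)) <= 2]
    if connectivity == 6:
        return [o for o in _OFFSETS_26 if sum(map(abs, o)) == 1]
    raise ValueError(connectivity)


def flood_fill_components(mask: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components of a boolean array by explicit BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    offs = _offsets(connectivity)
    seen = np.zeros_like(mask)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        frontier = [start]
        seen[start] = True
        while frontier:
            v = frontier.pop()
            comp.add(v)
            for o in offs:
                n = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                    if mask[n] and not seen[n]:
                        seen[n] = True
                        frontier.append(n)
        comps.append(comp)
    return comps


def size_filtered_mask(mask: np.ndarray, min_voxels: int, connectivity: int = 26) -> np.ndarray:
    """Flood-fill labelling followed by a size filter: the cluster-removal oracle."""
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in flood_fill_components(mask, connectivity):
        if len(comp) >= min_voxels:
            for v in comp:
                out[v] = True
    return out


def jaccard_pct(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard index x 100 via Python sets of voxel coordinates."""
    a = {tuple(v) for v in np.argwhere(np.asarray(mask_a, dtype=bool))}
    b = {tuple(v) for v in np.argwhere(np.asarray(mask_b, dtype=bool))}
    union = a | b
    if not union:
        return 100.0
    return 100.0 * len(a & b) / len(union)


def maxmin_connectivity(
    intensities: np.ndarray,
    brain: np.ndarray,
    seed_coords: np.ndarray,
    sigma_scale: float = 1.0,
    connectivity: int = 26,
) -> np.ndarray:
    """Exhaustive max–min path strength from the seed set, by union-find.

    Affinity between adjacent in-brain voxels c, d is the Gaussian
    homogeneity kernel around the seed-intensity mean (width sigma_scale x
    seed SD, with the same 10%-of-mean floor the library documents for
    zero-spread seeds). Processing edges in descending affinity order and
    recording, for each voxel, the affinity at the moment it first joins a
    seed-containing component yields exactly the maximin path strength
    (the bottleneck path runs along the maximum spanning forest).
    """
    intensities = np.asarray(intensities, dtype=float)
    brain = np.asarray(brain, dtype=bool)
    seed_vals = intensities[tuple(np.asarray(seed_coords).T)]
    m = float(seed_vals.mean())
    sigma = sigma_scale * float(seed_vals.std())
    if sigma <= 0:
        sigma = max(0.1 * max(abs(m), 1.0), 1e-12)

    def aff(c, d):
        pm = 0.5 * (intensities[c] + intensities[d])
        return math.exp(-((pm - m) ** 2) / (2.0 * sigma * sigma))

    voxels = [tuple(v) for v in np.argwhere(brain)]
    index = {v: i for i, v in enumerate(voxels)}
    parent = list(range(len(voxels)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    has_seed = [False] * len(voxels)
    conn = np.zeros(brain.shape, dtype=float)
    for sc in map(tuple, np.asarray(seed_coords)):
        has_seed[index[sc]] = True
        conn[sc] = 1.0

    edges = []
    offs = _offsets(connectivity)
    for v in voxels:
        for o in offs:
            n = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if n in index and n > v:
                edges.append((aff(v, n), index[v], index[n]))
    edges.sort(reverse=True)

    members: dict[int, list[int]] = {i: [i] for i in range(len(voxels))}
    for a, i, j in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        if has_seed[ri] != has_seed[rj]:
            newcomers = members[rj] if has_seed[ri] else members[ri]
            for k in newcomers:
                conn[voxels[k]] = a
        parent[rj] = ri
        members[ri].extend(members.pop(rj))
        has_seed[ri] = has_seed[ri] or has_seed[rj]
    return conn
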