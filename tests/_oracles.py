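"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: flood fills are
explicit breadth-first searches, and point-triangle distances follow the
classic closest-point-on-triangle region decomposition.
"""

from collections import deque

import numpy as np

_OFFSETS_6 = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
_OFFSETS_26 = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


def bfs_flood_fill(band: np.ndarray, seed, connectivity: int = 6) -> np.ndarray:
    """Connected component of the boolean ``band`` containing ``seed``."""
    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    shape = band.shape
    out = np.zeros(shape, dtype=bool)
    if not band[seed]:
        return out
    queue = deque([tuple(seed)])
    out[tuple(seed)] = True
    while queue:
        i, j, k = queue.popleft()
        for di, dj, dk in offsets:
            n = (i + di, j + dj, k + dk)
            if (
                0 <= n[0] < shape[0]
                and 0 <= n[1] < shape[1]
                and 0 <= n[2] < shape[2]
                and band[n]
                and not out[n]
            ):
                out[n] = True
                queue.append(n)
    return out


def border_reachable_background(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Background voxels reachable from the grid border (given bg connectivity)."""
    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    bg = ~mask
    shape = mask.shape
    reach = np.zeros(shape, dtype=bool)
    queue = deque()
    for idx in np.ndindex(shape):
        if any(idx[a] in (0, shape[a] - 1) for a in range(3)) and bg[idx]:
            if not reach[idx]:
                reach[idx] = True
                queue.append(idx)
    while queue:
        i, j, k = queue.popleft()
        for di, dj, dk in offsets:
            n = (i + di, j + dj, k + dk)
            if (
                0 <= n[0] < shape[0]
                and 0 <= n[1] < shape[1]
                and 0 <= n[2] < shape[2]
                and bg[n]
                and not reach[n]
            ):
                reach[n] = True
                queue.append(n)
    return reach


def closest_point_on_triangle(p, a, b, c):
    """Closest point to ``p`` on triangle ``abc`` (region decomposition)."""
    p, a, b, c = (np.asarray(x, dtype=float) for x in (p, a, b, c))
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + (d1 / (d1 - d3)) * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + (d2 / (d2 - d6)) * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + ((d4 - d3) / ((d4 - d3) + (d5 - d6))) * (c - b)
    denom = 1.0 / (va + vb + vc)
    v, w = vb * denom, vc * denom
    return a + ab * v + ac * w


def brute_force_distances(points, mesh) -> np.ndarray:
    """Unsigned nearest distance per point over ALL triangles of ``mesh``."""
    tri = np.asarray(mesh.vertices)[np.asarray(mesh.faces)]
    out = np.empty(len(points))
    for i, p in enumerate(np.atleast_2d(points)):
        best = np.inf
        for a, b, c in tri:
            cp = closest_point_on_triangle(p, a, b, c)
            best = min(best, float(np.linalg.norm(p - cp)))
        out[i] = best
    return out
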