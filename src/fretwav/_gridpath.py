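"""Numba kernels for linker path lengths on a 3-D occupancy grid.

The linker accessibility criterion is "reachable from the attachment point
through free space within the linker contour length".  Distances are exact
Euclidean wherever the straight segment from the attachment is free (line
of sight); shadowed cells are completed by a label-correcting shortest
path (Bellman-Ford style alternating sweeps) over an extended 124-offset
stencil (all nonzero integer offsets with Chebyshev radius <= 2), seeded
with the line-of-sight distances.  Long offsets check their intermediate
cells so paths cannot tunnel through thin walls.
"""

from __future__ import annotations

import itertools

import numpy as np
from numba import njit

__all__ = ["stencil_offsets", "geodesic_distances"]


def stencil_offsets():
    """Offsets, unit lengths and intermediate-cell offsets of the stencil."""
    offs = np.array(
        [v for v in itertools.product((-2, -1, 0, 1, 2), repeat=3) if any(v)],
        dtype=np.int64,
    )
    lens = np.sqrt((offs.astype(float) ** 2).sum(axis=1))
    half = offs / 2.0
    inter_a = np.floor(half).astype(np.int64)
    inter_b = np.ceil(half).astype(np.int64)
    has_inter = (np.abs(offs).max(axis=1) == 2).astype(np.int64)
    return offs, lens, np.where(has_inter[:, None] == 1, inter_a, 0), np.where(
        has_inter[:, None] == 1, inter_b, 0
    ), has_inter


@njit(cache=True)
def _line_of_sight(free, ax, ay, az, cx, cy, cz, inv_spacing, ox, oy, oz, n0, n1, n2):
    """True when the straight segment attach -> cell center crosses only free cells."""
    dx, dy, dz = cx - ax, cy - ay, cz - az
    length = (dx * dx + dy * dy + dz * dz) ** 0.5
    n_steps = int(length * inv_spacing * 2.0) + 1
    for s in range(1, n_steps + 1):
        f = s / n_steps
        px = ax + f * dx
        py = ay + f * dy
        pz = az + f * dz
        i = int(round((px - ox) * inv_spacing))
        j = int(round((py - oy) * inv_spacing))
        k = int(round((pz - oz) * inv_spacing))
        if i < 0 or j < 0 or k < 0 or i >= n0 or j >= n1 or k >= n2:
            return False
        if not free[i, j, k]:
            return False
    return True


@njit(cache=True)
def _init_los(free, dist, origin, spacing, attach, max_dist):
    n0, n1, n2 = free.shape
    ox, oy, oz = origin[0], origin[1], origin[2]
    ax, ay, az = attach[0], attach[1], attach[2]
    inv = 1.0 / spacing
    for i in range(n0):
        cx = ox + i * spacing
        for j in range(n1):
            cy = oy + j * spacing
            for k in range(n2):
                if not free[i, j, k]:
                    continue
                cz = oz + k * spacing
                d = ((cx - ax) ** 2 + (cy - ay) ** 2 + (cz - az) ** 2) ** 0.5
                if d > max_dist:
                    continue
                if _line_of_sight(free, ax, ay, az, cx, cy, cz, inv, ox, oy, oz, n0, n1, n2):
                    dist[i, j, k] = d


@njit(cache=True)
def _sweep(dist, free, offs, lens, inter_a, inter_b, has_inter, reverse_x, reverse_y, reverse_z):
    n0, n1, n2 = dist.shape
    n_off = offs.shape[0]
    changed = False
    for ii in range(n0):
        i = n0 - 1 - ii if reverse_x else ii
        for jj in range(n1):
            j = n1 - 1 - jj if reverse_y else jj
            for kk in range(n2):
                k = n2 - 1 - kk if reverse_z else kk
                if not free[i, j, k]:
                    continue
                best = dist[i, j, k]
                for m in range(n_off):
                    si = i - offs[m, 0]
                    sj = j - offs[m, 1]
                    sk = k - offs[m, 2]
                    if si < 0 or sj < 0 or sk < 0 or si >= n0 or sj >= n1 or sk >= n2:
                        continue
                    d0 = dist[si, sj, sk]
                    if d0 == np.inf:
                        continue
                    cand = d0 + lens[m]
                    if cand >= best:
                        continue
                    if has_inter[m] == 1:
                        ia = (si + inter_a[m, 0], sj + inter_a[m, 1], sk + inter_a[m, 2])
                        ib = (si + inter_b[m, 0], sj + inter_b[m, 1], sk + inter_b[m, 2])
                        if not free[ia] or not free[ib]:
                            continue
                    best = cand
                if best < dist[i, j, k]:
                    dist[i, j, k] = best
                    changed = True
    return changed


def geodesic_distances(
    free: np.ndarray,
    origin: np.ndarray,
    spacing: float,
    attach: np.ndarray,
    max_dist: float,
    max_sweeps: int = 64,
) -> np.ndarray:
    """Path-length field from the attachment point over free cells.

    ``free`` marks traversable cells; blocked cells stay at +inf.  The
    line-of-sight initialization is capped at ``max_dist`` (longer
    distances are irrelevant for the accessibility test); sweeps stop as
    soon as a full alternating cycle makes no update.
    """
    offs, lens, inter_a, inter_b, has_inter = stencil_offsets()
    dist = np.full(free.shape, np.inf)
    ai = np.round((attach - origin) / spacing).astype(int)
    ai = np.clip(ai, 0, np.array(free.shape) - 1)
    _init_los(free, dist, origin.astype(float), float(spacing), attach.astype(float),
              float(max_dist) * 1.2 + 2 * spacing)
    dist[ai[0], ai[1], ai[2]] = min(dist[ai[0], ai[1], ai[2]], 0.0)
    lens_scaled = lens * spacing
    for sweep in range(max_sweeps):
        changed = _sweep(
            dist, free, offs, lens_scaled, inter_a, inter_b, has_inter,
            bool(sweep & 1), bool(sweep & 2), bool(sweep & 4),
        )
        # a complete pass with no update is a fixed point regardless of order
        if not changed:
            break
    return dist
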