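"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plainly as possible (per-point loops,
triple-loop neighbourhood sums, BFS flood fill) and deliberately shares no
code with the package under test.
"""

from collections import deque

import numpy as np

FACE_NEIGHBOURS = [
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
]


def brute_bin_counts(xyz, origin, delta, dims):
    """Per-point loop binning with half-open voxels; upper-bound points go to
    the last voxel."""
    counts = np.zeros(dims, dtype=int)
    for p in np.asarray(xyz):
        idx = []
        for a in range(3):
            i = int(np.floor((p[a] - origin[a]) / delta))
            i = min(i, dims[a] - 1)
            idx.append(i)
        counts[tuple(idx)] += 1
    return counts


def brute_enhance(counts):
    """Triple-loop 27-neighbourhood sum; out-of-grid neighbours are zero."""
    nx, ny, nz = counts.shape
    out = np.zeros_like(counts)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                s = 0
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            jx, jy, jz = ix + dx, iy + dy, iz + dz
                            if 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz:
                                s += counts[jx, jy, jz]
                out[ix, iy, iz] = s
    return out


def brute_classify(counts, enhanced, min_l, inclusive=True, eligible=None):
    """Per-voxel core/border check; border = occupied non-core voxel sharing
    a face with a core voxel."""
    if eligible is None:
        eligible = counts > 0
    nx, ny, nz = counts.shape
    core = np.zeros(counts.shape, dtype=bool)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if not eligible[ix, iy, iz]:
                    continue
                v = enhanced[ix, iy, iz]
                if (v >= min_l) if inclusive else (v > min_l):
                    core[ix, iy, iz] = True
    border = np.zeros(counts.shape, dtype=bool)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if core[ix, iy, iz] or counts[ix, iy, iz] == 0:
                    continue
                for dx, dy, dz in FACE_NEIGHBOURS:
                    jx, jy, jz = ix + dx, iy + dy, iz + dz
                    if 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz:
                        if core[jx, jy, jz]:
                            border[ix, iy, iz] = True
                            break
    return core, border


def brute_components(core):
    """BFS flood fill of core voxels under 6-connectivity.  Returns a label
    array (0 = background, components numbered from 1 in scan order)."""
    nx, ny, nz = core.shape
    lab = np.zeros(core.shape, dtype=int)
    nxt = 1
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if not core[ix, iy, iz] or lab[ix, iy, iz]:
                    continue
                q = deque([(ix, iy, iz)])
                lab[ix, iy, iz] = nxt
                while q:
                    cx, cy, cz = q.popleft()
                    for dx, dy, dz in FACE_NEIGHBOURS:
                        jx, jy, jz = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= jx < nx
                            and 0 <= jy < ny
                            and 0 <= jz < nz
                            and core[jx, jy, jz]
                            and not lab[jx, jy, jz]
                        ):
                            lab[jx, jy, jz] = nxt
                            q.append((jx, jy, jz))
                nxt += 1
    return lab


def brute_pipeline(counts, min_l, min_c, inclusive=True):
    """Full enhance -> classify -> components -> border attach -> size filter
    pipeline on a count grid.  Returns a voxel label array with retained
    clusters numbered 1.. by ascending minimum x-fastest linear index.

    Border voxels attach to the adjacent component with the most touching
    core faces; ties go to the smaller component id.
    """
    enhanced = brute_enhance(counts)
    core, border = brute_classify(counts, enhanced, min_l, inclusive=inclusive)
    lab = brute_components(core)
    nx, ny, nz = counts.shape

    battach = {}
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if not border[ix, iy, iz]:
                    continue
                votes = {}
                for dx, dy, dz in FACE_NEIGHBOURS:
                    jx, jy, jz = ix + dx, iy + dy, iz + dz
                    if 0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz:
                        c = lab[jx, jy, jz]
                        if c:
                            votes[c] = votes.get(c, 0) + 1
                if votes:
                    best = max(votes.values())
                    battach[(ix, iy, iz)] = min(
                        c for c, v in votes.items() if v == best
                    )

    sizes = {}
    min_lin = {}
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                c = lab[ix, iy, iz]
                if c:
                    sizes[c] = sizes.get(c, 0) + 1
                    lin = ix + nx * (iy + ny * iz)
                    min_lin[c] = min(min_lin.get(c, lin), lin)
    for (ix, iy, iz), c in battach.items():
        sizes[c] = sizes.get(c, 0) + 1
        lin = ix + nx * (iy + ny * iz)
        min_lin[c] = min(min_lin.get(c, lin), lin)

    kept = sorted((c for c in sizes if sizes[c] >= min_c), key=lambda c: min_lin[c])
    remap = {c: i + 1 for i, c in enumerate(kept)}
    out = np.zeros(counts.shape, dtype=int)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                c = lab[ix, iy, iz]
                if c in remap:
                    out[ix, iy, iz] = remap[c]
    for (ix, iy, iz), c in battach.items():
        if c in remap:
            out[ix, iy, iz] = remap[c]
    return out


def brute_pair_count(xyz, radii):
    """O(n^2) ordered pair counts for Ripley's K."""
    xyz = np.asarray(xyz)
    n = len(xyz)
    d = np.sqrt(((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1))
    counts = []
    for r in radii:
        counts.append(int(((d <= r).sum() - n)))
    return np.array(counts)
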