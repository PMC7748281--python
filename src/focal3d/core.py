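"""Core FOCAL3D clustering.

FOCAL3D detects clusters in 3D single-molecule localization microscopy
(SMLM) point clouds by discretizing space into cubic voxels of side
``delta`` (nm), building an *enhanced density map* (each occupied voxel is
replaced by the sum of localization counts over its 3x3x3 neighbourhood),
thresholding that map at ``min_l`` to mark *core* voxels, attaching
face-adjacent sub-threshold occupied voxels as *border* voxels, and keeping
connected core+border candidates of at least ``min_c`` voxels as clusters.

All coordinates are continuous nanometres; voxel binning uses half-open
intervals ``[k*delta, (k+1)*delta)`` per axis, with points exactly on the
global upper bound assigned to the last voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LocalizationTable",
    "ClusteringParams",
    "VoxelGrid",
    "EnhancedDensityMap",
    "ClusterInfo",
    "ClusterResult",
    "build_density_map",
    "enhance_density_map",
    "classify_voxels",
    "extract_clusters",
    "focal3d",
]

NOISE_LABEL = -1

# Face (6-) connectivity structuring element; used for border adjacency and,
# by default, for core-core connectivity.
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)
_STRUCT_26 = ndimage.generate_binary_structure(3, 3)

_FACE_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LocalizationTable:
    """An ordered table of localizations.

    Parameters
    ----------
    xyz:
        ``(n_l, 3)`` float array of x, y, z coordinates in nanometres.
        Row order is the point identity used by all label vectors.
    extra:
        Optional per-point attributes (frame index, precision, ...) carried
        through untouched; must have ``n_l`` rows when present.
    """

    xyz: np.ndarray
    extra: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("localization coordinates must be finite")
        if self.extra is not None and len(self.extra) != len(self.xyz):
            raise ValueError("extra attributes must have one row per point")

    @property
    def n_l(self) -> int:
        return self.xyz.shape[0]

    def __len__(self) -> int:
        return self.n_l

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Tight axis-aligned bounding box ``(lo, hi)`` of the points."""
        if self.n_l == 0:
            raise ValueError("empty table has no bounding box")
        return self.xyz.min(axis=0), self.xyz.max(axis=0)


@dataclass(frozen=True)
class ClusteringParams:
    """FOCAL3D parameters: grid spacing ``delta`` (nm), density threshold
    ``min_l`` (localizations) and cluster-size threshold ``min_c`` (voxels)."""

    delta: float
    min_l: int
    min_c: int

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.min_l < 1:
            raise ValueError("min_l must be >= 1")
        if self.min_c < 1:
            raise ValueError("min_c must be >= 1")


@dataclass
class VoxelGrid:
    """Discretized localization density map.

    ``counts[ix, iy, iz]`` is the number of localizations in the voxel whose
    lower corner is ``origin + (ix, iy, iz) * delta``.  ``point_index`` holds
    each localization's voxel triple (rows of ``-1`` mark points outside an
    explicitly supplied bounding box).
    """

    origin: np.ndarray
    delta: float
    dims: tuple[int, int, int]
    counts: np.ndarray
    point_index: np.ndarray

    @property
    def in_bounds(self) -> np.ndarray:
        """Boolean mask of localizations that fell inside the grid."""
        return self.point_index[:, 0] >= 0

    def linear_index(self, triples: np.ndarray) -> np.ndarray:
        """x-fastest linear voxel index ``ix + nx*(iy + ny*iz)``."""
        nx, ny, _ = self.dims
        t = np.asarray(triples).reshape(-1, 3)
        return t[:, 0] + nx * (t[:, 1] + ny * t[:, 2])


@dataclass
class EnhancedDensityMap:
    """3x3x3-neighbourhood sums of a :class:`VoxelGrid`.

    ``enhanced`` is defined everywhere, but only voxels flagged in
    ``eligible`` (occupied voxels, minus the outermost layer in strict edge
    mode) may become core voxels.
    """

    grid: VoxelGrid
    enhanced: np.ndarray
    eligible: np.ndarray


@dataclass
class ClusterInfo:
    """One detected cluster: its voxel membership and summary geometry."""

    core_voxels: np.ndarray  # (k, 3) int triples
    border_voxels: np.ndarray  # (m, 3) int triples
    member_indices: np.ndarray  # localization row indices
    n_voxels: int
    n_localizations: int
    centroid: np.ndarray  # (3,) nm


@dataclass
class ClusterResult:
    """Per-localization labels (-1 = noise, 0..K-1 = cluster) plus
    per-cluster records, for a given parameter set."""

    labels: np.ndarray
    clusters: list[ClusterInfo]
    params: ClusteringParams

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------


def build_density_map(
    table: LocalizationTable,
    delta: float,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
) -> VoxelGrid:
    """Assign each localization to a cubic voxel of side ``delta``.

    When ``bounds`` is omitted the grid covers the tight bounding box of the
    data, expanded (upward) to an integer number of voxels per axis, so no
    point is discarded.  With explicit ``bounds = (lo, hi)`` points outside
    the box are dropped (marked ``-1`` in ``point_index``).
    """
    if not delta > 0:
        raise ValueError("delta must be positive")

    if table.n_l == 0:
        lo = np.zeros(3) if bounds is None else np.asarray(bounds[0], dtype=float)
        hi = lo + delta if bounds is None else np.asarray(bounds[1], dtype=float)
        dims = tuple(int(max(1, np.ceil((h - l) / delta))) for l, h in zip(lo, hi))
        return VoxelGrid(
            origin=lo,
            delta=float(delta),
            dims=dims,
            counts=np.zeros(dims, dtype=np.int64),
            point_index=np.empty((0, 3), dtype=np.int64),
        )

    if bounds is None:
        lo, hi = table.bounding_box()
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
        if np.any(hi < lo):
            raise ValueError("bounds upper corner must not be below lower corner")

    dims_arr = np.maximum(1, np.ceil((hi - lo) / delta - 1e-12).astype(np.int64))
    dims = (int(dims_arr[0]), int(dims_arr[1]), int(dims_arr[2]))

    inb = np.all((table.xyz >= lo) & (table.xyz <= hi), axis=1)
    idx = np.floor((table.xyz - lo) / delta).astype(np.int64)
    # points exactly on the global upper bound belong to the last voxel
    idx = np.minimum(idx, dims_arr - 1)
    point_index = np.where(inb[:, None], idx, -1)

    counts = np.zeros(dims, dtype=np.int64)
    if inb.any():
        np.add.at(counts, tuple(idx[inb].T), 1)
    return VoxelGrid(
        origin=lo, delta=float(delta), dims=dims, counts=counts, point_index=point_index
    )


# ---------------------------------------------------------------------------
# Enhanced density map
# ---------------------------------------------------------------------------


def enhance_density_map(grid: VoxelGrid, strict_edges: bool = False) -> EnhancedDensityMap:
    """Sum localization counts over the 3x3x3 neighbourhood of every voxel.

    Out-of-grid neighbours contribute zero.  Only occupied voxels
    (``counts > 0``) are eligible to become core.  With ``strict_edges`` the
    outermost voxel layer (along axes at least 3 voxels thick) is additionally
    made ineligible, mirroring the convention of exempting bins at the edge of
    the sample volume from the clustering analysis; the default zero-padding
    mode merely gives edge voxels smaller neighbourhood sums so that no
    localization is silently excluded.
    """
    kernel = np.ones((3, 3, 3), dtype=np.int64)
    enhanced = ndimage.convolve(grid.counts, kernel, mode="constant", cval=0)
    eligible = grid.counts > 0
    if strict_edges:
        eligible = eligible.copy()
        for ax, n in enumerate(grid.dims):
            if n >= 3:
                sl_first = [slice(None)] * 3
                sl_last = [slice(None)] * 3
                sl_first[ax] = 0
                sl_last[ax] = n - 1
                eligible[tuple(sl_first)] = False
                eligible[tuple(sl_last)] = False
    return EnhancedDensityMap(grid=grid, enhanced=enhanced, eligible=eligible)


# ---------------------------------------------------------------------------
# Core / border classification
# ---------------------------------------------------------------------------


def classify_voxels(
    edm: EnhancedDensityMap, min_l: int, inclusive: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Split voxels into core and border masks at density threshold ``min_l``.

    Core voxels are eligible voxels whose enhanced density meets the
    threshold (``>= min_l`` by default; ``> min_l`` with ``inclusive=False``).
    Border voxels are occupied non-core voxels sharing a face with at least
    one core voxel (6-connectivity).  The two masks are disjoint.
    """
    if min_l < 1:
        raise ValueError("min_l must be >= 1")
    if inclusive:
        core = edm.eligible & (edm.enhanced >= min_l)
    else:
        core = edm.eligible & (edm.enhanced > min_l)
    near_core = ndimage.binary_dilation(core, structure=_STRUCT_6)
    border = (edm.grid.counts > 0) & ~core & near_core
    return core, border


# ---------------------------------------------------------------------------
# Cluster extraction
# ---------------------------------------------------------------------------


def _attach_border(lab: np.ndarray, border: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign each border voxel to one adjacent core component.

    Returns ``(coords, assigned)`` where ``coords`` is ``(m, 3)`` border voxel
    triples and ``assigned`` the component id of each (0 = no adjacent
    component; such voxels are dropped by the caller).  A voxel adjacent to
    several components goes to the one with the most adjacent core faces;
    remaining ties go to the smallest component id.
    """
    coords = np.argwhere(border)
    if coords.shape[0] == 0:
        return coords, np.zeros(0, dtype=lab.dtype)
    dims = np.array(lab.shape)
    neigh = np.zeros((coords.shape[0], 6), dtype=lab.dtype)
    for j, off in enumerate(_FACE_OFFSETS):
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < dims), axis=1)
        neigh[ok, j] = lab[tuple(nb[ok].T)]
    counts = (neigh[:, :, None] == neigh[:, None, :]).sum(axis=2)
    counts[neigh == 0] = 0
    best = counts.max(axis=1)
    cand = np.where(counts == best[:, None], neigh, np.iinfo(lab.dtype).max)
    assigned = cand.min(axis=1)
    assigned[best == 0] = 0
    return coords, assigned


def extract_clusters(
    core_mask: np.ndarray,
    border_mask: np.ndarray,
    min_c: int,
    connectivity: int = 6,
    dims: tuple[int, int, int] | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Group core voxels into connected components, attach border voxels, and
    keep candidates with at least ``min_c`` voxels (core + border).

    Returns a voxel label array (0 = unclustered, 1..K = cluster) and a list
    of per-cluster dicts with keys ``core`` and ``border`` (voxel triples).
    Retained clusters are numbered canonically by ascending minimum voxel
    linear index (x-fastest ordering), so labels are reproducible.
    """
    if min_c < 1:
        raise ValueError("min_c must be >= 1")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    if np.any(core_mask & border_mask):
        raise ValueError("core and border masks must be disjoint")
    structure = _STRUCT_6 if connectivity == 6 else _STRUCT_26

    lab, ncomp = ndimage.label(core_mask, structure=structure)
    voxel_labels = np.zeros_like(lab)
    if ncomp == 0:
        return voxel_labels, []

    bcoords, bassign = _attach_border(lab, border_mask)
    keep_b = bassign > 0
    bcoords, bassign = bcoords[keep_b], bassign[keep_b]

    core_sizes = np.bincount(lab.ravel(), minlength=ncomp + 1)[1:]
    border_sizes = np.bincount(bassign, minlength=ncomp + 1)[1:]
    total = core_sizes + border_sizes
    kept = np.flatnonzero(total >= min_c) + 1  # component ids, 1-based
    if kept.size == 0:
        return voxel_labels, []

    ccoords = np.argwhere(core_mask)
    clab = lab[tuple(ccoords.T)]

    nx, ny, _ = lab.shape if dims is None else dims
    lin_core = ccoords[:, 0] + nx * (ccoords[:, 1] + ny * ccoords[:, 2])
    min_lin = np.full(ncomp + 1, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(min_lin, clab, lin_core)
    if bcoords.shape[0]:
        lin_b = bcoords[:, 0] + nx * (bcoords[:, 1] + ny * bcoords[:, 2])
        np.minimum.at(min_lin, bassign, lin_b)

    order = kept[np.argsort(min_lin[kept], kind="stable")]
    remap = np.zeros(ncomp + 1, dtype=lab.dtype)
    remap[order] = np.arange(1, order.size + 1)

    clusters: list[dict] = []
    new_clab = remap[clab]
    new_blab = remap[bassign] if bassign.size else bassign
    for new_id in range(1, order.size + 1):
        clusters.append(
            {
                "core": ccoords[new_clab == new_id],
                "border": bcoords[new_blab == new_id] if bassign.size else bcoords[:0],
            }
        )
    voxel_labels[tuple(ccoords.T)] = new_clab
    if bcoords.shape[0]:
        voxel_labels[tuple(bcoords.T)] = new_blab
    return voxel_labels, clusters


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def focal3d(
    table: LocalizationTable,
    params: ClusteringParams,
    *,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    inclusive: bool = True,
    strict_edges: bool = False,
    connectivity: int = 6,
) -> ClusterResult:
    """Run the full FOCAL3D pipeline on a localization table.

    Composes :func:`build_density_map`, :func:`enhance_density_map`,
    :func:`classify_voxels` and :func:`extract_clusters`, then labels every
    localization that falls in a retained cluster's core or border voxel with
    that cluster's id (0-based); all other localizations get ``-1``.  The
    result is deterministic and invariant to input row permutation up to the
    canonical cluster numbering.
    """
    labels = np.full(table.n_l, NOISE_LABEL, dtype=np.int64)
    if table.n_l == 0:
        return ClusterResult(labels=labels, clusters=[], params=params)

    grid = build_density_map(table, params.delta, bounds=bounds)
    edm = enhance_density_map(grid, strict_edges=strict_edges)
    core, border = classify_voxels(edm, params.min_l, inclusive=inclusive)
    voxel_labels, raw_clusters = extract_clusters(
        core, border, params.min_c, connectivity=connectivity
    )

    inb = grid.in_bounds
    if inb.any():
        pt_vlab = voxel_labels[tuple(grid.point_index[inb].T)]
        labels[np.flatnonzero(inb)] = pt_vlab - 1  # 0 -> -1 (noise)

    clusters: list[ClusterInfo] = []
    for k, rc in enumerate(raw_clusters):
        members = np.flatnonzero(labels == k)
        clusters.append(
            ClusterInfo(
                core_voxels=rc["core"],
                border_voxels=rc["border"],
                member_indices=members,
                n_voxels=rc["core"].shape[0] + rc["border"].shape[0],
                n_localizations=members.size,
                centroid=table.xyz[members].mean(axis=0)
                if members.size
                else np.full(3, np.nan),
            )
        )
    return ClusterResult(labels=labels, clusters=clusters, params=params)
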