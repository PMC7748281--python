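"""Objective parameter selection for FOCAL3D.

The density threshold ``min_l`` is not tuned by eye: for every grid spacing
``delta`` and cluster-size threshold ``min_c``, a complete-spatial-randomness
(CSR) surrogate with the same number of localizations as the data, scattered
uniformly over the same volume, is clustered over an ascending range of
``min_l``; the optimum ``min_l*`` is the lowest threshold at which the
surrogate yields zero clusters.  Scanning ``min_c`` at several ``delta``
values then produces cluster-count curves whose flat (parameter-insensitive)
regions identify the operating point ``(delta*, min_c*)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    EnhancedDensityMap,
    LocalizationTable,
    ClusteringParams,
    _STRUCT_6,
    _STRUCT_26,
    _attach_border,
    build_density_map,
    classify_voxels,
    enhance_density_map,
    focal3d,
)

__all__ = [
    "ScanPoint",
    "ParameterScanResult",
    "PlateauRun",
    "PlateauReport",
    "make_csr_surrogate",
    "optimize_min_l",
    "scan_parameters",
    "find_plateau",
    "surrogate_seed",
]


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanPoint:
    """One point of the parameter scan: the ``min_l*`` selected against the
    CSR surrogate at ``(delta, min_c)`` and the cluster count obtained on the
    real data at ``(delta, min_l_star, min_c)``."""

    delta: float
    min_c: int
    min_l_star: int
    n_clusters: int
    exhausted: bool = False  # min_l range ran out without reaching 0 clusters


@dataclass
class ParameterScanResult:
    """Grid of :class:`ScanPoint` over delta x min_c, with the seed and
    surrogate replicate count needed to reproduce it."""

    points: list[ScanPoint]
    seed: int
    surrogate_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "delta": p.delta,
                    "min_c": p.min_c,
                    "min_l_star": p.min_l_star,
                    "n_clusters": p.n_clusters,
                    "exhausted": p.exhausted,
                }
                for p in self.points
            ]
        )

    def curve(self, delta: float) -> tuple[np.ndarray, np.ndarray]:
        """(min_c values, cluster counts) for one delta, ascending in min_c."""
        pts = sorted(
            (p for p in self.points if p.delta == delta), key=lambda p: p.min_c
        )
        return (
            np.array([p.min_c for p in pts]),
            np.array([p.n_clusters for p in pts]),
        )


@dataclass(frozen=True)
class PlateauRun:
    """Longest run of consecutive ``min_c`` values, at one delta, whose
    cluster counts vary within the relative tolerance."""

    delta: float
    min_c_values: tuple[int, ...]
    n_clusters: tuple[int, ...]
    length: int


@dataclass
class PlateauReport:
    """Plateau (parameter-insensitivity) analysis of a scan.

    ``recommended`` is ``(delta_star, min_c_star, min_l_star)`` — the delta
    with the longest plateau and the smallest ``min_c`` of that run (the
    plateau cusp) — or ``None`` when every curve is identically zero.
    ``low_confidence`` flags a best run of length 1 (no insensitive region).
    """

    runs: dict[float, PlateauRun]
    recommended: tuple[float, int, int] | None
    plateau_n_clusters: int | None
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# CSR surrogate
# ---------------------------------------------------------------------------


def make_csr_surrogate(
    table: LocalizationTable,
    rng_seed,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
) -> LocalizationTable:
    """Uniform-random surrogate of ``table``: same number of localizations,
    i.i.d. uniform over the data's axis-aligned bounding box (or an explicit
    ``bounds`` box for cropped fields of view).  Deterministic given seed."""
    if table.n_l == 0:
        raise ValueError("cannot build a CSR surrogate of an empty table")
    lo, hi = table.bounding_box() if bounds is None else (
        np.asarray(bounds[0], dtype=float),
        np.asarray(bounds[1], dtype=float),
    )
    rng = np.random.default_rng(rng_seed)
    xyz = rng.uniform(lo, hi, size=(table.n_l, 3))
    return LocalizationTable(xyz=xyz)


def surrogate_seed(rng_seed: int, delta_index: int) -> int:
    """The per-delta surrogate seed used by :func:`scan_parameters`.

    One surrogate is drawn per (scan seed, delta); this derives its seed so a
    scan point can be reproduced by a standalone :func:`optimize_min_l` call.
    """
    ss = np.random.SeedSequence(entropy=rng_seed, spawn_key=(delta_index,))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# min_l* selection
# ---------------------------------------------------------------------------


def _candidate_sizes(
    edm: EnhancedDensityMap, min_l: int, inclusive: bool, connectivity: int
) -> np.ndarray:
    """Sizes (core + attached border voxels) of all cluster candidates at
    threshold ``min_l``, before the min_c filter.  Matches
    :func:`focal3d.core.extract_clusters` candidate-for-candidate."""
    core, border = classify_voxels(edm, min_l, inclusive=inclusive)
    structure = _STRUCT_6 if connectivity == 6 else _STRUCT_26
    lab, ncomp = ndimage.label(core, structure=structure)
    if ncomp == 0:
        return np.zeros(0, dtype=np.int64)
    _, bassign = _attach_border(lab, border)
    core_sizes = np.bincount(lab.ravel(), minlength=ncomp + 1)[1:]
    border_sizes = np.bincount(bassign[bassign > 0], minlength=ncomp + 1)[1:]
    return core_sizes + border_sizes


class _SurrogateSweep:
    """Lazy per-min_l candidate-size evaluation for one or more surrogate
    density maps, shared across min_c values of a scan."""

    def __init__(self, edms: list[EnhancedDensityMap], inclusive: bool, connectivity: int):
        self.edms = edms
        self.inclusive = inclusive
        self.connectivity = connectivity
        self._max_size: dict[int, int] = {}
        self.max_min_l = max(
            (int(e.enhanced[e.eligible].max()) for e in edms if e.eligible.any()),
            default=1,
        )

    def max_candidate_size(self, min_l: int) -> int:
        """Largest candidate size across replicates at this threshold."""
        if min_l not in self._max_size:
            sizes = [
                _candidate_sizes(e, min_l, self.inclusive, self.connectivity)
                for e in self.edms
            ]
            self._max_size[min_l] = max(
                (int(s.max()) for s in sizes if s.size), default=0
            )
        return self._max_size[min_l]

    def min_l_star(self, min_c: int, min_l_range: Sequence[int]) -> tuple[int, bool]:
        """Smallest min_l in range with zero clusters (no candidate of size
        >= min_c) on every replicate; (range max, True) if none qualifies."""
        for m in min_l_range:
            if self.max_candidate_size(int(m)) < min_c:
                return int(m), False
        return int(min_l_range[-1]), True


def _surrogate_edms(
    table: LocalizationTable,
    delta: float,
    rng_seed: int,
    replicates: int,
    bounds,
    strict_edges: bool,
) -> list[EnhancedDensityMap]:
    seeds = [rng_seed] + [
        np.random.SeedSequence(entropy=rng_seed, spawn_key=(i,))
        for i in range(1, replicates)
    ]
    edms = []
    for s in seeds:
        surro = make_csr_surrogate(table, s, bounds=bounds)
        grid = build_density_map(surro, delta, bounds=bounds)
        edms.append(enhance_density_map(grid, strict_edges=strict_edges))
    return edms


def optimize_min_l(
    table: LocalizationTable,
    delta: float,
    min_c: int,
    min_l_range: Sequence[int] | None = None,
    rng_seed: int = 0,
    replicates: int = 1,
    *,
    bounds=None,
    inclusive: bool = True,
    strict_edges: bool = False,
    connectivity: int = 6,
) -> int:
    """Select ``min_l*``: the lowest density threshold at which FOCAL3D finds
    zero clusters on the CSR surrogate of ``table`` at ``(delta, min_c)``.

    The zero-cluster test runs with the same ``min_c`` under optimization —
    chance clusters on random data are typically removed by the size
    threshold, so ``min_c`` matters.  ``min_l_range`` defaults to
    ``1..max(enhanced surrogate density)``, which guarantees termination; if
    no value in an explicit range qualifies, the range maximum is returned
    with a warning.  With ``replicates > 1``, zero clusters is required on
    every replicate (which can only raise ``min_l*``).
    """
    if table.n_l == 0:
        raise ValueError("cannot optimize min_l on an empty table")
    edms = _surrogate_edms(table, delta, rng_seed, replicates, bounds, strict_edges)
    sweep = _SurrogateSweep(edms, inclusive, connectivity)
    if min_l_range is None:
        min_l_range = range(1, sweep.max_min_l + 2)
    min_l_star, exhausted = sweep.min_l_star(min_c, list(min_l_range))
    if exhausted:
        warnings.warn(
            "min_l range exhausted without reaching zero clusters on the CSR "
            "surrogate; returning the range maximum",
            stacklevel=2,
        )
    return min_l_star


# ---------------------------------------------------------------------------
# Parameter scan
# ---------------------------------------------------------------------------


def scan_parameters(
    table: LocalizationTable,
    delta_values: Sequence[float],
    min_c_values: Sequence[int],
    min_l_range: Sequence[int] | None = None,
    rng_seed: int = 0,
    replicates: int = 1,
    *,
    bounds=None,
    inclusive: bool = True,
    strict_edges: bool = False,
    connectivity: int = 6,
) -> ParameterScanResult:
    """Build cluster-count-vs-min_c curves at each delta, auto-selecting
    ``min_l*`` against the CSR surrogate at every scan point.

    One surrogate is drawn per (seed, delta) — seed derivable via
    :func:`surrogate_seed` — and, since ``min_c`` acts purely as a size
    filter, the per-``min_l`` candidate sizes of both the surrogate and the
    real data are computed once per delta and shared across ``min_c``
    values.  Every scan point is identical to an independently executed
    (:func:`optimize_min_l`, :func:`focal3d`) pair at the same seed.
    """
    if len(delta_values) == 0 or len(min_c_values) == 0:
        raise ValueError("delta_values and min_c_values must be non-empty")
    min_c_values = sorted(int(c) for c in min_c_values)

    points: list[ScanPoint] = []
    for di, delta in enumerate(delta_values):
        sseed = surrogate_seed(rng_seed, di)
        edms = _surrogate_edms(table, delta, sseed, replicates, bounds, strict_edges)
        sweep = _SurrogateSweep(edms, inclusive, connectivity)
        rng_range = (
            range(1, sweep.max_min_l + 2) if min_l_range is None else min_l_range
        )
        rng_range = list(rng_range)

        real_grid = build_density_map(table, delta, bounds=bounds)
        real_edm = enhance_density_map(real_grid, strict_edges=strict_edges)
        real_sizes: dict[int, np.ndarray] = {}

        for min_c in min_c_values:
            min_l_star, exhausted = sweep.min_l_star(min_c, rng_range)
            if min_l_star not in real_sizes:
                real_sizes[min_l_star] = _candidate_sizes(
                    real_edm, min_l_star, inclusive, connectivity
                )
            n_clusters = int((real_sizes[min_l_star] >= min_c).sum())
            points.append(
                ScanPoint(
                    delta=float(delta),
                    min_c=min_c,
                    min_l_star=min_l_star,
                    n_clusters=n_clusters,
                    exhausted=exhausted,
                )
            )
    return ParameterScanResult(
        points=points, seed=int(rng_seed), surrogate_replicates=int(replicates)
    )


# ---------------------------------------------------------------------------
# Plateau identification
# ---------------------------------------------------------------------------


def _longest_tolerant_run(
    min_c: np.ndarray, counts: np.ndarray, rel_tol: float
) -> tuple[int, int] | None:
    """Longest window [i, j] of consecutive points with nonzero counts whose
    spread satisfies (max - min) / max <= rel_tol.  Ties go to the earliest
    window.  Returns None when no nonzero point exists."""
    n = len(counts)
    best: tuple[int, int] | None = None
    best_len = 0
    for i in range(n):
        if counts[i] == 0:
            continue
        cmax = cmin = counts[i]
        for j in range(i, n):
            if counts[j] == 0:
                break
            cmax = max(cmax, counts[j])
            cmin = min(cmin, counts[j])
            if (cmax - cmin) / cmax > rel_tol:
                break
            if j - i + 1 > best_len:
                best_len = j - i + 1
                best = (i, j)
    return best


def find_plateau(scan: ParameterScanResult, rel_tol: float = 0.02) -> PlateauReport:
    """Identify, per delta, the longest run of consecutive ``min_c`` values
    whose cluster counts agree within ``rel_tol`` (relative spread), and
    recommend the operating point.

    ``delta_star`` is the delta with the longest run; ``min_c_star`` is the
    smallest ``min_c`` of that run — the cusp of the plateau, just past the
    inflection where the steep small-cluster descent flattens out.  Runs at
    zero clusters are excluded.  A best run of length 1 sets the
    ``low_confidence`` flag; all-zero curves yield no recommendation.
    """
    if not 0 < rel_tol < 1:
        raise ValueError("rel_tol must be in (0, 1)")
    if not scan.points:
        raise ValueError("empty scan")

    deltas = sorted({p.delta for p in scan.points})
    runs: dict[float, PlateauRun] = {}
    for d in deltas:
        mc, counts = scan.curve(d)
        window = _longest_tolerant_run(mc, counts, rel_tol)
        if window is None:
            continue
        i, j = window
        runs[d] = PlateauRun(
            delta=d,
            min_c_values=tuple(int(c) for c in mc[i : j + 1]),
            n_clusters=tuple(int(c) for c in counts[i : j + 1]),
            length=j - i + 1,
        )

    if not runs:
        return PlateauReport(
            runs={}, recommended=None, plateau_n_clusters=None, low_confidence=True
        )

    # longest plateau wins; ties go to the smaller delta
    delta_star = min(runs, key=lambda d: (-runs[d].length, d))
    run = runs[delta_star]
    min_c_star = run.min_c_values[0]
    min_l_star = next(
        p.min_l_star
        for p in scan.points
        if p.delta == delta_star and p.min_c == min_c_star
    )
    plateau_count = int(round(float(np.median(run.n_clusters))))
    return PlateauReport(
        runs=runs,
        recommended=(delta_star, min_c_star, min_l_star),
        plateau_n_clusters=plateau_count,
        low_confidence=run.length == 1,
    )
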