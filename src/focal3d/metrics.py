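"""Validation and shape statistics for clustering results.

Provides localization-level precision/recall/F1 against ground truth
(binary clustered-vs-noise, ignoring cluster identity), the cluster-level
silhouette score S_C = (dbar_NN - dbar_C) / dbar_NN, convex-hull effective
cluster radii, and 3D Ripley's K/H point-pattern analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist

from .core import ClusterResult, LocalizationTable, NOISE_LABEL

__all__ = [
    "ConfusionReport",
    "SilhouetteReport",
    "RipleyCurve",
    "HullRadius",
    "confusion",
    "match_clusters",
    "silhouette",
    "silhouette_from_labels",
    "hull_radius",
    "cluster_shape_report",
    "radius_distribution",
    "ripley",
]


# ---------------------------------------------------------------------------
# Confusion / F1
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionReport:
    """Localization-level binary confusion counts and P/R/F1 scores.

    ``no_true_positives_flag`` marks the degenerate convention R := 1 when
    the ground truth contains no clustered point at all.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    no_true_positives_flag: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(labels: np.ndarray, truth: np.ndarray) -> ConfusionReport:
    """Binary clustered-vs-noise confusion of predicted labels against truth.

    Cluster identity is ignored: a localization counts as a true positive
    whenever both truth and prediction consider it clustered (label >= 0).
    Precision is the fraction of predicted-clustered localizations that are
    truly clustered; recall the fraction of truly clustered localizations
    recovered.  Degenerate conventions: no predicted positives -> P := 0 and
    F1 := 0; no true positives in the ground truth -> R := 1, flagged.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise ValueError("labels and truth must have equal length")
    pred_c = labels >= 0
    true_c = truth >= 0
    tp = int(np.sum(pred_c & true_c))
    fp = int(np.sum(pred_c & ~true_c))
    fn = int(np.sum(~pred_c & true_c))
    tn = int(np.sum(~pred_c & ~true_c))

    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    flag = tp + fn == 0
    recall = tp / (tp + fn) if not flag else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return ConfusionReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=precision,
        recall=recall,
        f1=f1,
        no_true_positives_flag=flag,
    )


def match_clusters(labels: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Optional identity-aware extension: greedy maximum-overlap pairing of
    predicted clusters to ground-truth clusters.

    Returns one row per predicted cluster with its best-overlap truth
    cluster, the overlap count, and the Jaccard index of the pair.  This is
    an extension beyond the binary P/R/F1 definitions, for diagnostic use.
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    rows = []
    taken: set[int] = set()
    pred_ids, pred_sizes = np.unique(labels[labels >= 0], return_counts=True)
    order = np.argsort(-pred_sizes)  # largest predicted clusters first
    for pi in pred_ids[order]:
        members = labels == pi
        t_ids, t_counts = np.unique(truth[members & (truth >= 0)], return_counts=True)
        best_t, best_ov = -1, 0
        for t, c in zip(t_ids, t_counts):
            if t in taken:
                continue
            if c > best_ov:
                best_t, best_ov = int(t), int(c)
        union = int(members.sum())
        if best_t >= 0:
            taken.add(best_t)
            union += int((truth == best_t).sum()) - best_ov
        rows.append(
            {
                "cluster_id": int(pi),
                "truth_id": best_t,
                "overlap": best_ov,
                "jaccard": best_ov / union if union else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "truth_id", "overlap", "jaccard"])


# ---------------------------------------------------------------------------
# Silhouette
# ---------------------------------------------------------------------------


@dataclass
class SilhouetteReport:
    """Cluster-level silhouette S_C = (dbar_NN - dbar_C) / dbar_NN.

    ``dbar_C`` is the mean over clusters of the average pairwise distance
    among cluster members (members subsampled to ``max_sample`` per cluster,
    seeded); ``dbar_NN`` the mean over clusters of the distance from each
    cluster centroid to the nearest other cluster centroid.  These estimator
    choices are recorded in ``definitions`` because the score depends on
    them.
    """

    d_nn_mean: float
    d_c_mean: float
    score: float
    per_cluster_d_c: np.ndarray
    per_cluster_d_nn: np.ndarray
    definitions: dict = field(default_factory=dict)


def silhouette_from_labels(
    labels: np.ndarray,
    xyz: np.ndarray,
    max_sample: int = 500,
    rng_seed: int = 0,
) -> SilhouetteReport:
    """Silhouette score from a per-point label vector (-1 = noise, excluded).

    Requires at least two clusters (otherwise no nearest-neighbour cluster
    distance exists).
    """
    labels = np.asarray(labels)
    xyz = np.asarray(xyz, dtype=float)
    ids = np.unique(labels[labels >= 0])
    k = ids.size
    if k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    rng = np.random.default_rng(rng_seed)

    centroids = np.empty((k, 3))
    d_c = np.empty(k)
    for i, cid in enumerate(ids):
        pts = xyz[labels == cid]
        centroids[i] = pts.mean(axis=0)
        if pts.shape[0] > max_sample:
            sel = rng.choice(pts.shape[0], size=max_sample, replace=False)
            pts = pts[sel]
        d_c[i] = pdist(pts).mean() if pts.shape[0] > 1 else 0.0

    tree = cKDTree(centroids)
    dist, _ = tree.query(centroids, k=2)
    d_nn = dist[:, 1]

    d_nn_mean = float(d_nn.mean())
    d_c_mean = float(d_c.mean())
    score = (d_nn_mean - d_c_mean) / d_nn_mean
    return SilhouetteReport(
        d_nn_mean=d_nn_mean,
        d_c_mean=d_c_mean,
        score=float(score),
        per_cluster_d_c=d_c,
        per_cluster_d_nn=d_nn,
        definitions={
            "d_c": "mean over clusters of average pairwise member distance "
            f"(subsampled to {max_sample} members, seed {rng_seed})",
            "d_nn": "mean over clusters of nearest other-cluster centroid distance",
        },
    )


def silhouette(
    result: ClusterResult,
    table: LocalizationTable,
    max_sample: int = 500,
    rng_seed: int = 0,
) -> SilhouetteReport:
    """Silhouette score of a :class:`ClusterResult`; noise excluded."""
    return silhouette_from_labels(
        result.labels, table.xyz, max_sample=max_sample, rng_seed=rng_seed
    )


# ---------------------------------------------------------------------------
# Convex-hull effective radius
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HullRadius:
    """Convex-hull volume and sphere-equivalent effective radius of a point
    set; ``defined`` is False for < 4 points or a degenerate (coplanar)
    configuration."""

    volume: float
    r_eff: float
    n_points: int
    defined: bool


def hull_radius(points: np.ndarray) -> HullRadius:
    """Effective cluster radius from the 3D convex hull:
    ``r_eff = (3 V_hull / (4 pi))^(1/3)``."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    if n < 4:
        return HullRadius(volume=np.nan, r_eff=np.nan, n_points=n, defined=False)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return HullRadius(volume=np.nan, r_eff=np.nan, n_points=n, defined=False)
    v = float(hull.volume)
    return HullRadius(
        volume=v,
        r_eff=(3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0),
        n_points=n,
        defined=True,
    )


def cluster_shape_report(
    result: ClusterResult, table: LocalizationTable
) -> pd.DataFrame:
    """Per-cluster hull volume, effective radius and member count."""
    rows = []
    for i, cl in enumerate(result.clusters):
        hr = hull_radius(table.xyz[cl.member_indices])
        rows.append(
            {
                "cluster_id": i,
                "n_localizations": cl.n_localizations,
                "hull_volume": hr.volume,
                "r_eff": hr.r_eff,
                "defined": hr.defined,
            }
        )
    return pd.DataFrame(
        rows, columns=["cluster_id", "n_localizations", "hull_volume", "r_eff", "defined"]
    )


def radius_distribution(
    result: ClusterResult, table: LocalizationTable
) -> dict:
    """Distribution of per-cluster effective radii.

    Returns the defined r_eff values with their mean and standard deviation;
    a long right tail diagnoses cluster merging at too-coarse parameters.
    """
    rep = cluster_shape_report(result, table)
    vals = rep.loc[rep["defined"], "r_eff"].to_numpy()
    return {
        "r_eff": vals,
        "mean": float(vals.mean()) if vals.size else np.nan,
        "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        "n": int(vals.size),
    }


# ---------------------------------------------------------------------------
# Ripley's K / H
# ---------------------------------------------------------------------------


@dataclass
class RipleyCurve:
    """3D Ripley statistics on an ascending radius grid.

    ``k`` is the unweighted 3D estimator K(r) = V/(n(n-1)) sum_{i!=j}
    1[d_ij <= r] (no edge correction; adequate when the clustering scale is
    much smaller than the analysis window).  L(r) = (3K/(4 pi))^(1/3),
    H(r) = L(r) - r; for complete spatial randomness H(r) is approximately
    zero.  ``r_peak`` (argmax H) and ``r_dh_zero`` (first downward zero
    crossing of dH/dr) are two readouts of the dominant cluster length
    scale; neither is privileged.
    """

    r: np.ndarray
    k: np.ndarray
    l: np.ndarray
    h: np.ndarray
    dh_dr: np.ndarray
    r_peak: float
    r_dh_zero: float


def ripley(
    table: LocalizationTable | np.ndarray,
    radii: Sequence[float],
    volume_box: tuple[Sequence[float], Sequence[float]],
    periodic: bool = False,
) -> RipleyCurve:
    """Compute 3D Ripley K/L/H curves of a point pattern.

    ``periodic=True`` wraps distances on the torus defined by ``volume_box``
    (toroidal edge correction), removing the negative bias of the plain
    estimator at radii comparable to the window size.
    """
    xyz = table.xyz if isinstance(table, LocalizationTable) else np.asarray(table)
    n = xyz.shape[0]
    if n < 2:
        raise ValueError("Ripley analysis requires at least 2 points")
    r = np.asarray(radii, dtype=float)
    if r.size == 0 or np.any(np.diff(r) <= 0):
        raise ValueError("radii must be non-empty and strictly ascending")
    lo = np.asarray(volume_box[0], dtype=float)
    hi = np.asarray(volume_box[1], dtype=float)
    v = float(np.prod(hi - lo))

    if periodic:
        side = hi - lo
        tree = cKDTree(np.mod(xyz - lo, side), boxsize=side)
    else:
        tree = cKDTree(xyz)
    # ordered pair counts (i != j); count_neighbors includes the n self pairs
    pair_counts = tree.count_neighbors(tree, r) - n
    k = v / (n * (n - 1)) * pair_counts
    l = (3.0 * k / (4.0 * np.pi)) ** (1.0 / 3.0)
    h = l - r
    dh = np.gradient(h, r)

    r_peak = float(r[np.argmax(h)])
    r_dh_zero = np.nan
    sign = np.sign(dh)
    for i in range(len(r) - 1):
        if sign[i] > 0 and sign[i + 1] <= 0:
            # linear interpolation of the downward crossing
            r_dh_zero = float(
                r[i] + (r[i + 1] - r[i]) * dh[i] / (dh[i] - dh[i + 1])
            )
            break
    return RipleyCurve(
        r=r, k=k, l=l, h=h, dh_dr=dh, r_peak=r_peak, r_dh_zero=r_dh_zero
    )
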