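"""Synthetic SMLM cluster simulator with full ground truth.

The generator reproduces the statistical structure of benchmark SMLM
simulations used to validate density-based clustering:

* spherically symmetric clusters whose radii follow a Gaussian law
  (truncated at zero) with stated mean and spread, e.g. 80 +/- 16 nm;
* cluster centroids uniform in the simulation volume subject to a minimum
  pairwise separation (density-based methods are not designed for
  overlapping clusters);
* a Poisson number of dyes per cluster, placed uniformly in the sphere;
* a geometric number of localizations per dye with mean
  ``Nbar_locs = tau_ON / (1 - exp(-1/lambda))`` — the discrete analogue of
  exponentially distributed blink counts, guaranteeing at least one
  localization per dye;
* anisotropic Gaussian localization scatter about each dye, with
  per-localization widths drawn from a log-normal precision law whose means
  are delta_xy = 10 nm laterally and delta_z = 20 nm axially (axial
  precision is poorer in astigmatic 3D SMLM, which elongates the otherwise
  symmetric clusters along z);
* uniform background noise controlled by the dimensionless noise level
  zeta — the ratio of background localization density to the mean
  in-cluster localization density:

      zeta = (N_noise / V_sim) / (Nbar_cluster / Vbar_cluster)

  so ``N_noise = round(zeta * (Nbar_cluster / Vbar_cluster) * V_sim)``;
  zeta = 1 means noise as dense as the clusters themselves.

Default simulation volume gives approximately one cluster per cubic micron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import LocalizationTable, NOISE_LABEL

__all__ = [
    "PopulationSpec",
    "NoiseSpec",
    "SimulationOutput",
    "PackingError",
    "place_centroids",
    "simulate_cluster",
    "add_noise",
    "simulate_dataset",
    "preset_specs",
    "simulate_preset",
    "PRESET_NAMES",
]


class PackingError(RuntimeError):
    """Raised when centroids cannot be packed at the requested density."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """One population of simulated clusters.

    ``locs_per_dye_mean`` may be given directly or via the blink parameters
    ``(tau_on, lam)`` through ``Nbar_locs = tau_on / (1 - exp(-1/lam))``;
    when both are supplied they must agree to 1e-9 relative.
    """

    n_clusters: int
    radius_mean: float  # nm
    radius_sd: float  # nm
    dyes_mean: float  # mean dyes per cluster (Poisson)
    locs_per_dye_mean: float | None = None
    tau_on: float | None = None
    lam: float | None = None
    precision_lateral: float = 10.0  # delta_xy, nm
    precision_axial: float = 20.0  # delta_z, nm
    min_separation: float = 0.0  # nm, between cluster centroids

    def __post_init__(self) -> None:
        for name in (
            "radius_mean",
            "radius_sd",
            "dyes_mean",
            "precision_lateral",
            "precision_axial",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        derived = None
        if self.tau_on is not None and self.lam is not None:
            derived = self.tau_on / (1.0 - math.exp(-1.0 / self.lam))
        if self.locs_per_dye_mean is None:
            if derived is None:
                raise ValueError(
                    "provide locs_per_dye_mean or both tau_on and lam"
                )
            object.__setattr__(self, "locs_per_dye_mean", derived)
        elif derived is not None:
            if abs(derived - self.locs_per_dye_mean) > 1e-9 * self.locs_per_dye_mean:
                raise ValueError(
                    "tau_on/(1-exp(-1/lam)) inconsistent with locs_per_dye_mean"
                )
        if not self.locs_per_dye_mean > 0:
            raise ValueError("locs_per_dye_mean must be positive")

    @property
    def mean_cluster_locs(self) -> float:
        """Expected localizations per cluster, dyes_mean * locs_per_dye_mean."""
        return self.dyes_mean * float(self.locs_per_dye_mean)

    @property
    def mean_cluster_volume(self) -> float:
        """Nominal mean cluster volume (4/3) pi radius_mean^3, nm^3."""
        return 4.0 / 3.0 * math.pi * self.radius_mean**3


@dataclass(frozen=True)
class NoiseSpec:
    """Uniform background noise at dimensionless level ``zeta``.

    ``mean_cluster_locs`` and ``mean_cluster_volume`` are the *expected*
    per-cluster localization count and volume of the generating model (for
    mixed populations: means pooled over populations weighted by cluster
    counts), so the noise count is a deterministic function of the spec."""

    zeta: float
    mean_cluster_locs: float
    mean_cluster_volume: float

    def __post_init__(self) -> None:
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0")

    @property
    def cluster_density(self) -> float:
        """Mean in-cluster localization density, nm^-3."""
        return self.mean_cluster_locs / self.mean_cluster_volume

    def n_noise(self, v_sim: float) -> int:
        """Noise localization count for simulation volume ``v_sim`` (nm^3)."""
        return int(round(self.zeta * self.cluster_density * v_sim))

    @classmethod
    def pooled(cls, specs: Sequence[PopulationSpec], zeta: float) -> "NoiseSpec":
        """Pool expected cluster count/volume over populations, weighted by
        the number of clusters each contributes."""
        w = np.array([s.n_clusters for s in specs], dtype=float)
        if w.sum() == 0:
            return cls(zeta=zeta, mean_cluster_locs=1.0, mean_cluster_volume=1.0)
        locs = np.array([s.mean_cluster_locs for s in specs])
        vols = np.array([s.mean_cluster_volume for s in specs])
        return cls(
            zeta=zeta,
            mean_cluster_locs=float((w * locs).sum() / w.sum()),
            mean_cluster_volume=float((w * vols).sum() / w.sum()),
        )


@dataclass
class SimulationOutput:
    """A simulated dataset with complete ground truth."""

    table: LocalizationTable
    truth_labels: np.ndarray  # per-localization cluster id, -1 = noise
    dye_positions: list[np.ndarray]  # per cluster, (n_dyes, 3) nm
    cluster_centroids: np.ndarray  # (K, 3) nm (generative sphere centres)
    cluster_radii: np.ndarray  # (K,) nm (drawn radii)
    population_ids: np.ndarray  # (K,) index into the spec list
    volume_box: tuple[np.ndarray, np.ndarray]
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_noise(self) -> int:
        return int((self.truth_labels == NOISE_LABEL).sum())

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_radii)


# ---------------------------------------------------------------------------
# Centroid placement
# ---------------------------------------------------------------------------


def place_centroids(
    n: int,
    volume_box: tuple[Sequence[float], Sequence[float]],
    min_separation: float,
    rng: np.random.Generator,
    max_attempts: int | None = None,
) -> np.ndarray:
    """Place ``n`` centroids uniformly in ``volume_box`` with all pairwise
    distances >= ``min_separation`` (dart throwing).

    Raises :class:`PackingError`, reporting the attempted packing density,
    if the attempt budget (default ``10000 * n``) runs out.
    """
    lo = np.asarray(volume_box[0], dtype=float)
    hi = np.asarray(volume_box[1], dtype=float)
    if n == 0:
        return np.empty((0, 3))
    if max_attempts is None:
        max_attempts = 10_000 * n
    out = np.empty((n, 3))
    placed = 0
    attempts = 0
    min_sq = min_separation**2
    while placed < n:
        if attempts >= max_attempts:
            vol = float(np.prod(hi - lo))
            sphere = 4.0 / 3.0 * math.pi * (min_separation / 2.0) ** 3
            raise PackingError(
                f"failed to place {n} centroids with min separation "
                f"{min_separation} nm in volume {vol:.3g} nm^3 "
                f"(packing fraction {n * sphere / vol:.3g})"
            )
        attempts += 1
        cand = rng.uniform(lo, hi)
        if placed and min_separation > 0:
            d2 = ((out[:placed] - cand) ** 2).sum(axis=1)
            if d2.min() < min_sq:
                continue
        out[placed] = cand
        placed += 1
    return out


# ---------------------------------------------------------------------------
# Single-cluster generation
# ---------------------------------------------------------------------------


def _uniform_in_sphere(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-300)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * r


def _blink_counts(
    n_dyes: int, mean: float, rng: np.random.Generator, law: str
) -> np.ndarray:
    if law == "geometric":
        # support {1, 2, ...}, mean 1/p
        return rng.geometric(p=1.0 / mean, size=n_dyes)
    if law == "exponential":
        # continuous exponential rounded to the nearest count; zero-blink
        # draws yield dyes that were never observed
        return np.rint(rng.exponential(scale=mean, size=n_dyes)).astype(np.int64)
    raise ValueError(f"unknown blink law {law!r}")


def _precision_draw(
    n: int, mean: float, cv: float, rng: np.random.Generator
) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    s2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(s2), size=n)


def simulate_cluster(
    centroid: Sequence[float],
    radius: float,
    spec: PopulationSpec,
    rng: np.random.Generator,
    *,
    blink_law: str = "geometric",
    precision_cv: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one cluster; returns ``(localizations, dye_positions)``.

    A Poisson(``dyes_mean``) number of dyes is placed uniformly in the
    sphere of the given radius; each dye emits a blink-law number of
    localizations scattered about it with anisotropic Gaussian noise whose
    per-localization widths come from the precision law (log-normal with
    means ``precision_lateral``/``precision_axial`` and coefficient of
    variation ``precision_cv``; ``precision_cv=0`` gives fixed widths).
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    c = np.asarray(centroid, dtype=float)
    n_dyes = rng.poisson(spec.dyes_mean)
    dyes = c + _uniform_in_sphere(n_dyes, radius, rng)
    blinks = _blink_counts(n_dyes, float(spec.locs_per_dye_mean), rng, blink_law)
    centres = np.repeat(dyes, blinks, axis=0)
    n_locs = centres.shape[0]
    sig_xy = _precision_draw(n_locs, spec.precision_lateral, precision_cv, rng)
    sig_z = _precision_draw(n_locs, spec.precision_axial, precision_cv, rng)
    sigma = np.column_stack([sig_xy, sig_xy, sig_z])
    locs = centres + rng.normal(size=(n_locs, 3)) * sigma
    return locs, dyes


# ---------------------------------------------------------------------------
# Noise and full datasets
# ---------------------------------------------------------------------------


def add_noise(
    table: LocalizationTable,
    truth_labels: np.ndarray,
    noise: NoiseSpec,
    volume_box: tuple[Sequence[float], Sequence[float]],
    rng: np.random.Generator,
) -> tuple[LocalizationTable, np.ndarray, int]:
    """Append uniformly distributed background localizations at level zeta.

    Returns the augmented table, the augmented truth labels (noise rows get
    -1), and the number of noise points added.
    """
    lo = np.asarray(volume_box[0], dtype=float)
    hi = np.asarray(volume_box[1], dtype=float)
    v_sim = float(np.prod(hi - lo))
    n_noise = noise.n_noise(v_sim)
    if n_noise == 0:
        return table, np.asarray(truth_labels, dtype=np.int64), 0
    pts = rng.uniform(lo, hi, size=(n_noise, 3))
    xyz = np.vstack([table.xyz, pts])
    labels = np.concatenate(
        [np.asarray(truth_labels, dtype=np.int64), np.full(n_noise, NOISE_LABEL)]
    )
    return LocalizationTable(xyz=xyz), labels, n_noise


def _default_box(n_clusters: int) -> tuple[np.ndarray, np.ndarray]:
    """Cube of volume ``n_clusters`` cubic microns — about 1 cluster/um^3."""
    side = 1000.0 * max(n_clusters, 1) ** (1.0 / 3.0)  # nm
    return np.zeros(3), np.full(3, side)


def simulate_dataset(
    specs: Sequence[PopulationSpec],
    zeta: float = 0.0,
    volume_box: tuple[Sequence[float], Sequence[float]] | None = None,
    rng_seed: int = 0,
    *,
    blink_law: str = "geometric",
    precision_cv: float = 0.25,
) -> SimulationOutput:
    """Generate a full synthetic dataset from one or more population specs.

    Centroids of all populations are placed jointly with a global minimum
    separation equal to the largest ``min_separation`` among the specs.  The
    background noise count follows the zeta relation with the pooled expected
    per-cluster localization count and volume.  Deterministic given
    ``rng_seed``.
    """
    if len(specs) == 0:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(rng_seed)
    n_total = sum(s.n_clusters for s in specs)
    box = _default_box(n_total) if volume_box is None else (
        np.asarray(volume_box[0], dtype=float),
        np.asarray(volume_box[1], dtype=float),
    )

    min_sep = max((s.min_separation for s in specs), default=0.0)
    centroids = place_centroids(n_total, box, min_sep, rng)

    xyz_parts: list[np.ndarray] = []
    label_parts: list[np.ndarray] = []
    dye_positions: list[np.ndarray] = []
    radii = np.empty(n_total)
    pop_ids = np.empty(n_total, dtype=np.int64)

    k = 0
    for pi, spec in enumerate(specs):
        for _ in range(spec.n_clusters):
            r = rng.normal(spec.radius_mean, spec.radius_sd)
            while r <= 0:  # truncate the radius law at zero
                r = rng.normal(spec.radius_mean, spec.radius_sd)
            locs, dyes = simulate_cluster(
                centroids[k],
                r,
                spec,
                rng,
                blink_law=blink_law,
                precision_cv=precision_cv,
            )
            xyz_parts.append(locs)
            label_parts.append(np.full(locs.shape[0], k, dtype=np.int64))
            dye_positions.append(dyes)
            radii[k] = r
            pop_ids[k] = pi
            k += 1

    xyz = np.vstack(xyz_parts) if xyz_parts else np.empty((0, 3))
    labels = (
        np.concatenate(label_parts) if label_parts else np.empty(0, dtype=np.int64)
    )
    table = LocalizationTable(xyz=xyz)

    noise = NoiseSpec.pooled(specs, zeta)
    table, labels, n_noise = add_noise(table, labels, noise, box, rng)

    meta = {
        "zeta": zeta,
        "n_noise": n_noise,
        "blink_law": blink_law,
        "precision_cv": precision_cv,
        "tau_on": [s.tau_on for s in specs],
        "lam": [s.lam for s in specs],
        "pooled_cluster_density": noise.cluster_density,
    }
    return SimulationOutput(
        table=table,
        truth_labels=labels,
        dye_positions=dye_positions,
        cluster_centroids=centroids,
        cluster_radii=radii,
        population_ids=pop_ids,
        volume_box=(box[0], box[1]),
        seed=int(rng_seed),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Benchmark presets
# ---------------------------------------------------------------------------

_POP_80 = dict(radius_mean=80.0, radius_sd=16.0, dyes_mean=20.0, locs_per_dye_mean=10.0)
_POP_60 = dict(radius_mean=60.0, radius_sd=12.0, dyes_mean=20.0, locs_per_dye_mean=10.0)
_POP_40 = dict(radius_mean=40.0, radius_sd=8.0, dyes_mean=10.0, locs_per_dye_mean=10.0)

PRESET_NAMES = (
    "80nm",
    "60nm",
    "40nm",
    "mix-40-80",
    "mix-60-80",
    "mix-40-60-80",
)


def preset_specs(name: str) -> list[PopulationSpec]:
    """Benchmark population specs.

    Single populations hold 100 clusters with centroid separations of at
    least 330/310/290 nm for 80/60/40 nm mean radii; the 50/50 mixtures hold
    100 clusters and the three-way mixture 40+40+40 = 120 clusters, all with
    250 nm minimum separation.
    """
    if name == "80nm":
        return [PopulationSpec(n_clusters=100, min_separation=330.0, **_POP_80)]
    if name == "60nm":
        return [PopulationSpec(n_clusters=100, min_separation=310.0, **_POP_60)]
    if name == "40nm":
        return [PopulationSpec(n_clusters=100, min_separation=290.0, **_POP_40)]
    if name == "mix-40-80":
        return [
            PopulationSpec(n_clusters=50, min_separation=250.0, **_POP_40),
            PopulationSpec(n_clusters=50, min_separation=250.0, **_POP_80),
        ]
    if name == "mix-60-80":
        return [
            PopulationSpec(n_clusters=50, min_separation=250.0, **_POP_60),
            PopulationSpec(n_clusters=50, min_separation=250.0, **_POP_80),
        ]
    if name == "mix-40-60-80":
        return [
            PopulationSpec(n_clusters=40, min_separation=250.0, **_POP_40),
            PopulationSpec(n_clusters=40, min_separation=250.0, **_POP_60),
            PopulationSpec(n_clusters=40, min_separation=250.0, **_POP_80),
        ]
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def simulate_preset(
    name: str, zeta: float = 0.01, rng_seed: int = 0, **kwargs
) -> SimulationOutput:
    """Generate one of the standard benchmark datasets."""
    return simulate_dataset(preset_specs(name), zeta=zeta, rng_seed=rng_seed, **kwargs)
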