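# Methods

This note documents the model and procedure implemented by `focal3d`, the
parameters that matter, the generative model behind the synthetic
benchmarks, the estimator definitions used by the metrics, and the design
choices made where the procedure admitted more than one reasonable
formalization.

## The clustering algorithm

Given a localization table (x, y, z in nm) and parameters (Δ, *minL*,
*minC*):

1. **Binning.** Voxels are half-open cubes `[kΔ, (k+1)Δ)` per axis. When
   no bounding box is supplied, the grid is the tight bounding box of the
   data expanded upward to an integer number of voxels, so no point is
   discarded; points exactly on the global upper bound fall in the last
   voxel. With an explicit box, outside points are dropped and reported.
2. **Enhanced density map.** Each voxel's count is replaced by the sum
   over its 3×3×3 neighbourhood (a 27-point box convolution;
   out-of-grid neighbours contribute zero). Only voxels that contain at
   least one localization are *eligible* to become core: an empty voxel
   can never seed a cluster regardless of its neighbourhood sum.
3. **Classification.** Core = eligible voxels with enhanced density
   ≥ *minL* (inclusive comparison; a `inclusive=False` flag switches to
   strict `>`). Border = occupied non-core voxels sharing a face
   (6-connectivity) with at least one core voxel. The inclusive
   convention is pinned by tests; it reads naturally with the definition
   of *minL** as the *lowest* threshold yielding zero clusters on random
   data.
4. **Extraction.** Connected components of core voxels under
   6-connectivity (26-connectivity available by flag). Each border voxel
   attaches to exactly one adjacent component: the one with the most
   touching core faces, remaining ties to the component with the smaller
   canonical index. Candidates with core + border voxel count ≥ *minC*
   are retained and numbered by ascending minimum voxel linear index
   (x-fastest), which makes labels reproducible and invariant to input
   row permutation.
5. **Labeling.** Every localization in a retained cluster's core or
   border voxel gets that cluster's 0-based id; all others get −1.

**Edge handling.** By default the neighbourhood sum is simply zero-padded,
so voxels at the edge of the volume receive smaller enhanced values but
their localizations are never silently excluded. A `strict_edges` mode
makes the outermost voxel layer ineligible as core (it may still be
border), reproducing the convention of exempting edge bins from the
analysis; the layer is only stripped along axes at least 3 voxels thick so
that single-slab (2D) grids are not emptied.

**2D input.** Tables without a z column are admitted as a one-voxel-thick
grid; the 3×3×3 neighbourhood degenerates to 3×3 automatically because
out-of-grid neighbours contribute zero.

**Complexity.** Binning is one pass over the points; all later stages
operate on the voxel grid, whose size is fixed by the volume and Δ. Run
time is therefore linear in the number of localizations (the test suite
checks a power-law exponent ≤ 1.2 over a 16× range of *n*<sub>l</sub>),
with a grid-dependent constant — very fine grids trade memory and
constant cost for resolution.

## Parameter selection

**Density threshold.** For each (Δ, *minC*), a CSR surrogate — the same
number of localizations scattered i.i.d. uniformly over the data's
bounding box — is clustered over an ascending range of *minL*; *minL** is
the lowest value at which zero clusters are found. The zero-cluster test
runs with the same *minC* under optimization (chance clusters on random
data are mostly removed by the size filter, so *minC* matters). The
default search range is 1..max(enhanced surrogate density), which
guarantees termination; an exhausted explicit range returns its maximum
with a warning. One surrogate is drawn per (scan seed, Δ);
`surrogate_seed(seed, delta_index)` exposes the derivation so any scan
point can be reproduced standalone. Optionally, R replicates require zero
clusters on all of them, which can only raise *minL**.

**Scan.** Because *minC* is a pure size filter, the candidate component
sizes at each *minL* are computed once per Δ and shared across the *minC*
axis; the scan is nonetheless point-for-point identical to independent
(optimize, cluster) executions, which a test asserts. Cluster counts are
non-increasing in *minC* by construction.

**Plateau identification.** The clusters-vs-*minC* curves are flat near
the optimal grid size Δ*. We formalize "flat" as the longest run of
consecutive *minC* values whose counts satisfy (max − min)/max ≤ 2%
(configurable `rel_tol`); runs at zero clusters are excluded. The
recommended operating point is the Δ with the longest run and the
smallest *minC* of that run — the cusp of the plateau, just past the
inflection where the steep descent from spurious small clusters levels
off. Two caveats, both visible in the emitted curves (raw scan output is
always written for user supervision): an over-coarse grid can produce a
long flat run that *undercounts* (flatness alone does not certify
accuracy, so the longest-run winner should be sanity-checked against the
neighbouring curves), and a best run of length 1 sets a low-confidence
flag. A Ripley's H analysis (`ripley`) gives a useful starting scale for
the Δ search range; wiring the two together is left to the user.

## The synthetic-data generator

The generator emulates benchmark SMLM simulations at the localization-
table level (no camera, PSF or fitting stage):

* **Clusters.** Spherical, radii Gaussian with stated mean ± sd
  (80 ± 16, 60 ± 12, 40 ± 8 nm presets), truncated at zero. Centroids
  uniform in the volume with a minimum pairwise separation (330/310/290 nm
  for the single-population presets, 250 nm for mixtures) placed by dart
  throwing with an attempt budget; the simulation volume defaults to a
  cube of *n*<sub>clusters</sub> µm³ — about one cluster per µm³.
* **Dyes.** Poisson-distributed count per cluster (means 20, 20, 10 for
  the 80, 60, 40 nm presets), positions uniform in the sphere.
* **Blinking.** Each dye yields a geometric number of localizations on
  {1, 2, …} with mean N̄<sub>locs</sub> = τ<sub>ON</sub>/(1 − e^(−1/λ)) =
  10 for the presets. The geometric law is the discrete analogue of an
  exponential blink-count distribution and guarantees at least one
  localization per observed dye; a continuous-exponential-then-round
  option is provided (its rounding can drop dyes). τ<sub>ON</sub> and λ
  are accepted and recorded but only their combination affects the
  generator.
* **Localization scatter.** Each localization is the dye position plus
  anisotropic Gaussian noise. Per-localization widths are drawn from
  log-normal laws with means δ<sub>xy</sub> = 10 nm (lateral) and
  δ<sub>z</sub> = 20 nm (axial) and coefficient of variation 0.25 — a
  strictly positive, right-skewed stand-in for typical SMLM precision
  histograms; `precision_cv=0` gives fixed widths for exact-variance
  tests. The poorer axial precision elongates the otherwise symmetric
  clusters along z.
* **Noise.** The dimensionless level ζ is the ratio of background to mean
  in-cluster localization density: N<sub>noise</sub> = round(ζ ·
  (N̄<sub>cluster</sub>/V̄<sub>cluster</sub>) · V<sub>sim</sub>), with
  the expected values N̄<sub>cluster</sub> = N̄<sub>dyes</sub> ·
  N̄<sub>locs</sub> and V̄<sub>cluster</sub> = (4/3)π R̄³ at the nominal
  mean radius (for mixtures, pooled over populations weighted by cluster
  counts). The nominal-radius convention reproduces the presets' stated
  in-cluster densities (~1×10⁻⁴, 2×10⁻⁴, 4×10⁻⁴ nm⁻³ for 80/60/40 nm) at
  one significant figure. ζ = 1 means background as dense as the clusters;
  because the background fills the whole volume, even ζ = 0.01 on the
  80 nm preset adds ~93k noise points to ~19k clustered ones.

**What passing tests show — and don't.** The generator realizes the
idealized conditions of the benchmark: hard minimum centroid separations
(no overlapping clusters), spherical shapes, spatially uniform background,
no drift, no repeated-blink merging artifacts beyond the blink law itself.
Performance on these benchmarks bounds what to expect on real data from
above; dense fields of touching or ring-like clusters will be harder, and
the plateau in particular narrows as clusters crowd together.

## Metric definitions

* **Precision/recall/F1** are binary clustered-vs-noise at the
  localization level; cluster identity is ignored. Degenerate
  conventions: no predicted positives → P := 0, F1 := 0; no truly
  clustered points → R := 1, flagged. An identity-aware greedy
  maximum-overlap pairing (`match_clusters`) is provided separately as a
  diagnostic extension. Note that uniform noise falling *inside* a
  cluster is unidentifiable in principle, so F1 decreases with ζ even for
  a perfect clusterer.
* **Silhouette** S<sub>C</sub> = (d̄<sub>NN</sub> − d̄<sub>C</sub>)/
  d̄<sub>NN</sub>, where d̄<sub>C</sub> = mean over clusters of the
  average pairwise distance among members (members subsampled to 500 per
  cluster, seeded) and d̄<sub>NN</sub> = mean over clusters of the
  distance to the nearest other cluster centroid. These are the closest
  literal readings of "mean intra-cluster distance" and "nearest-
  neighbour cluster distance"; since the score depends on the estimator
  choice, the definitions are recorded in the report itself.
* **Effective radius** r<sub>eff</sub> = (3 V<sub>hull</sub>/(4π))^(1/3)
  from the 3D convex hull of a cluster's member localizations (< 4 points
  or a degenerate configuration is flagged undefined). The per-cluster
  radius distribution diagnoses merging: a long right tail appears when
  the grid or *minC* is too coarse.
* **Ripley K/H.** K(r) = V/(n(n−1)) Σ<sub>i≠j</sub> 1[d<sub>ij</sub> ≤ r],
  L = (3K/4π)^(1/3), H = L − r. No edge correction by default (adequate
  when the cluster scale is far below the window size; the estimator
  biases negative as r approaches the window); toroidal wrapping is
  available by flag and used for CSR null checks. Both argmax H and the
  downward zero of dH/dr are reported as cluster-scale estimates; neither
  is privileged.

## Numerical choices and degenerate inputs

* Empty tables cluster to zero clusters; empty files read as empty tables
  with a warning. Non-finite coordinate rows are dropped with a logged
  count.
* A small epsilon guards the voxel-count computation against
  floating-point ties when the data extent is an exact multiple of Δ.
* All randomness flows through `numpy.random.default_rng` seeds;
  simulation, surrogate generation and silhouette subsampling are
  bit-reproducible given a seed. Derived seeds use `SeedSequence` spawn
  keys and stay below 2³¹.
* The noise label is −1 everywhere; cluster ids are dense 0..K−1 in
  canonical (minimum linear voxel index) order.

## Benchmark scales used by the test suite and acceptance script

The single-population 80 nm benchmark is run at its full stated scale
(100 clusters, ~1.1×10⁵ localizations at ζ = 0.01), the mixture at 120
clusters (~2×10⁵ localizations); the acceptance script averages each
reported quantity over three simulation seeds. Unit and property tests
use smaller instances (≤ 20³ voxel grids, ≤ a few hundred points) where
they compare against brute-force oracles, since the oracles are
deliberately written as per-voxel loops.

## Known limitations

* Not designed to split overlapping or touching clusters; the benchmark
  generator enforces separation, and on crowded data the choice of Δ
  becomes more delicate (use the radius distribution and silhouette to
  diagnose merging).
* Very fine grids (Δ far below the cluster scale) are memory- and
  time-costly and destroy the plateau; the localization precision sets a
  natural lower bound on useful Δ.
* The plateau recommendation is a formalized heuristic over a procedure
  that is supervised in practice; the raw curves are always emitted and
  should be inspected.
* The precision law's spread (CV 0.25) is a documented stand-in; all
  generator distributions are configurable.
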