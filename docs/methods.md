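# Methods

## The problem

Single-molecule localization microscopy (SMLM) produces point clouds of
detection events ("localizations"). Each target molecule appears as a
compact cluster of localizations; nonspecific signal adds background
noise. Density-based clustering (DBSCAN) is the standard grouping tool,
but its two parameters — the radius `eps` and the neighbor count
`minPts` — are usually hand-picked, and the result can change
qualitatively with that choice. This package selects a single global
`(minPts, eps)` pair for a dataset without prior knowledge, training
data, or manual tuning, by rewarding the clustering that is most *robust*
to parameter variation.

## Cluster definitions

A **core point** has at least `minPts` *other* points within distance
`eps` (closed neighborhood; the point itself is never counted — this
convention is applied identically in both back-ends, so the scikit-learn
equivalent of our `minpts` is `min_samples = minpts + 1`).

* **Classic DBSCAN** (`dbscan`): clusters grow from core points; non-core
  points within `eps` of a cluster's core point are attached as border
  points; everything else is noise. Border points reachable from two
  clusters join the cluster processed first in point-index order, making
  the output deterministic for a fixed input order.
* **Noise-free DBSCAN** (`noise_free_dbscan`, the default): all non-core
  points are removed *iteratively* — after each sweep, core status is
  recomputed against the surviving subset only, so removal can cascade
  (a chain of points erodes from its ends inward). The loop terminates in
  at most N sweeps because the surviving set strictly shrinks. Survivors
  are all core by construction, so the partition into clusters reduces to
  connected components of the `eps`-neighborhood graph over the
  survivors. The returned labeling satisfies a fixed-point property
  (every non-noise point has ≥ `minPts` non-noise neighbors within
  `eps`), and its noise set always contains classic DBSCAN's noise set at
  the same parameters; the monotone-in-`eps` noise fraction follows from
  the survivors under a smaller `eps` remaining valid under a larger one.

## Similarity of clusterings

Two clusters (index sets) X and Y are *similar* when the overlap exceeds
each side's leftover:

    s(X, Y) = 1   iff   |X ∩ Y| > max(|X \ (X ∩ Y)|, |Y \ (X ∩ Y)|),

strict inequality. The similarity of two clusterings is
S(C₁, C₂) = Σᵢⱼ s(Xᵢ, Yⱼ); noise sets are not clusters and never enter
the sum. Because similarity demands that the overlap outweigh each
side's leftover, a cluster can be similar to at most one cluster of the
other clustering, giving 0 ≤ S ≤ min(r, t). The score of a clustering
within an assembly A = {C₁…Cₘ} is S̄(Cᵢ, A) = Σⱼ≠ᵢ S(Cᵢ, Cⱼ). The
self-term is excluded by default: including S(Cᵢ, Cᵢ) = rᵢ would add an
offset growing with the cluster count and bias selection toward
over-segmented clusterings, against the method's purpose; an
`include_self` switch restores the inclusive sum.

## The parameter scan

1. Compute the k-th-neighbor distance of every point (`k = 10`).
2. Span the `eps` candidates over the 10th–90th percentile of that
   distribution (linear-interpolation percentiles; the convention is
   echoed in the output metadata), `n_eps = 15` values, logarithmically
   spaced. Zero distances from duplicate localizations are dropped from
   the percentile computation with a warning. A degenerate interval
   collapses to a single value with a warning and an all-zero score row.
3. `minPts` spans the integers 5…20, bracketing biologically plausible
   cluster sizes.
4. Cluster at every grid cell. The `eps`-neighborhood graph is built once
   per `eps` and shared across the `minPts` row — bit-identical to
   per-cell recomputation, just cheaper.
5. Score each cell by S̄ against the assembly of all clusterings sharing
   its `minPts`.
6. Per `minPts`, keep the `eps` with maximal S̄ (ties → smallest `eps`:
   the stricter core condition admits fewer false inclusions). This is
   the **line of optima**.
7. Rescale the line's scores to [0, 1]: subtract the minimum, divide by
   the maximum of the shifted values (so the maximum lands exactly at 1).
   A constant line carries no robustness signal: all normalized scores
   are set to 1 with a warning and selection falls back (below).
8. Walk the line in increasing `minPts` (configurable to decreasing) and
   select the first entry with normalized score < α = 0.5. If no entry
   falls below α, the entry with the largest raw score is returned and
   flagged `fallback_used`.

All defaults live in `FinderConfig` and are echoed into every result
file; a run is fully reproducible from the echoed config.

## Evaluation metric

A ground-truth cluster X is *detected* by a proposed cluster Y when
|X ∩ Y| > 0.3·|X| (strict; the threshold is configurable) and Y does not
stand in that relation to any other truth cluster — one proposed cluster
cannot detect two. Detections are one-to-one: among several detectors of
the same X, the largest overlap wins (ties → smaller id). Attributed
proposed clusters are true positives, the remainder false positives;
undetected truth clusters are false negatives.

The sweep helper asserts that TP never increases with the threshold.
That holds whenever each proposed cluster overlaps at most one truth
cluster (the regime of well-separated benchmarks); it can fail for
proposals straddling two truth clusters, where raising the threshold
lifts the two-cluster disqualification — the assertion then surfaces the
ambiguity rather than hiding it.

## Synthetic benchmarks

The generator re-creates the geometry of SMLM benchmark scenes without
any experimental input. Unit clusters are isotropic 2-D Gaussian blobs
with Poisson-distributed localization counts (minimum 3). Two presets
set the count means to the statistics of the experimental unit-cluster
libraries such tests emulate: `low_density` (mean 17 localizations,
spread 10 nm) and `origami` (mean 113, spread 8 nm). The spreads are
this package's own defaults — plausible localization-precision scales —
not measured values; all layout statistics below are invariant to the
spread because every length in the construction (grid spacing, noise
box) scales with the realized cluster diameter.

Layouts: a `rows × cols` **grid** with center spacing equal to
`spacing_factor` times the realized maximal within-cluster pairwise
distance (1.0 probes the high-overlap regime, 1.5 the separated one),
and a **sinusoid** with cluster centers at uniform-random positions
along one period (period = 2 × diameter × n_clusters, amplitude =
2.5 × diameter). Uniform placement means occasional adjacent clusters
overlap; this layout deliberately probes the unstructured regime, and
merged detections are punished by the two-cluster rule above. Uniform
background noise is added over the bounding box of the clustered points
plus a one-diameter margin, with count = round(noise_fraction ×
clustered count).

What the generator does **not** emulate: the empirical shape and
count-distribution of experimentally harvested unit clusters,
localization-precision heterogeneity, blinking-induced temporal
correlations, and drift. Passing benchmarks therefore demonstrate the
selection logic under controlled density contrast, not performance on
any specific instrument's data.

## Problem sizes and numerical choices

The benchmark suite runs grids of 25 low-density clusters (~900 points
with 100% noise) and sinusoids of 25 origami-like clusters (~5700
points); a full scan of the default 16 × 15 parameter grid on these
sizes takes well under a minute. Neighbor queries use a k-d tree and a
sparse adjacency; results are exactly equal to brute-force O(N²)
computation (asserted in the test suite on hundreds of randomized
instances). Distances are compared with closed inequalities (≤ `eps`),
duplicate points are allowed, and all tie-breaks (argmax over `eps`,
border-point attachment, competing detectors) are deterministic in the
input order.

## Known limitations

* One global `(minPts, eps)` pair per dataset: strong within-image
  density gradients are out of scope by design.
* Under heavy noise with Poisson-count heterogeneity, the α = 0.5
  elbow typically selects `minPts` near the middle of the 5…20 range;
  planted clusters with fewer localizations than the selected `minPts`
  cannot survive the noise-free definition, so recovery of *every*
  planted cluster is not guaranteed even when false positives are zero.
  The acceptance script reports the measured true/false-positive
  statistics rather than assuming perfect recovery.
* 2-D only; no anisotropic or precision-weighted distances.
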