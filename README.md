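# finder-smlm

Unbiased global parameter selection for density-based clustering of
2-D single-molecule localization microscopy (SMLM) data.

SMLM experiments (DNA-PAINT, STORM, …) yield tables of localizations —
point detections that pile up into compact clusters wherever a target
molecule sits, on top of nonspecific background noise. Grouping those
points with DBSCAN requires choosing a radius `eps` and a neighbor count
`minPts`, and the outcome is sensitive to that choice. This package
scans the `(minPts, eps)` phase space, scores every clustering by how
similar it is to the clusterings at neighboring parameters, and selects
the most *robust* one — using the dataset's own noise level as the
sensitivity floor instead of user-supplied priors or training data.

## Method in brief

For a point set P = {p₁…p_N}:

1. `eps` candidates: 15 log-spaced values spanning the 10th–90th
   percentile of the 10th-neighbor distance distribution; `minPts`
   spans 5…20.
2. Every cell of the grid is clustered with **noise-free DBSCAN**:
   non-core points (fewer than `minPts` other points within `eps`) are
   removed iteratively until only core points remain, which are then
   partitioned into connected components of the `eps`-neighborhood
   graph. Classic DBSCAN is available as an alternative back-end.
3. Two clusters are *similar* when |X ∩ Y| > max(|X\(X∩Y)|, |Y\(X∩Y)|);
   S(C₁,C₂) counts similar cluster pairs, and each cell's assembly score
   S̄ sums S against all clusterings sharing its `minPts`.
4. Per `minPts`, the best-`eps` cell forms the *line of optima*; its
   scores are rescaled to [0, 1], and the selected parameters are the
   first (by increasing `minPts`) whose normalized score drops below
   α = 0.5.

Clusterings are compared to a ground truth with a strict 30%-overlap,
one-to-one true/false-positive metric. A synthetic-data module generates
ground-truth-labeled benchmark scenes (cluster grids and sinusoidal
layouts with uniform background noise) for validation. Details and
assumptions: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a 5×5 grid of low-density clusters (average 17 localizations
each) buried in an equal number (100%) of uniform noise points, select
parameters, and score the result against the planted truth:

```sh
$ finder simulate --layout grid --preset low_density --noise-fraction 1.0 \
      --seed 7 --out data.csv
[finder_smlm] INFO wrote 874 points (25 clusters, 100% noise) to data.csv

$ finder run --input data.csv --out results
[finder_smlm] INFO read 874 localizations (0 dropped) from data.csv
[finder_smlm] INFO selected minPts=12 eps=28.83 nm: 19 clusters, 49.2% noise (0.33s)

$ finder evaluate --truth data.csv --proposed results/labels.csv --threshold 0.3
{ "overlap_threshold": 0.3, "tp": 19, "fp": 0, "fn": 6, ... }
```

Reading the output: the scan settled on `minPts = 12`, `eps ≈ 28.8 nm`
and labeled 49.2% of all points as noise — close to the 50% actually
planted. All 19 reported clusters are genuine (`fp = 0`); 6 planted
clusters had too few localizations to survive the conservative
`minPts = 12` core condition and were missed (`fn = 6`). Keeping false
positives at zero while conceding some faint clusters is the intended
trade-off of the noise-free definition.

The same pipeline is available as a library:

```python
from finder_smlm import PRESETS, make_grid_dataset, run_finder, match_clusters

ds = make_grid_dataset(PRESETS["low_density"], noise_fraction=1.0, seed=7)
res = run_finder(ds.locs)                       # FinderResult
rep = match_clusters(ds.truth, res.clustering)  # MatchReport
print(res.selected, rep.tp_count, rep.fp_count)
```

`finder run` accepts any delimited table with `x_nm, y_nm` (or `x, y`)
columns and writes `labels.csv` (input rows plus a `cluster_label`
column, noise = −1) and `result.json` (selected parameters, full phase
space, line of optima, config echo). Runs are deterministic:
re-running on the same input reproduces both files byte for byte.

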