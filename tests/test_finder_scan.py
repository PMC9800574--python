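"""Phase-space scan, line of optima, and parameter selection."""

import numpy as np
import pytest

from finder_smlm import (
    Clustering,
    EpsilonGrid,
    FinderConfig,
    LocalizationSet,
    NOISE,
    ParameterGrid,
    compute_phase_space,
    extract_line_of_optima,
    make_grid_dataset,
    noise_free_dbscan,
    run_finder,
    select_parameters,
)
from finder_smlm.density_clustering import ClusteringParams
from finder_smlm.finder_scan import LineEntry, LineOfOptima, PhaseSpace
from finder_smlm.similarity import ClusteringAssembly, assembly_similarity
from conftest import brute_clustering_similarity


def make_phase_space(scores, n_clusters=None):
    """A minimal PhaseSpace carrying only what the line extraction reads."""
    scores = np.asarray(scores, dtype=np.int64)
    n_mp, n_eps = scores.shape
    grid = ParameterGrid(
        minpts_values=tuple(range(5, 5 + n_mp)),
        eps_grid=EpsilonGrid(values=np.geomspace(1.0, 10.0, n_eps) if n_eps > 1
                             else np.array([1.0])),
    )
    dummy = Clustering(np.full(4, NOISE, dtype=np.int64))
    return PhaseSpace(
        grid=grid,
        algorithm="noise_free_dbscan",
        clusterings=tuple(tuple(dummy for _ in range(n_eps)) for _ in range(n_mp)),
        n_clusters=np.zeros_like(scores) if n_clusters is None else n_clusters,
        noise_fractions=np.ones(scores.shape),
        scores=scores,
    )


def line_from_normalized(norms, minpts_start=5):
    entries = tuple(
        LineEntry(minpts=minpts_start + i, eps=1.0 + i, eps_index=i,
                  raw_score=0, normalized_score=float(v))
        for i, v in enumerate(norms)
    )
    return LineOfOptima(entries=entries)


class TestComputePhaseSpace:
    def test_identical_partitions_score_identity(self, blob_field):
        """Well-separated dense blobs cluster identically in every cell, so
        every assembly score equals (n_eps - 1) * r."""
        locs = LocalizationSet(blob_field)
        grid = ParameterGrid(
            minpts_values=(5, 7, 9),
            eps_grid=EpsilonGrid(values=np.geomspace(1.0, 5.0, 6)),
        )
        ps = compute_phase_space(locs, grid, algorithm="noise_free_dbscan")
        assert np.all(ps.n_clusters == 3)
        assert np.all(ps.scores == (6 - 1) * 3)
        assert np.all(ps.noise_fractions == 0.0)

    def test_scores_match_brute_force_oracle(self, rng):
        pts = rng.uniform(0, 10, size=(100, 2))
        locs = LocalizationSet(pts)
        grid = ParameterGrid(
            minpts_values=(3, 5, 7),
            eps_grid=EpsilonGrid(values=np.array([0.6, 1.0, 1.6])),
        )
        ps = compute_phase_space(locs, grid)
        for i in range(3):
            row = list(ps.clusterings[i])
            for j in range(3):
                expected = sum(
                    brute_clustering_similarity(row[j], row[l])
                    for l in range(3) if l != j
                )
                assert ps.scores[i, j] == expected

    def test_single_eps_grid_scores_zero_with_warning(self, blob_field):
        locs = LocalizationSet(blob_field)
        grid = ParameterGrid(
            minpts_values=(5, 6),
            eps_grid=EpsilonGrid(values=np.array([2.0])),
        )
        with pytest.warns(UserWarning, match="single value"):
            ps = compute_phase_space(locs, grid)
        assert np.all(ps.scores == 0)

    def test_noise_fraction_non_increasing_in_eps(self, rng):
        """Larger eps can only make core status easier for the noise-free
        definition, so each row's noise fraction is non-increasing."""
        from finder_smlm import PRESETS

        ds = make_grid_dataset(PRESETS["low_density"], rows=3, cols=3,
                               noise_fraction=0.5, seed=11)
        grid = ParameterGrid.from_data(ds.locs, FinderConfig(n_eps=8))
        ps = compute_phase_space(ds.locs, grid, algorithm="noise_free_dbscan")
        assert np.all(np.diff(ps.noise_fractions, axis=1) <= 1e-12)


class TestLineOfOptima:
    def test_step7_rescaling_arithmetic(self):
        ps = make_phase_space([[2], [6], [10]])
        line = extract_line_of_optima(ps)
        np.testing.assert_allclose(
            [e.normalized_score for e in line.entries], [0.0, 0.5, 1.0]
        )
        assert [e.raw_score for e in line.entries] == [2, 6, 10]

    def test_argmax_tie_takes_smallest_eps(self):
        ps = make_phase_space([[4, 4, 2], [1, 3, 3]])
        line = extract_line_of_optima(ps)
        assert line.entries[0].eps_index == 0
        assert line.entries[1].eps_index == 1

    def test_constant_line_degenerates_to_ones(self):
        ps = make_phase_space([[5, 2], [5, 1], [5, 0]])
        with pytest.warns(UserWarning, match="normalization undefined"):
            line = extract_line_of_optima(ps)
        assert line.degenerate
        assert all(e.normalized_score == 1.0 for e in line.entries)

    def test_normalized_scores_span_unit_interval(self, rng):
        scores = rng.integers(0, 50, size=(8, 6))
        if scores.max() == scores.min():
            scores[0, 0] += 1
        line = extract_line_of_optima(make_phase_space(scores))
        norms = np.array([e.normalized_score for e in line.entries])
        opt = scores.max(axis=1)
        if opt.max() > opt.min():
            assert norms.min() == 0.0 and norms.max() == 1.0
        assert np.all((0.0 <= norms) & (norms <= 1.0))


class TestSelectParameters:
    def test_first_entry_below_alpha(self):
        line = line_from_normalized([1.0, 0.8, 0.6, 0.4, 0.0])
        params, fallback = select_parameters(line, alpha=0.5)
        assert params.minpts == 8 and not fallback

    def test_fallback_to_argmax_raw(self):
        entries = tuple(
            LineEntry(minpts=5 + i, eps=1.0 + i, eps_index=i,
                      raw_score=raw, normalized_score=norm)
            for i, (raw, norm) in enumerate([(10, 1.0), (30, 0.9), (20, 0.6)])
        )
        params, fallback = select_parameters(LineOfOptima(entries), alpha=0.5)
        assert fallback and params.minpts == 6

    def test_first_entry_selected_immediately(self):
        line = line_from_normalized([0.2, 0.9, 0.9])
        params, fallback = select_parameters(line, alpha=0.5)
        assert params.minpts == 5 and not fallback

    def test_downward_traversal(self):
        line = line_from_normalized([0.1, 0.9, 0.2])
        params, _ = select_parameters(line, alpha=0.5, direction="down")
        assert params.minpts == 7

    def test_empty_line_rejected(self):
        with pytest.raises(ValueError):
            select_parameters(LineOfOptima(entries=()), alpha=0.5)


class TestRunFinder:
    def test_recovers_well_separated_dense_blobs(self):
        """Dense clusters with sparse background: the selected parameters
        reproduce the planted cluster count in a large majority of seeds."""
        from finder_smlm import UnitClusterModel, match_clusters

        model = UnitClusterModel(mean_localizations=60, localization_spread=10.0)
        hits = 0
        for seed in range(10):
            ds = make_grid_dataset(model, rows=5, cols=5, spacing_factor=2.0,
                                   noise_fraction=0.2, seed=seed)
            res = run_finder(ds.locs)
            if res.clustering.n_clusters == 25:
                hits += 1
        assert hits >= 8

    def test_no_possible_core_point_yields_zero_clusters(self, rng):
        """With minPts above N-1, no point can ever be core: every cell is
        all-noise, the line is degenerate and selection falls back."""
        locs = LocalizationSet(rng.uniform(0, 100, size=(11, 2)))
        cfg = FinderConfig(minpts_min=12, minpts_max=15)
        with pytest.warns(UserWarning):
            res = run_finder(locs, cfg)
        assert res.clustering.n_clusters == 0
        assert res.fallback_used

    def test_deterministic_and_consistent(self):
        from finder_smlm import PRESETS

        ds = make_grid_dataset(PRESETS["low_density"], rows=3, cols=3,
                               noise_fraction=0.5, seed=3)
        res1 = run_finder(ds.locs)
        res2 = run_finder(ds.locs)
        assert res1.to_dict() == res2.to_dict()
        # the stored clustering equals a fresh run at the selected params
        fresh = noise_free_dbscan(ds.locs, res1.selected)
        np.testing.assert_array_equal(fresh.labels, res1.clustering.labels)
        # selected cell is on the grid
        assert res1.selected.minpts in res1.phase_space.grid.minpts_values
        assert any(
            np.isclose(res1.selected.eps, v)
            for v in res1.phase_space.grid.eps_grid.values
        )

    def test_config_defaults_echoed(self):
        cfg = FinderConfig()
        assert cfg.k == 10 and cfg.n_eps == 15
        assert cfg.spacing == "logarithmic"
        assert cfg.minpts_values == tuple(range(5, 21))
        assert cfg.alpha == 0.5
        assert cfg.algorithm == "noise_free_dbscan"
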