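"""Clustering pipeline: model selection, search range, refinement, filters."""

import numpy as np
import pandas as pd
import pytest

from smorph import (
    PipelineConfig,
    cluster,
    compute_search_range,
    load_profile,
    select_initial_model,
    standardize,
    temporal_refinement,
    topological_failsafe,
)
from smorph.clustering import ZeroSpreadError, local_densities, smart_density_filter
from smorph.io import minmax_scale


def search_range_oracle(points, radius_ratio=1.96):
    """Brute-force reference: IQR-kept pairwise distances, SEM with the
    point count as effective sample size, r = sqrt(radius_ratio * SEM)."""
    pts = np.asarray(points, float)
    d = []
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d.append(np.sqrt(((pts[i] - pts[j]) ** 2).sum()))
    d = np.sort(np.array(d))
    # outward-inclusive quartiles via order statistics
    q1 = d[int(np.floor(0.25 * (len(d) - 1)))]
    q3 = d[int(np.ceil(0.75 * (len(d) - 1)))]
    kept = d[(d >= q1) & (d <= q3)]
    sem = kept.std(ddof=1) / np.sqrt(len(pts))
    return np.sqrt(radius_ratio * sem)


class TestSearchRange:
    def test_unit_square_corners_match_oracle(self):
        corners = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        expected = search_range_oracle(corners)  # = 0.45784...
        assert compute_search_range(corners) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4578, abs=1e-4)

    def test_radius_ratio_scales_by_sqrt(self):
        pts = np.random.default_rng(0).uniform(size=(50, 2))
        r196 = compute_search_range(pts, radius_ratio=1.96)
        r1 = compute_search_range(pts, radius_ratio=1.0)
        assert r196 / r1 == pytest.approx(np.sqrt(1.96))

    def test_collinear_points_match_oracle(self):
        pts = np.column_stack([np.linspace(0, 1, 100), np.zeros(100)])
        r = compute_search_range(pts)
        assert r == pytest.approx(search_range_oracle(pts), rel=1e-9)
        assert 0 < r < 1.0  # below the maximal pairwise distance

    def test_identical_distances_raise(self):
        # equilateral triangle: all pairwise distances equal
        tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        with pytest.raises(ZeroSpreadError):
            compute_search_range(tri)

    def test_subsampling_is_seeded(self):
        pts = np.random.default_rng(1).uniform(size=(3000, 2))
        rs = {compute_search_range(pts, max_points=500,
                                   rng=np.random.default_rng(9)) for _ in range(3)}
        assert len(rs) == 1


class TestModelSelection:
    def _table(self, n, spread):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, spread, size=(n, 2))
        return standardize(pd.DataFrame(xy, columns=["x", "y"]))[0]

    def test_low_density_selects_dbscan(self):
        kind, _ = select_initial_model(self._table(1000, 1000), PipelineConfig())
        assert kind == "dbscan"

    def test_high_density_selects_hdbscan(self):
        kind, _ = select_initial_model(self._table(30000, 1000), PipelineConfig())
        assert kind == "hdbscan"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_initial_model(pd.DataFrame({"x": [], "y": []}), PipelineConfig())

    def test_forced_model_override(self):
        kind, _ = select_initial_model(
            self._table(1000, 1000), PipelineConfig(initial_model="hdbscan")
        )
        assert kind == "hdbscan"


class TestTopologicalFailsafe:
    def test_recovers_dense_blob_from_sparse_noise(self, rng):
        blob = rng.normal(0, 0.05, size=(500, 2))
        noise = rng.uniform(-3, 3, size=(300, 2))
        table = pd.DataFrame(np.vstack([blob, noise]), columns=["x", "y"])
        labels = topological_failsafe(table, PipelineConfig())
        in_region = labels[:500] != -1
        assert in_region.mean() >= 0.95

    def test_always_returns_a_region(self, rng):
        table = pd.DataFrame(rng.uniform(size=(400, 2)), columns=["x", "y"])
        labels = topological_failsafe(table, PipelineConfig())
        assert (labels != -1).any()


class TestTemporalRefinement:
    def _two_phase_region(self, rng, gap=150):
        """Two spatially overlapping bursts separated by `gap` frames."""
        n = 400
        a = pd.DataFrame({
            "x": rng.normal(0, 30, n), "y": rng.normal(0, 30, n),
            "t": rng.integers(0, 60, n),
        })
        b = pd.DataFrame({
            "x": rng.normal(15, 30, n), "y": rng.normal(0, 30, n),
            "t": rng.integers(60 + gap, 120 + gap, n),
        })
        truth = np.repeat([0, 1], n)
        return pd.concat([a, b], ignore_index=True), truth

    def test_splits_temporally_distinct_overlapping_assemblies(self, rng):
        region, truth = self._two_phase_region(rng)
        config = PipelineConfig(investigate_min_sample=25)
        sub = temporal_refinement(region, config)
        kept = sub != -1
        assert len(np.unique(sub[kept])) == 2
        for lab in np.unique(sub[kept]):
            purity = np.bincount(truth[sub == lab]).max() / (sub == lab).sum()
            assert purity >= 0.9

    def test_single_assembly_not_split(self):
        from smorph.simulate import IsotropicGrowthParams, simulate_isotropic

        region = simulate_isotropic(
            IsotropicGrowthParams(0, 90), np.random.default_rng(4)
        )
        sub = temporal_refinement(region, PipelineConfig(investigate_min_sample=25))
        labs = np.unique(sub[sub != -1])
        assert len(labs) == 1
        assert (sub != -1).mean() > 0.8

    def test_static_region_passes_through(self):
        region = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [0.0, 1, 0, 1]})
        sub = temporal_refinement(region, PipelineConfig())
        assert (sub == 0).all()

    def test_matches_plain_dbscan_on_single_well_separated_assembly(self):
        """With one growing assembly and no noise, refinement reduces to
        DBSCAN at eps = r_search (the no-splitting oracle)."""
        from sklearn.cluster import DBSCAN
        from smorph.simulate import IsotropicGrowthParams, simulate_isotropic

        region = simulate_isotropic(
            IsotropicGrowthParams(0, 20), np.random.default_rng(2)
        )
        scaled, _ = minmax_scale(region[["x", "y", "t"]])
        config = PipelineConfig(investigate_min_sample=25)
        r = compute_search_range(scaled.to_numpy(), config.radius_ratio)
        ours = temporal_refinement(region, config, r)
        ref = DBSCAN(eps=r, min_samples=config.investigate_min_sample).fit_predict(
            scaled.to_numpy()
        )
        # same partition on the dominant cluster
        ours_main = ours == np.bincount(ours[ours != -1]).argmax()
        ref_main = ref == np.bincount(ref[ref != -1]).argmax()
        agreement = (ours_main == ref_main).mean()
        assert agreement > 0.9


class TestSmartDensityFilter:
    def _candidates(self):
        return pd.DataFrame({
            "label": [0, 1], "region": [0, 0], "seed_frame": [0, 10],
            "n_points": [100, 8],
        })

    def test_mode_none_keeps_everything(self):
        out = smart_density_filter(
            self._candidates(), np.array([5.0, 0.1]), np.array([1.0, 1.1, 0.9]),
            PipelineConfig(filter_mode="none"),
        )
        assert out["kept"].all()

    def test_strict_requires_both(self):
        noise = np.full(100, 1.0) + np.linspace(0, 0.2, 100)
        out = smart_density_filter(
            self._candidates(), np.array([5.0, 5.0]), noise,
            PipelineConfig(filter_mode="strict", final_min_points=20),
        )
        assert out["kept"].tolist() == [True, False]  # second fails size

    def test_lose_requires_either(self):
        noise = np.full(100, 1.0) + np.linspace(0, 0.2, 100)
        out = smart_density_filter(
            self._candidates(), np.array([5.0, 5.0]), noise,
            PipelineConfig(filter_mode="lose", final_min_points=20),
        )
        assert out["kept"].all()

    def test_empty_noise_reduces_to_size_rule(self):
        out = smart_density_filter(
            self._candidates(), np.array([5.0, 0.001]), np.array([]),
            PipelineConfig(filter_mode="strict", final_min_points=20),
        )
        assert out["kept"].tolist() == [True, False]
        assert out.attrs["density_baseline"] == 0.0

    def test_planted_cluster_survives_noise_cluster_removed(self, rng):
        """End-to-end: a dense planted blob passes, a relabelled patch of
        uniform noise fails the density criterion."""
        blob = rng.normal(0, 0.05, size=(300, 2))
        noise = rng.uniform(-2, 2, size=(3000, 2))
        xy = np.vstack([blob, noise])
        dens = local_densities(xy, xy, 10)
        cands = pd.DataFrame({
            "label": [0, 1], "region": [0, 1], "seed_frame": [0, 0],
            "n_points": [300, 300],
        })
        member_density = np.array([
            dens[:300].mean(),          # the planted blob
            dens[300:600].mean(),       # a noise patch posing as a cluster
        ])
        out = smart_density_filter(
            cands, member_density, dens[600:1100],
            PipelineConfig(filter_mode="strict", final_min_points=50),
        )
        assert out["kept"].tolist() == [True, False]


class TestClusterPipeline:
    def test_noise_free_single_assembly_filter_none(self):
        from smorph.simulate import IsotropicGrowthParams, simulate_isotropic

        table = simulate_isotropic(
            IsotropicGrowthParams(0, 80), np.random.default_rng(3)
        )
        res = cluster(table, PipelineConfig(filter_mode="none",
                                            investigate_min_sample=25))
        assert res.n_clusters == 1
        # the diffuse late-growth edge can fall below seeding density and
        # stay unassigned; the single cluster must still hold the majority
        assert (res.labels == 0).mean() > 0.5

    def test_scale_invariance(self, single_isotropic_movie):
        table = single_isotropic_movie.table[["x", "y", "t"]]
        config = load_profile("isotropic")
        a = cluster(table, config).labels
        scaled = table.copy()
        scaled[["x", "y"]] *= 1000.0
        b = cluster(scaled, config).labels
        np.testing.assert_array_equal(a, b)

    def test_permutation_invariance_up_to_renaming(self, single_isotropic_movie):
        table = single_isotropic_movie.table[["x", "y", "t"]]
        config = load_profile("isotropic")
        a = cluster(table, config).labels
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        b = cluster(table.iloc[perm].reset_index(drop=True), config).labels
        # compare as partitions
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a[perm], b) == pytest.approx(1.0)

    def test_determinism(self, single_isotropic_movie):
        table = single_isotropic_movie.table[["x", "y", "t"]]
        config = load_profile("isotropic")
        a = cluster(table, config)
        b = cluster(table, config)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cluster(pd.DataFrame({"x": [], "y": []}), PipelineConfig())

    def test_report_carries_derived_parameters(self, single_isotropic_movie):
        res = cluster(single_isotropic_movie.table[["x", "y", "t"]],
                      load_profile("isotropic"))
        assert res.params["model"] in ("dbscan", "hdbscan")
        assert "density_baseline" in res.params
        assert set(res.assemblies.columns) >= {
            "label", "region", "seed_frame", "n_points", "density",
            "passed_density", "passed_size", "kept", "final_label",
        }
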