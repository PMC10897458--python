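"""Growth engines, corruption operators and movie assembly."""

import numpy as np
import pandas as pd
import pytest

from smorph import simulate
from smorph.simulate import (
    FibrilGrowthParams,
    IsotropicGrowthParams,
    MovieSpec,
    StericGrowthParams,
    add_noise,
    apply_blinking,
    assemble_movie,
    interpolate_pair,
    isotropic_bandwidth,
    morph_sequence,
    reverse_time,
    simulate_fibril,
    simulate_isotropic,
    simulate_sparse_structure,
    simulate_steric,
    steric_hindrance,
)


class TestIsotropic:
    def test_bandwidth_law_endpoints(self):
        # at onset the numerator vanishes; at the end frame it is (end+1)*10
        assert isotropic_bandwidth(100, 100, 300) == pytest.approx(10.0)
        assert isotropic_bandwidth(300, 100, 300) == pytest.approx((300 + 1) * 10.0)

    def test_bandwidth_monotone_in_frame(self):
        p = IsotropicGrowthParams(0, 200)
        bws = [p.bandwidth(f) for f in range(0, 201, 20)]
        assert all(b > 0 for b in bws)
        assert bws == sorted(bws)

    def test_growth_is_centred_and_expanding(self, rng):
        pts = simulate_isotropic(IsotropicGrowthParams(0, 100), rng)
        xy = pts[["x", "y"]].to_numpy()
        # radial extent per time-third grows; centroid drifts far less than extent
        t = pts["t"].to_numpy()
        thirds = np.array_split(np.argsort(t), 3)
        extents = [np.linalg.norm(xy[ix], axis=1).max() for ix in thirds]
        assert extents[2] > extents[0]
        assert np.linalg.norm(xy.mean(axis=0)) < np.linalg.norm(xy, axis=1).max() / 3

    def test_per_frame_point_count_in_range(self, rng):
        p = IsotropicGrowthParams(0, 50, points_per_frame=(0, 30))
        pts = simulate_isotropic(p, rng)
        per_frame = pts.groupby("t").size()
        assert per_frame.max() <= 31  # seed point shares frame 0
        assert pts["t"].between(0, 50).all()


class TestSteric:
    @pytest.mark.parametrize(
        "distances, expected",
        [([0.0], 1.0), ([1.0, 1.0], 2 * np.exp(-1)), ([50.0], 0.0)],
    )
    def test_hindrance_values(self, distances, expected):
        assert steric_hindrance(distances) == pytest.approx(expected, abs=1e-12)

    def test_growth_produces_points_each_frame(self, rng):
        pts = simulate_steric(StericGrowthParams(0, 60), rng)
        assert len(pts) > 60  # Poisson(10)/frame on average
        assert pts["t"].between(0, 60).all()


class TestFibril:
    def test_zero_branch_probability_gives_single_path(self, rng):
        p = FibrilGrowthParams(0, 200, branch_prob=0.0)
        pts = simulate_fibril(p, rng)
        # an unbranched directed walk: consecutive steps ~ N(100, 20^2)
        xy = pts[["x", "y"]].to_numpy()
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        assert abs(steps.mean() - 100) < 3 * 20 / np.sqrt(len(steps))

    def test_step_length_statistics(self):
        rng = np.random.default_rng(5)
        p = FibrilGrowthParams(0, 600, branch_prob=0.0)
        pts = simulate_fibril(p, rng)
        steps = np.linalg.norm(np.diff(pts[["x", "y"]].to_numpy(), axis=0), axis=1)
        se = 20 / np.sqrt(len(steps))
        assert abs(steps.mean() - 100) < 3 * se

    def test_branch_cap_never_exceeded(self):
        # forced heavy branching can never create more than max_branches events
        p = FibrilGrowthParams(0, 80, branch_prob=0.5, max_branches=3)
        for seed in range(200):
            rng = np.random.default_rng(seed)
            before = simulate_fibril(p, rng)
            # branches add extra tips; with cap 3 there are at most 4 tips,
            # so per-frame growth is bounded by a Poisson race among <=4 tips
            per_frame = before.groupby("t").size()
            assert per_frame.mean() < 4 * p.points_per_step_mean + 3


class TestSparse:
    @pytest.mark.parametrize("kind", ["fibril", "ellipse"])
    @pytest.mark.parametrize("n", [4, 8, 15, 25])
    def test_exact_point_count(self, kind, n, rng):
        out = simulate_sparse_structure(kind, n, rng)
        assert len(out) == n

    def test_ellipse_anisotropy_before_rotation(self):
        # y is drawn with twice the sigma of x; check via PCA over many seeds
        ratios = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            xy = np.column_stack([rng.normal(0, 10.0, 25), rng.normal(0, 20.0, 25)])
            ratios.append(xy[:, 1].std() / xy[:, 0].std())
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.1)

    def test_too_few_points_raises(self, rng):
        with pytest.raises(ValueError):
            simulate_sparse_structure("fibril", 1, rng)

    def test_sparse_movie_class_split(self):
        spec = MovieSpec(
            fov=(3000.0, 3000.0),
            n_assemblies={"sparse_fibril": 15, "ellipse": 15},
            start_window=300, min_lifetime=50, sparse_n_points=4, seed=0,
        )
        movie = assemble_movie(spec)
        counts = movie.ground_truth["class"].value_counts()
        assert counts["sparse_fibril"] == 15 and counts["ellipse"] == 15


class TestBlinking:
    def test_output_size_bounds(self, rng):
        structure = pd.DataFrame({"x": np.arange(10.0), "y": np.zeros(10), "t": range(10)})
        out = apply_blinking(structure, rng)
        assert 10 <= len(out) <= 60

    def test_mean_multiplicity(self):
        structure = pd.DataFrame({"x": np.zeros(300), "y": np.zeros(300)})
        out = apply_blinking(structure, np.random.default_rng(3))
        # E[Uniform{1..6}] = 3.5 detections per ground-truth point
        assert len(out) / 300 == pytest.approx(3.5, rel=0.1)

    def test_originals_never_kept(self):
        structure = pd.DataFrame({"x": [0.0, 100.0], "y": [0.0, 50.0]})
        for seed in range(50):
            out = apply_blinking(structure, np.random.default_rng(seed))
            merged = out.merge(structure, on=["x", "y"], how="inner")
            assert len(merged) == 0


class TestNoise:
    def _movie(self, seed=0, noise_mode="none"):
        spec = MovieSpec(n_assemblies={"isotropic": 2}, noise_mode=noise_mode, seed=seed)
        return assemble_movie(spec)

    def test_zero_amount_unchanged(self):
        movie = self._movie()
        out = add_noise(movie, mode="uniform", amount=0.0)
        pd.testing.assert_frame_equal(out.table, movie.table)

    def test_uniform_time_marginal(self):
        from scipy.stats import kstest

        movie = self._movie()
        out = add_noise(movie, mode="uniform", amount=1.0,
                        rng=np.random.default_rng(0))
        t = out.table.loc[out.table["assembly_id"] == -1, "t"].to_numpy()
        stat = kstest(t / movie.spec.max_frames, "uniform").pvalue
        assert stat > 0.01

    def test_heterogeneous_count_bounds(self):
        movie = self._movie()
        out = add_noise(movie, mode="heterogeneous", rng=np.random.default_rng(1))
        n_noise = int((out.table["assembly_id"] == -1).sum())
        assert 100 <= n_noise <= 1250  # 5..25 seeds x 20..50 points

    def test_noise_never_alters_signal_rows(self):
        movie = self._movie()
        out = add_noise(movie, mode="heterogeneous", rng=np.random.default_rng(2))
        sig_before = movie.table[movie.table["assembly_id"] != -1]
        sig_after = out.table[out.table["assembly_id"] != -1]
        pd.testing.assert_frame_equal(sig_before, sig_after)


class TestAssembleMovie:
    def test_assembly_count_and_lifetimes(self):
        spec = MovieSpec(n_assemblies={"isotropic": 10}, seed=3)
        movie = assemble_movie(spec)
        ids = movie.table.loc[movie.table["assembly_id"] != -1, "assembly_id"]
        assert ids.nunique() == 10
        lifetimes = movie.ground_truth["end"] - movie.ground_truth["onset"]
        assert (lifetimes >= 100).all()

    def test_points_lie_within_assembly_lifetime(self):
        spec = MovieSpec(n_assemblies={"random": 3}, seed=4)
        movie = assemble_movie(spec)
        for _, gt in movie.ground_truth.iterrows():
            t = movie.table.loc[movie.table["assembly_id"] == gt["assembly_id"], "t"]
            assert t.min() >= gt["onset"] and t.max() <= gt["end"]

    def test_fixed_seed_reproduces_csv_bytes(self, tmp_path):
        spec = MovieSpec(n_assemblies={"fibril": 5}, seed=11)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        assemble_movie(spec).to_csv(p1)
        assemble_movie(spec).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            MovieSpec(start_window=350, min_lifetime=100, max_frames=400)


class TestClassGeometry:
    def test_fibril_far_more_elongated_than_isotropic(self):
        """Aspect ratio (major/minor PCA extent) separates the classes."""
        def aspect(xy):
            ev = np.sort(np.linalg.eigvalsh(np.cov(xy.T)))[::-1]
            return np.sqrt(ev[0] / max(ev[1], 1e-12))

        fib_aspects, iso_aspects = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            fib = simulate_fibril(FibrilGrowthParams(0, 150), rng)
            iso = simulate_isotropic(IsotropicGrowthParams(0, 40), rng)
            n = min(len(fib), len(iso))
            fib_aspects.append(aspect(fib[["x", "y"]].to_numpy()[:n]))
            iso_aspects.append(aspect(iso[["x", "y"]].to_numpy()[:n]))
        # directed walks with pi/4 turn spread still curl, but stay clearly
        # more elongated than radially symmetric growth
        assert np.median(fib_aspects) > 1.8 * np.median(iso_aspects)


class TestMorphSequence:
    def test_endpoints_exact(self, rng):
        a = rng.normal(size=(20, 2))
        b = rng.normal(size=(20, 2))
        np.testing.assert_allclose(interpolate_pair(a, b, 0.0), a - a.mean(axis=0))
        # fraction 1 returns the second structure (possibly permuted rows)
        end = interpolate_pair(a, b, 1.0)
        bc = b - b.mean(axis=0)
        assert set(map(tuple, np.round(end, 9))) == set(map(tuple, np.round(bc, 9)))

    def test_interpolant_count(self, rng):
        structures = [rng.normal(size=(15, 2)) for _ in range(90)]
        seq = morph_sequence(structures, 100)
        assert len(seq) == 8900

    def test_single_structure_rejected(self, rng):
        with pytest.raises(ValueError):
            morph_sequence([rng.normal(size=(5, 2))], 10)


class TestReverseTime:
    def test_reversal_and_involution(self):
        spec = MovieSpec(n_assemblies={"isotropic": 2}, seed=5)
        movie = assemble_movie(spec)
        rev = reverse_time(movie)
        tmax = movie.table["t"].max()
        assert (rev.table["t"] == tmax - movie.table["t"]).all()
        # onset/end swap and reflect
        assert (rev.ground_truth["onset"] == tmax - movie.ground_truth["end"]).all()
        back = reverse_time(rev)
        pd.testing.assert_frame_equal(back.table, movie.table)
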