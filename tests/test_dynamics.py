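"""UV mapping, anisotropy D, RV coefficient, MSCD/MSD and bootstrap baseline."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from chromotrack import (DistanceSeries, SimulationConfig, anisotropy_D,
                         bootstrap_baseline, distance_series, ks2d_uniform,
                         mscd_curve, msd_curve, pair_vectors, plateau_estimate,
                         rv_coefficient, simulate_pair_video, uv_map,
                         uv_map_many)
from chromotrack.io import ValidationError
from chromotrack.simulate import MAXWELL_VAR


def ks2d_oracle(points):
    """Brute-force 2D KS statistic: explicit loops over points x orientations."""
    n = len(points)
    best = 0.0
    for (u, v) in points:
        n_ll = n_lu = n_rl = n_rr = 0
        for (x, y) in points:
            if x <= u and y <= v:
                n_ll += 1
            elif x <= u:
                n_lu += 1
            elif y <= v:
                n_rl += 1
            else:
                n_rr += 1
        for emp, area in ((n_ll, u * v), (n_lu, u * (1 - v)),
                          (n_rl, (1 - u) * v), (n_rr, (1 - u) * (1 - v))):
            best = max(best, abs(emp / n - area))
    return best


class TestUVMap:
    def test_polar_extremes(self):
        assert uv_map([0.0, 0.0, 5.0])[1] == 0.0
        assert uv_map([0.0, 0.0, -5.0])[1] == 1.0

    def test_x_axis_maps_to_centre(self):
        assert uv_map([1.0, 0.0, 0.0]) == (0.5, 0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            uv_map([0.0, 0.0, 0.0])

    def test_x_equals_y_equals_zero_gets_half(self):
        u, v = uv_map([0.0, 0.0, 3.0])
        assert u == 0.5

    @given(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3),
                     st.floats(-1e3, 1e3)).filter(lambda t: any(abs(c) > 1e-6 for c in t)))
    def test_range_invariants(self, vec):
        u, v = uv_map(vec)
        assert 0.0 <= u < 1.0
        assert 0.0 <= v <= 1.0

    def test_isotropic_vectors_map_to_uniform_square(self, rng):
        vecs = rng.normal(size=(10_000, 3))
        uv = uv_map_many(vecs)
        # marginal and joint uniformity via the 2D KS statistic itself
        assert ks2d_uniform(uv) < 0.05

    def test_many_matches_scalar(self, rng):
        vecs = rng.normal(size=(50, 3))
        uv = uv_map_many(vecs)
        for vec, (u, v) in zip(vecs, uv):
            assert uv_map(vec) == pytest.approx((u, v))


class TestAnisotropyD:
    def test_single_central_point(self):
        assert ks2d_uniform(np.array([[0.5, 0.5]])) == pytest.approx(0.75)

    def test_two_diagonal_points(self):
        pts = np.array([[0.25, 0.25], [0.75, 0.75]])
        assert ks2d_uniform(pts) == pytest.approx(0.4375)

    def test_equals_bruteforce_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 60))
            pts = rng.uniform(size=(n, 2))
            assert ks2d_uniform(pts) == pytest.approx(ks2d_oracle(pts), abs=1e-12)

    def test_large_uniform_sample_has_small_D(self, rng):
        pts = rng.uniform(size=(10_000, 2))
        assert ks2d_uniform(pts) < 0.05

    def test_rotation_about_optical_axis_stability(self, rng):
        """Rotating all vectors about z shifts the azimuth modularly, which
        leaves the uniform reference invariant; D is stable (the quadrant
        construction is not exactly shift-invariant, so only approximately)
        and the isotropy/anisotropy ordering is preserved."""
        aniso = rng.normal(size=(150, 3)) * [1.0, 0.3, 1.0]
        iso = rng.normal(size=(150, 3))
        d_aniso = anisotropy_D(aniso).D
        d_iso = anisotropy_D(iso).D
        for angle in (30.0, 117.0, 240.0):
            R = Rotation.from_euler("z", angle, degrees=True).as_matrix()
            d_aniso_rot = anisotropy_D(aniso @ R.T).D
            d_iso_rot = anisotropy_D(iso @ R.T).D
            assert d_aniso_rot == pytest.approx(d_aniso, abs=0.12)
            assert d_iso_rot == pytest.approx(d_iso, abs=0.12)
            assert d_aniso_rot > d_iso_rot

    def test_zero_vectors_skipped_and_counted(self):
        vecs = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        res = anisotropy_D(vecs)
        assert res.n == 1
        with pytest.raises(ValidationError):
            anisotropy_D(np.zeros((3, 3)))

    def test_fixed_direction_simulation_exceeds_isotropic(self):
        """Persistent relative orientation inflates D at matched n."""
        n_iso_wins = 0
        for seed in range(20):
            iso = simulate_pair_video(
                SimulationConfig(noise_sd=0.0, n_frames=100), seed)
            fixed = simulate_pair_video(
                SimulationConfig(noise_sd=0.0, n_frames=100,
                                 anisotropy_mode="fixed-direction"), seed)
            d_iso = anisotropy_D(pair_vectors(iso)).D
            d_fixed = anisotropy_D(pair_vectors(fixed)).D
            if d_fixed > d_iso:
                n_iso_wins += 1
        assert n_iso_wins == 20


class TestRV:
    def test_identical_trajectories(self, rng):
        X = rng.normal(size=(50, 3))
        assert rv_coefficient(X, X) == pytest.approx(1.0)

    def test_rotation_of_one_trajectory_is_invisible(self, rng):
        X = rng.normal(size=(50, 3))
        R = Rotation.from_euler("xyz", [12, 34, 56], degrees=True).as_matrix()
        assert rv_coefficient(X, X @ R.T) == pytest.approx(1.0, abs=1e-12)
        Y = rng.normal(size=(50, 3))
        assert rv_coefficient(X, Y @ R.T) == pytest.approx(
            rv_coefficient(X, Y), abs=1e-12)

    def test_symmetry_and_range(self, rng):
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 3))
        rv = rv_coefficient(X, Y)
        assert rv == pytest.approx(rv_coefficient(Y, X))
        assert 0.0 <= rv <= 1.0

    def test_independent_trajectories_give_small_rv(self, rng):
        values = [rv_coefficient(rng.normal(size=(100, 3)),
                                 rng.normal(size=(100, 3))) for _ in range(50)]
        assert np.mean(values) < 0.2

    def test_null_rv_decreases_with_length(self, rng):
        short = np.mean([rv_coefficient(rng.normal(size=(20, 3)),
                                        rng.normal(size=(20, 3)))
                         for _ in range(100)])
        long = np.mean([rv_coefficient(rng.normal(size=(200, 3)),
                                       rng.normal(size=(200, 3)))
                        for _ in range(100)])
        assert long < short

    def test_zero_variance_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValidationError):
            rv_coefficient(X, np.random.default_rng(0).normal(size=(10, 3)))


def series(video_id, times, distances):
    return DistanceSeries(video_id, np.asarray(times, float),
                          np.asarray(distances, float))


class TestMSCD:
    def test_direct_enumeration_of_small_series(self):
        """d = [100, 200, 100, 200] at 1 s: MSCD(1 s)=10^4, MSCD(2 s)=0."""
        s = series("v0", [0, 1, 2, 3], [100.0, 200.0, 100.0, 200.0])
        curve = mscd_curve([s], bin_width_s=1.0)
        by_bin = dict(zip(np.floor(curve.bin_centres).astype(int), curve.mscd))
        assert by_bin[1] == pytest.approx(10_000.0)   # 3 lag-1 pairs
        assert by_bin[2] == pytest.approx(0.0)        # 2 lag-2 pairs
        assert by_bin[3] == pytest.approx(10_000.0)   # 1 lag-3 pair
        np.testing.assert_array_equal(curve.n_pairs, [3, 2, 1])

    def test_constant_series_is_identically_zero(self):
        s = series("v0", np.arange(10), np.full(10, 150.0))
        curve = mscd_curve([s], bin_width_s=6.0)
        np.testing.assert_allclose(curve.mscd, 0.0)

    def test_time_reversal_invariance(self, rng):
        t = np.arange(30.0)
        d = rng.uniform(50, 400, size=30)
        fwd = mscd_curve([series("v", t, d)], 6.0)
        rev = mscd_curve([series("v", t, d[::-1])], 6.0)
        np.testing.assert_allclose(fwd.mscd, rev.mscd)
        np.testing.assert_array_equal(fwd.n_pairs, rev.n_pairs)

    def test_plateau_matches_stationary_closed_form(self):
        """Noiseless confined pair: plateau → 2*sigma^2*(3-8/pi)."""
        sigma, theta = 100.0, 5.0
        cfg = SimulationConfig(sigma=sigma, theta=theta, frame_interval=1.0,
                               n_frames=240, noise_sd=0.0, centre_sigma=0.0)
        videos = [simulate_pair_video(cfg, s, video_id=f"v{s}") for s in range(30)]
        all_series = [distance_series(v) for v in videos]
        per_video = []
        for s in all_series:
            i, j = np.triu_indices(len(s.times), k=1)
            tau = s.times[j] - s.times[i]
            sq = (s.distances[j] - s.distances[i]) ** 2
            per_video.append(sq[tau >= 6 * theta].mean())
        per_video = np.array(per_video)
        theory = 2.0 * sigma ** 2 * MAXWELL_VAR
        se = per_video.std(ddof=1) / math.sqrt(len(per_video))
        assert abs(per_video.mean() - theory) < 3 * se
        # and the pooled curve agrees with the per-video estimate
        curve = mscd_curve(all_series, 6.0)
        assert plateau_estimate(curve, 6 * theta) == pytest.approx(
            per_video.mean(), rel=0.05)

    def test_half_rise_on_theta_timescale(self):
        """The lag at half-plateau tracks (theta/2)*ln2 within a factor 1.5.

        The distance is an even function of the Gaussian inter-locus
        vector, so its autocorrelation decays as exp(-2*tau/theta) to
        leading order and the MSCD half-rise sits near theta*ln2/2."""
        sigma, theta = 100.0, 8.0
        cfg = SimulationConfig(sigma=sigma, theta=theta, frame_interval=1.0,
                               n_frames=300, noise_sd=0.0, centre_sigma=0.0)
        videos = [simulate_pair_video(cfg, 100 + s, video_id=f"v{s}")
                  for s in range(20)]
        curve = mscd_curve([distance_series(v) for v in videos], 1.0)
        plateau = plateau_estimate(curve, 6 * theta)
        half_idx = int(np.argmax(curve.mscd >= plateau / 2))
        # sampling is at integer lags, so the bin labelled k+0.5 holds lag k
        tau_half = math.floor(curve.bin_centres[half_idx])
        expected = 0.5 * theta * math.log(2)
        assert expected / 1.5 < tau_half < expected * 1.5

    def test_series_shorter_than_two_rejected(self):
        with pytest.raises(ValidationError):
            mscd_curve([series("v", [0.0], [100.0])], 6.0)
        with pytest.raises(ValidationError):
            mscd_curve([], 6.0)


class TestBootstrapBaseline:
    def test_identical_constant_videos_give_zero(self):
        coll = [series(f"v{i}", np.arange(5), np.full(5, 100.0)) for i in range(3)]
        baseline, se = bootstrap_baseline(coll, n_boot=500, seed=0)
        assert baseline == 0.0

    def test_two_constant_videos_cross_pairs_only(self):
        coll = [series("a", np.arange(5), np.full(5, 100.0)),
                series("b", np.arange(5), np.full(5, 200.0))]
        baseline, se = bootstrap_baseline(coll, n_boot=200, seed=1)
        assert baseline == pytest.approx(10_000.0)  # every draw crosses videos

    def test_exclusion_list(self):
        coll = [series("a", np.arange(5), np.full(5, 100.0)),
                series("b", np.arange(5), np.full(5, 100.0)),
                series("outlier", np.arange(5), np.full(5, 900.0))]
        with_outlier, _ = bootstrap_baseline(coll, 2000, 0)
        without, _ = bootstrap_baseline(coll, 2000, 0, exclude_videos=["outlier"])
        assert without == 0.0
        assert with_outlier > 0.0

    def test_fewer_than_two_videos_rejected(self):
        coll = [series("a", np.arange(5), np.full(5, 100.0))]
        with pytest.raises(ValidationError):
            bootstrap_baseline(coll, 100, 0)

    def test_homogeneous_population_baseline_matches_plateau(self):
        """Ergodic stationary population: between-cell baseline ≈ within-cell
        plateau (both → 2 Var(d))."""
        cfg = SimulationConfig(sigma=100.0, theta=5.0, n_frames=200,
                               noise_sd=0.0, centre_sigma=0.0)
        videos = [simulate_pair_video(cfg, 200 + s, video_id=f"v{s}")
                  for s in range(25)]
        coll = [distance_series(v) for v in videos]
        curve = mscd_curve(coll, 6.0)
        plateau = plateau_estimate(curve, 30.0)
        baseline, se = bootstrap_baseline(coll, n_boot=20_000, seed=3)
        assert baseline == pytest.approx(plateau, rel=0.10)


class TestPlateau:
    def test_single_qualifying_bin(self):
        s = series("v", [0.0, 151.0], [100.0, 200.0])
        curve = mscd_curve([s], 6.0)  # one pair at lag 151 s → one bin ≥ 150 s
        assert plateau_estimate(curve, 150.0) == pytest.approx(10_000.0)

    def test_count_weighted_mean(self):
        from chromotrack.dynamics import MSCDCurve
        curve = MSCDCurve(np.array([153.0, 159.0]), np.array([9000.0, 11000.0]),
                          np.array([10, 10]), np.array([0.0, 0.0]))
        assert plateau_estimate(curve, 150.0) == pytest.approx(10_000.0)
        curve = MSCDCurve(np.array([153.0, 159.0]), np.array([9000.0, 12000.0]),
                          np.array([30, 10]), np.array([0.0, 0.0]))
        assert plateau_estimate(curve, 150.0) == pytest.approx(9750.0)

    def test_no_bins_beyond_threshold(self):
        s = series("v", [0.0, 1.0], [100.0, 200.0])
        curve = mscd_curve([s], 6.0)
        with pytest.raises(ValidationError):
            plateau_estimate(curve, 150.0)


class TestMSD:
    def test_static_locus_is_zero(self):
        pos = np.tile([100.0, 200.0, 300.0], (10, 1))
        curve = msd_curve([(np.arange(10.0), pos)], 6.0)
        np.testing.assert_allclose(curve.mscd, 0.0)

    def test_pure_drift_is_quadratic(self):
        t = np.arange(20.0)
        v = np.array([10.0, 0.0, 0.0])
        pos = t[:, None] * v
        curve = msd_curve([(t, pos)], bin_width_s=1.0)
        # within each 1-s bin the lag is exact: MSD = |v|^2 tau^2
        lags = np.floor(curve.bin_centres)
        np.testing.assert_allclose(curve.mscd, 100.0 * lags ** 2)

    def test_confined_locus_matches_ou_closed_form(self):
        """Confined diffusion: MSD(τ) = 6 σ_c² (1 − exp(−τ/θ_c))."""
        sigma_c, theta_c = 150.0, 10.0
        cfg = SimulationConfig(sigma=0.0, noise_sd=0.0, centre_sigma=sigma_c,
                               centre_theta=theta_c, frame_interval=1.0,
                               n_frames=300)
        videos = [simulate_pair_video(cfg, 300 + s, video_id=f"v{s}")
                  for s in range(25)]
        curve = msd_curve([(v.times, v.positions("green")) for v in videos],
                          bin_width_s=1.0)
        for tau_target in (2.0, 10.0, 40.0):
            idx = int(np.argmin(np.abs(curve.bin_centres - tau_target)))
            # integer-lag sampling: the bin labelled k+0.5 holds lag k exactly
            tau = math.floor(curve.bin_centres[idx])
            expected = 6.0 * sigma_c ** 2 * (1.0 - math.exp(-tau / theta_c))
            assert curve.mscd[idx] == pytest.approx(expected, rel=0.12)
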