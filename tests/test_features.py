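"""Set A feature statistics: frozen oracles, conventions and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sptclass import (
    FEATURE_COLUMNS,
    TAMSDCurve,
    Trajectory2D,
    dbm_trajectory,
    fbm_trajectory,
    feature_vector,
    features_table,
    fit_alpha_diffusivity,
    geometry_features,
    monotonicity_stat,
    msd_ratio,
    p_variation_profile,
    tamsd,
    velocity_autocorr,
)
from sptclass.features import default_m_grid

from conftest import make_track


def brute_force_tamsd(pos, n_max):
    """Independent double-loop oracle for the TAMSD."""
    N = pos.shape[0] - 1
    out = []
    for n in range(1, n_max + 1):
        acc = 0.0
        for i in range(0, N - n + 1):
            d = pos[i + n] - pos[i]
            acc += d @ d
        out.append(acc / (N - n + 1))
    return np.array(out)


class TestTAMSD:
    def test_straight_unit_path_is_n_squared(self):
        traj = make_track([(i, 0.0) for i in range(11)])
        curve = tamsd(traj, max_lag_fraction=0.5)
        assert np.array_equal(curve.lags, np.arange(1, 6))
        assert np.allclose(curve.values, curve.lags.astype(float) ** 2)

    def test_stationary_path_is_zero(self):
        traj = make_track([(2.0, 3.0)] * 20)
        assert np.allclose(tamsd(traj).values, 0.0)

    def test_matches_brute_force_on_random_tracks(self, rng):
        for _ in range(20):
            n_steps = int(rng.integers(5, 30))
            pos = np.cumsum(rng.standard_normal((n_steps + 1, 2)), axis=0)
            traj = make_track(pos)
            frac = rng.uniform(0.2, 1.0)
            curve = tamsd(traj, max_lag_fraction=frac)
            assert np.allclose(
                curve.values, brute_force_tamsd(pos, curve.lags[-1])
            )

    def test_brownian_ensemble_mean(self):
        # E rho(n) = 4 D n dt = 2 n for sigma = 1, dt = 1 (2D, D = 1/2)
        acc = np.zeros(5)
        n_rep = 4000
        for s in range(n_rep):
            traj = dbm_trajectory(50, drift=(0, 0), seed=s)
            acc += tamsd(traj, max_lag_fraction=0.1).values
        assert np.allclose(acc / n_rep, 2 * np.arange(1, 6), rtol=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 positions"):
            tamsd(make_track([(0, 0), (1, 1)]))


class TestAlphaDiffusivity:
    def test_ballistic_curve(self):
        curve = TAMSDCurve(np.arange(1, 6), np.arange(1, 6) ** 2.0, dt=1.0)
        alpha, D = fit_alpha_diffusivity(curve)
        assert alpha == pytest.approx(2.0)
        assert D == pytest.approx(0.25)

    def test_flat_curve_has_zero_slope(self):
        curve = TAMSDCurve(np.arange(1, 6), np.full(5, 3.7), dt=1.0)
        alpha, _ = fit_alpha_diffusivity(curve)
        assert alpha == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_curve_degenerates(self):
        curve = TAMSDCurve(np.arange(1, 4), np.zeros(3), dt=1.0)
        assert fit_alpha_diffusivity(curve) == (0.0, 0.0)

    def test_fbm_quarter_hurst_recovery(self):
        alphas = [
            fit_alpha_diffusivity(tamsd(fbm_trajectory(500, 0.25, seed=s)))[0]
            for s in range(1000)
        ]
        assert abs(np.mean(alphas) - 0.5) < 0.05


class TestMSDRatio:
    def test_ballistic_hand_value(self):
        curve = TAMSDCurve(np.arange(1, 5), np.arange(1, 5) ** 2.0, dt=1.0)
        expected = -(0.25 + 2 / 9 + 3 / 16) / 3
        assert msd_ratio(curve) == pytest.approx(expected)

    def test_linear_curve_is_zero(self):
        curve = TAMSDCurve(np.arange(1, 8), 3.1 * np.arange(1, 8.0), dt=1.0)
        assert msd_ratio(curve) == pytest.approx(0.0, abs=1e-12)

    def test_brownian_ensemble_mean_is_near_zero(self):
        # E rho(n) is linear in n, so kappa ~ 0; the ratio estimator keeps a
        # small positive O(1/N) Jensen bias at finite track length
        vals = [
            msd_ratio(tamsd(dbm_trajectory(100, drift=(0, 0), seed=s)))
            for s in range(5000)
        ]
        assert abs(np.mean(vals)) < 0.01


class TestGeometry:
    def test_straight_path_maximises_linearity(self, straight_track):
        E, S, ME = geometry_features(straight_track)
        assert E == pytest.approx(1.0)
        assert S == pytest.approx(1.0)

    def test_closed_loop_conventions(self):
        traj = make_track([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        E, S, ME = geometry_features(traj)
        assert (E, S, ME) == (0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        traj = make_track([(0, 0), (3, 0), (4, 0)])
        E, S, ME = geometry_features(traj)
        assert E == pytest.approx(16 / (2 * 10))
        assert S == pytest.approx(1.0)
        assert ME == pytest.approx(0.75)

    def test_stationary_track_warns(self):
        with pytest.warns(UserWarning):
            assert geometry_features(make_track([(1, 1)] * 5)) == (0, 0, 0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_bounds_hold_on_random_tracks(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.standard_normal((rng.integers(2, 40), 2)), axis=0)
        E, S, _ = geometry_features(make_track(pos))
        assert 0.0 <= E <= 1.0 + 1e-12
        assert 0.0 <= S <= 1.0 + 1e-12


class TestVelocityAutocorr:
    def test_aligned_unit_steps(self, straight_track):
        assert velocity_autocorr(straight_track) == pytest.approx(1.0)

    def test_alternating_steps(self):
        xs = [0, 1, 0, 1, 0, 1, 0]
        traj = make_track([(x, 0.0) for x in xs])
        assert velocity_autocorr(traj) == pytest.approx(-1.0)

    def test_brownian_null_and_fbm_antipersistence(self):
        bm = np.mean(
            [velocity_autocorr(dbm_trajectory(100, (0, 0), seed=s)) for s in range(3000)]
        )
        assert abs(bm) < 0.01
        fbm = np.mean(
            [velocity_autocorr(fbm_trajectory(100, 0.3, seed=s)) for s in range(500)]
        )
        assert fbm < -0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="4 positions"):
            velocity_autocorr(make_track([(0, 0), (1, 0), (2, 0)]))


class TestPVariation:
    def test_ballistic_profile_p2(self):
        traj = make_track([(i, 0.0) for i in range(101)])
        vals = p_variation_profile(traj, p=2, m_grid=[1, 2, 5])
        assert np.allclose(vals, [100.0, 200.0, 500.0])

    def test_ballistic_p1_is_path_length(self):
        traj = make_track([(i, 0.0) for i in range(101)])
        vals = p_variation_profile(traj, p=1, m_grid=[1, 2, 4, 5, 10])
        assert np.allclose(vals, 100.0)

    def test_stationary_path_is_zero(self):
        traj = make_track([(0.0, 0.0)] * 50)
        assert np.allclose(p_variation_profile(traj, 3, [1, 2, 5]), 0.0)

    def test_block_size_limit_enforced(self):
        traj = make_track([(i, 0.0) for i in range(11)])
        with pytest.raises(ValueError, match="exceeds"):
            p_variation_profile(traj, 2, [1, 6])

    def test_m1_p2_equals_sum_squared_steps(self, random_track):
        vals = p_variation_profile(random_track, 2, [1])
        steps = random_track.increments()
        assert vals[0] == pytest.approx(np.sum(steps**2))

    def test_default_grid_shape(self):
        assert np.array_equal(default_m_grid(500), np.arange(1, 51))
        assert np.array_equal(default_m_grid(50), np.arange(1, 6))
        assert np.array_equal(default_m_grid(10), np.arange(1, 4))
        assert default_m_grid(2000).size == 50


class TestMonotonicityStat:
    def test_monotone_profiles_return_zero(self):
        profiles = {p: np.arange(1, 6) ** p for p in (1.0, 2.0, 3.0)}
        assert monotonicity_stat(profiles) == 0

    def test_convex_change(self):
        assert monotonicity_stat({2.0: [3, 1, 2]}) == 1

    def test_concave_change(self):
        assert monotonicity_stat({2.0: [1, 3, 2]}) == -1

    def test_highest_p_wins(self):
        profiles = {1.0: [3, 1, 2], 2.0: [1, 3, 2], 3.0: [1, 2, 3]}
        assert monotonicity_stat(profiles) == -1  # p=2 is highest with a change

    def test_zero_curvature_tie(self):
        assert monotonicity_stat({1.0: [0, 1, 0, 1]}) == 0

    def test_short_profile_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            monotonicity_stat({1.0: [1, 2]})


class TestFeatureVector:
    def test_fixed_order_and_d_removal(self, random_track):
        vec = feature_vector(random_track)
        d = vec.to_dict(include_D=True)
        assert list(d) == list(FEATURE_COLUMNS)
        d7 = vec.to_dict(include_D=False)
        assert list(d7) == [c for c in FEATURE_COLUMNS if c != "D"]

    def test_deterministic(self, random_track):
        a = feature_vector(random_track).to_array()
        b = feature_vector(random_track).to_array()
        assert np.array_equal(a, b)

    def test_short_track_rejected_by_name(self):
        traj = make_track([(i, 0.0) for i in range(8)])
        with pytest.raises(ValueError, match="10 steps"):
            feature_vector(traj)

    def test_p_var_stat_is_ternary_and_all_finite(self):
        for s in range(25):
            traj = fbm_trajectory(60, hurst=0.2 + 0.02 * s, seed=s)
            vec = feature_vector(traj)
            assert vec.p_var_stat in (-1, 0, 1)
            assert np.all(np.isfinite(vec.to_array()))

    @pytest.mark.parametrize("angle", [0.3, 1.2])
    def test_rigid_motion_invariance(self, random_track, angle):
        # E, S, ME, alpha, kappa, P are invariant under rotation+translation
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = random_track.with_positions(
            random_track.positions @ R.T + np.array([5.0, -2.0])
        )
        a, b = feature_vector(random_track), feature_vector(moved)
        for name in ("alpha", "msd_ratio", "efficiency", "straightness",
                     "max_excursion", "p_var_stat"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-9)
        # chi and D are rotation-invariant too (dot products / distances)
        assert b.vac1 == pytest.approx(a.vac1, abs=1e-9)
        assert b.D == pytest.approx(a.D, rel=1e-9)

    def test_rescaling_covariance(self, random_track):
        factor = 2.5
        scaled = random_track.with_positions(random_track.positions * factor)
        a, b = feature_vector(random_track), feature_vector(scaled)
        for name in ("alpha", "efficiency", "straightness", "max_excursion",
                     "p_var_stat"):
            assert getattr(b, name) == pytest.approx(getattr(a, name), abs=1e-9)
        assert b.vac1 == pytest.approx(a.vac1 * factor**2, rel=1e-9)
        assert b.D == pytest.approx(a.D * factor**2, rel=1e-9)

    def test_features_table_columns(self, rng):
        trajs = [dbm_trajectory(50, (0, 0), seed=s) for s in range(5)]
        df = features_table(trajs, labels=["normal"] * 5)
        assert list(df.columns) == ["traj_id", *FEATURE_COLUMNS, "mode"]
        assert len(df) == 5
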