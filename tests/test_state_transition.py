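import numpy as np
import pandas as pd
import pytest

from surpass import (
    ExpressionMatrix,
    PotentialModel,
    SampleTable,
    assign_critical_points,
    estimate_beta_inv,
    estimate_c1_c3,
    estimate_c2,
    fit_potential,
    potential_value,
    pseudotime_from_marker,
    simulate_langevin,
    solve_fokker_planck,
    stationary_density,
)


class TestPotential:
    def test_symmetric_unit_barrier(self):
        m = PotentialModel(0.0, 0.5, 1.0, scale=64.0)
        assert potential_value(m, 0.5) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_wells_equal_energy(self):
        m = PotentialModel(-1.0, 0.0, 1.0, scale=3.0)
        assert potential_value(m, -1.0) == pytest.approx(0.0, abs=1e-12)
        assert potential_value(m, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_gradient_vanishes_at_critical_points(self):
        m = PotentialModel(0.2, 0.9, 2.3, scale=7.0)
        for c in (m.c1, m.c2, m.c3):
            assert m.gradient(c) == pytest.approx(0.0, abs=1e-10)

    def test_numerical_gradient_matches_cubic(self):
        """Finite differences of U_p reproduce the defining cubic."""
        m = PotentialModel(-0.5, 0.4, 1.5, scale=10.0)
        x = np.linspace(-1.0, 2.0, 1000)
        h = 1e-6
        num = (potential_value(m, x + h) - potential_value(m, x - h)) / (2 * h)
        np.testing.assert_allclose(num, m.gradient(x), atol=1e-5)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError, match="c1 < c2 < c3"):
            PotentialModel(1.0, 0.5, 2.0)


class TestCriticalPointEstimation:
    def test_point_masses_recovered_exactly(self):
        coords = np.array([0.0] * 20 + [5.0] * 20)
        groups = np.array(["normal"] * 20 + ["AML"] * 20, dtype=object)
        fit = estimate_c1_c3(coords, groups, seed=0)
        assert fit.c1 == pytest.approx(0.0, abs=1e-12)
        assert fit.c3 == pytest.approx(5.0, abs=1e-12)
        assert (fit.n_c1, fit.n_c3) == (20, 20)

    def test_gaussian_clusters_recovered(self):
        rng = np.random.default_rng(1)
        coords = np.concatenate(
            [rng.normal(0, 0.1, 200), rng.normal(10, 0.1, 200)]
        )
        groups = np.array(["normal"] * 200 + ["AML"] * 200, dtype=object)
        fit = estimate_c1_c3(coords, groups, seed=0)
        assert -0.1 < fit.c1 < 0.1
        assert 9.9 < fit.c3 < 10.1

    def test_label_flip_swaps_designation(self):
        coords = np.array([0.0] * 10 + [5.0] * 10)
        groups = np.array(["normal"] * 10 + ["AML"] * 10, dtype=object)
        flipped = np.array(["AML"] * 10 + ["normal"] * 10, dtype=object)
        a = estimate_c1_c3(coords, groups, seed=0)
        b = estimate_c1_c3(coords, flipped, seed=0)
        assert (a.c1, a.c3) == (b.c3, b.c1)

    def test_degenerate_coordinates_rejected(self):
        with pytest.raises(ValueError):
            estimate_c1_c3(np.ones(10), np.array(["normal"] * 10, dtype=object))


class TestEstimateC2:
    def test_equal_occupancy_gives_midpoint(self):
        c2, resid = estimate_c2(0.0, 1.0, 1.0, scale=64.0)
        assert c2 == pytest.approx(0.5, abs=1e-3)
        assert resid < 1e-6

    def test_closed_form_positive_log_ratio(self):
        # with scale 6 on the unit interval, ln r = 1/2 - c2
        c2, _ = estimate_c2(0.0, 1.0, np.exp(0.2), scale=6.0)
        assert c2 == pytest.approx(0.3, abs=1e-3)

    def test_closed_form_negative_log_ratio(self):
        c2, _ = estimate_c2(0.0, 1.0, np.exp(-0.1), scale=6.0)
        assert c2 == pytest.approx(0.6, abs=1e-3)

    def test_monotone_in_observed_ratio(self):
        """A fuller AML well (larger ratio) pulls the barrier toward c1."""
        ratios = np.exp(np.linspace(-1.0, 1.0, 9))
        c2s = [estimate_c2(0.0, 1.0, r, scale=64.0)[0] for r in ratios]
        assert all(a > b for a, b in zip(c2s, c2s[1:]))

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            estimate_c2(0.0, 1.0, 0.0, scale=6.0)

    def test_unattainable_ratio_warns(self):
        with pytest.warns(UserWarning, match="residual"):
            estimate_c2(0.0, 1.0, np.exp(50.0), scale=6.0)


class TestAssignment:
    model = PotentialModel(0.0, 1.0, 2.0, scale=4.0)

    def test_exact_critical_point(self):
        out = assign_critical_points(np.array([1.0]), self.model)
        assert out["assigned"].iloc[0] == "c2"
        assert out["distance"].iloc[0] == 0.0

    def test_nearest_point_wins(self):
        out = assign_critical_points(np.array([0.4]), self.model)
        assert out["assigned"].iloc[0] == "c1"

    def test_midpoint_tie_goes_to_c2(self):
        out = assign_critical_points(np.array([0.5]), self.model)
        assert out["assigned"].iloc[0] == "c2"

    def test_series_index_preserved(self):
        coords = pd.Series([0.1, 1.9], index=["a", "b"])
        out = assign_critical_points(coords, self.model)
        assert out["sample_id"].tolist() == ["a", "b"]
        assert out["assigned"].tolist() == ["c1", "c3"]


class TestLangevin:
    def test_deterministic_descent_to_well(self):
        m = PotentialModel(0.0, 0.5, 1.0, scale=64.0, beta_inv=0.0)
        _, x = simulate_langevin(m, x0=0.99, t_end=5.0, dt=0.001, seed=0)
        assert abs(x[-1] - 1.0) < 1e-4

    def test_barrier_top_is_stationary(self):
        m = PotentialModel(0.0, 0.5, 1.0, scale=64.0, beta_inv=0.0)
        _, x = simulate_langevin(m, x0=0.5, t_end=1.0, dt=0.001, seed=0)
        np.testing.assert_allclose(x, 0.5, atol=1e-12)

    def test_unstable_step_rejected(self):
        m = PotentialModel(0.0, 0.5, 1.0, scale=64.0, beta_inv=0.1)
        with pytest.raises(ValueError, match="dt"):
            simulate_langevin(m, x0=0.0, t_end=1.0, dt=0.1, seed=0)

    def test_occupancy_matches_boltzmann(self):
        """Long-run Langevin histogram agrees with the stationary law."""
        m = PotentialModel(0.0, 0.5, 1.0, scale=64.0, beta_inv=0.4)
        _, x = simulate_langevin(m, x0=0.0, t_end=200.0, dt=0.002, seed=1)
        hist, edges = np.histogram(
            x[5000:], bins=50, range=(-0.4, 1.4), density=True
        )
        centers = 0.5 * (edges[:-1] + edges[1:])
        p = stationary_density(m, centers)
        p /= p.sum() * (edges[1] - edges[0])
        tv = 0.5 * np.sum(np.abs(hist - p)) * (edges[1] - edges[0])
        assert tv < 0.05


class TestFokkerPlanck:
    def test_stationary_density_is_fixed_point(self):
        m = PotentialModel(0.0, 0.5, 1.0, scale=64.0, beta_inv=0.4)
        grid = np.linspace(-0.4, 1.4, 801)
        p0 = stationary_density(m, grid)
        sol = solve_fokker_planck(m, p0, grid, t_end=0.2)
        assert np.abs(sol.final() - p0).max() < 1e-4

    def test_mass_conserved(self):
        m = PotentialModel(0.0, 0.5, 1.0, scale=64.0, beta_inv=0.3)
        grid = np.linspace(-0.5, 1.5, 401)
        p0 = np.exp(-((grid - 0.1) ** 2) / (2 * 0.05**2))
        p0 /= np.trapezoid(p0, grid)
        sol = solve_fokker_planck(m, p0, grid, t_end=0.3)
        assert np.abs(sol.mass() - 1.0).max() < 1e-6
        assert np.all(sol.density >= -1e-12)

    def test_symmetry_preserved(self):
        """A symmetric potential keeps a symmetric density symmetric."""
        m = PotentialModel(-1.0, 0.0, 1.0, scale=4.0, beta_inv=0.5)
        grid = np.linspace(-2.0, 2.0, 401)
        p0 = np.exp(-(grid**2) / (2 * 0.3**2))
        p0 /= np.trapezoid(p0, grid)
        sol = solve_fokker_planck(m, p0, grid, t_end=0.25)
        assert np.abs(sol.final() - sol.final()[::-1]).max() < 1e-6

    def test_ou_limit_matches_analytic_gaussian(self):
        """With a quadratic-drift override the solution is the exact
        Ornstein-Uhlenbeck Gaussian."""
        kappa, mu, D, t_end = 1.0, 0.5, 0.05, 0.5
        m = PotentialModel(0.0, 0.5, 1.0, scale=1.0, beta_inv=D)
        grid = np.linspace(-1.0, 2.0, 601)
        s0, m0 = 0.1, 0.2
        p0 = np.exp(-((grid - m0) ** 2) / (2 * s0**2))
        p0 /= np.trapezoid(p0, grid)
        sol = solve_fokker_planck(
            m, p0, grid, t_end=t_end, drift=lambda x: -kappa * (x - mu)
        )
        mean_t = mu + (m0 - mu) * np.exp(-kappa * t_end)
        var_t = s0**2 * np.exp(-2 * kappa * t_end) + (D / kappa) * (
            1 - np.exp(-2 * kappa * t_end)
        )
        pa = np.exp(-((grid - mean_t) ** 2) / (2 * var_t))
        pa /= np.trapezoid(pa, grid)
        assert np.trapezoid(np.abs(sol.final() - pa), grid) < 1e-3

    def test_cfl_violation_rejected(self):
        m = PotentialModel(0.0, 0.5, 1.0, scale=64.0, beta_inv=0.4)
        grid = np.linspace(-0.4, 1.4, 201)
        p0 = stationary_density(m, grid)
        with pytest.raises(ValueError, match="stability"):
            solve_fokker_planck(m, p0, grid, t_end=1.0, dt=1.0)

    def test_langevin_and_fp_agree_on_stationary_state(self):
        """The two dynamics engines cross-validate each other."""
        m = PotentialModel(0.0, 0.5, 1.0, scale=64.0, beta_inv=0.4)
        grid = np.linspace(-0.4, 1.4, 301)
        p0 = np.exp(-((grid - 0.2) ** 2) / (2 * 0.1**2))
        p0 /= np.trapezoid(p0, grid)
        sol = solve_fokker_planck(m, p0, grid, t_end=3.0)
        _, x = simulate_langevin(m, x0=0.2, t_end=300.0, dt=0.002, seed=3)
        hist, edges = np.histogram(x[10000:], bins=45, range=(-0.4, 1.4), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        fp = np.interp(centers, grid, sol.final())
        fp /= fp.sum() * (edges[1] - edges[0])
        tv = 0.5 * np.sum(np.abs(hist - fp)) * (edges[1] - edges[0])
        assert tv < 0.07

    def test_lower_barrier_speeds_escape(self):
        """Reducing the energy barrier increases the fraction of
        trajectories that cross from the normal well within a fixed time."""
        crossed = {}
        for scale in (64.0, 16.0):
            m = PotentialModel(0.0, 0.5, 1.0, scale=scale, beta_inv=0.15)
            frac = 0.0
            for seed in range(20):
                _, x = simulate_langevin(m, x0=0.0, t_end=20.0, dt=0.002, seed=seed)
                frac += float(np.any(x > 0.5))
            crossed[scale] = frac / 20
        assert crossed[16.0] > crossed[64.0]


class TestBetaInvAndFit:
    def test_beta_inv_from_harmonic_fit(self):
        m = PotentialModel(0.0, 0.5, 1.0, scale=64.0)
        coords = np.random.default_rng(0).normal(0.0, 0.05, 500)
        est = estimate_beta_inv(m, coords)
        assert est == pytest.approx(m.curvature(0.0) * coords.var(ddof=1), rel=1e-12)

    def test_fit_potential_recovers_two_well_structure(self):
        rng = np.random.default_rng(4)
        coords = np.concatenate(
            [rng.normal(0, 0.05, 80), rng.normal(1.0, 0.05, 120)]
        )
        groups = np.array(["normal"] * 80 + ["AML"] * 120, dtype=object)
        model, info = fit_potential(coords, groups, seed=0)
        assert model.c1 == pytest.approx(0.0, abs=0.03)
        assert model.c3 == pytest.approx(1.0, abs=0.03)
        assert model.c1 < model.c2 < model.c3
        assert info["observed_ratio"] == pytest.approx(1.5)
        assert model.beta_inv > 0


class TestPseudotime:
    def matrix(self, marker_values, groups):
        n = len(marker_values)
        vals = np.vstack([marker_values, np.linspace(1, 2, n)])
        m = ExpressionMatrix(
            gene_ids=["KIT", "other"],
            sample_ids=[f"s{k}" for k in range(n)],
            values=vals,
        )
        meta = SampleTable(
            pd.DataFrame({"sample_id": m.sample_ids, "group": groups})
        )
        return m, meta

    def test_rank_rescaling(self):
        m, meta = self.matrix([1.0, 5.0, 3.0], ["normal", "AML", "AML"])
        pt = pseudotime_from_marker(m, "KIT", meta)
        np.testing.assert_allclose(pt.to_numpy(), [0.0, 1.0, 0.5])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 10, 30)
        groups = ["normal"] * 15 + ["AML"] * 15
        x[15:] += 20
        m1, meta = self.matrix(x, groups)
        m2, _ = self.matrix(np.exp(0.3 * x), groups)
        a = pseudotime_from_marker(m1, "KIT", meta)
        b = pseudotime_from_marker(m2, "KIT", meta)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy())

    def test_ties_share_midrank(self):
        m, meta = self.matrix(
            [2.0, 2.0, 5.0, 7.0], ["normal", "normal", "AML", "AML"]
        )
        with pytest.warns(UserWarning):  # tiny groups: t-test underpowered
            pt = pseudotime_from_marker(m, "KIT", meta)
        np.testing.assert_allclose(pt.to_numpy(), [1 / 6, 1 / 6, 2 / 3, 1.0])

    def test_constant_marker_rejected(self):
        m, meta = self.matrix([3.0, 3.0, 3.0, 3.0], ["normal", "normal", "AML", "AML"])
        with pytest.raises(ValueError, match="constant"):
            pseudotime_from_marker(m, "KIT", meta)

    def test_uninformative_marker_warns_not_errors(self):
        rng = np.random.default_rng(6)
        m, meta = self.matrix(
            rng.uniform(1, 2, 20), ["normal"] * 10 + ["AML"] * 10
        )
        with pytest.warns(UserWarning, match="separate"):
            pseudotime_from_marker(m, "KIT", meta)

    def test_unknown_marker_rejected(self):
        m, meta = self.matrix([1.0, 2.0, 3.0, 4.0], ["normal", "normal", "AML", "AML"])
        with pytest.raises(KeyError):
            pseudotime_from_marker(m, "CD33", meta)
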