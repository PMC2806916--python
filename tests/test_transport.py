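import numpy as np
import pytest

from seepscape import (
    DepthGrid,
    DomainError,
    EstimationError,
    RateProfile,
    SoluteProfile,
    TransportSystem,
    ValidationError,
    effective_diffusivity,
    fit_rates_inverse,
    penetration_depth,
    solve_forward,
)


class TestEffectiveDiffusivity:
    def test_unit_porosity_leaves_diffusivity_unchanged(self):
        assert effective_diffusivity(1.0, 5e-6) == pytest.approx(5e-6)

    def test_tortuosity_formula(self):
        # D_s = D_O / (1 - ln(phi^2)); direct evaluation at phi = 0.8
        assert effective_diffusivity(0.8, 5e-6) == pytest.approx(5e-6 / (1 - np.log(0.64)))
        assert effective_diffusivity(0.8, 5e-6) == pytest.approx(3.457e-6, rel=1e-3)

    def test_monotone_in_porosity(self):
        assert effective_diffusivity(0.5, 5e-6) < effective_diffusivity(0.9, 5e-6)

    @pytest.mark.parametrize("phi", [0.0, -0.2, 1.1])
    def test_domain_errors(self, phi):
        with pytest.raises(DomainError):
            effective_diffusivity(phi, 5e-6)


class TestForwardSolver:
    def test_no_reaction_fixed_bottom_is_linear(self):
        """Pure diffusion between two Dirichlet boundaries is the straight line."""
        grid = DepthGrid(np.linspace(0, 30, 200))
        sys = TransportSystem(grid, bottom_boundary=5.0)
        c = solve_forward(sys, RateProfile(grid, np.zeros(len(grid)))).concentration
        line = 28.0 + (5.0 - 28.0) * grid.x / 30.0
        assert np.max(np.abs(c - line)) < 1e-8 * 28.0

    def test_constant_rate_matches_quadratic_closed_form(self):
        """Constant consumption + zero-gradient bottom: C = C0 - (R/Ds)(Lx - x^2/2)."""
        grid = DepthGrid(np.linspace(0, 30, 400))
        sys = TransportSystem(grid, porosity=0.8)
        R = 100.0  # nmol cm^-3 d^-1
        c = solve_forward(sys, RateProfile(grid, np.full(len(grid), R))).concentration
        Ds = float(sys.sediment_diffusivity[0])
        closed = 28.0 - (R * 1e-3 / Ds) * (30.0 * grid.x - grid.x**2 / 2.0)
        assert np.max(np.abs(c - closed)) / 28.0 < 1e-6

    def test_bioirrigation_relaxes_to_overlying_water(self):
        """With exchange only, C returns to C_ow within a few decay lengths sqrt(Ds/alpha)."""
        grid = DepthGrid.uniform(50.0, 0.05)
        sys = TransportSystem(grid, bioirrigation=0.5)
        c = solve_forward(sys, RateProfile(grid, np.zeros(len(grid)))).concentration
        Ds = float(sys.sediment_diffusivity[0])
        ten_lengths = 10.0 * np.sqrt(Ds / 0.5)
        idx = int(np.searchsorted(grid.x, ten_lengths))
        assert np.all(np.abs(c[idx:] - 28.0) < 1e-3 * 28.0)

    def test_exponential_rate_closed_form_and_convergence_order(self):
        """Non-polynomial closed form: observed convergence order ~2 under grid halving."""
        def max_err(nodes):
            grid = DepthGrid(np.linspace(0, 30, nodes))
            sys = TransportSystem(grid)
            lam, R0 = 3.0, 0.2  # cm, micromol cm^-3 d^-1
            c = solve_forward(sys, RateProfile(grid, 1e3 * R0 * np.exp(-grid.x / lam))).concentration
            Ds = float(sys.sediment_diffusivity[0])
            K = R0 * lam**2 / Ds
            B = (K / lam) * np.exp(-30.0 / lam)
            closed = (28.0 - K) + B * grid.x + K * np.exp(-grid.x / lam)
            return np.max(np.abs(c - closed))
        e_coarse, e_fine = max_err(201), max_err(401)
        assert e_fine / 28.0 < 1e-4
        assert np.log2(e_coarse / e_fine) >= 1.9

    def test_linearity_in_rates(self, grid30, diffusion_system):
        rng = np.random.default_rng(7)
        r1 = RateProfile(grid30, rng.uniform(0, 50, len(grid30)))
        r2 = RateProfile(grid30, rng.uniform(0, 50, len(grid30)))
        a, b = 2.0, -0.5
        combo = RateProfile(grid30, a * r1.rate + b * r2.rate)
        c_combo = solve_forward(diffusion_system, combo).concentration
        c0 = solve_forward(diffusion_system, RateProfile(grid30, np.zeros(len(grid30)))).concentration
        c1 = solve_forward(diffusion_system, r1).concentration
        c2 = solve_forward(diffusion_system, r2).concentration
        expected = a * c1 + b * c2 - (a + b - 1) * c0
        assert np.max(np.abs(c_combo - expected)) < 1e-8 * 28.0

    def test_negative_concentrations_are_reported_not_clipped(self, grid30, diffusion_system):
        huge = RateProfile(grid30, np.full(len(grid30), 2000.0))
        c = solve_forward(diffusion_system, huge).concentration
        assert c.min() < 0

    def test_rate_grid_mismatch_rejected(self, diffusion_system):
        other = DepthGrid.uniform(30.0, 0.5)
        with pytest.raises(ValidationError):
            solve_forward(diffusion_system, RateProfile(other, np.zeros(len(other))))


class TestInverse:
    def test_noise_free_round_trip_recovers_layer_rates(self, grid30, diffusion_system):
        true = RateProfile.from_layers(grid30, [(0, 10, 40.0), (10, 20, 15.0), (20, 30, 5.0)])
        obs = solve_forward(diffusion_system, true)
        fit = fit_rates_inverse(diffusion_system, obs, 3)
        np.testing.assert_allclose(fit.layer_rates, [40.0, 15.0, 5.0], rtol=1e-6)
        assert fit.residual_norm < 1e-6

    def test_flat_profile_yields_zero_rates(self, grid30, diffusion_system):
        obs = SoluteProfile(grid30, np.full(len(grid30), 28.0))
        fit = fit_rates_inverse(diffusion_system, obs, 3)
        np.testing.assert_allclose(fit.layer_rates, 0.0, atol=1e-8)

    def test_noisy_recovery_within_ten_percent_median(self, grid30, diffusion_system):
        """3% multiplicative noise, 100 replicates: median per-layer error < 10%."""
        truth = np.array([40.0, 15.0, 5.0])
        true = RateProfile.from_layers(grid30, [(0, 10, truth[0]), (10, 20, truth[1]), (20, 30, truth[2])])
        clean = solve_forward(diffusion_system, true)
        assert clean.concentration.min() > 0  # physically sensible scenario
        rng = np.random.default_rng(2024)
        errs = []
        for _ in range(100):
            noisy = clean.with_concentration(
                np.maximum(clean.concentration * (1 + 0.03 * rng.standard_normal(len(grid30))), 0.0))
            fit = fit_rates_inverse(diffusion_system, noisy, 3)
            errs.append(np.abs(fit.layer_rates - truth) / truth)
        med = np.median(np.array(errs), axis=0)
        assert np.all(med < 0.10)

    def test_empty_layer_is_an_estimation_error(self, grid30, diffusion_system):
        obs = solve_forward(diffusion_system, RateProfile(grid30, np.zeros(len(grid30))))
        with pytest.raises(EstimationError):
            fit_rates_inverse(diffusion_system, obs, 2, layer_bounds=[(0, 10), (40, 50)])


class TestPenetrationDepth:
    def test_linear_profile_interpolates(self):
        grid = DepthGrid(np.array([0.0, 10.0]))
        prof = SoluteProfile(grid, np.array([28.0, 0.0]))
        res = penetration_depth(prof, 0.7)
        assert not res.beyond_domain
        assert res.depth_cm == pytest.approx(10 * (28 - 0.7) / 28)  # 9.75

    def test_non_depleting_profile_is_beyond_domain(self, grid30):
        prof = SoluteProfile(grid30, np.full(len(grid30), 28.0))
        res = penetration_depth(prof, 0.7)
        assert res.beyond_domain and res.depth_cm == 30.0

    def test_surface_already_below_threshold(self, grid30):
        prof = SoluteProfile(grid30, np.full(len(grid30), 0.5))
        assert penetration_depth(prof, 0.7).depth_cm == 0.0

    def test_nonpositive_threshold_rejected(self, grid30):
        prof = SoluteProfile(grid30, np.full(len(grid30), 1.0))
        with pytest.raises(DomainError):
            penetration_depth(prof, 0.0)


def test_flux_balance_conservation(grid30):
    """With no burial or irrigation, the diffusive influx at the surface equals
    the depth integral of phi*R (discrete conservation, < 1e-6 relative).

    The discrete flux uses the matrix's own top stencil so the identity holds
    to solver precision."""
    sys = TransportSystem(grid30, porosity=0.8)
    rates = RateProfile.from_layers(grid30, [(5, 15, 120.0)])
    c = solve_forward(sys, rates).concentration
    phi_ds = 0.8 * float(sys.sediment_diffusivity[0])
    influx = -phi_ds * (c[1] - c[0]) / (grid30.x[1] - grid30.x[0])  # micromol cm^-2 d^-1 downward
    sink = np.trapezoid(0.8 * rates.rate * 1e-3, grid30.x)
    # rates vanish near the surface, so the two-point gradient is exact there
    assert abs(influx - sink) / sink < 1e-6
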