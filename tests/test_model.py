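import numpy as np
import pytest

from hydrostoma import GROUP_PARAMS, StomatalParams
from hydrostoma.errors import DomainError
from hydrostoma.model import (
    LeafEnvironment,
    hydraulic_conductance,
    osmotic_pressure,
    solve_gs,
    solve_leaf,
    transpiration,
)


@pytest.fixture
def subs():
    return GROUP_PARAMS["SUBS"]


class TestOsmoticPressure:
    def test_photosynthesis_raises_osmotic_pressure(self, subs):
        # pi_0 * (1 + xi*A/(K_i+A)) at A=6.5 for the subshrub parameters
        assert osmotic_pressure(subs, 6.5) == pytest.approx(2.239, abs=0.001)

    def test_no_gain_means_baseline(self, subs):
        p = subs.with_(xi=0.0)
        for a in (0.0, 5.0, 20.0):
            assert osmotic_pressure(p, a) == p.pi_0

    def test_zero_assimilation_is_baseline(self, subs):
        assert osmotic_pressure(subs, 0.0) == subs.pi_0

    def test_respiring_leaf_floored_at_baseline(self, subs):
        assert osmotic_pressure(subs, -3.0) == subs.pi_0

    def test_ci_below_ambient_amplifies(self, subs):
        assert osmotic_pressure(subs, 6.5, C_i=0.5 * subs.C_0) > osmotic_pressure(subs, 6.5)

    def test_degenerate_denominator_rejected(self, subs):
        with pytest.raises(DomainError):
            osmotic_pressure(subs, -subs.K_i - 1.0)


class TestHydraulicConductance:
    def test_no_tension_no_cavitation(self, subs):
        assert hydraulic_conductance(subs, 0.0) == pytest.approx(subs.g_p)

    def test_half_loss_at_analytic_point(self):
        p = StomatalParams(K_psi=0.5, g_p=0.01906, C_lambda=3.13, pi_0=1.5, K_i=300, xi=10)
        psi_half = -1.0 / (p.C_lambda * p.g_p)
        assert psi_half == pytest.approx(-16.76, abs=0.01)
        assert hydraulic_conductance(p, psi_half) == pytest.approx(p.g_p / 2, rel=1e-12)

    def test_efficiency_safety_tradeoff(self):
        p1 = StomatalParams(K_psi=0.5, g_p=0.002, C_lambda=3.13, pi_0=1.5, K_i=300, xi=10)
        p2 = p1.with_(g_p=0.004)
        for psi in (-0.5, -2.0, -8.0):
            frac1 = hydraulic_conductance(p1, psi) / p1.g_p
            frac2 = hydraulic_conductance(p2, psi) / p2.g_p
            assert frac2 < frac1

    def test_positive_tension_rejected(self, subs):
        with pytest.raises(DomainError):
            hydraulic_conductance(subs, 0.1)


class TestSolveLeaf:
    def test_favorable_corner(self, subs):
        state = solve_leaf(subs, LeafEnvironment(-0.033, 0.0035, 6.5))
        assert state.g_s == pytest.approx(1.65, abs=0.01)
        assert state.psi_x == pytest.approx(-1.07, abs=0.01)

    def test_no_demand_no_gradient(self, subs):
        state = solve_leaf(subs, LeafEnvironment(-0.5, 0.0, 6.5))
        assert state.psi_x == -0.5
        assert state.E == 0.0
        pi = osmotic_pressure(subs, 6.5)
        assert state.g_s == pytest.approx(subs.K_psi * (pi - 0.5))

    def test_closure_when_soil_drier_than_osmotic_offset(self, subs):
        state = solve_leaf(subs, LeafEnvironment(-2.5, 0.01, 6.5))
        assert state.g_s == 0.0
        assert state.E == 0.0
        assert state.psi_x == -2.5

    @pytest.mark.parametrize("label", ["GLB", "DCDS", "LEGM", "SUBS"])
    def test_mass_balance_and_root_agreement_on_grid(self, label, driver_grid):
        params = GROUP_PARAMS[label]
        psi_ax, D_ax, A_ax = driver_grid
        for psi in psi_ax:
            for D in D_ax:
                for A in A_ax:
                    st_c = solve_leaf(params, LeafEnvironment(psi, D, A), method="closed")
                    st_b = solve_leaf(params, LeafEnvironment(psi, D, A), method="bisect")
                    assert abs(st_c.psi_x - st_b.psi_x) < 1e-8
                    resid = st_c.g_s * D - st_c.K * (psi - st_c.psi_x)
                    assert abs(resid) < 1e-10

    def test_monotonic_in_soil_drought_and_demand(self, subs):
        psi_ax = np.linspace(-3.0, -0.05, 60)
        D_ax = np.linspace(0.0005, 0.06, 60)
        gs = solve_gs(subs, psi_ax[:, None], D_ax[None, :], 6.5)
        assert np.all(np.diff(gs, axis=0) >= -1e-12)   # wetter soil opens stomata
        assert np.all(np.diff(gs, axis=1) <= 1e-12)    # drier air closes them

    def test_closure_is_exactly_at_minus_pi(self, subs):
        pi = osmotic_pressure(subs, 6.5)
        assert solve_leaf(subs, LeafEnvironment(-pi - 1e-9, 0.01, 6.5)).g_s == 0.0
        assert solve_leaf(subs, LeafEnvironment(-pi + 1e-6, 0.01, 6.5)).g_s > 0.0

    def test_vanishing_cavitation_reduces_to_linear_supply(self, subs):
        p = subs.with_(C_lambda=1e-9)
        for psi, D, A in [(-0.5, 0.02, 6.5), (-1.5, 0.05, 12.0), (-0.1, 0.005, 2.0)]:
            state = solve_leaf(p, LeafEnvironment(psi, D, A))
            pi = osmotic_pressure(p, A)
            # linear model: K_psi*(pi+psi_x)*D = g_p*(psi - psi_x)
            psi_x_lin = (p.g_p * psi - p.K_psi * D * pi) / (p.g_p + p.K_psi * D)
            gs_lin = p.K_psi * max(pi + psi_x_lin, 0.0)
            assert state.g_s == pytest.approx(gs_lin, abs=1e-6)

    def test_state_invariants_on_grid(self, subs, driver_grid):
        psi_ax, D_ax, A_ax = driver_grid
        for psi in psi_ax:
            for D in D_ax[::3]:
                for A in A_ax[::2]:
                    s = solve_leaf(subs, LeafEnvironment(psi, D, A))
                    assert 0 < s.K <= subs.g_p + 1e-15
                    assert s.E >= 0.0
                    assert s.g_s >= 0.0
                    if s.g_s > 0:
                        assert -s.pi - 1e-9 <= s.psi_x <= psi + 1e-9

    def test_vectorized_matches_scalar(self, subs):
        rng = np.random.default_rng(0)
        psi = -rng.uniform(0.05, 3.5, 50)
        D = rng.uniform(0.0, 0.06, 50)
        A = rng.uniform(-2.0, 18.0, 50)
        vec = solve_gs(subs, psi, D, A)
        scal = [solve_leaf(subs, LeafEnvironment(p, d, a)).g_s for p, d, a in zip(psi, D, A)]
        np.testing.assert_allclose(vec, scal, atol=1e-12)

    def test_positive_soil_potential_rejected(self, subs):
        with pytest.raises(DomainError):
            LeafEnvironment(0.5, 0.01, 6.5)


class TestTranspiration:
    def test_product(self, subs):
        state = solve_leaf(subs, LeafEnvironment(-0.033, 0.0035, 6.5))
        assert transpiration(state, 0.0035) == pytest.approx(state.g_s * 0.0035)
        assert transpiration(1.7, 0.0035) == pytest.approx(0.00595)
        assert transpiration(0.23, 0.05) == pytest.approx(0.0115)
        assert transpiration(0.0, 0.05) == 0.0


class TestParams:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            StomatalParams(K_psi=2.0, g_p=0.01, C_lambda=3.13, pi_0=1.5, K_i=300, xi=10)
        with pytest.raises(ValueError):
            StomatalParams(K_psi=0.5, g_p=-0.01, C_lambda=3.13, pi_0=1.5, K_i=300, xi=10)
        with pytest.raises(ValueError):
            StomatalParams(K_psi=0.5, g_p=0.01, C_lambda=3.13, pi_0=3.5, K_i=300, xi=10)

    def test_group_fixtures_in_internal_units(self):
        # table prints g_p in mmol; internal storage is mol m-2 s-1 MPa-1
        assert GROUP_PARAMS["SUBS"].g_p == pytest.approx(0.00566)
        assert GROUP_PARAMS["SUBS"].lam == pytest.approx(3.13 * 0.00566)
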