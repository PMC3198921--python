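"""Vector fields, equilibria, Jacobian and stability classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nichecomp import (
    CompetitionParams,
    DensityState,
    ValidationError,
    boundary_equilibria,
    classify_stability,
    equilibrium_classic,
    interior_equilibrium_general,
    jacobian_general,
    rhs_classic,
    rhs_general,
)
from nichecomp.errors import DegenerateParametersError

from conftest import random_params, random_state

rates = st.floats(0.05, 2.0)
mortalities = st.floats(0.0, 1.0)
props = st.floats(0.0, 1.0)


@st.composite
def params_states(draw, k=None, v=None):
    p = CompetitionParams(
        beta1=draw(rates), beta2=draw(rates),
        mu1=draw(mortalities), mu2=draw(mortalities),
        k=draw(props) if k is None else k,
        v=draw(props) if v is None else v,
    )
    r1 = draw(st.floats(0.0, 1.0))
    r2 = draw(st.floats(0.0, 1.0)) * (1.0 - r1)
    return p, DensityState(r1, r2)


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(beta1=0.0, beta2=0.8, mu1=0.1, mu2=0.1),
            dict(beta1=0.2, beta2=-0.5, mu1=0.1, mu2=0.1),
            dict(beta1=0.2, beta2=0.8, mu1=-0.1, mu2=0.1),
            dict(beta1=0.2, beta2=0.8, mu1=0.1, mu2=0.1, k=1.2),
            dict(beta1=0.2, beta2=0.8, mu1=0.1, mu2=0.1, v=-0.3),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            CompetitionParams(**kwargs)

    @pytest.mark.parametrize("r1,r2", [(-0.01, 0.5), (0.7, 0.5), (0.5, -1e-6)])
    def test_states_off_simplex_rejected(self, r1, r2):
        with pytest.raises(ValidationError):
            DensityState(r1, r2)

    def test_tiny_numerical_negatives_tolerated(self):
        DensityState(-1e-10, 0.5)  # within the 1e-9 band: no error


class TestVectorFields:
    def test_classic_vanishes_at_coexistence_point(self, classic_params):
        """The closed-form equilibrium is an exact zero of the flow."""
        d = rhs_classic(classic_params, DensityState(0.5, 0.25))
        assert d == (0.0, 0.0)

    def test_classic_at_panel_initial_state(self, classic_params):
        # hand-evaluated at (0.6, 0.0001)
        d1, d2 = rhs_classic(classic_params, DensityState(0.6, 0.0001))
        assert d1 == pytest.approx(-0.012, rel=1e-12)
        assert d2 == pytest.approx(9.992e-6, rel=1e-9)

    @pytest.mark.parametrize("rho2", [0.0, 0.3, 0.9])
    def test_extinction_is_absorbing_for_species1(self, classic_params, rho2):
        d1, _ = rhs_classic(classic_params, DensityState(0.0, rho2))
        assert d1 == 0.0

    def test_general_vanishes_at_interior_point(self, general_params):
        d1, d2 = rhs_general(general_params, DensityState(1 / 7, 5 / 7))
        assert abs(d1) < 1e-12 and abs(d2) < 1e-12

    def test_origin_is_fixed_point(self, general_params):
        assert rhs_general(general_params, DensityState(0.0, 0.0)) == (0.0, 0.0)

    @given(params_states(k=1.0, v=0.0))
    def test_reduction_identity(self, ps):
        """k=1, v=0 collapses the generalized flow onto the classic one."""
        p, s = ps
        g = rhs_general(p, s)
        c = rhs_classic(p, s)
        for a, b in zip(g, c):
            assert a == pytest.approx(b, rel=1e-15, abs=0.0)

    @given(params_states())
    def test_full_occupancy_boundary_drains_at_death_rate(self, ps):
        """On rho1+rho2 = 1 colonization cancels: d(sum)/dt = -mu1*rho1 - mu2*rho2."""
        p, s = ps
        total = s.rho1 + s.rho2
        if total == 0.0:
            return
        b = DensityState(s.rho1 / total, s.rho2 / total)  # project to the boundary
        d1, d2 = rhs_general(p, b)
        assert d1 + d2 == pytest.approx(-p.mu1 * b.rho1 - p.mu2 * b.rho2, abs=1e-12)


class TestEquilibria:
    def test_classic_coexistence(self, classic_params):
        eq = equilibrium_classic(classic_params)
        assert (eq.rho1_star, eq.rho2_star) == (0.5, 0.25)
        assert eq.regime == "coexistence" and eq.feasible and eq.method == "closed_form"

    def test_classic_lower_inferior_birth_rate(self):
        eq = equilibrium_classic(CompetitionParams(0.2, 0.6, 0.1, 0.1))
        assert eq.rho1_star == pytest.approx(0.5)
        assert eq.rho2_star == pytest.approx(1 / 6, abs=1e-12)

    def test_classic_superior_extinct_when_mu_equals_beta(self):
        eq = equilibrium_classic(CompetitionParams(0.2, 0.8, 0.2, 0.1))
        assert eq.rho1_star == 0.0
        assert eq.rho2_star == pytest.approx(1 - 0.1 / 0.8)
        assert eq.regime == "species2-only"

    def test_classic_two_printed_forms_agree(self):
        """1 - mu2/b2 - rho1*(1+b1/b2) equals mu1/b1 - mu2/b2 + mu1/b2 - b1/b2."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = random_params(rng)
            r1 = 1 - p.mu1 / p.beta1
            form_a = 1 - p.mu2 / p.beta2 - r1 * (1 + p.beta1 / p.beta2)
            form_b = p.mu1 / p.beta1 - p.mu2 / p.beta2 + p.mu1 / p.beta2 - p.beta1 / p.beta2
            assert form_a == pytest.approx(form_b, abs=1e-12)

    def test_interior_general_panel_values(self, general_params):
        eq = interior_equilibrium_general(general_params)
        assert eq.rho1_star == pytest.approx(1 / 7, abs=1e-12)
        assert eq.rho2_star == pytest.approx(5 / 7, abs=1e-12)
        assert eq.regime == "coexistence" and eq.feasible
        assert eq.method == "linear_solve"

    def test_interior_general_reduces_to_classic(self, classic_params):
        eq = interior_equilibrium_general(classic_params)
        ref = equilibrium_classic(classic_params)
        assert eq.rho1_star == pytest.approx(ref.rho1_star, abs=1e-12)
        assert eq.rho2_star == pytest.approx(ref.rho2_star, abs=1e-12)

    def test_interior_infeasible_falls_back_to_boundary(self):
        # raw closed-form rho2* = -0.5: species 2 is excluded
        eq = interior_equilibrium_general(CompetitionParams(0.2, 0.8, 0.1, 0.7))
        assert (eq.rho1_star, eq.rho2_star) == (0.5, 0.0)
        assert eq.regime == "species1-only"
        assert not eq.feasible

    def test_interior_singular_system_raises(self):
        # k = v = 0: parallel nullclines, no isolated interior point
        with pytest.raises(DegenerateParametersError, match="det"):
            interior_equilibrium_general(CompetitionParams(0.2, 0.8, 0.1, 0.1, k=0.0, v=0.0))

    @given(params_states())
    def test_interior_solution_is_a_nullcline_zero(self, ps):
        """Whenever the linear solve is feasible the flow vanishes there."""
        p, _ = ps
        try:
            eq = interior_equilibrium_general(p)
        except DegenerateParametersError:
            return
        if eq.feasible:
            d = rhs_general(p, DensityState(eq.rho1_star, eq.rho2_star))
            assert max(abs(d[0]), abs(d[1])) < 1e-10

    def test_boundary_equilibria(self, classic_params):
        pts = {(e.rho1_star, e.rho2_star) for e in boundary_equilibria(classic_params)}
        assert pts == {(0.0, 0.0), (0.5, 0.0), (0.0, 0.875)}

    def test_boundary_infeasible_when_mu_exceeds_beta(self):
        eqs = boundary_equilibria(CompetitionParams(0.2, 0.8, 0.5, 0.1))
        sp1 = next(e for e in eqs if e.regime == "species1-only")
        assert not sp1.feasible and sp1.rho1_star < 0

    def test_boundary_full_occupancy_without_mortality(self):
        eqs = boundary_equilibria(CompetitionParams(0.2, 0.8, 0.0, 0.0))
        pts = {(e.rho1_star, e.rho2_star) for e in eqs}
        assert (1.0, 0.0) in pts and (0.0, 1.0) in pts


class TestJacobianStability:
    def test_jacobian_at_origin_is_diagonal_growth_rates(self, general_params):
        j = jacobian_general(general_params, DensityState(0.0, 0.0))
        assert np.allclose(j, np.diag([0.2 - 0.1, 0.8 - 0.1]))

    def test_jacobian_classic_coexistence_point(self, classic_params):
        j = jacobian_general(classic_params, DensityState(0.5, 0.25))
        assert np.allclose(j, [[-0.1, 0.0], [-0.25, -0.2]], atol=1e-14)

    def test_jacobian_matches_finite_differences(self):
        """Analytic partials agree with a central-difference oracle (step 1e-6)."""
        rng = np.random.default_rng(7)
        h = 1e-6
        for _ in range(300):
            p = random_params(rng)
            r1 = rng.uniform(0.01, 0.98)
            r2 = rng.uniform(0.01, 0.99 - r1)
            j = jacobian_general(p, DensityState(r1, r2))
            for col, (d1, d2) in enumerate([(h, 0.0), (0.0, h)]):
                fp = rhs_general(p, DensityState(r1 + d1, r2 + d2))
                fm = rhs_general(p, DensityState(r1 - d1, r2 - d2))
                fd = (np.array(fp) - np.array(fm)) / (2 * h)
                assert np.allclose(j[:, col], fd, atol=1e-6)

    def test_classic_coexistence_point_is_stable(self, classic_params):
        eq = equilibrium_classic(classic_params)
        assert classify_stability(classic_params, eq) == "stable"

    def test_origin_unstable_when_growth_positive(self, general_params):
        from nichecomp.model import EquilibriumResult

        origin = EquilibriumResult(0.0, 0.0, "both-extinct", True, "closed_form")
        assert classify_stability(general_params, origin) == "unstable"

    def test_single_species_point_is_saddle_under_invasion(self, classic_params):
        """(1-mu1/beta1, 0) can be invaded by species 2: a saddle."""
        from nichecomp.model import EquilibriumResult

        eq = EquilibriumResult(0.5, 0.0, "species1-only", True, "closed_form")
        assert classify_stability(classic_params, eq) == "saddle"

    def test_general_interior_point_is_stable(self, general_params):
        eq = interior_equilibrium_general(general_params)
        assert classify_stability(general_params, eq) == "stable"

    def test_non_fixed_point_rejected(self, classic_params):
        from nichecomp.model import EquilibriumResult

        bogus = EquilibriumResult(0.3, 0.3, "coexistence", True, "closed_form")
        with pytest.raises(ValidationError, match="not a fixed point"):
            classify_stability(classic_params, bogus)
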