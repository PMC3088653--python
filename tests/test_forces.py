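"""Force tests: every conservative force must equal the numerical variation
of its own free-energy term under normal node displacement (central
differences), and the analytic circle values pin the sign conventions."""

import numpy as np
import pytest

from protrusim import forces, geometry as geom
from protrusim.model_core import ContourState, FlatState, ModelParams

from conftest import make_flat_state, make_round_state

DELTA = 1e-6  # displacement step (um) for the variational oracle

TERMS_FLAT = {
    "curvature": forces.force_curvature,
    "tension": forces.force_tension,
    "spring": forces.force_spring,
    "aggregation_surface": forces.force_aggregation,
}
TERMS_ROUND = {
    "curvature": forces.force_curvature,
    "tension": forces.force_tension,
    "aggregation_surface": forces.force_aggregation,
}


def numeric_force_flat(state, p, term):
    n = state.N
    f = np.empty(n)
    for i in range(n):
        sp, sm = state.copy(), state.copy()
        sp.h[i] += DELTA
        sm.h[i] -= DELTA
        ep = forces.energy_terms(sp, p)[term]
        em = forces.energy_terms(sm, p)[term]
        f[i] = -(ep - em) / (2 * DELTA * state.dx)
    return f


def numeric_force_round(state, p, term):
    g = geom.closed_geometry(state.nodes)
    n = state.N
    f = np.empty(n)
    for i in range(n):
        sp, sm = state.copy(), state.copy()
        sp.nodes[i] += DELTA * g.normal[i]
        sm.nodes[i] -= DELTA * g.normal[i]
        ep = forces.energy_terms(sp, p)[term]
        em = forces.energy_terms(sm, p)[term]
        f[i] = -(ep - em) / (2 * DELTA * g.ds_node[i])
    return f


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("term", sorted(TERMS_FLAT))
def test_flat_forces_match_variational_oracle(term, seed):
    p = ModelParams(alpha_adh=30.0, lam_nl=0.1, J_bind=1.0)
    state = make_flat_state(N=48, seed=seed)
    fa = TERMS_FLAT[term](state, p)
    fn = numeric_force_flat(state, p, term)
    scale = max(np.max(np.abs(fa)), 1e-12)
    assert np.max(np.abs(fa - fn)) / scale < 1e-3


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("term", sorted(TERMS_ROUND))
def test_round_forces_match_variational_oracle(term, seed):
    p = ModelParams(alpha_adh=30.0, lam_nl=0.1, J_bind=1.0)
    state = make_round_state(N=128, seed=seed)
    fa = TERMS_ROUND[term](state, p)
    fn = numeric_force_round(state, p, term)
    scale = max(np.max(np.abs(fa)), 1e-12)
    assert np.max(np.abs(fa - fn)) / scale < 1e-3


class TestFreeEnergy:
    def test_uniform_flat_closed_form(self):
        """Hand-evaluated integrand at a uniform point times the area."""
        p = ModelParams(A_actin=0.0, alpha_adh=0.0, gamma=0.0)
        N, L = 64, 20.0
        x = np.arange(N) * (L / N)
        phi = 0.1
        s = FlatState(x=x, h=np.zeros(N), phi=np.full(N, phi), L_init=L)
        ent = p.temperature * p.n_s * (phi * np.log(phi)
                                       + (1 - phi) * np.log(1 - phi))
        agg = -0.5 * p.J_bind * p.n_s * phi ** 2
        curv = 0.5 * p.kappa * (p.Hbar * phi) ** 2
        expected = L * p.w * (ent + agg + curv)  # tension term: G(L0) = 0
        assert forces.free_energy(s, p) == pytest.approx(expected, rel=1e-12)

    def test_curvature_term_vanishes_at_perfect_mismatch(self):
        """H = Hbar*phi everywhere cancels the bending energy."""
        p = ModelParams()
        N, R = 256, 3.0
        theta = 2 * np.pi * np.arange(N) / N
        nodes = R * np.column_stack([np.cos(theta), np.sin(theta)])
        phi0 = (-1 / R) / p.Hbar  # coverage matching the circle curvature
        c = ContourState(nodes=nodes, phi=np.full(N, phi0),
                         A_pref=np.pi * R ** 2, L_init=2 * np.pi * R)
        assert forces.energy_terms(c, p)["curvature"] == pytest.approx(
            0.0, abs=1e-10)

    def test_energy_linear_in_strip_width(self):
        p1 = ModelParams(w=1.0)
        p2 = ModelParams(w=2.0)
        s = make_flat_state(seed=1)
        assert forces.free_energy(s, p2) == pytest.approx(
            2 * forces.free_energy(s, p1), rel=1e-12)

    def test_saturated_coverage_warns(self):
        p = ModelParams()
        s = make_flat_state(seed=0)
        s.phi[3] = 1.0
        with pytest.warns(UserWarning, match="clamped"):
            forces.free_energy(s, p)


class TestCircleValues:
    def circle(self, N=256, R=3.0, phi=0.0):
        theta = 2 * np.pi * np.arange(N) / N
        nodes = R * np.column_stack([np.cos(theta), np.sin(theta)])
        return ContourState(nodes=nodes, phi=np.full(N, phi),
                            A_pref=np.pi * R ** 2, L_init=2 * np.pi * R)

    def test_tension_is_inward_lam_over_R(self):
        p = ModelParams(alpha_adh=0.0, lam_nl=0.0)
        c = self.circle()
        np.testing.assert_allclose(forces.force_tension(c, p), -p.lam / 3.0,
                                   rtol=1e-9)

    def test_bare_bending_force_is_outward(self):
        p = ModelParams()
        c = self.circle(phi=0.0)
        np.testing.assert_allclose(forces.force_curvature(c, p),
                                   p.kappa / (2 * 3.0 ** 3), rtol=1e-6)


class TestEffectiveTension:
    def test_reference_length_gives_bare_tension(self):
        p = ModelParams(lam_nl=0.7)
        s = FlatState(x=np.arange(64) * 0.3, h=np.zeros(64),
                      phi=np.zeros(64), L_init=64 * 0.3)
        np.testing.assert_allclose(forces.effective_tension(s, p), p.lam)

    def test_hardening_switched_off(self):
        p = ModelParams(lam_nl=0.0)
        s = make_flat_state(N=64, amp=0.8, seed=2)
        lam_eff = forces.effective_tension(s, p)
        np.testing.assert_allclose(lam_eff, p.lam - p.alpha_adh * s.phi)

    def test_local_negative_effective_tension_under_strong_adhesion(self):
        p = ModelParams(alpha_adh=50.0, lam_nl=0.0)
        s = make_flat_state(N=64, seed=2, phi_bar=0.3)
        lam_eff = forces.effective_tension(s, p)
        assert lam_eff.min() < 0.0  # alpha*phi exceeds lam locally


class TestSpring:
    def test_zero_at_rest_and_linear(self):
        p = ModelParams()
        s = make_flat_state(seed=4)
        f1 = forces.force_spring(s, p)
        s2 = s.copy()
        s2.h *= 2
        np.testing.assert_allclose(forces.force_spring(s2, p), 2 * f1)

    def test_round_geometry_rejected(self):
        p = ModelParams()
        c = make_round_state(N=64)
        with pytest.raises(TypeError):
            forces.force_spring(c, p)


class TestAggregation:
    def test_uniform_phi_gives_zero(self):
        p = ModelParams(J_bind=2.0)
        c = make_round_state(N=64, phi_amp=0.0, amp=0.1)
        np.testing.assert_allclose(forces.force_aggregation(c, p), 0.0,
                                   atol=1e-14)

    def test_switch_off(self):
        p = ModelParams(J_bind=0.0)
        s = make_flat_state(seed=1)
        np.testing.assert_allclose(forces.force_aggregation(s, p), 0.0)


class TestActin:
    def test_zero_coverage_zero_force(self):
        p = ModelParams(A_actin=50.0)
        s = make_flat_state(seed=0)
        s.phi[:] = 0.0
        np.testing.assert_allclose(forces.force_actin(s, p), 0.0)

    def test_flat_mean_subtraction_exact(self):
        p = ModelParams(A_actin=50.0)
        s = make_flat_state(seed=0, phi_amp=0.0)  # uniform phi
        np.testing.assert_allclose(forces.force_actin(s, p), 0.0, atol=1e-13)

    def test_uniform_circle_outward_with_zero_vector_sum(self):
        p = ModelParams(A_actin=50.0)
        c = make_round_state(N=128, amp=0.0, phi_amp=0.0)
        f = forces.force_actin(c, p)
        np.testing.assert_allclose(f, 50.0 * 0.1)
        g = geom.closed_geometry(c.nodes)
        F = np.sum(f[:, None] * g.normal * g.ds_node[:, None], axis=0)
        assert np.hypot(*F) < 1e-10


class TestAreaPressure:
    def test_zero_at_preferred_area(self):
        p = ModelParams()
        c = make_round_state(N=128, amp=0.0)
        c.A_pref = geom.signed_area(c.nodes)
        np.testing.assert_allclose(forces.force_area_pressure(c, p), 0.0)

    def test_inward_when_over_area_and_linear_slope(self):
        p = ModelParams()
        c = make_round_state(N=128, amp=0.0)
        A = geom.signed_area(c.nodes)
        c.A_pref = 0.9 * A
        f1 = forces.force_area_pressure(c, p)[0]
        assert f1 < 0  # inflated -> inward
        # finite-difference slope versus the area strain
        c.A_pref = A * 0.95
        f2 = forces.force_area_pressure(c, p)[0]
        slope = (f1 - f2) / ((A / (0.9 * A) - 1) - (A / (0.95 * A) - 1))
        assert slope == pytest.approx(-p.K_area, rel=1e-9)


class TestAssemble:
    def test_uniform_passive_flat_is_stationary(self):
        p = ModelParams(A_actin=0.0, alpha_adh=0.0)
        N, L = 64, 20.0
        s = FlatState(x=np.arange(N) * (L / N), h=np.zeros(N),
                      phi=np.full(N, 0.1), L_init=L)
        v, fb = forces.assemble_normal_velocity(s, p)
        np.testing.assert_allclose(v, 0.0, atol=1e-13)
        np.testing.assert_allclose(fb.f_total,
                                   fb.f_curv + fb.f_tension + fb.f_spring
                                   + fb.f_agg + fb.f_actin + fb.f_area)

    def test_doubling_friction_halves_velocity(self):
        s = make_flat_state(seed=3)
        v1, _ = forces.assemble_normal_velocity(s, ModelParams(xi=100.0))
        v2, _ = forces.assemble_normal_velocity(s, ModelParams(xi=200.0))
        np.testing.assert_allclose(v2, 0.5 * v1, rtol=1e-12)
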