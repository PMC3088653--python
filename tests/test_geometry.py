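import numpy as np
import pytest

from protrusim import geometry as geom
from protrusim.model_core import ContourState, FlatState

from conftest import make_flat_state, make_round_state


def circle_state(N, R=3.0, phi=0.1):
    theta = 2 * np.pi * np.arange(N) / N
    nodes = R * np.column_stack([np.cos(theta), np.sin(theta)])
    return ContourState(nodes=nodes, phi=np.full(N, phi),
                        A_pref=np.pi * R ** 2, L_init=2 * np.pi * R)


class TestCurvatureClosed:
    def test_circle_convention(self):
        c = circle_state(96, R=3.0)
        np.testing.assert_allclose(geom.curvature_closed(c), -1 / 3.0,
                                   rtol=1e-12)

    def test_second_order_convergence_on_ellipse(self):
        # curvature magnitude of an ellipse: ab / (a^2 sin^2 t + b^2 cos^2 t)^{3/2}
        a, b = 2.0, 1.0
        errs = []
        for N in (128, 256):
            t = 2 * np.pi * np.arange(N) / N
            nodes = np.column_stack([a * np.cos(t), b * np.sin(t)])
            c = ContourState(nodes=nodes, phi=np.full(N, 0.1),
                             A_pref=np.pi * a * b, L_init=1.0)
            H = geom.curvature_closed(c)
            H_exact = -a * b / (a ** 2 * np.sin(t) ** 2
                                + b ** 2 * np.cos(t) ** 2) ** 1.5
            errs.append(np.max(np.abs(H - H_exact)))
        assert errs[0] / errs[1] >= 3.0  # ~4x for a 2nd-order scheme

    def test_ellipse_apex_value(self):
        a, b, N = 2.0, 1.0, 512
        t = 2 * np.pi * np.arange(N) / N
        nodes = np.column_stack([a * np.cos(t), b * np.sin(t)])
        c = ContourState(nodes=nodes, phi=np.full(N, 0.1),
                         A_pref=np.pi * a * b, L_init=1.0)
        H = geom.curvature_closed(c)
        assert H[0] == pytest.approx(-a / b ** 2, rel=1e-3)

    def test_coincident_nodes_rejected(self):
        c = circle_state(32)
        c.nodes[5] = c.nodes[4]
        with pytest.raises(ValueError, match="coincident"):
            geom.curvature_closed(c)


class TestCurvatureFlat:
    def test_flat_is_zero(self):
        s = FlatState(x=np.linspace(0, 10, 50, endpoint=False),
                      h=np.zeros(50), phi=np.full(50, 0.1), L_init=10.0)
        assert np.all(geom.curvature_flat_linearized(s) == 0.0)

    def test_cosine_spectral_identity_and_convergence(self):
        L, eps, k = 20.0, 0.1, 3
        q = 2 * np.pi * k / L
        errs = []
        for N in (64, 128):
            x = np.arange(N) * (L / N)
            s = FlatState(x=x, h=eps * np.cos(q * x),
                          phi=np.full(N, 0.1), L_init=L)
            H = geom.curvature_flat_linearized(s)
            errs.append(np.max(np.abs(H + eps * q * q * np.cos(q * x))))
        assert errs[0] / errs[1] >= 3.5  # second order in dx
        assert errs[1] < 1e-3 * eps * q * q * 20


class TestEnclosedArea:
    def test_circle(self):
        c = circle_state(512, R=3.0)
        assert geom.enclosed_area(c) == pytest.approx(9 * np.pi, rel=1e-4)

    def test_unit_square_exact(self):
        nodes = np.array([[0., 0.], [1., 0.], [1., 1.], [0., 1.]])
        c = ContourState(nodes=nodes, phi=np.full(4, 0.1), A_pref=1.0,
                         L_init=4.0)
        assert geom.enclosed_area(c) == 1.0

    def test_star_polygon_matches_triangulation(self):
        rng = np.random.default_rng(5)
        N = 40
        theta = np.sort(rng.uniform(0, 2 * np.pi, N))
        r = rng.uniform(1.0, 2.0, N)
        nodes = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        c = ContourState(nodes=nodes, phi=np.full(N, 0.1), A_pref=1.0,
                         L_init=1.0)
        # independent oracle: fan triangulation from the origin
        area = 0.0
        for i in range(N):
            pj = nodes[(i + 1) % N]
            area += 0.5 * (nodes[i][0] * pj[1] - pj[0] * nodes[i][1])
        assert geom.enclosed_area(c) == pytest.approx(area, abs=1e-12)

    def test_self_intersection_is_hard_error(self):
        nodes = np.array([[0., 0.], [1., 1.], [1., 0.], [0., 1.]])  # bowtie
        c = ContourState.__new__(ContourState)
        c.nodes, c.phi, c.A_pref, c.L_init, c.t, c.M_total = \
            nodes, np.full(4, 0.1), 1.0, 4.0, 0.0, 0.0
        with pytest.raises(ValueError):
            geom.enclosed_area(c)


class TestResample:
    def test_uniform_circle_is_fixed_point(self):
        c = circle_state(128)
        out = geom.resample_contour(c)
        np.testing.assert_allclose(out.nodes, c.nodes, atol=1e-10)

    def test_clustered_nodes_equalized_radius_kept(self):
        R, N = 3.0, 128
        u = np.linspace(0, 1, N, endpoint=False)
        theta = 2 * np.pi * (u + 0.08 * np.sin(2 * np.pi * u))  # clustered
        nodes = R * np.column_stack([np.cos(theta), np.sin(theta)])
        c = ContourState(nodes=nodes, phi=np.full(N, 0.1),
                         A_pref=np.pi * R ** 2, L_init=2 * np.pi * R)
        out = geom.resample_contour(c)
        g = geom.closed_geometry(out.nodes)
        assert g.ds_edge.max() / g.ds_edge.min() <= 1 + 1e-6
        r = np.hypot(out.nodes[:, 0], out.nodes[:, 1])
        np.testing.assert_allclose(r, R, atol=1e-6)

    def test_mass_conserved_through_resampling(self):
        c = make_round_state(N=128, amp=0.2, seed=2)
        g0 = geom.closed_geometry(c.nodes)
        m0 = float(np.sum(c.phi * g0.ds_node))
        out = geom.resample_contour(c)
        g1 = geom.closed_geometry(out.nodes)
        m1 = float(np.sum(out.phi * g1.ds_node))
        assert abs(m1 / m0 - 1) < 1e-12

    def test_mass_conserved_through_chain_of_resamples(self):
        c = make_round_state(N=96, amp=0.15, seed=3)
        g = geom.closed_geometry(c.nodes)
        m0 = float(np.sum(c.phi * g.ds_node))
        for _ in range(10):
            c = geom.resample_contour(c)
        g = geom.closed_geometry(c.nodes)
        m1 = float(np.sum(c.phi * g.ds_node))
        assert abs(m1 / m0 - 1) < 1e-9


class TestTransferDensity:
    def test_uniform_stays_uniform(self):
        N, L = 64, 10.0
        s_old = np.arange(N) * (L / N)
        s_new = np.sort(np.random.default_rng(0).uniform(0, L, N))
        ds = np.full(N, L / N)
        gaps = np.diff(np.concatenate([s_new, [s_new[0] + L]]))
        ds_new = 0.5 * (gaps + np.roll(gaps, 1))  # dual cells, sum == L
        phi = geom.transfer_density(s_old, np.full(N, 0.3), ds,
                                    s_new, ds_new, L)
        np.testing.assert_allclose(phi, 0.3, rtol=1e-12)

    def test_sinusoid_interpolation_second_order(self):
        L = 10.0
        f = lambda s: 0.3 + 0.2 * np.sin(2 * np.pi * s / L)
        errs = []
        for N in (64, 128):
            s_old = np.arange(N) * (L / N)
            s_new = s_old + 0.5 * (L / N)  # half-cell shift
            ds = np.full(N, L / N)
            phi = geom.transfer_density(s_old, f(s_old), ds, s_new, ds, L)
            errs.append(np.max(np.abs(phi - f(s_new))))
        assert errs[0] / errs[1] > 3.0


class TestSignConsistency:
    def test_closed_and_flat_conventions_agree_in_large_radius_limit(self):
        """A shallow bump on a huge circle matches the Monge curvature of
        the unrolled bump (same sign, within 2%)."""
        R, N = 500.0, 4096
        L_arc = 2 * np.pi * R
        k = 200  # azimuthal mode -> wavelength ~ 15.7 um
        amp = 0.02
        theta = 2 * np.pi * np.arange(N) / N
        r = R + amp * np.cos(k * theta)
        nodes = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        c = ContourState(nodes=nodes, phi=np.full(N, 0.1),
                         A_pref=np.pi * R ** 2, L_init=L_arc)
        H_round = geom.curvature_closed(c) + 1.0 / R  # subtract base circle
        x = R * theta
        s = FlatState(x=x, h=amp * np.cos(k * theta),
                      phi=np.full(N, 0.1), L_init=L_arc)
        H_flat = geom.curvature_flat_linearized(s)
        i = np.argmin(np.abs(theta - np.pi / k / 2))  # generic phase point
        assert np.sign(H_round[0]) == np.sign(H_flat[0]) == -1
        np.testing.assert_allclose(H_round, H_flat, atol=0.02 * np.max(
            np.abs(H_flat)))
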