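"""Free energy and the normal forces entering the equations of motion.

The free energy is of Helfrich type, extended with the protein field::

    F = w * integral ds [ kappa/2 (H - Hbar*phi)^2        curvature mismatch
                          + (lam(L) - alpha*phi)          tension - adhesion
                          + gamma/2 h^2                   pinning (flat only)
                          + T n_s (phi ln phi
                                   + (1-phi) ln(1-phi))   saturated entropy
                          - J n_s/2 phi^2                 bulk aggregation
                          + J n_s b^2/2 (d phi/ds)^2 ]    surface aggregation

with ``lam(L)`` the hardening tension (see :func:`tension_of_length`).
Conservative forces are the exact (machine-precision) discrete gradients of
the discretized energy terms with respect to normal node displacement at
fixed ``phi``; in the continuum limit they reduce to the classical
contour-variation formulas, e.g. for the curvature term::

    f_curv = -kappa [ (d^2/ds^2 + H^2)(H - Hbar*phi) ]
             + kappa/2 H (H - Hbar*phi)^2

The entropic and bulk-aggregation contour-expansion (metric) forces are
neglected, as is conventional for this model class; those terms contribute
to the energy and to the protein fluxes but exert no shape force.  The
actin pressure and the global area-preserving pressure are active /
constraint forces and are not derived from ``F``.

In the flat (Monge) geometry the curvature force is kept to linear order
(``f_curv = -kappa (h_xxxx - Hbar phi_xx)``) and the quadratic-slope length
``L2 = integral (1 + h_x^2/2) dx`` stands in for the arclength, so that all
flat forces remain exact discrete gradients of the flat energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import geometry as geom
from .model_core import ContourState, FlatState, ModelParams

State = Union[FlatState, ContourState]

__all__ = [
    "ForceBreakdown",
    "free_energy",
    "energy_terms",
    "tension_of_length",
    "tension_potential",
    "effective_tension",
    "force_curvature",
    "force_tension",
    "force_spring",
    "force_aggregation",
    "force_actin",
    "force_area_pressure",
    "assemble_normal_velocity",
]


@dataclass
class ForceBreakdown:
    """Per-node normal force components (k_BT/um^3, outward positive)."""

    f_curv: np.ndarray
    f_tension: np.ndarray
    f_spring: np.ndarray
    f_agg: np.ndarray
    f_actin: np.ndarray
    f_area: np.ndarray

    @property
    def f_total(self) -> np.ndarray:
        return (self.f_curv + self.f_tension + self.f_spring + self.f_agg
                + self.f_actin + self.f_area)

    def to_frame(self, s: np.ndarray):
        import pandas as pd

        return pd.DataFrame({
            "s": s, "f_curv": self.f_curv, "f_tension": self.f_tension,
            "f_spring": self.f_spring, "f_agg": self.f_agg,
            "f_actin": self.f_actin, "f_area": self.f_area,
            "f_total": self.f_total,
        })


# ----------------------------------------------------------------- tension

def tension_of_length(L: float, p: ModelParams, L0: float) -> float:
    """Hardening tension ``lam(L) = lam (1 + ((L-L0)/(lam_nl L0))^2)``.

    ``lam_nl`` is the contour strain at which the nonlinear growth sets in;
    ``lam_nl = 0`` switches the hardening off (tension independent of L).
    """
    if p.lam_nl <= 0 or L0 <= 0:
        return p.lam
    strain = (L - L0) / (p.lam_nl * L0)
    return p.lam * (1.0 + strain * strain)


def tension_potential(L: float, p: ModelParams, L0: float) -> float:
    """Line-energy primitive G(L) with ``G'(L) = tension_of_length(L)``."""
    if p.lam_nl <= 0 or L0 <= 0:
        return p.lam * (L - L0)
    d = L - L0
    return p.lam * (d + d ** 3 / (3.0 * (p.lam_nl * L0) ** 2))


def _flat_quadratic_length(state: FlatState) -> float:
    dh = np.roll(state.h, -1) - state.h
    return state.L_domain + float(np.sum(dh * dh)) / (2.0 * state.dx)


def effective_tension(state: State, p: ModelParams) -> np.ndarray:
    """Local effective tension ``lam(L) - alpha*phi`` per node.

    Can turn negative where adhesion is strong and the proteins concentrate
    (locally negative effective membrane tension, the adhesion-driven
    protrusion mechanism).
    """
    if isinstance(state, FlatState):
        L = _flat_quadratic_length(state)
    else:
        L = geom.closed_geometry(state.nodes).L
    lamL = tension_of_length(L, p, state.L_init)
    return lamL - p.alpha_adh * state.phi


# ------------------------------------------------------------ energy terms

def _entropy_density(phi: np.ndarray, p: ModelParams) -> np.ndarray:
    import warnings

    if np.any((phi == 0.0) | (phi == 1.0)):
        warnings.warn("phi exactly at 0 or 1: entropy evaluated with "
                      "clamped log arguments", UserWarning, stacklevel=3)
    ph = np.clip(phi, 1e-15, 1.0 - 1e-15)
    return p.temperature * p.n_s * (ph * np.log(ph)
                                    + (1.0 - ph) * np.log(1.0 - ph))


def energy_terms(state: State, p: ModelParams) -> dict:
    """Discretized energy terms, per unit strip width w (k_BT/um)."""
    phi = state.phi
    if isinstance(state, FlatState):
        dx = state.dx
        H = geom.curvature_flat_linearized(state)
        u = H - p.Hbar * phi
        e_curv = 0.5 * p.kappa * float(np.sum(u * u)) * dx
        L2 = _flat_quadratic_length(state)
        dh = np.roll(state.h, -1) - state.h
        phi_e = 0.5 * (phi + np.roll(phi, -1))
        e_ten = (tension_potential(L2, p, state.L_init)
                 - p.alpha_adh * (float(np.sum(phi)) * dx
                                  + float(np.sum(phi_e * dh * dh)) / (2 * dx)))
        e_spring = 0.5 * p.gamma * float(np.sum(state.h ** 2)) * dx
        ds_e = np.hypot(dx, dh)
        dphi = np.roll(phi, -1) - phi
        e_agg_s = (0.5 * p.J_bind * p.n_s * p.b_agg ** 2
                   * float(np.sum(dphi * dphi / ds_e)))
        ds_n = 0.5 * (ds_e + np.roll(ds_e, 1))
    else:
        g = geom.closed_geometry(state.nodes)
        u = g.H - p.Hbar * phi
        e_curv = 0.5 * p.kappa * float(np.sum(u * u * g.ds_node))
        phi_e = 0.5 * (phi + np.roll(phi, -1))
        e_ten = (tension_potential(g.L, p, state.L_init)
                 - p.alpha_adh * float(np.sum(phi_e * g.ds_edge)))
        e_spring = 0.0
        dphi = np.roll(phi, -1) - phi
        e_agg_s = (0.5 * p.J_bind * p.n_s * p.b_agg ** 2
                   * float(np.sum(dphi * dphi / g.ds_edge)))
        ds_n = g.ds_node
    e_agg_b = -0.5 * p.J_bind * p.n_s * float(np.sum(phi * phi * ds_n))
    e_ent = float(np.sum(_entropy_density(phi, p) * ds_n))
    return {
        "curvature": e_curv,
        "tension": e_ten,
        "spring": e_spring,
        "aggregation_surface": e_agg_s,
        "aggregation_bulk": e_agg_b,
        "entropy": e_ent,
    }


def free_energy(state: State, p: ModelParams) -> float:
    """Total free energy (k_BT), quadrature over ``dA = w ds``."""
    return p.w * sum(energy_terms(state, p).values())


# ------------------------------------------------- flat conservative forces

def _d2(arr: np.ndarray, dx: float) -> np.ndarray:
    return (np.roll(arr, -1) - 2.0 * arr + np.roll(arr, 1)) / dx ** 2


def _flat_force_curvature(state: FlatState, p: ModelParams) -> np.ndarray:
    H = geom.curvature_flat_linearized(state)
    u = H - p.Hbar * state.phi
    return -p.kappa * _d2(u, state.dx)


def _flat_force_tension(state: FlatState, p: ModelParams) -> np.ndarray:
    dx = state.dx
    H = _d2(state.h, dx)
    L2 = _flat_quadratic_length(state)
    lamL = tension_of_length(L2, p, state.L_init)
    dh = np.roll(state.h, -1) - state.h
    phi_e = 0.5 * (state.phi + np.roll(state.phi, -1))
    g_e = phi_e * dh / dx  # phi * h_x at edges
    f_adh = -p.alpha_adh * (g_e - np.roll(g_e, 1)) / dx
    return lamL * H + f_adh


def _flat_force_aggregation(state: FlatState, p: ModelParams) -> np.ndarray:
    c = 0.5 * p.J_bind * p.n_s * p.b_agg ** 2
    dx = state.dx
    dh = np.roll(state.h, -1) - state.h
    ds_e = np.hypot(dx, dh)
    dphi = np.roll(state.phi, -1) - state.phi
    t_e = dphi * dphi * dh / ds_e ** 3
    return -(c / dx) * (t_e - np.roll(t_e, 1))


# ------------------------------------------------ round conservative forces

def _round_grad_pieces(nodes: np.ndarray):
    """Per-triple analytic gradients of Menger curvature and arclength."""
    a = nodes - np.roll(nodes, 1, axis=0)  # r_i - r_{i-1}
    b = np.roll(nodes, -1, axis=0) - nodes  # r_{i+1} - r_i
    c = np.roll(nodes, -1, axis=0) - np.roll(nodes, 1, axis=0)
    la = np.hypot(a[:, 0], a[:, 1])
    lb = np.hypot(b[:, 0], b[:, 1])
    lc = np.hypot(c[:, 0], c[:, 1])
    ua, ub, uc = a / la[:, None], b / lb[:, None], c / lc[:, None]
    cr = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    den = la * lb * lc
    H = -2.0 * cr / den

    def perp(v):  # (v_y, -v_x)
        return np.column_stack([v[:, 1], -v[:, 0]])

    dcr_m1 = -perp(b)  # d(cross)/d r_{i-1}
    dcr_0 = perp(c)
    dcr_p1 = -perp(a)  # = (-a_y, a_x)
    dden_m1 = -(lb * lc)[:, None] * ua - (la * lb)[:, None] * uc
    dden_0 = (lb * lc)[:, None] * ua - (la * lc)[:, None] * ub
    dden_p1 = (la * lc)[:, None] * ub + (la * lb)[:, None] * uc
    inv = 1.0 / den
    fac = (2.0 * cr * inv * inv)
    dH_m1 = -2.0 * dcr_m1 * inv[:, None] + fac[:, None] * dden_m1
    dH_0 = -2.0 * dcr_0 * inv[:, None] + fac[:, None] * dden_0
    dH_p1 = -2.0 * dcr_p1 * inv[:, None] + fac[:, None] * dden_p1
    return H, ua, ub, la, lb, dH_m1, dH_0, dH_p1


def _scatter(g_m1, g_0, g_p1):
    """Accumulate per-triple gradients onto nodes (periodic index algebra)."""
    return (g_0 + np.roll(g_m1, -1, axis=0) + np.roll(g_p1, 1, axis=0))


def _round_force_curvature(c: ContourState, p: ModelParams) -> np.ndarray:
    g = geom.closed_geometry(c.nodes)
    H, ua, ub, la, lb, dH_m1, dH_0, dH_p1 = _round_grad_pieces(c.nodes)
    u = H - p.Hbar * c.phi
    wH = (p.kappa * u * g.ds_node)[:, None]
    we = (0.25 * p.kappa * u * u)[:, None]  # kappa/2 u^2 * d(ds_node)/dr
    grad = _scatter(wH * dH_m1 - we * ua,
                    wH * dH_0 + we * (ua - ub),
                    wH * dH_p1 + we * ub)
    return -np.einsum("ij,ij->i", grad, g.normal) / g.ds_node


def _round_force_tension(c: ContourState, p: ModelParams) -> np.ndarray:
    g = geom.closed_geometry(c.nodes)
    edges = np.roll(c.nodes, -1, axis=0) - c.nodes
    ue = edges / g.ds_edge[:, None]
    lamL = tension_of_length(g.L, p, c.L_init)
    phi_e = 0.5 * (c.phi + np.roll(c.phi, -1))
    w_e = (lamL - p.alpha_adh * phi_e)[:, None]
    grad = np.roll(w_e * ue, 1, axis=0) - w_e * ue
    return -np.einsum("ij,ij->i", grad, g.normal) / g.ds_node


def _round_force_aggregation(c: ContourState, p: ModelParams) -> np.ndarray:
    g = geom.closed_geometry(c.nodes)
    cc = 0.5 * p.J_bind * p.n_s * p.b_agg ** 2
    edges = np.roll(c.nodes, -1, axis=0) - c.nodes
    ue = edges / g.ds_edge[:, None]
    dphi = np.roll(c.phi, -1) - c.phi
    w_e = (-cc * (dphi / g.ds_edge) ** 2)[:, None]
    grad = np.roll(w_e * ue, 1, axis=0) - w_e * ue
    return -np.einsum("ij,ij->i", grad, g.normal) / g.ds_node


# ------------------------------------------------------------ public forces

def force_curvature(state: State, p: ModelParams) -> np.ndarray:
    """Curvature-mismatch restoring force (Helfrich bending with the
    protein's spontaneous curvature); flat geometry is linearized."""
    if isinstance(state, FlatState):
        return _flat_force_curvature(state, p)
    return _round_force_curvature(state, p)


def force_tension(state: State, p: ModelParams) -> np.ndarray:
    """Tension force ``(lam(L) - alpha*phi) H`` (plus the slope-gradient
    adhesion term in the flat geometry).  With adhesion the ``phi H`` part
    does not integrate to zero on a closed contour: a polarized steady
    state exerts a net force on the cell."""
    if isinstance(state, FlatState):
        return _flat_force_tension(state, p)
    return _round_force_tension(state, p)


def force_spring(state: FlatState, p: ModelParams) -> np.ndarray:
    """Harmonic pinning force ``-gamma h`` (flat geometry only)."""
    if not isinstance(state, FlatState):
        raise TypeError("the pinning spring acts only in the flat geometry")
    return -p.gamma * state.h


def force_aggregation(state: State, p: ModelParams) -> np.ndarray:
    """Shape force of the surface (gradient) aggregation energy; vanishes
    for uniform phi and for J_bind = 0."""
    if isinstance(state, FlatState):
        return _flat_force_aggregation(state, p)
    return _round_force_aggregation(state, p)


def force_actin(state: State, p: ModelParams) -> np.ndarray:
    """Actin polymerization pressure ``A_actin * phi`` along the outward
    normal; in the flat geometry the instantaneous mean coverage is
    subtracted to prevent a net drift of the membrane."""
    if isinstance(state, FlatState):
        g = geom.flat_geometry(state)
        phibar_inst = float(np.sum(state.phi * g.ds_node)) / g.L
        return p.A_actin * (state.phi - phibar_inst)
    return p.A_actin * state.phi


def force_area_pressure(c: ContourState, p: ModelParams) -> np.ndarray:
    """Global pressure restoring the projected area toward its preferred
    value: ``-K_area (A - A0)/A0`` on every node (round geometry only)."""
    if not isinstance(c, ContourState):
        raise TypeError("area pressure acts only in the round geometry")
    A = geom.signed_area(c.nodes)
    f = -p.K_area * (A - c.A_pref) / c.A_pref
    return np.full(c.N, f)


def assemble_normal_velocity(state: State, p: ModelParams
                             ) -> tuple[np.ndarray, ForceBreakdown]:
    """Total normal force per node and the resulting normal velocity
    ``v_n = f_total / xi``."""
    n = len(state.phi)
    zeros = np.zeros(n)
    if isinstance(state, FlatState):
        fb = ForceBreakdown(
            f_curv=force_curvature(state, p),
            f_tension=force_tension(state, p),
            f_spring=force_spring(state, p),
            f_agg=force_aggregation(state, p),
            f_actin=force_actin(state, p),
            f_area=zeros,
        )
    else:
        fb = ForceBreakdown(
            f_curv=force_curvature(state, p),
            f_tension=force_tension(state, p),
            f_spring=zeros,
            f_agg=force_aggregation(state, p),
            f_actin=force_actin(state, p),
            f_area=force_area_pressure(state, p),
        )
    return fb.f_total / p.xi, fb
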