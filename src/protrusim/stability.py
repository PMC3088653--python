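"""Linear stability analysis of the uniform membrane states.

The equations of motion are linearized about the uniform state (flat
membrane ``h = 0`` or the equilibrium circle) and Fourier transformed,
giving a 2x2 matrix ``M(q)`` acting on the perturbation vector
``(shape, coverage)``; its eigenvalues ``omega_-(q) <= omega_+(q)`` are the
decay/growth rates of mode ``q``.  The matrix entries are assembled from
the same force and flux expressions the simulator integrates (one source
of truth); the nonlinear simulator cross-checks them in the test suite.

Flat geometry, about ``(h=0, phi=phi_bar)`` with ``lam_eff = lam -
alpha*phi_bar``::

    M11 = -(kappa q^4 + lam_eff q^2 + gamma) / xi
    M12 = (-kappa Hbar q^2 + A_actin) / xi
    M21 = -Lambda phi_bar kappa Hbar q^4
    M22 = -q^2 (Lambda phi_bar (kappa Hbar^2 - J n_s) + D)
          - q^4 Lambda phi_bar J n_s b^2

Both eigenvalues are real for this sign structure (``M12 M21 >= 0``); one
branch is negative for every ``q > 0``.  The instability is classified
type II when the unstable band ``[q1, q2]`` is bounded away from the
smallest resolved wavevector and type I when it reaches it.

Round geometry: perturbations ``rho ~ exp(i m theta)`` of the equilibrium
circle, integer mode ``m``, tangential wavevector ``q = m / R_eq``.  The
curvature perturbation of mode m is ``(1/R^2 - q^2) rho``, so the m = 1
(translation) mode is exactly neutral; the area-preserving pressure drops
out of every ``m >= 1`` mode.  The covariant dilution term couples the
coverage equation to the shape equation at first order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .model_core import ModelParams

__all__ = [
    "DispersionResult",
    "dispersion_flat",
    "dispersion_round",
    "classify_regime",
    "critical_boundary",
    "most_unstable_mode",
    "equilibrium_round_state",
]

#: default flat-domain size used by q-grid scans (um)
DEFAULT_L = 24.0
#: default grid resolution used to bound the q-scan
DEFAULT_N = 256


@dataclass
class DispersionResult:
    """Two-branch dispersion relation and its classification."""

    q: np.ndarray
    omega_minus: np.ndarray
    omega_plus: np.ndarray
    q_max: float | None
    omega_max: float | None
    unstable_band: tuple[float, float] | None
    regime: str  # "stable" | "typeI" | "typeII"
    is_real: bool = True


def _flat_matrix(q: np.ndarray, p: ModelParams):
    q2 = q * q
    q4 = q2 * q2
    lam_eff = p.lam - p.alpha_adh * p.phi_bar
    M11 = -(p.kappa * q4 + lam_eff * q2 + p.gamma) / p.xi
    M12 = (-p.kappa * p.Hbar * q2 + p.A_actin) / p.xi
    M21 = -p.Lambda * p.phi_bar * p.kappa * p.Hbar * q4
    M22 = (-q2 * (p.Lambda * p.phi_bar * (p.kappa * p.Hbar ** 2
                                          - p.J_bind * p.n_s) + p.D)
           - q4 * p.Lambda * p.phi_bar * p.J_bind * p.n_s * p.b_agg ** 2)
    return M11, M12, M21, M22


def _eigs(M11, M12, M21, M22):
    tr = M11 + M22
    det = M11 * M22 - M12 * M21
    disc = tr * tr / 4.0 - det
    disc = np.asarray(disc, dtype=complex)
    root = np.sqrt(disc)
    om_p = tr / 2.0 + root
    om_m = tr / 2.0 - root
    return om_m, om_p


def dispersion_flat(q, p: ModelParams):
    """Eigenvalue branches ``(omega_minus, omega_plus)`` at wavevector(s) q.

    Returns real arrays when both branches are real (the generic case);
    complex arrays otherwise.
    """
    q = np.asarray(q, dtype=float)
    om_m, om_p = _eigs(*_flat_matrix(q, p))
    if np.all(np.abs(np.imag(om_p)) < 1e-14 * (1 + np.abs(om_p))):
        return np.real(om_m), np.real(om_p)
    return om_m, om_p


def _round_matrix(m: np.ndarray, p: ModelParams, R: float, phi0: float):
    q = m / R
    q2 = q * q
    H0 = -1.0 / R
    u0 = H0 - p.Hbar * phi0
    cH = 1.0 / R ** 2 - q2  # curvature perturbation per unit radial rho
    k = p.kappa
    # shape equation: xi * rho_dot = a_rho * rho + a_phi * dphi
    du_coeff = k * q2 - k * H0 ** 2 + k * H0 * u0  # multiplies delta-u
    dH_extra = -2.0 * k * H0 * u0 + 0.5 * k * u0 ** 2
    a_rho = (du_coeff + dH_extra + (p.lam - p.alpha_adh * phi0)) * cH
    # the area-preserving pressure acts only on the breathing (m=0) mode
    a_rho = a_rho - np.where(np.asarray(m) == 0,
                             p.K_area * 2 * np.pi * R / (np.pi * p.R0 ** 2),
                             0.0)
    a_phi = (-p.Hbar) * du_coeff - p.alpha_adh * H0 + p.A_actin
    M11 = a_rho / p.xi
    M12 = a_phi / p.xi
    # coverage equation: flux divergence + covariant dilution phi0*H0*rho_dot
    b_rho = p.Lambda * phi0 * k * p.Hbar * q2 * cH
    b_phi = (-q2 * (p.Lambda * phi0 * (k * p.Hbar ** 2 - p.J_bind * p.n_s)
                    + p.D)
             - q2 * q2 * p.Lambda * phi0 * p.J_bind * p.n_s * p.b_agg ** 2)
    M21 = b_rho + phi0 * H0 * M11
    M22 = b_phi + phi0 * H0 * M12
    return M11, M12, M21, M22


def dispersion_round(m, p: ModelParams,
                     equilibrium: tuple[float, float] | None = None):
    """Branches at integer mode number(s) m on the equilibrium circle.

    ``equilibrium`` is ``(R_eq, phi0)``; if omitted it is solved from the
    reference radius and mean coverage.  Mode 1 is the neutral translation
    mode (``Re omega_plus = 0`` identically).
    """
    m = np.asarray(m)
    if np.any(np.abs(m - np.round(m)) > 1e-9):
        raise ValueError("round-geometry modes must be integers")
    m = np.asarray(np.round(m), dtype=float)
    if equilibrium is None:
        M_total = p.phi_bar * 2 * np.pi * p.R0 * p.w
        equilibrium = equilibrium_round_state(p, M_total)
    R, phi0 = equilibrium
    M11, M12, M21, M22 = _round_matrix(m, p, R, phi0)
    om_m, om_p = _eigs(M11, M12, M21, M22)
    # m = 0: uniform coverage change is forbidden by mass conservation;
    # the breathing mode carries delta-phi = -phi0 * rho / R
    if np.any(np.asarray(m) == 0):
        breathing = M11 + M12 * (-phi0 / R)
        zero = np.asarray(m) == 0
        om_p = np.where(zero, breathing, om_p)
        om_m = np.where(zero, breathing, om_m)
    if np.all(np.abs(np.imag(om_p)) < 1e-12 * (1 + np.abs(om_p))):
        return np.real(om_m), np.real(om_p)
    return om_m, om_p


# ----------------------------------------------------------- classification

def _q_grid(p: ModelParams, L: float, N: int, n_pts: int = 400) -> np.ndarray:
    q_min = 2 * np.pi / L
    q_nyq = np.pi / (L / N)
    return np.geomspace(q_min, q_nyq, n_pts)


def classify_regime(p: ModelParams, L: float = DEFAULT_L, N: int = DEFAULT_N
                    ) -> DispersionResult:
    """Scan the dispersion relation and classify the uniform flat state.

    ``stable``: no growing mode.  ``typeII``: the unstable band is bounded
    away from the smallest resolved wavevector ``2 pi / L``.  ``typeI``:
    the band reaches it (long-wavelength instability).
    """
    q = _q_grid(p, L, N)
    om_m, om_p = dispersion_flat(q, p)
    re_p = np.real(om_p)
    unstable = re_p > 0
    if not np.any(unstable):
        return DispersionResult(q, om_m, om_p, None, None, None, "stable",
                                is_real=not np.iscomplexobj(om_p))
    idx = np.nonzero(unstable)[0]
    # refine band edges by bisection between grid neighbours
    def _om(qq):
        return float(np.real(dispersion_flat(np.array([qq]), p)[1][0]))

    if idx[0] == 0:
        q1 = q[0]
    else:
        q1 = brentq(_om, q[idx[0] - 1], q[idx[0]], xtol=1e-10)
    if idx[-1] == len(q) - 1:
        q2 = q[-1]
    else:
        q2 = brentq(_om, q[idx[-1]], q[idx[-1] + 1], xtol=1e-10)
    q_max, om_max = most_unstable_mode(p, L=L, N=N, _scan=(q, re_p))[:2]
    regime = "typeI" if idx[0] == 0 else "typeII"
    return DispersionResult(q, om_m, om_p, q_max, om_max, (q1, q2), regime,
                            is_real=not np.iscomplexobj(om_p))


def most_unstable_mode(p: ModelParams, L: float = DEFAULT_L,
                       N: int = DEFAULT_N, _scan=None
                       ) -> tuple[float, float, float]:
    """``(q_max, omega_max, lambda_max)`` of the fastest-growing flat mode.

    Grid scan refined by bounded golden-section search.  Raises in the
    stable regime.
    """
    if _scan is None:
        q = _q_grid(p, L, N)
        re_p = np.real(dispersion_flat(q, p)[1])
    else:
        q, re_p = _scan
    i = int(np.argmax(re_p))
    if re_p[i] <= 0:
        raise ValueError("no unstable mode: the uniform state is stable")
    lo = q[max(i - 1, 0)]
    hi = q[min(i + 1, len(q) - 1)]

    def neg(qq):
        return -float(np.real(dispersion_flat(np.array([qq]), p)[1][0]))

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    q_max = float(res.x)
    om_max = -float(res.fun)
    return q_max, om_max, 2 * np.pi / q_max


def critical_boundary(p: ModelParams, axis: str = "alpha",
                      bracket: tuple[float, float] = (0.0, 500.0),
                      L: float = DEFAULT_L, N: int = DEFAULT_N,
                      rtol: float = 1e-4) -> tuple[float, float]:
    """Critical driver value and marginal wavevector on the flat phase
    diagram.

    Bisects ``max_q Re omega_plus(q) = 0`` along ``axis`` ("alpha" for the
    adhesion strength, "A" for the actin force) with all other parameters
    fixed.  Returns ``(critical_value, q_c)``.
    """
    from dataclasses import replace

    attr = {"alpha": "alpha_adh", "A": "A_actin"}.get(axis)
    if attr is None:
        raise ValueError("axis must be 'alpha' or 'A'")

    q = _q_grid(p, L, N)

    def max_growth(v):
        pp = replace(p, **{attr: float(v)})
        return float(np.max(np.real(dispersion_flat(q, pp)[1])))

    g_lo, g_hi = max_growth(bracket[0]), max_growth(bracket[1])
    if g_lo > 0:
        raise ValueError("lower bracket is already unstable")
    if g_hi < 0:
        raise ValueError("no instability up to the upper bracket")
    v_c = brentq(max_growth, bracket[0], bracket[1],
                 rtol=rtol, xtol=rtol * max(1.0, bracket[1] * 1e-4))
    from dataclasses import replace as _r
    pp = _r(p, **{attr: float(v_c) * (1 + 10 * rtol)})
    q_c = most_unstable_mode(pp, L=L, N=N)[0]
    return float(v_c), float(q_c)


# -------------------------------------------------------- round equilibrium

def _uniform_round_force(R: float, p: ModelParams, M_total: float) -> float:
    """Net outward normal force per area on a uniform circle of radius R."""
    phi0 = M_total / (2 * np.pi * R * p.w)
    H0 = -1.0 / R
    u0 = H0 - p.Hbar * phi0
    f_curv = -p.kappa * H0 ** 2 * u0 + 0.5 * p.kappa * H0 * u0 ** 2
    f_ten = H0 * (p.lam - p.alpha_adh * phi0)
    f_act = p.A_actin * phi0
    A0 = np.pi * p.R0 ** 2
    f_area = -p.K_area * (np.pi * R * R - A0) / A0
    return f_curv + f_ten + f_act + f_area


def equilibrium_round_state(p: ModelParams, M_total: float,
                            N: int | None = None) -> tuple[float, float]:
    """Radius and coverage of the force-free uniform circle.

    Solves the uniform normal-force balance (curvature + tension + actin +
    area pressure) with the coverage tied to the circumference,
    ``phi0 = M_total / (2 pi R w)``.  With ``N`` given, the balance of the
    *discrete* forces on the regular N-gon is solved instead, so that the
    residual force of the discretized initial state vanishes to round-off.
    """
    if M_total <= 0:
        raise ValueError("M_total must be positive")

    if N is None:
        fun = lambda R: _uniform_round_force(R, p, M_total)
    else:
        from . import forces as _forces
        from .model_core import ContourState

        theta = 2 * np.pi * np.arange(N) / N

        def fun(R):
            L_poly = 2 * N * R * np.sin(np.pi / N)
            phi0 = M_total / (L_poly * p.w)
            nodes = R * np.column_stack([np.cos(theta), np.sin(theta)])
            c = ContourState(nodes=nodes, phi=np.full(N, phi0),
                             A_pref=np.pi * p.R0 ** 2,
                             L_init=L_poly)
            v, _ = _forces.assemble_normal_velocity(c, p)
            return float(v[0]) * p.xi

    # dense scan; keep only mechanically stable roots (force decreasing in R,
    # i.e. outward displacement met by a restoring inward force)
    Rs = np.geomspace(0.05 * p.R0, 20 * p.R0, 400)
    vals = np.array([fun(R) for R in Rs])
    sign = np.sign(vals)
    idx = np.nonzero((sign[:-1] > 0) & (sign[1:] < 0))[0]
    if len(idx) == 0:
        idx = np.nonzero(np.diff(sign) != 0)[0]
        if len(idx) == 0:
            raise ValueError("no equilibrium radius found in bracket")
    # among stable roots take the one closest to the reference radius
    cand = [brentq(fun, Rs[i], Rs[i + 1], xtol=1e-13, rtol=8.9e-16)
            for i in idx]
    R_eq = min(cand, key=lambda R: abs(R - p.R0))
    if N is None:
        circumference = 2 * np.pi * R_eq
    else:
        circumference = 2 * N * R_eq * np.sin(np.pi / N)
    phi0 = M_total / (circumference * p.w)
    return float(R_eq), float(phi0)
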