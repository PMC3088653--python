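"""Parameter set, state containers and seeded initial-condition generators.

The model couples a one-dimensional membrane contour (a periodic height
profile ``h(x)`` for a segment of the cell edge, or a closed polyline for a
whole spread cell) to a conserved field ``phi`` of curved membrane-protein
complexes (BAR/IMD-domain type, fractional area coverage between 0 and 1).
The proteins prefer convex membrane shape (intrinsic curvature ``Hbar < 0``
in the sign convention of :mod:`protrusim.geometry`) and recruit two kinds
of protrusive force: actin polymerization (a local outward pressure
``A_actin * phi``) and adhesion (a negative, ``phi``-proportional
contribution to the effective membrane tension).

Units are micrometres, seconds and k_BT throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ModelParams",
    "InitSpec",
    "FlatState",
    "ContourState",
    "validate_params",
    "init_flat",
    "init_round",
    "DEFAULT_N_FLAT",
    "DEFAULT_N_ROUND",
]

#: default grid resolutions (>= 20 nodes per fastest-growing wavelength at
#: the default parameters)
DEFAULT_N_FLAT = 256
DEFAULT_N_ROUND = 256


@dataclass
class ModelParams:
    """Physical constants of the membrane / membrane-protein model.

    Attributes
    ----------
    xi : float
        Effective friction coefficient of the membrane (k_BT*s/um^4): normal
        force per unit area divided by normal velocity.
    D : float
        Lateral thermal diffusion coefficient of the protein complexes
        (um^2/s).
    phi_bar : float
        Mean fractional area coverage of the proteins, in (0, 1).
    n_s : float
        Saturating (close-packed) protein density (1/um^2).
    kappa : float
        Membrane bending rigidity (k_BT).
    Hbar : float
        Intrinsic (spontaneous) curvature of the protein complex (1/um).
        Negative values are convex (protrusion-like); the instability
        requires ``Hbar < 0``.
    lam : float
        Bare membrane tension (k_BT/um^2).
    gamma : float
        Harmonic pinning spring constant (k_BT/um^4), flat geometry only.
    J_bind : float
        Direct protein-protein binding energy (k_BT).
    K_area : float
        Effective bulk modulus for the cell's projected area (k_BT/um^3),
        round geometry only.
    R0 : float
        Reference (preferred) cell radius (um).
    Lambda : float
        Protein mobility (um^4/(k_BT*s)) of the energetic fluxes; kept
        independent of D, as is conventional for this model.
    lam_nl : float
        Strain scale of the nonlinear (hardening) tension; ``0`` switches the
        hardening off.
    A_actin : float
        Actin protrusive force coefficient (k_BT/um^3 per unit phi).
    alpha_adh : float
        Adhesion strength: negative-tension proportionality (k_BT/um^2 per
        unit phi).
    w : float
        Thickness of the membrane strip represented by the contour (um);
        the area element is ``dA = w * ds``.
    temperature : float
        Thermal energy scale (k_BT units; 1 by construction).
    b_agg : float
        Interaction range of the direct binding term (um); sets the surface
        (gradient) aggregation energy.
    """

    xi: float = 100.0
    D: float = 0.2
    phi_bar: float = 0.1
    n_s: float = 10.0
    kappa: float = 100.0
    Hbar: float = -10.0
    lam: float = 1.0
    gamma: float = 0.1
    J_bind: float = 1.0
    K_area: float = 100.0
    R0: float = 3.0
    Lambda: float = 0.003
    lam_nl: float = 0.1
    A_actin: float = 0.0
    alpha_adh: float = 0.0
    w: float = 1.0
    temperature: float = 1.0
    b_agg: float = 0.1


@dataclass
class InitSpec:
    """Synthetic initial condition for the protein coverage field.

    ``uniform_random_noise`` seeds i.i.d. uniform noise in ``[-eps, +eps]``
    on top of ``phi_bar`` and then subtracts the sample mean so the mean
    coverage is exact; ``gaussian_density`` places a localized Gaussian bump
    carrying the same total protein mass.
    """

    kind: str = "uniform_random_noise"
    noise_amplitude: float | None = None  # defaults to 0.01 * phi_bar
    gaussian_center: float = 0.0  # arclength position (um) / angle for round
    gaussian_width: float = 1.0  # um
    gaussian_mass_fraction: float = 1.0  # fraction of total mass in the bump
    rng_seed: int = 0

    def resolve_eps(self, p: ModelParams) -> float:
        eps = self.noise_amplitude
        if eps is None:
            eps = 0.01 * p.phi_bar
        return float(eps)


@dataclass
class FlatState:
    """Membrane segment in the Monge representation (periodic in x)."""

    x: np.ndarray  # uniform grid positions (um)
    h: np.ndarray  # height deviation (um)
    phi: np.ndarray  # fractional coverage
    t: float = 0.0
    L_init: float = 0.0  # reference contour length for the nonlinear tension

    @property
    def N(self) -> int:
        return len(self.x)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def L_domain(self) -> float:
        return float(self.N * self.dx)

    def copy(self) -> "FlatState":
        return FlatState(self.x.copy(), self.h.copy(), self.phi.copy(),
                         self.t, self.L_init)

    def validate(self) -> None:
        if not (len(self.x) == len(self.h) == len(self.phi)):
            raise ValueError("x, h, phi must have equal length")
        if np.any(self.phi < -1e-12) or np.any(self.phi > 1 + 1e-12):
            raise ValueError("phi out of [0, 1]")


@dataclass
class ContourState:
    """Closed cell contour: counterclockwise polyline plus coverage field."""

    nodes: np.ndarray  # (N, 2) positions (um), counterclockwise
    phi: np.ndarray  # fractional coverage per node
    t: float = 0.0
    A_pref: float = 0.0  # preferred projected area (um^2)
    M_total: float = 0.0  # total protein mass  sum(phi * w * ds)
    L_init: float = 0.0  # reference contour length for the nonlinear tension

    @property
    def N(self) -> int:
        return len(self.phi)

    def copy(self) -> "ContourState":
        return ContourState(self.nodes.copy(), self.phi.copy(), self.t,
                            self.A_pref, self.M_total, self.L_init)

    def validate(self) -> None:
        from . import geometry  # local import to avoid a cycle

        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise ValueError("nodes must be an (N, 2) array")
        if len(self.nodes) != len(self.phi):
            raise ValueError("nodes and phi must have equal length")
        if geometry.signed_area(self.nodes) <= 0:
            raise ValueError("contour must be counterclockwise (signed area > 0)")
        if not geometry.is_simple(self.nodes):
            raise ValueError("contour is self-intersecting")
        if np.any(self.phi < -1e-12) or np.any(self.phi > 1 + 1e-12):
            raise ValueError("phi out of [0, 1]")


def validate_params(p: ModelParams) -> ModelParams:
    """Range-check a parameter set; returns it unchanged if valid.

    ``Hbar >= 0`` is legal but emits a warning: the curvature feedback that
    drives the protrusion instability requires convex (negative intrinsic
    curvature) proteins.
    """
    for name in ("xi", "kappa", "n_s", "w", "temperature"):
        if getattr(p, name) <= 0:
            raise ValueError(f"{name} must be positive, got {getattr(p, name)}")
    for name in ("D", "Lambda", "lam_nl", "K_area", "gamma", "A_actin",
                 "alpha_adh", "J_bind", "b_agg"):
        if getattr(p, name) < 0:
            raise ValueError(f"{name} must be non-negative, got {getattr(p, name)}")
    if not (0.0 < p.phi_bar < 1.0):
        raise ValueError(f"phi_bar must lie in (0, 1), got {p.phi_bar}")
    if p.lam < 0:
        raise ValueError(f"lam must be non-negative, got {p.lam}")
    if p.R0 <= 0:
        raise ValueError(f"R0 must be positive, got {p.R0}")
    if p.Hbar >= 0:
        warnings.warn(
            "Hbar >= 0: instability requires convex membrane proteins "
            "(Hbar < 0); the uniform state will be linearly stable.",
            UserWarning, stacklevel=2)
    return p


def _phi_field(p: ModelParams, spec: InitSpec, s_nodes: np.ndarray,
               ds: np.ndarray, L: float) -> np.ndarray:
    """Generate the initial coverage field on arclength positions s_nodes.

    Mass is fixed at phi_bar * L (per unit strip width) for either kind.
    """
    eps = spec.resolve_eps(p)
    if eps < 0:
        raise ValueError("noise amplitude must be non-negative")
    rng = np.random.default_rng(spec.rng_seed)
    if spec.kind == "uniform_random_noise":
        if eps > p.phi_bar:
            raise ValueError("noise amplitude must not exceed phi_bar")
        noise = rng.uniform(-eps, eps, size=len(s_nodes))
        # mean correction in the mass sense, then exact amplitude bound kept
        noise -= np.sum(noise * ds) / L
        phi = p.phi_bar + noise
    elif spec.kind == "gaussian_density":
        # periodic Gaussian bump carrying gaussian_mass_fraction of the mass
        width = spec.gaussian_width
        d = np.abs(s_nodes - spec.gaussian_center)
        d = np.minimum(d, L - d)
        bump = np.exp(-0.5 * (d / width) ** 2)
        bump_mass = np.sum(bump * ds)
        M = p.phi_bar * L
        f = spec.gaussian_mass_fraction
        phi = (1.0 - f) * p.phi_bar + f * M * bump / bump_mass
        if np.any(phi > 1.0):
            raise ValueError(
                "gaussian initial condition exceeds phi = 1; widen the bump "
                "or lower gaussian_mass_fraction")
    else:
        raise ValueError(f"unknown init kind {spec.kind!r}")
    phi = np.clip(phi, 0.0, 1.0)
    return phi


def init_flat(p: ModelParams, N: int, L: float,
              spec: InitSpec | None = None) -> FlatState:
    """Uniform flat membrane with a seeded perturbation of ``phi`` only.

    The height field starts identically zero (the noise perturbs the protein
    distribution, not the shape).
    """
    validate_params(p)
    if N < 16:
        raise ValueError("N must be >= 16")
    if L <= 0:
        raise ValueError("L must be positive")
    spec = spec or InitSpec()
    dx = L / N
    x = np.arange(N) * dx
    ds = np.full(N, dx)
    phi = _phi_field(p, spec, x, ds, L)
    return FlatState(x=x, h=np.zeros(N), phi=phi, t=0.0, L_init=L)


def init_round(p: ModelParams, N: int,
               spec: InitSpec | None = None) -> ContourState:
    """Equilibrium circle with a seeded perturbation of ``phi`` only.

    The radius solves the uniform normal-force balance (curvature + tension
    + actin + area pressure) at coverage ``phi_bar``; see
    :func:`protrusim.stability.equilibrium_round_state`.
    """
    from . import stability  # local import to avoid a cycle

    validate_params(p)
    if N < 32:
        raise ValueError("N must be >= 32")
    spec = spec or InitSpec()
    M_total = p.phi_bar * 2.0 * np.pi * p.R0 * p.w
    # discrete (N-gon) balance: the generated state carries ~zero residual force
    R_eq, phi0 = stability.equilibrium_round_state(p, M_total, N=N)
    theta = 2.0 * np.pi * np.arange(N) / N
    nodes = R_eq * np.column_stack([np.cos(theta), np.sin(theta)])
    L = 2.0 * N * R_eq * np.sin(np.pi / N)  # polygon perimeter
    s = np.arange(N) * (L / N)
    ds = np.full(N, L / N)
    # phi field carries coverage phi0 on the equilibrium circumference
    p_eff = replace(p, phi_bar=phi0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        phi = _phi_field(p_eff, spec, s, ds, L)
    state = ContourState(nodes=nodes, phi=phi, t=0.0,
                         A_pref=np.pi * p.R0 ** 2,
                         M_total=float(np.sum(phi * ds) * p.w),
                         L_init=L)
    state.validate()
    return state
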