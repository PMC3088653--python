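"""Quantitative observables: protrusion counting, coalescence dynamics,
force balance, morphology scans and the cortical-actin layer profile.

After the linear instability saturates, the membrane undulations evolve by
coalescence: protrusions merge into progressively fewer, larger features
until a single one remains.  The time of the final merger is the
coalescence time ``tau_c``; at strong driving it scales as the inverse of
the fastest linear growth rate, while close to the critical line it
diverges faster (the nonlinear tension stalls the cascade).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import dynamics, geometry as geom, stability
from .model_core import ContourState, FlatState, InitSpec, ModelParams, \
    init_flat, init_round

__all__ = [
    "ActinLayerParams",
    "count_protrusions",
    "coalescence_time",
    "coalescence_scan",
    "protrusion_count_vs_driver",
    "net_active_force",
    "crescent_scan",
    "steady_state_density_curvature_check",
    "actin_layer_thickness",
]


@dataclass
class ActinLayerParams:
    """Cortical actin layer behind the leading edge.

    Filaments nucleated at the membrane treadmill inward with velocity ``v``
    and depolymerize at constant rate ``k_d``; their number decays as
    ``n0 * exp(-k_d d / v)`` with distance ``d`` from the membrane.
    """

    k_d: float  # severing/depolymerization rate (1/s)
    v: float  # treadmilling velocity (um/s)
    n0: float  # filament density at the membrane
    n_th: float  # detection threshold

    def __post_init__(self):
        if self.k_d <= 0 or self.v <= 0 or self.n0 <= 0 or self.n_th <= 0:
            raise ValueError("all actin-layer parameters must be positive")
        if self.n_th > self.n0:
            raise ValueError("detection threshold exceeds membrane density")


def actin_layer_thickness(alp: ActinLayerParams) -> float:
    """Visible layer thickness ``d = (v / k_d) ln(n0 / n_th)`` (um)."""
    return alp.v / alp.k_d * float(np.log(alp.n0 / alp.n_th))


# -------------------------------------------------------------- counting

def _amplitude_of(shape) -> np.ndarray:
    if isinstance(shape, np.ndarray):
        return shape - float(np.mean(shape))
    return dynamics._amplitude_profile(shape)


def count_protrusions(shape, threshold_fraction: float = 0.1,
                      noise_floor: float = 0.02) -> int:
    """Number of protrusions: local maxima of the amplitude above the mean
    shape whose height is at least ``threshold_fraction`` of the global
    maximum (periodic-aware); 0 when the global maximum is below
    ``noise_floor``."""
    a = _amplitude_of(shape)
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 nodes to count protrusions")
    a_max = float(np.max(a))
    if a_max < noise_floor:
        return 0
    thr = threshold_fraction * a_max
    left = np.roll(a, 1)
    right = np.roll(a, -1)
    # plateau-safe: a strict rise on the left, non-rise on the right
    peaks = (a > left) & (a >= right) & (a >= thr)
    count = int(np.sum(peaks))
    if count == 0:
        # a perfectly flat profile at the maximum (degenerate); count one
        count = 1 if a_max >= noise_floor else 0
    return count


# ------------------------------------------------------------ coalescence

def coalescence_time(summary: dynamics.TrajectorySummary):
    """First time the protrusion count reaches 1 and stays 1 through the
    end of the run, confirmed either by the steady-state detector or by a
    persistent-count termination; ``None`` if the run never coalesces."""
    counts = np.asarray(summary.n_protrusions)
    if not (summary.steady or summary.termination == "count_persistent"):
        return None
    if counts[-1] != 1:
        return None
    ones = counts == 1
    # last index where the count was not 1
    not_one = np.nonzero(~ones)[0]
    j = 0 if len(not_one) == 0 else not_one[-1] + 1
    return float(summary.times[j])


def _flat_run(p: ModelParams, seed: int, L: float, N: int,
              cfg: dynamics.RunConfig):
    state0 = init_flat(p, N, L, InitSpec(rng_seed=seed))
    return dynamics.run(state0, p, cfg)


def coalescence_scan(p: ModelParams, driver_values, driver: str = "alpha_adh",
                     seeds=(0, 1, 2), L: float = 40.0, N: int = 128,
                     t_max: float = 20000.0, snapshot_dt: float = 5.0):
    """Coalescence time versus fastest growth rate along a driver axis.

    For each driver value the flat system is simulated from seeded noise
    (median ``tau_c`` over the seeds) and paired with ``omega_max`` from the
    dispersion relation.  A log-log line is fitted over the large-omega_max
    half of the points; an inverse relation gives slope -1.  Returns
    ``(table, fit)`` where ``fit`` is ``(slope, intercept)`` or ``None``
    when fewer than 3 points are available for the fit.
    """
    import pandas as pd

    rows = []
    for val in driver_values:
        pp = replace(p, **{driver: float(val)})
        q_max, om_max, lam_max = stability.most_unstable_mode(pp, L=L)
        taus = []
        for seed in seeds:
            cfg = dynamics.RunConfig(t_end=t_max, snapshot_dt=snapshot_dt,
                                     store_snapshots=False, steady_count=1,
                                     steady_tol=1e-3,
                                     count_persist_time=600.0,
                                     min_steady_time=5.0 / om_max)
            summary, _ = _flat_run(pp, seed, L, N, cfg)
            tau = coalescence_time(summary)
            if tau is None:
                warnings.warn(f"{driver}={val}: run (seed {seed}) did not "
                              "coalesce to a single protrusion; excluded",
                              UserWarning, stacklevel=2)
            else:
                taus.append(tau)
        rows.append((float(val), om_max,
                     float(np.median(taus)) if taus else np.nan))
    table = pd.DataFrame(rows, columns=[driver, "omega_max", "tau_c"])
    good = table.dropna()
    fit = None
    if len(good) >= 3:
        # fit over the large-omega_max half (at least 3 points)
        k = max(3, len(good) // 2)
        sel = good.nlargest(k, "omega_max")
        slope, intercept = np.polyfit(np.log(sel["omega_max"]),
                                      np.log(sel["tau_c"]), 1)
        fit = (float(slope), float(intercept))
    return table, fit


def protrusion_count_vs_driver(p: ModelParams, driver_values, T_cell: float,
                               driver: str = "alpha_adh", seed: int = 0,
                               L: float = 40.0, N: int = 128):
    """Protrusion count at the cellular time scale ``T_cell``.

    Below the critical driver the count is 0; just above it the coalescence
    is slower than ``T_cell`` and the count is maximal (set by the fastest
    wavelength); at strong driving everything has merged into one.
    """
    import pandas as pd

    if T_cell <= 0:
        raise ValueError("T_cell must be positive")
    rows = []
    for val in driver_values:
        pp = replace(p, **{driver: float(val)})
        cfg = dynamics.RunConfig(t_end=T_cell, store_snapshots=True,
                                 snapshot_dt=max(T_cell / 200.0, 1.0))
        summary, snaps = _flat_run(pp, seed, L, N, cfg)
        rows.append((float(val), int(summary.n_protrusions[-1])))
    return pd.DataFrame(rows, columns=[driver, "count"])


# ------------------------------------------------------------ force balance

def net_active_force(c: ContourState, p: ModelParams):
    """Vector sum of the active normal forces (actin pressure plus the
    adhesion part of the tension force) over the closed contour.

    Returns ``((Fx, Fy), normalized_magnitude)`` with the magnitude
    normalized by the integral of |force|.  At an actin-driven steady state
    the sum vanishes (the force is slaved to the curvature, whose vector
    integral is zero on a closed contour); an adhesion-driven steady state
    keeps a finite polar force and the cell drifts.
    """
    if not isinstance(c, ContourState):
        raise TypeError("net_active_force requires the round geometry")
    g = geom.closed_geometry(c.nodes)
    f_actin = p.A_actin * c.phi
    # adhesion part of the tension force: gradient of -alpha*phi*ds term
    edges = np.roll(c.nodes, -1, axis=0) - c.nodes
    ue = edges / g.ds_edge[:, None]
    phi_e = 0.5 * (c.phi + np.roll(c.phi, -1))
    w_e = (-p.alpha_adh * phi_e)[:, None]
    grad = np.roll(w_e * ue, 1, axis=0) - w_e * ue
    f_adh = -np.einsum("ij,ij->i", grad, g.normal) / g.ds_node
    f = f_actin + f_adh
    weights = (p.w * g.ds_node)[:, None]
    F = np.sum(f[:, None] * g.normal * weights, axis=0)
    norm = float(np.sum(np.abs(f) * p.w * g.ds_node))
    mag = float(np.hypot(F[0], F[1])) / max(norm, 1e-300)
    return (float(F[0]), float(F[1])), mag


# -------------------------------------------------------------- morphology

def crescent_scan(p: ModelParams, A_values, seed: int = 0, N: int = 128,
                  t_end: float = 3000.0, dip_threshold: float = 0.35):
    """Steady-shape classification of the actin-driven round cell.

    With adhesion off, increasing the actin force parameter switches the
    steady state abruptly from a circular shape with a small concave dip to
    a crescent; the membrane proteins are strongly depleted in the dip.
    Returns a table ``(A, shape_class, dip_depth, min_phi_dip)``.
    """
    import pandas as pd

    rows = []
    for A in A_values:
        pp = replace(p, A_actin=float(A), alpha_adh=0.0)
        state0 = init_round(pp, N, InitSpec(rng_seed=seed))
        cfg = dynamics.RunConfig(t_end=t_end, store_snapshots=True,
                                 snapshot_dt=2.0, min_steady_time=20.0)
        summary, snaps = dynamics.run(state0, pp, cfg)
        final = snaps[-1]
        cen = dynamics._centroid(final)
        r = np.hypot(final.nodes[:, 0] - cen[0], final.nodes[:, 1] - cen[1])
        r_mean = float(np.mean(r))
        dip_depth = float((r_mean - np.min(r)) / r_mean)
        dip_nodes = r < r_mean
        # contiguous dip region around the deepest node
        i0 = int(np.argmin(r))
        mask = np.zeros(len(r), bool)
        j = i0
        while dip_nodes[j]:
            mask[j] = True
            j = (j + 1) % len(r)
            if j == i0:
                break
        j = (i0 - 1) % len(r)
        while dip_nodes[j] and not mask[j]:
            mask[j] = True
            j = (j - 1) % len(r)
        min_phi = float(np.min(final.phi[mask])) if mask.any() \
            else float(np.min(final.phi))
        cls = "crescent" if dip_depth > dip_threshold else \
            ("circular_with_dip" if dip_depth > 0.02 else "circular")
        rows.append((float(A), cls, dip_depth, min_phi))
    return pd.DataFrame(rows, columns=["A", "shape_class", "dip_depth",
                                       "min_phi_dip"])


def steady_state_density_curvature_check(state, p: ModelParams, *,
                                         steady: bool = True):
    """Steady-state current balance and coverage-curvature correlation.

    At steady state the dominant currents (curvature attraction vs
    bending-resistance dispersion) balance, which makes the coverage follow
    the membrane curvature, ``phi ~ H / Hbar + const``.  Returns
    ``(residual, rank_correlation)`` where the residual is
    ``max|J_curv + J_disp|`` normalized by the largest individual current
    and the correlation is Spearman's between ``phi`` and ``-H``.
    """
    from scipy.stats import spearmanr

    from . import transport

    if not steady:
        raise ValueError("density/curvature balance requires a steady state")
    fluxes = transport.total_flux(state, p)
    scale = max(float(np.max(np.abs(fluxes.J_curv))),
                float(np.max(np.abs(fluxes.J_disp))))
    if scale < 1e-8:  # uniform state: both currents vanish identically
        residual = 0.0
    else:
        residual = float(np.max(np.abs(fluxes.J_curv + fluxes.J_disp))) \
            / scale
    if isinstance(state, FlatState):
        H = geom.curvature_flat_linearized(state)
    else:
        H = geom.curvature_closed(state)
    if np.ptp(state.phi) < 1e-14 or np.ptp(H) < 1e-14:
        return residual, float("nan")  # correlation undefined on uniform data
    rho = float(spearmanr(state.phi, -H).statistic)
    return residual, rho
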