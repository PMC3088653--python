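"""Time integration of the coupled shape / coverage system.

The reference scheme is explicit Euler on the equations of motion
``xi * v_n = f_total`` and the covariant conservation law for the coverage
field.  The coverage update is finite-volume (per-node conserved mass), so
total protein number is conserved to round-off over arbitrarily long runs,
including through the occasional arclength re-discretization of the round
contour.  A positivity guard sub-steps (halving dt down to a floor) when a
step would take the coverage out of [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import geometry as geom
from .model_core import ContourState, FlatState, ModelParams

__all__ = [
    "RunConfig",
    "TrajectorySummary",
    "stable_dt_bound",
    "step",
    "run",
    "detect_steady_state",
]


@dataclass
class RunConfig:
    """Simulation-control knobs (all times in seconds)."""

    t_end: float = 1000.0
    dt: Optional[float] = None  # None: auto from stable_dt_bound
    safety: float = 0.1  # explicit-scheme safety factor C
    snapshot_dt: float = 5.0  # time between recorded samples
    resample_every: int = 200  # steps between resampling checks (round)
    resample_ratio: float = 1.5  # max/min ds triggering resampling
    steady_tol: float = 1e-4
    steady_window_frac: float = 0.05  # window as fraction of elapsed time
    stop_at_steady: bool = True
    min_steady_time: float = 0.0  # do not declare steady before this time
    steady_count: int | None = None  # only stop steady at this count
    count_persist_time: float | None = None  # stop when the count has held
    #   steady_count for this long (coalescence-time runs)
    count_threshold: float = 0.1  # protrusion-counting threshold fraction
    count_floor: float = 0.02  # absolute amplitude floor (um)
    store_snapshots: bool = True


@dataclass
class TrajectorySummary:
    """Time series of the scalar observables of a run."""

    times: np.ndarray
    max_amplitude: np.ndarray
    n_protrusions: np.ndarray
    net_force: np.ndarray
    centroid: np.ndarray  # (n, 2); zeros in the flat geometry
    L: np.ndarray
    A_enc: np.ndarray
    M_total: np.ndarray
    steady: bool = False
    t_steady: Optional[float] = None
    termination: str = "t_end"

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.times,
            "max_amplitude": self.max_amplitude,
            "n_protrusions": self.n_protrusions,
            "net_force": self.net_force,
            "centroid_x": self.centroid[:, 0],
            "centroid_y": self.centroid[:, 1],
            "L": self.L,
            "A_enc": self.A_enc,
            "M_total": self.M_total,
        })


# ------------------------------------------------------------------- dt

def stable_dt_bound(state, p: ModelParams, safety: float = 0.1) -> float:
    """Explicit-Euler step bound ``C * min(xi ds^4/kappa, ds^2/D,
    ds^2/(Lambda kappa Hbar^2))`` with safety factor ``C``.

    The first term is the bending stiffness limit (the binding one at the
    default parameters), the others the diffusive limits of the coverage
    fluxes evaluated at full coverage.
    """
    if isinstance(state, FlatState):
        ds_min = state.dx
    else:
        ds_min = float(geom.closed_geometry(state.nodes).ds_edge.min())
    bounds = [p.xi * ds_min ** 4 / p.kappa]
    if p.D > 0:
        bounds.append(ds_min ** 2 / p.D)
    transport = p.Lambda * p.kappa * p.Hbar ** 2
    if transport > 0:
        bounds.append(ds_min ** 2 / transport)
    return safety * min(bounds)


# ------------------------------------------------------------------ step

def _apply_euler(state, p: ModelParams, dt: float):
    """One candidate Euler update via the numpy force/flux path."""
    from . import forces, transport

    v, fb = forces.assemble_normal_velocity(state, p)
    if isinstance(state, FlatState):
        g = geom.flat_geometry(state)
    else:
        g = geom.closed_geometry(state.nodes)
    mass = state.phi * g.ds_node
    J = transport.total_flux(state, p).J_total
    mass_new = mass + dt * (np.roll(J, 1) - J)
    new = state.copy()
    if isinstance(state, FlatState):
        new.h = state.h + dt * v
        g_new = geom.flat_geometry(new)
    else:
        new.nodes = state.nodes + dt * v[:, None] * g.normal
        g_new = geom.closed_geometry(new.nodes)
    new.phi = mass_new / g_new.ds_node
    new.t = state.t + dt
    return new, fb


def step(state, p: ModelParams, dt: float, _depth: int = 12):
    """One explicit Euler step; sub-steps recursively if the coverage
    would leave [0, 1] (halving dt, at most ``_depth`` times)."""
    new, _ = _apply_euler(state, p, dt)
    if not (np.all(np.isfinite(new.phi))
            and (np.all(np.isfinite(new.h)) if isinstance(new, FlatState)
                 else np.all(np.isfinite(new.nodes)))):
        raise FloatingPointError("non-finite state after Euler step")
    if np.any(new.phi < 0.0) or np.any(new.phi > 1.0):
        if _depth <= 0:
            raise RuntimeError(
                "coverage guard exhausted: dt cannot be reduced further")
        half = step(state, p, 0.5 * dt, _depth - 1)
        return step(half, p, 0.5 * dt, _depth - 1)
    return new


# ----------------------------------------------------------- observables

def _amplitude_profile(state) -> np.ndarray:
    if isinstance(state, FlatState):
        return state.h - float(np.mean(state.h))
    centroid = _centroid(state)
    r = np.hypot(state.nodes[:, 0] - centroid[0],
                 state.nodes[:, 1] - centroid[1])
    return r - float(np.mean(r))


def _centroid(state) -> np.ndarray:
    if isinstance(state, FlatState):
        return np.zeros(2)
    g = geom.closed_geometry(state.nodes)
    w = g.ds_node / g.L
    return np.array([float(np.sum(state.nodes[:, 0] * w)),
                     float(np.sum(state.nodes[:, 1] * w))])


def _observe(state, p: ModelParams, cfg: RunConfig):
    from .analysis import count_protrusions, net_active_force

    amp = _amplitude_profile(state)
    a_max = float(np.max(amp))
    n_pro = count_protrusions(state, cfg.count_threshold,
                              noise_floor=cfg.count_floor)
    if isinstance(state, FlatState):
        g = geom.flat_geometry(state)
        nf = 0.0
        cen = np.zeros(2)
        A_enc = 0.0
    else:
        g = geom.closed_geometry(state.nodes)
        nf = float(np.hypot(*net_active_force(state, p)[0]))
        cen = _centroid(state)
        A_enc = g.A_enc
    M = float(np.sum(state.phi * g.ds_node) * p.w)
    return a_max, n_pro, nf, cen, g.L, A_enc, M


# -------------------------------------------------------- steady detection

def detect_steady_state(times: np.ndarray, amps: np.ndarray,
                        counts: np.ndarray, tol: float = 1e-4,
                        window_frac: float = 0.05
                        ) -> tuple[bool, Optional[float]]:
    """Steady when the relative change of the maximum amplitude over the
    trailing window (a fraction of the elapsed time) is below ``tol`` and
    the protrusion count has not changed over that window."""
    if len(times) < 3:
        return False, None
    t_now = times[-1]
    window = max(window_frac * t_now, times[-1] - times[-3])
    j = int(np.searchsorted(times, t_now - window))
    if j >= len(times) - 1:
        return False, None
    a_ref = max(abs(amps[-1]), 1e-12)
    if np.max(np.abs(amps[j:] - amps[-1])) / a_ref > tol:
        return False, None
    if np.any(counts[j:] != counts[-1]):
        return False, None
    return True, float(times[j])


# -------------------------------------------------------------------- run

def _kernel_params_flat(p: ModelParams):
    return (p.xi, p.D, p.kappa, p.Hbar, p.lam, p.gamma,
            p.J_bind * p.n_s, p.b_agg ** 2, p.A_actin, p.alpha_adh,
            p.lam_nl, p.Lambda)


def _kernel_params_round(p: ModelParams, A0: float):
    return (p.xi, p.D, p.kappa, p.Hbar, p.lam, p.K_area,
            p.J_bind * p.n_s, p.b_agg ** 2, p.A_actin, p.alpha_adh,
            p.lam_nl, p.Lambda)


def run(state0, p: ModelParams, cfg: RunConfig
        ) -> tuple[TrajectorySummary, list]:
    """Integrate to ``t_end`` or steady state.

    Returns the trajectory summary and (optionally) the recorded snapshot
    states.  The flat geometry keeps periodic boundary conditions and the
    mean-subtracted actin force; the round geometry applies the resampling
    policy and is checked for self-intersection at every observation.
    """
    from ._kernels import flat_steps, round_steps

    state = state0.copy()
    flat = isinstance(state, FlatState)
    dt = cfg.dt or stable_dt_bound(state, p, cfg.safety)

    rows = []
    snaps = []
    termination = "t_end"
    t = state.t
    t_stop = state.t + cfg.t_end

    def record():
        a_max, n_pro, nf, cen, L, A_enc, M = _observe(state, p, cfg)
        rows.append((state.t, a_max, n_pro, nf, cen[0], cen[1], L, A_enc, M))
        if cfg.store_snapshots:
            snaps.append(state.copy())

    record()
    guard_budget = 200  # sporadic positivity-guard events allowed per run
    while t < t_stop - 1e-12:
        t_next = min(t + cfg.snapshot_dt, t_stop)
        while t < t_next - 1e-12:
            # flat geometry never resamples: one kernel call per snapshot
            cap = 10 ** 9 if flat else cfg.resample_every
            n_chunk = int(min(np.ceil((t_next - t) / dt), cap))
            n_chunk = max(n_chunk, 1)
            if flat:
                g0 = geom.flat_geometry(state)
                m = state.phi * g0.ds_node
                done, status = flat_steps(state.h, m, n_chunk, dt, state.dx,
                                          state.L_init,
                                          *_kernel_params_flat(p))
                t = state.t = state.t + done * dt
                state.phi = m / geom.flat_geometry(state).ds_node
            else:
                g0 = geom.closed_geometry(state.nodes)
                m = state.phi * g0.ds_node
                xarr = np.ascontiguousarray(state.nodes[:, 0])
                yarr = np.ascontiguousarray(state.nodes[:, 1])
                done, status = round_steps(
                    xarr, yarr, m, n_chunk, dt, state.L_init, state.A_pref,
                    *_kernel_params_round(p, state.A_pref))
                state.nodes = np.column_stack([xarr, yarr])
                t = state.t = state.t + done * dt
                state.phi = m / geom.closed_geometry(state.nodes).ds_node
            if status == 2:
                raise FloatingPointError(
                    "simulation diverged (non-finite state)")
            if status == 1:
                # positivity guard: advance a few sub-steps at reduced dt
                if guard_budget <= 0:
                    raise RuntimeError("coverage guard exhausted")
                guard_budget -= 1
                for _ in range(2):
                    state = step(state, p, 0.5 * dt)
                t = state.t
            if not flat:
                # resampling: every cfg.resample_every steps at most, fired
                # by the node-spacing ratio
                g = geom.closed_geometry(state.nodes)
                if g.ds_edge.max() / g.ds_edge.min() > cfg.resample_ratio:
                    state = geom.resample_contour(state)
                    dt = cfg.dt or stable_dt_bound(state, p, cfg.safety)
        if not flat and not geom.is_simple(state.nodes):
            raise RuntimeError("contour self-intersected during the run")
        record()
        if (cfg.count_persist_time is not None
                and cfg.steady_count is not None):
            arr = np.asarray(rows, dtype=float)
            cnt = arr[:, 2].astype(int)
            if cnt[-1] == cfg.steady_count:
                not_tgt = np.nonzero(cnt != cfg.steady_count)[0]
                j = 0 if len(not_tgt) == 0 else not_tgt[-1] + 1
                held = arr[-1, 0] - arr[j, 0]
                if held >= cfg.count_persist_time and arr[j, 0] > 0:
                    termination = "count_persistent"
                    break
        if cfg.stop_at_steady and state.t >= cfg.min_steady_time:
            arr = np.asarray(rows, dtype=float)
            ok, t_ss = detect_steady_state(arr[:, 0], arr[:, 1],
                                           arr[:, 2].astype(int),
                                           cfg.steady_tol,
                                           cfg.steady_window_frac)
            if ok and (cfg.steady_count is None
                       or rows[-1][2] == cfg.steady_count):
                termination = "steady_state"
                break

    arr = np.asarray(rows, dtype=float)
    steady, t_ss = detect_steady_state(arr[:, 0], arr[:, 1],
                                       arr[:, 2].astype(int),
                                       cfg.steady_tol,
                                       cfg.steady_window_frac)
    summary = TrajectorySummary(
        times=arr[:, 0], max_amplitude=arr[:, 1],
        n_protrusions=arr[:, 2].astype(int), net_force=arr[:, 3],
        centroid=arr[:, 4:6], L=arr[:, 6], A_enc=arr[:, 7], M_total=arr[:, 8],
        steady=steady, t_steady=t_ss, termination=termination)
    return summary, snaps
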