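"""Discrete differential geometry of the evolving contour.

Sign convention
---------------
The mean curvature ``H`` of a counterclockwise circle of radius ``R`` is
``-1/R``; outward bulges (cellular protrusions) therefore have ``H`` of the
same sign as the convex protein curvature ``Hbar < 0``.  In the flat (Monge)
geometry the linearized curvature is ``H = d^2h/dx^2``, so a peak also has
``H < 0``.  All force and flux expressions in the package are written under
this one convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .model_core import ContourState, FlatState

__all__ = [
    "GeometryCache",
    "flat_geometry",
    "closed_geometry",
    "curvature_closed",
    "curvature_flat_linearized",
    "enclosed_area",
    "signed_area",
    "is_simple",
    "resample_contour",
    "transfer_density",
]


@dataclass
class GeometryCache:
    """Per-node metric quantities of a contour (or flat segment)."""

    ds_edge: np.ndarray  # edge i connects node i to i+1 (periodic)
    ds_node: np.ndarray  # dual cell length around each node
    tangent: np.ndarray  # (N, 2) unit tangents (round only; None-like for flat)
    normal: np.ndarray  # (N, 2) outward unit normals (round only)
    H: np.ndarray  # mean curvature per node (sign convention above)
    L: float  # total contour length
    A_enc: float  # enclosed area (round; 0 for flat)


def signed_area(nodes: np.ndarray) -> float:
    """Shoelace signed area; positive for counterclockwise orientation."""
    x, y = nodes[:, 0], nodes[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def is_simple(nodes: np.ndarray) -> bool:
    """True when the closed polyline has no self-intersection."""
    from shapely.geometry import LinearRing

    if len(nodes) < 3:
        return False
    try:
        return LinearRing(nodes).is_simple
    except Exception:
        return False


def enclosed_area(c: ContourState) -> float:
    """Positive (shoelace) area enclosed by a simple counterclockwise contour."""
    area = signed_area(c.nodes)
    if area <= 0:
        raise ValueError("contour is not counterclockwise")
    if not is_simple(c.nodes):
        raise ValueError("contour is self-intersecting")
    return area


def _menger_curvature(nodes: np.ndarray) -> np.ndarray:
    """Signed curvature from the circumscribed circle of node triples.

    Returns H with the package convention (counterclockwise circle: -1/R).
    """
    prev = np.roll(nodes, 1, axis=0)
    nxt = np.roll(nodes, -1, axis=0)
    a = nodes - prev
    b = nxt - nodes
    c = nxt - prev
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    la = np.hypot(a[:, 0], a[:, 1])
    lb = np.hypot(b[:, 0], b[:, 1])
    lc = np.hypot(c[:, 0], c[:, 1])
    denom = la * lb * lc
    if np.any(denom == 0):
        raise ValueError("duplicate or coincident nodes on the contour")
    return -2.0 * cross / denom


def closed_geometry(nodes: np.ndarray) -> GeometryCache:
    """Arclength elements, outward normals and curvature of a closed polyline."""
    edges = np.roll(nodes, -1, axis=0) - nodes
    ds_edge = np.hypot(edges[:, 0], edges[:, 1])
    if np.any(ds_edge == 0):
        raise ValueError("duplicate or coincident nodes on the contour")
    ds_node = 0.5 * (ds_edge + np.roll(ds_edge, 1))
    chord = np.roll(nodes, -1, axis=0) - np.roll(nodes, 1, axis=0)
    tangent = chord / np.hypot(chord[:, 0], chord[:, 1])[:, None]
    # rotate tangent by -90 deg: outward normal for a counterclockwise contour
    normal = np.column_stack([tangent[:, 1], -tangent[:, 0]])
    H = _menger_curvature(nodes)
    return GeometryCache(ds_edge=ds_edge, ds_node=ds_node, tangent=tangent,
                         normal=normal, H=H, L=float(ds_edge.sum()),
                         A_enc=signed_area(nodes))


def flat_geometry(state: FlatState) -> GeometryCache:
    """Metric quantities of a periodic Monge profile.

    Arclength elements use the true line element ``ds = sqrt(dx^2 + dh^2)``
    (needed for exact protein mass bookkeeping); the curvature is the
    linearized ``d^2 h / dx^2``.
    """
    dx = state.dx
    dh = np.roll(state.h, -1) - state.h
    ds_edge = np.hypot(dx, dh)
    ds_node = 0.5 * (ds_edge + np.roll(ds_edge, 1))
    H = curvature_flat_linearized(state)
    n = len(state.h)
    return GeometryCache(ds_edge=ds_edge, ds_node=ds_node,
                         tangent=np.zeros((n, 2)), normal=np.zeros((n, 2)),
                         H=H, L=float(ds_edge.sum()), A_enc=0.0)


def curvature_closed(c: ContourState) -> np.ndarray:
    """Per-node curvature of a closed contour (circle of radius R: -1/R)."""
    return _menger_curvature(c.nodes)


def curvature_flat_linearized(state: FlatState) -> np.ndarray:
    """Linearized Monge curvature ``H = d^2h/dx^2`` (periodic central diff)."""
    h = state.h
    dx = state.dx
    return (np.roll(h, -1) - 2.0 * h + np.roll(h, 1)) / dx ** 2


def _arclength_param(nodes: np.ndarray) -> tuple[np.ndarray, float]:
    edges = np.roll(nodes, -1, axis=0) - nodes
    ds = np.hypot(edges[:, 0], edges[:, 1])
    s = np.concatenate([[0.0], np.cumsum(ds)])
    return s, float(s[-1])


def transfer_density(old_s_nodes: np.ndarray, old_phi: np.ndarray,
                     old_ds_node: np.ndarray, new_s_nodes: np.ndarray,
                     new_ds_node: np.ndarray, L: float) -> np.ndarray:
    """Move a coverage field between node sets on the same closed curve.

    Piecewise-linear (periodic) interpolation in arclength followed by one
    global rescale so the total mass ``sum(phi * ds)`` is exactly preserved.
    If the rescale would push a node above saturation the excess is clipped
    and redistributed (with a warning), which signals near-saturation.
    """
    import warnings

    M_old = float(np.sum(old_phi * old_ds_node))
    # periodic linear interpolation
    xp = np.concatenate([old_s_nodes, [old_s_nodes[0] + L]])
    fp = np.concatenate([old_phi, [old_phi[0]]])
    new_phi = np.interp(np.mod(new_s_nodes, L), xp, fp)
    M_new = float(np.sum(new_phi * new_ds_node))
    if M_new <= 0:
        raise ValueError("degenerate density transfer (non-positive mass)")
    new_phi = new_phi * (M_old / M_new)
    if np.any(new_phi > 1.0):
        warnings.warn("density transfer hit saturation; clipping and "
                      "redistributing excess mass", UserWarning, stacklevel=2)
        for _ in range(100):
            over = new_phi > 1.0
            if not np.any(over):
                break
            excess = np.sum((new_phi[over] - 1.0) * new_ds_node[over])
            new_phi[over] = 1.0
            room = ~over
            w_room = new_ds_node[room] * (1.0 - new_phi[room])
            if w_room.sum() <= 0:
                raise ValueError("cannot redistribute mass: contour saturated")
            new_phi[room] += excess * (1.0 - new_phi[room]) / w_room.sum() * 1.0
    np.clip(new_phi, 0.0, 1.0, out=new_phi)
    return new_phi


def resample_contour(c: ContourState, N: int | None = None) -> ContourState:
    """Re-discretize a closed contour into equally spaced nodes.

    A periodic cubic spline through the current nodes is sampled at uniform
    arclength; the coverage field is transferred with exact global mass
    conservation (:func:`transfer_density`).
    """
    N_new = N or c.N
    nodes = c.nodes
    s, L = _arclength_param(nodes)
    pts = np.vstack([nodes, nodes[:1]])
    spl_x = CubicSpline(s, pts[:, 0], bc_type="periodic")
    spl_y = CubicSpline(s, pts[:, 1], bc_type="periodic")
    # iterate once: uniform in the spline's arclength, not the chord length
    s_new = np.linspace(0.0, L, N_new, endpoint=False)
    for _ in range(12):
        new_nodes = np.column_stack([spl_x(s_new), spl_y(s_new)])
        edges = np.roll(new_nodes, -1, axis=0) - new_nodes
        ds = np.hypot(edges[:, 0], edges[:, 1])
        if ds.max() / ds.min() <= 1.0 + 1e-8:
            break
        L_poly = ds.sum()
        # redistribute target arclengths proportionally to measured spacing
        cum = np.concatenate([[0.0], np.cumsum(ds)])
        target = np.linspace(0.0, L_poly, N_new, endpoint=False)
        s_new = np.interp(target, cum, np.concatenate([s_new, [L]]))
    new_nodes = np.column_stack([spl_x(s_new), spl_y(s_new)])
    if not is_simple(new_nodes):
        raise ValueError("contour self-intersects after resampling")

    old_ds_node = closed_geometry(nodes).ds_node
    new_geom = closed_geometry(new_nodes)
    s_old_nodes = s[:-1]
    new_phi = transfer_density(s_old_nodes, c.phi, old_ds_node,
                               s_new, new_geom.ds_node, L)
    out = ContourState(nodes=new_nodes, phi=new_phi, t=c.t, A_pref=c.A_pref,
                       M_total=c.M_total, L_init=c.L_init)
    return out
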