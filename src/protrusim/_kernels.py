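"""Jit-compiled explicit-Euler inner loops.

These kernels repeat, in loop form, exactly the force and flux expressions
of :mod:`protrusim.forces` and :mod:`protrusim.transport`; the test suite
pins single-step agreement between the two paths.  Python-level concerns
(resampling, snapshots, steady-state detection, self-intersection checks)
happen between kernel calls in :mod:`protrusim.dynamics`.

Status codes: 0 = completed, 1 = coverage left [0, 1] (caller sub-steps),
2 = non-finite value encountered.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["flat_steps", "round_steps"]


@njit(cache=False, fastmath=True, error_model="numpy")
def flat_steps(h, m, n_steps, dt, dx, L0,
               xi, D, kappa, Hbar, lam, gamma, Jns, b2, Aact, alpha,
               lam_nl, Lambda):
    N = h.shape[0]
    phi = np.empty(N)
    H = np.empty(N)
    u = np.empty(N)
    ds_e = np.empty(N)
    ds_n = np.empty(N)
    dh = np.empty(N)
    ge = np.empty(N)
    te = np.empty(N)
    grad_e = np.empty(N)
    phiss = np.empty(N)
    J = np.empty(N)
    v = np.empty(N)
    h_new = np.empty(N)
    m_new = np.empty(N)
    c_agg = 0.5 * Jns * b2
    inv_dx2 = 1.0 / (dx * dx)
    for step in range(n_steps):
        L = 0.0
        L2 = 0.0
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            d = h[ip] - h[i]
            dh[i] = d
            ds_e[i] = np.sqrt(dx * dx + d * d)
            L += ds_e[i]
            L2 += d * d
        L2 = N * dx + L2 / (2.0 * dx)
        Msum = 0.0
        for i in range(N):
            im = i - 1 if i > 0 else N - 1
            ds_n[i] = 0.5 * (ds_e[i] + ds_e[im])
            phi[i] = m[i] / ds_n[i]
            Msum += m[i]
        phibar = Msum / L
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            im = i - 1 if i > 0 else N - 1
            H[i] = (h[ip] - 2.0 * h[i] + h[im]) * inv_dx2
        for i in range(N):
            u[i] = H[i] - Hbar * phi[i]
        if lam_nl > 0.0:
            s = (L2 - L0) / (lam_nl * L0)
            lamL = lam * (1.0 + s * s)
        else:
            lamL = lam
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            ge[i] = 0.5 * (phi[i] + phi[ip]) * dh[i] / dx
            dphi = phi[ip] - phi[i]
            te[i] = dphi * dphi * dh[i] / (ds_e[i] * ds_e[i] * ds_e[i])
            grad_e[i] = dphi / ds_e[i]
        for i in range(N):
            im = i - 1 if i > 0 else N - 1
            phiss[i] = (grad_e[i] - grad_e[im]) / ds_n[i]
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            im = i - 1 if i > 0 else N - 1
            f_curv = -kappa * (u[ip] - 2.0 * u[i] + u[im]) * inv_dx2
            f_ten = lamL * H[i] - alpha * (ge[i] - ge[im]) / dx
            f_spr = -gamma * h[i]
            f_agg = -(c_agg / dx) * (te[i] - te[im])
            f_act = Aact * (phi[i] - phibar)
            v[i] = (f_curv + f_ten + f_spr + f_agg + f_act) / xi
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            phie = 0.5 * (phi[i] + phi[ip])
            dHe = (H[ip] - H[i]) / ds_e[i]
            dphiss = (phiss[ip] - phiss[i]) / ds_e[i]
            mob = Lambda * phie
            vel = Lambda * kappa * Hbar * dHe
            phiu = phi[i] if vel > 0.0 else phi[ip]
            J[i] = (phiu * vel
                    - mob * kappa * Hbar * Hbar * grad_e[i]
                    + mob * Jns * (grad_e[i] + b2 * dphiss)
                    - D * grad_e[i])
        for i in range(N):
            im = i - 1 if i > 0 else N - 1
            m_new[i] = m[i] + dt * (J[im] - J[i])
            h_new[i] = h[i] + dt * v[i]
        # validity of the candidate state
        ok = True
        for i in range(N):
            if not np.isfinite(h_new[i]) or not np.isfinite(m_new[i]):
                return step, 2
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            d = h_new[ip] - h_new[i]
            ds_e[i] = np.sqrt(dx * dx + d * d)
        for i in range(N):
            im = i - 1 if i > 0 else N - 1
            dsn = 0.5 * (ds_e[i] + ds_e[im])
            ph = m_new[i] / dsn
            if ph < 0.0 or ph > 1.0:
                ok = False
        if not ok:
            return step, 1
        for i in range(N):
            h[i] = h_new[i]
            m[i] = m_new[i]
    return n_steps, 0


@njit(cache=False, fastmath=True, error_model="numpy")
def round_steps(x, y, m, n_steps, dt, L0, A0,
                xi, D, kappa, Hbar, lam, Karea, Jns, b2, Aact, alpha,
                lam_nl, Lambda):
    N = x.shape[0]
    phi = np.empty(N)
    H = np.empty(N)
    u = np.empty(N)
    ds_e = np.empty(N)
    ds_n = np.empty(N)
    nx = np.empty(N)
    ny = np.empty(N)
    gcx = np.empty(N)  # curvature-energy gradient (scattered)
    gcy = np.empty(N)
    gm1x = np.empty(N)
    gm1y = np.empty(N)
    g0x = np.empty(N)
    g0y = np.empty(N)
    gp1x = np.empty(N)
    gp1y = np.empty(N)
    grad_e = np.empty(N)
    phiss = np.empty(N)
    J = np.empty(N)
    v = np.empty(N)
    x_new = np.empty(N)
    y_new = np.empty(N)
    m_new = np.empty(N)
    c_agg = 0.5 * Jns * b2
    for step in range(n_steps):
        L = 0.0
        A = 0.0
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            ex = x[ip] - x[i]
            ey = y[ip] - y[i]
            ds_e[i] = np.sqrt(ex * ex + ey * ey)
            L += ds_e[i]
            A += 0.5 * (x[i] * y[ip] - x[ip] * y[i])
        Msum = 0.0
        for i in range(N):
            im = i - 1 if i > 0 else N - 1
            ds_n[i] = 0.5 * (ds_e[i] + ds_e[im])
            phi[i] = m[i] / ds_n[i]
            Msum += m[i]
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            im = i - 1 if i > 0 else N - 1
            cx = x[ip] - x[im]
            cy = y[ip] - y[im]
            lc = np.sqrt(cx * cx + cy * cy)
            tx = cx / lc
            ty = cy / lc
            nx[i] = ty
            ny[i] = -tx
            ax = x[i] - x[im]
            ay = y[i] - y[im]
            bx = x[ip] - x[i]
            by = y[ip] - y[i]
            la = ds_e[im]
            lb = ds_e[i]
            cr = ax * by - ay * bx
            H[i] = -2.0 * cr / (la * lb * lc)
        for i in range(N):
            u[i] = H[i] - Hbar * phi[i]
        if lam_nl > 0.0:
            s = (L - L0) / (lam_nl * L0)
            lamL = lam * (1.0 + s * s)
        else:
            lamL = lam
        f_area = -Karea * (A - A0) / A0
        # per-triple gradients of the curvature energy
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            im = i - 1 if i > 0 else N - 1
            ax = x[i] - x[im]
            ay = y[i] - y[im]
            bx = x[ip] - x[i]
            by = y[ip] - y[i]
            cx = ax + bx
            cy = ay + by
            la = ds_e[im]
            lb = ds_e[i]
            lc = np.sqrt(cx * cx + cy * cy)
            uax = ax / la
            uay = ay / la
            ubx = bx / lb
            uby = by / lb
            ucx = cx / lc
            ucy = cy / lc
            cr = ax * by - ay * bx
            inv = 1.0 / (la * lb * lc)
            fac = 2.0 * cr * inv * inv
            # d(cross)/dr
            dcrm1x = -by
            dcrm1y = bx
            dcr0x = cy
            dcr0y = -cx
            dcrp1x = -ay
            dcrp1y = ax
            # d(la*lb*lc)/dr
            ddenm1x = -(lb * lc) * uax - (la * lb) * ucx
            ddenm1y = -(lb * lc) * uay - (la * lb) * ucy
            dden0x = (lb * lc) * uax - (la * lc) * ubx
            dden0y = (lb * lc) * uay - (la * lc) * uby
            ddenp1x = (la * lc) * ubx + (la * lb) * ucx
            ddenp1y = (la * lc) * uby + (la * lb) * ucy
            dHm1x = -2.0 * dcrm1x * inv + fac * ddenm1x
            dHm1y = -2.0 * dcrm1y * inv + fac * ddenm1y
            dH0x = -2.0 * dcr0x * inv + fac * dden0x
            dH0y = -2.0 * dcr0y * inv + fac * dden0y
            dHp1x = -2.0 * dcrp1x * inv + fac * ddenp1x
            dHp1y = -2.0 * dcrp1y * inv + fac * ddenp1y
            wH = kappa * u[i] * ds_n[i]
            we = 0.25 * kappa * u[i] * u[i]
            gm1x[i] = wH * dHm1x - we * uax
            gm1y[i] = wH * dHm1y - we * uay
            g0x[i] = wH * dH0x + we * (uax - ubx)
            g0y[i] = wH * dH0y + we * (uay - uby)
            gp1x[i] = wH * dHp1x + we * ubx
            gp1y[i] = wH * dHp1y + we * uby
        for j in range(N):
            jp = j + 1 if j + 1 < N else 0
            jm = j - 1 if j > 0 else N - 1
            gcx[j] = g0x[j] + gm1x[jp] + gp1x[jm]
            gcy[j] = g0y[j] + gm1y[jp] + gp1y[jm]
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            dphi = phi[ip] - phi[i]
            grad_e[i] = dphi / ds_e[i]
        for i in range(N):
            im = i - 1 if i > 0 else N - 1
            phiss[i] = (grad_e[i] - grad_e[im]) / ds_n[i]
        for j in range(N):
            jp = j + 1 if j + 1 < N else 0
            jm = j - 1 if j > 0 else N - 1
            # tension + surface-aggregation edge weights
            exj = x[jp] - x[j]
            eyj = y[jp] - y[j]
            uejx = exj / ds_e[j]
            uejy = eyj / ds_e[j]
            exm = x[j] - x[jm]
            eym = y[j] - y[jm]
            uemx = exm / ds_e[jm]
            uemy = eym / ds_e[jm]
            phie_j = 0.5 * (phi[j] + phi[jp])
            phie_m = 0.5 * (phi[jm] + phi[j])
            w_j = (lamL - alpha * phie_j) - c_agg * grad_e[j] * grad_e[j]
            w_m = (lamL - alpha * phie_m) - c_agg * grad_e[jm] * grad_e[jm]
            gtx = w_m * uemx - w_j * uejx
            gty = w_m * uemy - w_j * uejy
            f_cons = -((gcx[j] + gtx) * nx[j] + (gcy[j] + gty) * ny[j]) \
                / ds_n[j]
            f_act = Aact * phi[j]
            v[j] = (f_cons + f_act + f_area) / xi
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            phie = 0.5 * (phi[i] + phi[ip])
            dHe = (H[ip] - H[i]) / ds_e[i]
            dphiss = (phiss[ip] - phiss[i]) / ds_e[i]
            mob = Lambda * phie
            vel = Lambda * kappa * Hbar * dHe
            phiu = phi[i] if vel > 0.0 else phi[ip]
            J[i] = (phiu * vel
                    - mob * kappa * Hbar * Hbar * grad_e[i]
                    + mob * Jns * (grad_e[i] + b2 * dphiss)
                    - D * grad_e[i])
        for i in range(N):
            im = i - 1 if i > 0 else N - 1
            m_new[i] = m[i] + dt * (J[im] - J[i])
            x_new[i] = x[i] + dt * v[i] * nx[i]
            y_new[i] = y[i] + dt * v[i] * ny[i]
        for i in range(N):
            if (not np.isfinite(x_new[i]) or not np.isfinite(y_new[i])
                    or not np.isfinite(m_new[i])):
                return step, 2
        ok = True
        for i in range(N):
            ip = i + 1 if i + 1 < N else 0
            ex = x_new[ip] - x_new[i]
            ey = y_new[ip] - y_new[i]
            ds_e[i] = np.sqrt(ex * ex + ey * ey)
        for i in range(N):
            im = i - 1 if i > 0 else N - 1
            dsn = 0.5 * (ds_e[i] + ds_e[im])
            ph = m_new[i] / dsn
            if ph < 0.0 or ph > 1.0:
                ok = False
        if not ok:
            return step, 1
        for i in range(N):
            x[i] = x_new[i]
            y[i] = y_new[i]
            m[i] = m_new[i]
    return n_steps, 0
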