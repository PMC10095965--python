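"""Numerical kernels for rod relaxation (numba-accelerated when available).

The relaxation schemes move free vertices (index >= 2) along the total force.
Both schemes keep the per-component displacement accounting exact: every
update applied to the positions is a scalar-weighted combination of stored
total forces, and the identical scalars are applied to the per-component
accumulators, so ``dx_total = dx_s + dx_b + dx_g`` holds to rounding error.

Status codes returned by the relaxation kernels:
0 = converged, 1 = iteration budget exhausted, 2 = degenerate geometry.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def force_kernel(x, a, k0, ks, bmod, w, fs, fb, fg):
    """Fill per-vertex force components; returns 0, or 1 on degeneracy."""
    n = x.shape[0]
    for i in range(n):
        fs[i, 0] = 0.0
        fs[i, 1] = 0.0
        fb[i, 0] = 0.0
        fb[i, 1] = 0.0
        fg[i, 0] = 0.0
        fg[i, 1] = -w[i]
    # bond quantities
    for j in range(n - 1):
        ex = x[j + 1, 0] - x[j, 0]
        ey = x[j + 1, 1] - x[j, 1]
        ell = np.sqrt(ex * ex + ey * ey)
        if ell < 1e-12:
            return 1
        f = ks * (ell - a[j])
        tx = ex / ell
        ty = ey / ell
        fs[j, 0] += f * tx
        fs[j, 1] += f * ty
        fs[j + 1, 0] -= f * tx
        fs[j + 1, 1] -= f * ty
    # bending at interior vertices
    for j in range(1, n - 1):
        e0x = x[j, 0] - x[j - 1, 0]
        e0y = x[j, 1] - x[j - 1, 1]
        e1x = x[j + 1, 0] - x[j, 0]
        e1y = x[j + 1, 1] - x[j, 1]
        l0sq = e0x * e0x + e0y * e0y
        l1sq = e1x * e1x + e1y * e1y
        phi = np.arctan2(e0x * e1y - e0y * e1x, e0x * e1x + e0y * e1y)
        abar = 0.5 * (a[j - 1] + a[j])
        m = (bmod / abar) * (phi - k0[j - 1] * abar)
        # p = perp(e)/|e|^2 ; dphi/dx_{j+1} = p1, dphi/dx_j = -(p0+p1),
        # dphi/dx_{j-1} = p0 ; F = -m * dphi/dx
        p0x = -e0y / l0sq
        p0y = e0x / l0sq
        p1x = -e1y / l1sq
        p1y = e1x / l1sq
        fb[j + 1, 0] -= m * p1x
        fb[j + 1, 1] -= m * p1y
        fb[j, 0] += m * (p0x + p1x)
        fb[j, 1] += m * (p0y + p1y)
        fb[j - 1, 0] -= m * p0x
        fb[j - 1, 1] -= m * p0y
    return 0


@njit(cache=True)
def _residual(fs, fb, fg):
    n = fs.shape[0]
    res = 0.0
    for i in range(2, n):
        fx = fs[i, 0] + fb[i, 0] + fg[i, 0]
        fy = fs[i, 1] + fb[i, 1] + fg[i, 1]
        r = np.sqrt(fx * fx + fy * fy)
        if r > res:
            res = r
    return res


@njit(cache=True)
def relax_fire(
    x, a, k0, ks, bmod, w, mu, tol, dt_max, max_iters, acc_s, acc_b, acc_g
):
    """FIRE relaxation with per-component velocity bookkeeping.

    The velocity (and each component velocity) is built from scalar-weighted
    sums of the (component) forces, so ``acc_s + acc_b + acc_g`` equals the
    net displacement exactly.  Returns (status, n_iters, residual).
    """
    n = x.shape[0]
    fs = np.zeros((n, 2))
    fb = np.zeros((n, 2))
    fg = np.zeros((n, 2))
    v = np.zeros((n, 2))
    vs = np.zeros((n, 2))
    vb = np.zeros((n, 2))
    vg = np.zeros((n, 2))
    xprev = np.zeros((n, 2))

    if force_kernel(x, a, k0, ks, bmod, w, fs, fb, fg) != 0:
        return 2, 0, np.inf
    res = _residual(fs, fb, fg)

    alpha0 = 0.1
    alpha = alpha0
    dt = 0.1 * dt_max
    npos = 0
    it = 0
    while res >= tol:
        if it >= max_iters:
            return 1, it, res
        # power of the total force on the free vertices
        power = 0.0
        for i in range(2, n):
            power += (fs[i, 0] + fb[i, 0] + fg[i, 0]) * v[i, 0]
            power += (fs[i, 1] + fb[i, 1] + fg[i, 1]) * v[i, 1]
        if power > 0.0:
            npos += 1
            if npos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            for i in range(n):
                v[i, 0] = 0.0
                v[i, 1] = 0.0
                vs[i, 0] = 0.0
                vs[i, 1] = 0.0
                vb[i, 0] = 0.0
                vb[i, 1] = 0.0
                vg[i, 0] = 0.0
                vg[i, 1] = 0.0
            dt *= 0.5
            alpha = alpha0
            npos = 0
        # semi-implicit Euler (acceleration mu*F) with FIRE velocity mixing
        vnorm2 = 0.0
        fnorm2 = 0.0
        for i in range(2, n):
            v[i, 0] += dt * mu * (fs[i, 0] + fb[i, 0] + fg[i, 0])
            v[i, 1] += dt * mu * (fs[i, 1] + fb[i, 1] + fg[i, 1])
            vs[i, 0] += dt * mu * fs[i, 0]
            vs[i, 1] += dt * mu * fs[i, 1]
            vb[i, 0] += dt * mu * fb[i, 0]
            vb[i, 1] += dt * mu * fb[i, 1]
            vg[i, 0] += dt * mu * fg[i, 0]
            vg[i, 1] += dt * mu * fg[i, 1]
            vnorm2 += v[i, 0] * v[i, 0] + v[i, 1] * v[i, 1]
            fx = fs[i, 0] + fb[i, 0] + fg[i, 0]
            fy = fs[i, 1] + fb[i, 1] + fg[i, 1]
            fnorm2 += fx * fx + fy * fy
        if fnorm2 > 0.0:
            c1 = 1.0 - alpha
            c2 = alpha * np.sqrt(vnorm2 / fnorm2)
            for i in range(2, n):
                v[i, 0] = c1 * v[i, 0] + c2 * (fs[i, 0] + fb[i, 0] + fg[i, 0])
                v[i, 1] = c1 * v[i, 1] + c2 * (fs[i, 1] + fb[i, 1] + fg[i, 1])
                vs[i, 0] = c1 * vs[i, 0] + c2 * fs[i, 0]
                vs[i, 1] = c1 * vs[i, 1] + c2 * fs[i, 1]
                vb[i, 0] = c1 * vb[i, 0] + c2 * fb[i, 0]
                vb[i, 1] = c1 * vb[i, 1] + c2 * fb[i, 1]
                vg[i, 0] = c1 * vg[i, 0] + c2 * fg[i, 0]
                vg[i, 1] = c1 * vg[i, 1] + c2 * fg[i, 1]
        for i in range(2, n):
            xprev[i, 0] = x[i, 0]
            xprev[i, 1] = x[i, 1]
            x[i, 0] += dt * v[i, 0]
            x[i, 1] += dt * v[i, 1]
            acc_s[i, 0] += dt * vs[i, 0]
            acc_s[i, 1] += dt * vs[i, 1]
            acc_b[i, 0] += dt * vb[i, 0]
            acc_b[i, 1] += dt * vb[i, 1]
            acc_g[i, 0] += dt * vg[i, 0]
            acc_g[i, 1] += dt * vg[i, 1]
        if force_kernel(x, a, k0, ks, bmod, w, fs, fb, fg) != 0:
            # undo the step (roll back accumulators too) and restart cautiously
            for i in range(2, n):
                x[i, 0] = xprev[i, 0]
                x[i, 1] = xprev[i, 1]
                acc_s[i, 0] -= dt * vs[i, 0]
                acc_s[i, 1] -= dt * vs[i, 1]
                acc_b[i, 0] -= dt * vb[i, 0]
                acc_b[i, 1] -= dt * vb[i, 1]
                acc_g[i, 0] -= dt * vg[i, 0]
                acc_g[i, 1] -= dt * vg[i, 1]
                v[i, 0] = 0.0
                v[i, 1] = 0.0
                vs[i, 0] = 0.0
                vs[i, 1] = 0.0
                vb[i, 0] = 0.0
                vb[i, 1] = 0.0
                vg[i, 0] = 0.0
                vg[i, 1] = 0.0
            dt *= 0.25
            alpha = alpha0
            npos = 0
            if force_kernel(x, a, k0, ks, bmod, w, fs, fb, fg) != 0:
                return 2, it, res
            if dt < 1e-12 * dt_max:
                return 2, it, res
        res = _residual(fs, fb, fg)
        it += 1
    return 0, it, res


@njit(cache=True)
def relax_gd(x, a, k0, ks, bmod, w, mu, dtau, tol, max_iters, acc_s, acc_b, acc_g):
    """Literal fixed-step overdamped descent: x += mu*F_total*dtau.

    Returns (status, n_iters, residual).
    """
    n = x.shape[0]
    fs = np.zeros((n, 2))
    fb = np.zeros((n, 2))
    fg = np.zeros((n, 2))
    if force_kernel(x, a, k0, ks, bmod, w, fs, fb, fg) != 0:
        return 2, 0, np.inf
    res = _residual(fs, fb, fg)
    it = 0
    step = mu * dtau
    while res >= tol:
        if it >= max_iters:
            return 1, it, res
        for i in range(2, n):
            x[i, 0] += step * (fs[i, 0] + fb[i, 0] + fg[i, 0])
            x[i, 1] += step * (fs[i, 1] + fb[i, 1] + fg[i, 1])
            acc_s[i, 0] += step * fs[i, 0]
            acc_s[i, 1] += step * fs[i, 1]
            acc_b[i, 0] += step * fb[i, 0]
            acc_b[i, 1] += step * fb[i, 1]
            acc_g[i, 0] += step * fg[i, 0]
            acc_g[i, 1] += step * fg[i, 1]
        if force_kernel(x, a, k0, ks, bmod, w, fs, fb, fg) != 0:
            return 2, it, res
        res = _residual(fs, fb, fg)
        it += 1
    return 0, it, res
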