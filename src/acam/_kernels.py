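"""Compiled inner loops for the energy/gradient kernels.

Numba-jitted versions of the rod and spring kernels; ``acam.mech`` falls
back to pure numpy when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True, fastmath=False)
def rod_energy_grad_nb(x, seg_a, seg_b, ref, bend_prev, bend_next, kap2, g):
    n_seg = seg_a.shape[0]
    v = np.empty((n_seg, 2))
    d = np.empty(n_seg)
    e = 0.0
    for s in range(n_seg):
        vx = x[seg_b[s], 0] - x[seg_a[s], 0]
        vy = x[seg_b[s], 1] - x[seg_a[s], 1]
        v[s, 0] = vx
        v[s, 1] = vy
        ds = np.sqrt(vx * vx + vy * vy)
        d[s] = ds
        if ds <= 0.0:
            return -1.0  # degenerate segment sentinel
        eps = ds / ref[s] - 1.0
        e += 0.5 * eps * eps * ref[s]
        c = eps / ds
        g[seg_b[s], 0] += c * vx
        g[seg_b[s], 1] += c * vy
        g[seg_a[s], 0] -= c * vx
        g[seg_a[s], 1] -= c * vy
    for k in range(bend_prev.shape[0]):
        p = bend_prev[k]
        q = bend_next[k]
        cross = v[p, 0] * v[q, 1] - v[p, 1] * v[q, 0]
        dot = v[p, 0] * v[q, 0] + v[p, 1] * v[q, 1]
        theta = np.arctan2(cross, dot)
        dS = 0.5 * (ref[p] + ref[q])
        e += 0.5 * kap2[k] * theta * theta / dS
        m = kap2[k] * theta / dS
        cn = m / (d[q] * d[q])
        gx = cn * (-v[q, 1])
        gy = cn * v[q, 0]
        g[seg_b[q], 0] += gx
        g[seg_b[q], 1] += gy
        g[seg_a[q], 0] -= gx
        g[seg_a[q], 1] -= gy
        cp = -m / (d[p] * d[p])
        gx = cp * (-v[p, 1])
        gy = cp * v[p, 0]
        g[seg_b[p], 0] += gx
        g[seg_b[p], 1] += gy
        g[seg_a[p], 0] -= gx
        g[seg_a[p], 1] -= gy
    return e


@njit(cache=True, fastmath=False)
def area_energy_grad_nb(x, starts, counts, area0, k_area, g):
    e = 0.0
    for li in range(starts.shape[0]):
        a0 = area0[li]
        if a0 <= 0.0:
            continue
        s = starts[li]
        n = counts[li]
        area = 0.0
        for i in range(n):
            j = s + i
            jn = s + (i + 1) % n
            area += x[j, 0] * x[jn, 1] - x[jn, 0] * x[j, 1]
        area *= 0.5
        dev = area / a0 - 1.0
        e += 0.5 * k_area * dev * dev * a0
        coef = 0.5 * k_area * dev
        for i in range(n):
            j = s + i
            jn = s + (i + 1) % n
            jp = s + (i - 1) % n
            g[j, 0] += coef * (x[jn, 1] - x[jp, 1])
            g[j, 1] += coef * (x[jp, 0] - x[jn, 0])
    return e


@njit(cache=True, fastmath=False)
def bond_energy_grad_nb(x, pa, pb, k, delta_max, g):
    e = 0.0
    for i in range(pa.shape[0]):
        ux = x[pb[i], 0] - x[pa[i], 0]
        uy = x[pb[i], 1] - x[pa[i], 1]
        delta = np.sqrt(ux * ux + uy * uy)
        dd = min(delta, delta_max) - 1.0
        e += 0.5 * k[i] * dd * dd
        if 0.0 < delta <= delta_max:
            c = k[i] * (delta - 1.0) / delta
            g[pb[i], 0] += c * ux
            g[pb[i], 1] += c * uy
            g[pa[i], 0] -= c * ux
            g[pa[i], 1] -= c * uy
    return e


@njit(cache=True, fastmath=False)
def anchor_energy_grad_nb(x, pa, anchor, k, delta_max, g):
    e = 0.0
    for i in range(pa.shape[0]):
        ux = anchor[i, 0] - x[pa[i], 0]
        uy = anchor[i, 1] - x[pa[i], 1]
        delta = np.sqrt(ux * ux + uy * uy)
        dd = min(delta, delta_max) - 1.0
        e += 0.5 * k[i] * dd * dd
        if 0.0 < delta <= delta_max:
            c = k[i] * (delta - 1.0) / delta
            g[pa[i], 0] -= c * ux
            g[pa[i], 1] -= c * uy
    return e
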