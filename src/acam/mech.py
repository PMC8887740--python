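"""Vectorised energy/gradient kernels for cortex rods and adhesion springs.

All quantities are dimensionless: lengths in units of the adhesion rest
length, moduli scaled by the cortex extensional stiffness.  The kernels
operate on flat arrays so that a whole tissue (many loops plus bonds) can
be minimised in a single call.
"""

from __future__ import annotations

import numpy as np

from . import _kernels


def _perp(v: np.ndarray) -> np.ndarray:
    """Rotate 2D vectors by +90 degrees."""
    out = np.empty_like(v)
    out[:, 0] = -v[:, 1]
    out[:, 1] = v[:, 0]
    return out


def rod_energy_grad(
    x: np.ndarray,
    seg_a: np.ndarray,
    seg_b: np.ndarray,
    ref: np.ndarray,
    bend_prev: np.ndarray,
    bend_next: np.ndarray,
    kap2: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Stretching + bending energy of a set of discrete rods, with gradient.

    Parameters
    ----------
    x : (N, 2) node positions.
    seg_a, seg_b : (S,) tail/head node index of each segment.
    ref : (S,) reference (post active contraction) segment lengths.
    bend_prev, bend_next : (B,) segment indices meeting at each hinge node.
    kap2 : (B,) squared bending-to-stretching ratio at each hinge.

    Energy is ``sum(0.5*eps^2*ref) + sum(0.5*kap2*theta^2/dS)`` with strain
    ``eps = d/ref - 1``, turning angle ``theta`` and reference hinge length
    ``dS = (ref_prev + ref_next)/2`` — the discrete form of the rod energy
    ``\\oint [k^2 c^2 + eps^2]/2 dS``.
    """
    if _kernels.HAVE_NUMBA:
        g = np.zeros_like(x)
        e = _kernels.rod_energy_grad_nb(x, seg_a, seg_b, ref, bend_prev, bend_next, kap2, g)
        if e < 0.0:
            raise ValueError("degenerate segment (zero length)")
        return e, g
    v = x[seg_b] - x[seg_a]
    d = np.hypot(v[:, 0], v[:, 1])
    if np.any(d <= 0.0):
        bad = int(np.argmin(d))
        raise ValueError(f"degenerate segment (zero length) at segment index {bad}")
    eps = d / ref - 1.0
    e_stretch = 0.5 * float(np.sum(eps * eps * ref))

    g = np.zeros_like(x)
    # dE/dd = eps, along the unit tangent
    gv = (eps / d)[:, None] * v
    np.add.at(g, seg_b, gv)
    np.add.at(g, seg_a, -gv)

    if len(bend_prev):
        vp = v[bend_prev]
        vn = v[bend_next]
        dp = d[bend_prev]
        dn = d[bend_next]
        cross = vp[:, 0] * vn[:, 1] - vp[:, 1] * vn[:, 0]
        dot = vp[:, 0] * vn[:, 0] + vp[:, 1] * vn[:, 1]
        theta = np.arctan2(cross, dot)
        ds = 0.5 * (ref[bend_prev] + ref[bend_next])
        e_bend = 0.5 * float(np.sum(kap2 * theta * theta / ds))
        m = kap2 * theta / ds  # dE/dtheta
        # grad of theta w.r.t. the two segment vectors
        gn = (m / (dn * dn))[:, None] * _perp(vn)
        gp = (-m / (dp * dp))[:, None] * _perp(vp)
        np.add.at(g, seg_b[bend_next], gn)
        np.add.at(g, seg_a[bend_next], -gn)
        np.add.at(g, seg_b[bend_prev], gp)
        np.add.at(g, seg_a[bend_prev], -gp)
    else:
        e_bend = 0.0

    return e_stretch + e_bend, g


def area_energy_grad(
    x: np.ndarray,
    starts: np.ndarray,
    counts: np.ndarray,
    area0: np.ndarray,
    k_area: float,
) -> tuple[float, np.ndarray]:
    """Weak areal elasticity per closed loop: (k/2)(A/A0 - 1)^2 A0.

    A0 <= 0 disables the term for that loop.  Gradient via the shoelace
    derivative dA/dx_i = (perp of x_{i+1} - x_{i-1})/2.
    """
    g = np.zeros_like(x)
    e = 0.0
    if k_area <= 0:
        return e, g
    if _kernels.HAVE_NUMBA:
        e = _kernels.area_energy_grad_nb(
            x, np.asarray(starts, np.int64), np.asarray(counts, np.int64),
            np.asarray(area0, np.float64), k_area, g,
        )
        return e, g
    for s, n, a0 in zip(starts, counts, area0):
        if a0 <= 0:
            continue
        xs = x[s : s + n]
        xn = np.roll(xs, -1, axis=0)
        area = 0.5 * float(np.sum(xs[:, 0] * xn[:, 1] - xn[:, 0] * xs[:, 1]))
        dev = area / a0 - 1.0
        e += 0.5 * k_area * dev * dev * a0
        coef = k_area * dev  # dE/dA
        xp = np.roll(xs, 1, axis=0)
        dax = np.empty_like(xs)
        dax[:, 0] = 0.5 * (xn[:, 1] - xp[:, 1])
        dax[:, 1] = 0.5 * (xp[:, 0] - xn[:, 0])
        g[s : s + n] += coef * dax
    return e, g


def spring_energy(delta: np.ndarray, k: np.ndarray, delta_max: float) -> np.ndarray:
    """Saturating Hookean adhesion energy per bond (vectorised)."""
    dd = np.minimum(delta, delta_max) - 1.0
    return 0.5 * k * dd * dd


def bond_energy_grad(
    x: np.ndarray,
    pa: np.ndarray,
    pb: np.ndarray,
    k: np.ndarray,
    delta_max: float,
) -> tuple[float, np.ndarray]:
    """Energy/gradient of node-node adhesion springs (both endpoints free).

    Saturated bonds (delta > delta_max) keep a constant energy and exert no
    force; bonds shorter than the rest length push apart, maintaining the
    inter-cortical spacing.
    """
    g = np.zeros_like(x)
    if len(pa) == 0:
        return 0.0, g
    if _kernels.HAVE_NUMBA:
        e = _kernels.bond_energy_grad_nb(x, pa, pb, k, delta_max, g)
        return e, g
    u = x[pb] - x[pa]
    delta = np.hypot(u[:, 0], u[:, 1])
    e = float(np.sum(spring_energy(delta, k, delta_max)))
    act = (delta <= delta_max) & (delta > 0.0)
    if np.any(act):
        coef = np.zeros_like(delta)
        coef[act] = k[act] * (delta[act] - 1.0) / delta[act]
        gu = coef[:, None] * u
        np.add.at(g, pb, gu)
        np.add.at(g, pa, -gu)
    return e, g


def anchor_energy_grad(
    x: np.ndarray,
    pa: np.ndarray,
    anchor: np.ndarray,
    k: np.ndarray,
    delta_max: float,
) -> tuple[float, np.ndarray]:
    """Energy/gradient of springs from free nodes to fixed wall anchors."""
    g = np.zeros_like(x)
    if len(pa) == 0:
        return 0.0, g
    if _kernels.HAVE_NUMBA:
        e = _kernels.anchor_energy_grad_nb(x, pa, anchor, k, delta_max, g)
        return e, g
    u = anchor - x[pa]
    delta = np.hypot(u[:, 0], u[:, 1])
    e = float(np.sum(spring_energy(delta, k, delta_max)))
    act = (delta <= delta_max) & (delta > 0.0)
    if np.any(act):
        coef = np.zeros_like(delta)
        coef[act] = k[act] * (delta[act] - 1.0) / delta[act]
        np.add.at(g, pa, -coef[:, None] * u)
    return e, g
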