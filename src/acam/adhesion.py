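"""Adhesion bonds between cortices: creation, turnover and force transfer.

Bonds are saturating Hookean springs (rest length 1, stiffness ``omega``)
between discretisation nodes of *different* cells, or between a node and a
fixed boundary-wall anchor.  Unpaired nodes re-bind instantaneously to a
partner within ``delta_max``, sampled from the binding kernel Phi with
weights proportional to the inverse candidate distance.  Each bond lives
for an exponentially distributed time of mean ``tau_adh``, realising the
linear relaxation of the bond density towards Phi at rate ``1/tau_adh``;
the turnover of a sheared bond population yields an emergent cortex-cortex
sliding friction of coefficient ``mu_adh = omega * tau_adh``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely import STRtree
from shapely.geometry import LineString

from . import mech

__all__ = [
    "AdhesionBond",
    "BindingKernel",
    "BondSet",
    "bond_energy",
    "bond_force",
    "spawn_bonds",
    "turnover_step",
    "build_mean_field_bonds",
    "mean_field_adhesion_force",
    "adhesion_energy",
]


def bond_energy(delta: float, omega: float, delta_max: float) -> float:
    """Energy of one bond: (omega/2)(delta-1)^2, constant beyond delta_max."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    return float(mech.spring_energy(np.asarray([delta], float), np.asarray([omega]), delta_max)[0])


@dataclass
class BindingKernel:
    """Binding probability density Phi over candidate partners.

    A seeking node's candidates are the nearest reachable point of each
    foreign cortex (or wall) within ``max_range``; the kernel weights
    choose *which* partner cortex to bind, proportionally to the inverse
    candidate distance (closer cortices proportionally more likely),
    normalised over the candidate set and zero beyond ``max_range``.
    Bonds are therefore born near-normal to the partner cortex, at the
    local inter-cortical gap; shear angles grow only by subsequent
    sliding.  A ``uniform`` alternative is kept for robustness studies.
    """

    max_range: float
    mode: str = "inverse"  # "inverse" or "uniform"

    def weights(self, dists: np.ndarray) -> np.ndarray:
        dists = np.asarray(dists, dtype=float)
        w = np.where(dists <= self.max_range, 1.0, 0.0)
        if self.mode == "inverse":
            w = w / np.maximum(dists, 1e-12)
        elif self.mode != "uniform":
            raise ValueError(f"unknown kernel mode {self.mode!r}")
        tot = w.sum()
        if tot > 0:
            w = w / tot
        return w


@dataclass
class BondSet:
    """Struct-of-arrays store of live adhesion bonds.

    Endpoint b may be a wall anchor, encoded as ``b_loop = -1 - wall_index``
    with ``b_node`` indexing the wall point chain.  ``factor`` multiplies the
    tissue adhesion stiffness omega (1 for ordinary bonds, 50 for boundary
    pins, fractional Phi-weights in the mean-field regime).  ``pin`` bonds
    are permanent and survive turnover and mean-field rebuilds.
    """

    a_loop: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    a_node: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    b_loop: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    b_node: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    factor: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    birth: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    life: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    pin: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def __len__(self) -> int:
        return len(self.a_loop)

    def add(self, a_loop, a_node, b_loop, b_node, factor, birth, life, pin=False):
        def cat(arr, vals, dtype):
            return np.concatenate([arr, np.asarray(np.atleast_1d(vals), dtype=dtype)])

        k = len(np.atleast_1d(a_loop))
        self.a_loop = cat(self.a_loop, a_loop, int)
        self.a_node = cat(self.a_node, a_node, int)
        self.b_loop = cat(self.b_loop, b_loop, int)
        self.b_node = cat(self.b_node, b_node, int)
        self.factor = cat(self.factor, factor, float)
        self.birth = cat(self.birth, np.broadcast_to(np.asarray(birth, float), (k,)), float)
        self.life = cat(self.life, np.broadcast_to(np.asarray(life, float), (k,)), float)
        self.pin = cat(self.pin, np.broadcast_to(np.asarray(pin, bool), (k,)), bool)

    def keep(self, mask: np.ndarray) -> None:
        for name in ("a_loop", "a_node", "b_loop", "b_node", "factor", "birth", "life", "pin"):
            setattr(self, name, getattr(self, name)[mask])

    def copy(self) -> "BondSet":
        out = BondSet()
        for name in ("a_loop", "a_node", "b_loop", "b_node", "factor", "birth", "life", "pin"):
            setattr(out, name, getattr(self, name).copy())
        return out

    def records(self) -> list[tuple]:
        """Serialisable view: (cell_a, label_a, cell_b, label_b, birth, life)."""
        return list(
            zip(
                self.a_loop.tolist(),
                self.a_node.tolist(),
                self.b_loop.tolist(),
                self.b_node.tolist(),
                self.birth.tolist(),
                self.life.tolist(),
            )
        )


@dataclass
class AdhesionBond:
    """A single bond, resolved to current endpoint positions (view object)."""

    endpoint_a: tuple[int, int]
    endpoint_b: tuple[int, int]
    xa: np.ndarray
    xb: np.ndarray
    omega: float
    delta_max: float
    birth_time: float = 0.0
    scheduled_lifetime: float = np.inf

    @property
    def delta(self) -> float:
        return float(np.hypot(*(self.xb - self.xa)))

    @property
    def energy(self) -> float:
        return bond_energy(self.delta, self.omega, self.delta_max)

    def shear_angle(self, normal: np.ndarray) -> float:
        """Angle phi between the bond axis and the local cortex normal d1."""
        u = (self.xb - self.xa) / max(self.delta, 1e-12)
        nrm = normal / np.linalg.norm(normal)
        return float(np.arccos(np.clip(abs(float(u @ nrm)), 0.0, 1.0)))


def bond_force(bond: AdhesionBond) -> tuple[np.ndarray, np.ndarray]:
    """Equal-and-opposite central force pair (on endpoint a, endpoint b).

    Magnitude ``omega * |delta - 1|`` for delta <= delta_max, zero beyond
    (the saturated branch is constant); attractive when stretched,
    repulsive when compressed below the rest length.
    """
    u = bond.xb - bond.xa
    delta = float(np.hypot(*u))
    if delta <= 0:
        raise ValueError("dangling or coincident bond endpoints")
    if delta > bond.delta_max:
        f = np.zeros(2)
    else:
        f = bond.omega * (delta - 1.0) * u / delta
    return f, -f


# ---------------------------------------------------------------------------
# tissue-level bond dynamics (operate on acam.tissue.Tissue)
# ---------------------------------------------------------------------------


class _Occlusion:
    """Line-of-sight test: a bond cannot cross an intervening cortex."""

    def __init__(self, tissue):
        self.rings = []
        self.ring_loop = []
        for i, lp in enumerate(tissue.loops):
            pts = np.vstack([lp.x, lp.x[:1]]) if lp.closed else lp.x
            self.rings.append(LineString(pts))
            self.ring_loop.append(i)
        self.tree = STRtree(self.rings)

    def blocked(self, xa, xb, loop_a: int, loop_b: int) -> bool:
        seg = LineString([xa, xb])
        for k in self.tree.query(seg):
            if self.ring_loop[k] in (loop_a, loop_b):
                continue
            if self.rings[k].intersects(seg):
                return True
        return False


def _target_trees(tissue):
    """(target_id, KDTree, points) per cortex loop and per wall chain."""
    out = []
    for i, lp in enumerate(tissue.loops):
        out.append((i, cKDTree(lp.x), lp.x))
    for w, wall in enumerate(tissue.walls):
        out.append((-1 - w, cKDTree(wall.points), wall.points))
    return out


def spawn_bonds(tissue, rng: np.random.Generator) -> int:
    """Form new bonds for currently unpaired cortex nodes.

    Unpaired nodes are processed in a shuffled order; each gains exactly
    one bond, attached at the nearest node of a partner cortex chosen from
    the binding kernel over the reachable foreign cortices (within
    ``delta_max``).  Candidates whose bond segment would cross a third
    cell's cortex are occluded (adhesion molecules link apposed membranes;
    they cannot reach through an intervening cell).  A node that receives
    a bond mid-round is no longer unpaired and does not seek.  Returns the
    number of bonds formed.
    """
    p = tissue.params
    kernel = BindingKernel(p.delta_max, p.kernel_mode)

    # paired state of every cortex node
    paired = [np.zeros(lp.n, dtype=bool) for lp in tissue.loops]
    b = tissue.bonds
    for al, an in zip(b.a_loop, b.a_node):
        paired[al][an] = True
    for bl, bn in zip(b.b_loop, b.b_node):
        if bl >= 0:
            paired[bl][bn] = True

    seekers = [(i, j) for i, lp in enumerate(tissue.loops) for j in range(lp.n) if not paired[i][j]]
    if not seekers:
        return 0
    order = rng.permutation(len(seekers))
    occ = _Occlusion(tissue)
    targets = _target_trees(tissue)

    # nearest node of every target for every seeker, vectorised per target
    seeker_x = np.array([tissue.loops[i].x[j] for i, j in seekers])
    near = []
    for tid, tree, tpts in targets:
        dist, idx = tree.query(seeker_x, distance_upper_bound=p.delta_max)
        near.append((tid, dist, idx, tpts))

    new = {"al": [], "an": [], "bl": [], "bn": []}
    for k in order:
        i, j = seekers[k]
        if paired[i][j]:
            continue
        xq = tissue.loops[i].x[j]
        cand = []  # (target_id, node_index, distance)
        for tid, dist, idx, tpts in near:
            if tid == i or not np.isfinite(dist[k]):
                continue
            cand.append((tid, int(idx[k]), float(dist[k]), tpts))
        if not cand:
            continue
        w = kernel.weights(np.array([c[2] for c in cand]))
        pick = None
        while w.sum() > 0:
            ci = int(rng.choice(len(cand), p=w / w.sum()))
            tid, nn, dd, tpts = cand[ci]
            if not occ.blocked(xq, tpts[nn], i, tid):
                pick = (tid, nn)
                break
            w[ci] = 0.0
        if pick is None:
            continue
        new["al"].append(i)
        new["an"].append(j)
        new["bl"].append(pick[0])
        new["bn"].append(pick[1])
        paired[i][j] = True
        if pick[0] >= 0:
            paired[pick[0]][pick[1]] = True

    m = len(new["al"])
    if m:
        lives = rng.exponential(p.tau_adh, size=m) if np.isfinite(p.tau_adh) else np.full(m, np.inf)
        # stiffness scaled by the node spacing: adhesion energy per unit
        # cortex length is omega*(delta-1)^2/2, independent of the mesh
        tissue.bonds.add(
            new["al"], new["an"], new["bl"], new["bn"],
            np.full(m, p.mesh_spacing), tissue.time, lives, pin=False,
        )
    return m


def turnover_step(tissue, dt: float, rng: np.random.Generator | None = None) -> int:
    """Remove bonds whose age exceeds their scheduled lifetime.

    Lifetimes are exponential with mean ``tau_adh``, drawn at birth, so the
    survival fraction after time t is exp(-t/tau_adh).  Pins never expire.
    Returns the number of bonds removed; freed nodes become eligible for
    ``spawn_bonds`` in the same step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    b = tissue.bonds
    age = (tissue.time + dt) - b.birth
    expired = (age > b.life) & ~b.pin
    # bonds sheared by an intervening cortex break regardless of age
    cc = (b.b_loop >= 0) & ~b.pin & ~expired
    if cc.any() and len(tissue.loops) > 2:
        idx = np.where(cc)[0]
        xa = np.array([tissue.loops[l].x[nn] for l, nn in zip(b.a_loop[idx], b.a_node[idx])])
        xb = np.array([tissue.loops[l].x[nn] for l, nn in zip(b.b_loop[idx], b.b_node[idx])])
        segs = shapely.linestrings(np.stack([xa, xb], axis=1))
        occ = _Occlusion(tissue)
        si, ri = occ.tree.query(segs, predicate="intersects")
        for s, r in zip(si, ri):
            k = idx[s]
            if occ.ring_loop[r] not in (b.a_loop[k], b.b_loop[k]):
                expired[k] = True
    n = int(expired.sum())
    if n:
        b.keep(~expired)
    return n


def clear_transient_bonds(tissue) -> None:
    """Drop all non-pin bonds (pins are permanent boundary attachments)."""
    b = tissue.bonds
    if len(b):
        b.keep(b.pin.copy())


def rebind_nearest(tissue) -> int:
    """Deterministic instantaneous rebinding (expectation of the kernel).

    The zero-lifetime limit of the binding dynamics used for static
    (fixed-point) problems, where a deterministic bond set is required.
    Every node gains one (fractional) bond to the nearest unoccluded node
    of each reachable foreign cortex/wall, weighted by the binding kernel
    over those partners.  Cortex-cortex bonds carry an extra factor 1/2
    because apposed nodes each bind (the pair is counted from both sides,
    matching the ~one-bond-per-node steady state of the stochastic
    scheme); cortex-wall weights are unhalved (walls do not seek).  Pins
    are preserved.  Returns the bond count.
    """
    clear_transient_bonds(tissue)
    p = tissue.params
    kernel = BindingKernel(p.delta_max, p.kernel_mode)
    occ = _Occlusion(tissue) if len(tissue.loops) > 2 else None
    targets = _target_trees(tissue)
    for i, lp in enumerate(tissue.loops):
        near = []
        for tid, tree, tpts in targets:
            if tid == i:
                continue
            dist, idx = tree.query(lp.x, distance_upper_bound=p.delta_max)
            near.append((tid, dist, idx, tpts))
        al, an, bl, bn, fac = [], [], [], [], []
        for j in range(lp.n):
            cand = []
            for tid, dist, idx, tpts in near:
                if not np.isfinite(dist[j]):
                    continue
                if occ is not None and occ.blocked(lp.x[j], tpts[int(idx[j])], i, tid):
                    continue
                cand.append((tid, int(idx[j]), float(dist[j])))
            if not cand:
                continue
            w = kernel.weights(np.array([c[2] for c in cand]))
            for (tid, nn, _), wk in zip(cand, w):
                if wk <= 0:
                    continue
                al.append(i)
                an.append(j)
                bl.append(tid)
                bn.append(nn)
                fac.append((0.5 if tid >= 0 else 1.0) * wk * p.mesh_spacing)
        if al:
            tissue.bonds.add(al, an, bl, bn, fac, tissue.time, np.inf, pin=False)
    return len(tissue.bonds)


def resample_bonds(tissue, rng: np.random.Generator) -> int:
    """Fast-adhesion regime (tau_adh below one cortex step): no bond
    persists between steps; the whole transient bond set is resampled from
    the binding kernel every step."""
    clear_transient_bonds(tissue)
    return spawn_bonds(tissue, rng)


def build_mean_field_bonds(tissue) -> None:
    """Replace ordinary bonds by the Phi-weighted bond expectation.

    When binding and unbinding are instantaneous the adhesion force at a
    node is the Phi-weighted expectation of the discrete bond force over
    the reachable partner cortices (attachment at each partner's nearest
    node; no occlusion test — an expectation operator for unobstructed
    geometries).  Realised as fractional-stiffness bonds: pair
    (i, j) receives weight ``(w_ij + w_ji)/2`` (symmetrised so forces stay
    central and momentum is conserved; exact for an isolated candidate
    pair), and cortex-wall pairs ``w_ij`` (walls do not seek).  Pins are
    preserved.  This is the expectation operator behind
    ``mean_field_adhesion_force``; the simulation loop realises the fast
    regime by resampling discrete bonds instead (``resample_bonds``), whose
    time average this expectation approximates.
    """
    p = tissue.params
    kernel = BindingKernel(p.delta_max, p.kernel_mode)
    b = tissue.bonds
    if len(b):
        b.keep(b.pin.copy())

    targets = _target_trees(tissue)
    offsets = {}
    off = 0
    for i, lp in enumerate(tissue.loops):
        offsets[i] = off
        off += lp.n
    for w, wall in enumerate(tissue.walls):
        offsets[-1 - w] = off
        off += len(wall.points)
    lid = np.empty(off, int)
    nid = np.empty(off, int)
    for tid, _, tpts in targets:
        lid[offsets[tid] : offsets[tid] + len(tpts)] = tid
        nid[offsets[tid] : offsets[tid] + len(tpts)] = np.arange(len(tpts))

    weights: dict[tuple[int, int], float] = {}
    for i, lp in enumerate(tissue.loops):
        near = []
        for tid, tree, tpts in targets:
            if tid == i:
                continue
            dist, idx = tree.query(lp.x, distance_upper_bound=p.delta_max)
            near.append((tid, dist, idx))
        for j in range(lp.n):
            cand = [
                (tid, int(idx[j]), float(dist[j]))
                for tid, dist, idx in near
                if np.isfinite(dist[j])
            ]
            if not cand:
                continue
            w = kernel.weights(np.array([c[2] for c in cand]))
            gi = offsets[i] + j
            for (tid, nn, _), wc in zip(cand, w):
                if wc <= 0:
                    continue
                gc = offsets[tid] + nn
                if tid < 0:
                    weights[(gi, gc)] = weights.get((gi, gc), 0.0) + wc
                else:
                    key = (gi, gc) if gi < gc else (gc, gi)
                    weights[key] = weights.get(key, 0.0) + 0.5 * wc

    if weights:
        keys = np.array(list(weights.keys()))
        vals = np.array(list(weights.values())) * p.mesh_spacing
        ga, gb = keys[:, 0], keys[:, 1]
        tissue.bonds.add(
            lid[ga], nid[ga], lid[gb], nid[gb], vals,
            tissue.time, np.inf, pin=False,
        )


def _bond_arrays(tissue):
    """Resolve the live bond set to global-index pair and anchor arrays."""
    b = tissue.bonds
    off = tissue.loop_offsets()
    cc = b.b_loop >= 0
    pa = off[b.a_loop[cc]] + b.a_node[cc]
    pb = off[b.b_loop[cc]] + b.b_node[cc]
    kcc = tissue.params.omega * b.factor[cc]
    cw = ~cc
    wa = off[b.a_loop[cw]] + b.a_node[cw]
    anchors = (
        np.array([tissue.walls[-1 - l].points[nn] for l, nn in zip(b.b_loop[cw], b.b_node[cw])])
        if cw.any()
        else np.empty((0, 2))
    )
    kw = tissue.params.omega * b.factor[cw]
    return pa, pb, kcc, wa, anchors, kw


def adhesion_energy(tissue) -> float:
    """Total adhesion energy: sum of bond energies, each bond counted once."""
    x = tissue.stacked_positions()
    pa, pb, kcc, wa, anchors, kw = _bond_arrays(tissue)
    e1, _ = mech.bond_energy_grad(x, pa, pb, kcc, tissue.params.delta_max)
    e2, _ = mech.anchor_energy_grad(x, wa, anchors, kw, tissue.params.delta_max)
    return e1 + e2


def adhesion_force(tissue) -> np.ndarray:
    """Per-node force from the live bond set (stacked over all loops)."""
    x = tissue.stacked_positions()
    pa, pb, kcc, wa, anchors, kw = _bond_arrays(tissue)
    _, g1 = mech.bond_energy_grad(x, pa, pb, kcc, tissue.params.delta_max)
    _, g2 = mech.anchor_energy_grad(x, wa, anchors, kw, tissue.params.delta_max)
    return -(g1 + g2)


def mean_field_adhesion_force(tissue) -> np.ndarray:
    """Per-node adhesion force in the instantaneous-binding limit.

    Builds the Phi-weighted mean-field bond set on the current geometry
    (keeping pins) and returns the resulting per-node forces.
    """
    build_mean_field_bonds(tissue)
    return adhesion_force(tissue)
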