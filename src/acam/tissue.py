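"""Tissue assembly, quasi-static force balance and viscoelastic stepping.

A tissue is a set of cortex loops coupled by adhesion bonds, optionally
constrained by fixed boundary walls.  Dynamics are quasi-static: at every
step the node positions minimise the total energy (cortex stretching and
bending, adhesion springs, boundary pins) with bond topology and rest
lengths frozen; the cortex then behaves as a viscoelastic fluid on longer
timescales, realised by relaxing every undeformed segment length to the
current length once per step.  One simulation step corresponds to one
cortical turnover time tau_cor.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import adhesion, mech
from .cortex import CortexLoop, rediscretise, remesh


@dataclass
class Params:
    """Global mechanical parameters (dimensionless)."""

    kappa: float = 0.01  # bending-to-stretching ratio sqrt(B/E)/delta_0
    omega: float = 0.05  # adhesion stiffness / cortex extensional stiffness
    delta_max: float = 4.0  # maximum adhesion binding length
    delta_gamma: float = 4.0  # identity-sensing range for contractility
    tau_adh: float = 10.0  # mean bond lifetime, units of tau_cor
    gamma0: float = 1.0 - 2e-4  # background pre-stress contraction
    mesh_spacing: float = 0.25  # target node spacing, units of delta_0
    area_stiffness: float = 0.03  # weak areal elasticity k_A (0 disables)
    tol: float = 1e-6  # max residual force at equilibrium
    max_iter: int = 2500
    kernel_mode: str = "inverse"  # binding kernel Phi weighting
    pin_factor: float = 50.0  # stiffness multiplier of boundary pins

    def validate(self) -> None:
        if self.kappa <= 0 or self.omega < 0:
            raise ValueError("kappa must be > 0 and omega >= 0")
        if self.delta_max <= 1.0:
            raise ValueError("delta_max must exceed the bond rest length 1")
        if not (0 < self.gamma0 <= 1):
            raise ValueError("gamma0 must be in (0, 1]")


@dataclass
class Wall:
    """A fixed boundary chain the tissue can adhere to."""

    points: np.ndarray  # (m, 2), ordered
    corner_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    closed: bool = True


@dataclass
class EquilibriumReport:
    converged: bool
    residual: float
    iterations: int
    energy_trace: list[float] = field(default_factory=list)


@dataclass
class Tissue:
    loops: list[CortexLoop]
    params: Params = field(default_factory=Params)
    walls: list[Wall] = field(default_factory=list)
    bonds: adhesion.BondSet = field(default_factory=adhesion.BondSet)
    time: float = 0.0

    def __post_init__(self) -> None:
        self.params.validate()
        if not self.loops:
            raise ValueError("tissue needs at least one cell")

    # -- indexing -------------------------------------------------------
    def loop_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum([lp.n for lp in self.loops])])[:-1].astype(int)

    def n_nodes(self) -> int:
        return sum(lp.n for lp in self.loops)

    def stacked_positions(self) -> np.ndarray:
        return np.concatenate([lp.x for lp in self.loops])

    def set_positions(self, x: np.ndarray) -> None:
        off = 0
        for lp in self.loops:
            lp.x = x[off : off + lp.n].copy()
            off += lp.n

    def loop_by_id(self, cell_id: int) -> CortexLoop:
        for lp in self.loops:
            if lp.cell_id == cell_id:
                return lp
        raise KeyError(f"no cell with id {cell_id}")

    def copy(self) -> "Tissue":
        return Tissue(
            loops=[lp.copy() for lp in self.loops],
            params=copy.deepcopy(self.params),
            walls=[Wall(w.points.copy(), w.corner_ids.copy(), w.closed) for w in self.walls],
            bonds=self.bonds.copy(),
            time=self.time,
        )

    # -- static assembly ------------------------------------------------
    def _assembly(self):
        """Concatenate rod and bond arrays for a single energy functional."""
        seg_a, seg_b, ref, bprev, bnext, kap2 = [], [], [], [], [], []
        soff = 0
        noff = 0
        for lp in self.loops:
            a, b = lp.seg_indices()
            seg_a.append(a + noff)
            seg_b.append(b + noff)
            ref.append(lp.ref_lengths)
            p, nx = lp.bend_indices()
            bprev.append(p + soff)
            bnext.append(nx + soff)
            kap2.append(np.full(len(nx), lp.kappa**2))
            soff += lp.nseg
            noff += lp.n
        off = self.loop_offsets()
        bs = self.bonds
        cc = bs.b_loop >= 0
        pa = off[bs.a_loop[cc]] + bs.a_node[cc]
        pb = off[bs.b_loop[cc]] + bs.b_node[cc]
        kcc = self.params.omega * bs.factor[cc]
        cw = ~cc
        wa = off[bs.a_loop[cw]] + bs.a_node[cw]
        if cw.any():
            anchors = np.array(
                [self.walls[-1 - l].points[nn] for l, nn in zip(bs.b_loop[cw], bs.b_node[cw])]
            )
        else:
            anchors = np.empty((0, 2))
        kw = self.params.omega * bs.factor[cw]
        starts = off
        counts = np.array([lp.n for lp in self.loops])
        area0 = np.array(
            [lp.area0 if lp.closed else 0.0 for lp in self.loops]
        )
        return (
            np.concatenate(seg_a),
            np.concatenate(seg_b),
            np.concatenate(ref),
            np.concatenate(bprev),
            np.concatenate(bnext),
            np.concatenate(kap2),
            pa,
            pb,
            kcc,
            wa,
            anchors,
            kw,
            starts,
            counts,
            area0,
        )


def total_energy(tissue: Tissue) -> float:
    """Total dimensionless energy: cortex elastic + adhesion + areal
    elasticity (+ pins)."""
    sa, sb, ref, bp, bn, k2, pa, pb, kcc, wa, anch, kw, st, ct, a0 = tissue._assembly()
    x = tissue.stacked_positions()
    e1, _ = mech.rod_energy_grad(x, sa, sb, ref, bp, bn, k2)
    e2, _ = mech.bond_energy_grad(x, pa, pb, kcc, tissue.params.delta_max)
    e3, _ = mech.anchor_energy_grad(x, wa, anch, kw, tissue.params.delta_max)
    e4, _ = mech.area_energy_grad(x, st, ct, a0, tissue.params.area_stiffness)
    return e1 + e2 + e3 + e4


def residual_force(tissue: Tissue) -> float:
    """Max per-node net force magnitude (internal + adhesion + boundary)."""
    sa, sb, ref, bp, bn, k2, pa, pb, kcc, wa, anch, kw, st, ct, a0 = tissue._assembly()
    x = tissue.stacked_positions()
    _, g1 = mech.rod_energy_grad(x, sa, sb, ref, bp, bn, k2)
    _, g2 = mech.bond_energy_grad(x, pa, pb, kcc, tissue.params.delta_max)
    _, g3 = mech.anchor_energy_grad(x, wa, anch, kw, tissue.params.delta_max)
    _, g4 = mech.area_energy_grad(x, st, ct, a0, tissue.params.area_stiffness)
    g = g1 + g2 + g3 + g4
    return float(np.hypot(g[:, 0], g[:, 1]).max())


def equilibrate(tissue: Tissue, tol: float | None = None, max_iter: int | None = None) -> EquilibriumReport:
    """Minimise total energy over node positions (bonds, rest lengths frozen).

    Quasi-static force balance: at convergence every node's net force
    (internal cortical force + adhesion + boundary) is below ``tol``.  Uses
    L-BFGS on the assembled energy; the energy trace is non-increasing.
    """
    tol = tissue.params.tol if tol is None else tol
    if tol <= 0:
        raise ValueError("tol must be positive")
    max_iter = tissue.params.max_iter if max_iter is None else max_iter
    sa, sb, ref, bp, bn, k2, pa, pb, kcc, wa, anch, kw, st, ct, a0 = tissue._assembly()
    ka = tissue.params.area_stiffness
    dmax = tissue.params.delta_max
    x0 = tissue.stacked_positions()
    nn = len(x0)
    trace: list[float] = []
    last_f = [np.inf]

    def fg(xf):
        x = xf.reshape(nn, 2)
        e1, g1 = mech.rod_energy_grad(x, sa, sb, ref, bp, bn, k2)
        e2, g2 = mech.bond_energy_grad(x, pa, pb, kcc, dmax)
        e3, g3 = mech.anchor_energy_grad(x, wa, anch, kw, dmax)
        e4, g4 = mech.area_energy_grad(x, st, ct, a0, ka)
        last_f[0] = e1 + e2 + e3 + e4
        return last_f[0], (g1 + g2 + g3 + g4).ravel()

    def cb(_xk):
        trace.append(last_f[0])

    # already at force balance: nothing to do
    f0, g0 = fg(x0.ravel())
    r0 = float(np.hypot(*g0.reshape(nn, 2).T).max())
    if r0 <= tol:
        return EquilibriumReport(True, r0, 0, [f0])

    res = minimize(
        fg,
        x0.ravel(),
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": max_iter, "gtol": 0.5 * tol, "ftol": 1e-15, "maxcor": 12},
    )
    x = res.x.reshape(nn, 2)
    tissue.set_positions(x)
    _, g = fg(res.x)
    resid = float(np.hypot(*g.reshape(nn, 2).T).max())
    return EquilibriumReport(
        converged=resid <= tol,
        residual=resid,
        iterations=int(res.nit),
        energy_trace=trace,
    )


def viscoelastic_step(tissue: Tissue) -> Tissue:
    """Relax all residual elastic stress (viscoelastic-fluid limit).

    Every undeformed segment length is updated to the current length and
    the active field is reset to 1; the protocol re-imposes its gamma field
    at the start of the next step, so sustained activity holds a steady
    strain (1-gamma)/gamma while transient stress relaxes completely within
    one cortical turnover time.  Advances the clock by one tau_cor.
    """
    for lp in tissue.loops:
        lp.lhat = lp.seg_lengths()
        lp.gamma = np.ones(lp.nseg)
    tissue.time += 1.0
    return tissue


def remesh_tissue(tissue: Tissue, target: float | None = None) -> None:
    """Remesh every loop and re-attach bond endpoints to surviving nodes."""
    target = tissue.params.mesh_spacing if target is None else target
    for i, lp in enumerate(tissue.loops):
        new, node_map = remesh(lp, target)
        if new.n == lp.n and np.array_equal(node_map, np.arange(lp.n)):
            continue
        tissue.loops[i] = new
        b = tissue.bonds
        ma = b.a_loop == i
        b.a_node[ma] = node_map[b.a_node[ma]]
        mb = b.b_loop == i
        b.b_node[mb] = node_map[b.b_node[mb]]


def rediscretise_tissue(tissue: Tissue, target: float | None = None,
                        smooth_sigma: float = 0.5) -> None:
    """Resample every loop on uniform arclength; re-attach bonds by label.

    Bond endpoints are material points: after resampling they move to the
    node whose material label is (cyclically) closest to the old one.
    """
    target = tissue.params.mesh_spacing if target is None else target
    for i, lp in enumerate(tissue.loops):
        if not lp.closed:
            continue
        old_labels = lp.labels
        new = rediscretise(lp, target, smooth_sigma)
        tissue.loops[i] = new
        b = tissue.bonds
        per = new.label_period
        # sorted new labels for fast cyclic nearest-label lookup
        order = np.argsort(new.labels)
        slab = new.labels[order]

        def remap(nodes):
            lab = old_labels[nodes] % per
            pos = np.searchsorted(slab, lab)
            cand = np.stack([(pos - 1) % len(slab), pos % len(slab)], axis=1)
            dd = np.abs(slab[cand] - lab[:, None])
            dd = np.minimum(dd, per - dd)
            best = cand[np.arange(len(lab)), np.argmin(dd, axis=1)]
            return order[best]

        ma = b.a_loop == i
        if ma.any():
            b.a_node[ma] = remap(b.a_node[ma])
        mb = b.b_loop == i
        if mb.any():
            b.b_node[mb] = remap(b.b_node[mb])


@dataclass
class FractureEvent:
    kind: str  # "vertex" or "junction"
    where: tuple  # member cells of the vertex, or the ruptured pair
    value: float  # opening radius or minimum inter-cortex distance


def detect_fracture(
    tissue: Tissue,
    junction_map=None,
    reference_pairs: set[frozenset] | None = None,
    check_vertices: bool = True,
) -> FractureEvent | None:
    """Report tissue fracture, if any.

    Two modes of failure are distinguished: a *vertex* fracture, where the
    opening at a vertex has been forced beyond the maximum binding length
    ``delta_max`` (no bonds can span it), and a mid-*junction* rupture,
    where a formerly adhered interface carries no bonds and no candidate
    pairs remain within ``delta_max``.  Returns None for an intact tissue;
    a fractured interface whose cortices re-enter range is re-adhered by
    the normal binding dynamics (repair).
    """
    from . import observables as obs

    if junction_map is None:
        junction_map = obs.detect_junctions(tissue)
    dmax = tissue.params.delta_max

    if reference_pairs:
        current = {j.pair for j in junction_map.junctions}
        for pair in reference_pairs:
            if pair in current:
                continue
            ids = sorted(pair)
            la = tissue.loop_by_id(ids[0])
            lb = tissue.loop_by_id(ids[1])
            dmin = obs.min_ring_distance(la, lb)
            if dmin > dmax:
                return FractureEvent("junction", tuple(ids), dmin)

    if check_vertices:
        for v in junction_map.vertices:
            r = obs.vertex_opening(tissue, v)
            if r > dmax:
                return FractureEvent("vertex", tuple(sorted(v.cells)), r)
    return None


@dataclass
class SimulationTrace:
    """Per-step observables, snapshots and the bond event log."""

    observables: "object" = None  # pandas DataFrame, built at the end
    snapshots: list = field(default_factory=list)  # (step, Tissue copy)
    events: list = field(default_factory=list)  # (step, kind, payload)
    junction_maps: list = field(default_factory=list)  # (step, JunctionMap)


def simulate(
    tissue: Tissue,
    protocol,
    n_steps: int,
    seed: int = 0,
    snapshot_every: int = 0,
    remesh_every: int = 1,
    observer=None,
    stop_when=None,
) -> SimulationTrace:
    """Run the quasi-static simulation loop.

    Per step (one tau_cor): protocol update -> bond turnover/spawning (or
    mean-field rebuild when ``tau_adh < 1``) -> energy minimisation ->
    observables -> viscoelastic rest-length relaxation and remeshing.
    Deterministic for a fixed (tissue, protocol, seed).

    ``observer(tissue, step, jmap, report)`` may append extra columns to the
    per-step record by returning a dict; ``stop_when(tissue, step, jmap)``
    can terminate the run early.
    """
    import pandas as pd

    from . import observables as obs

    rng = np.random.default_rng(seed)
    mean_field = tissue.params.tau_adh < 1.0
    trace = SimulationTrace()
    rows = []
    jmap = obs.detect_junctions(tissue)

    for step in range(n_steps):
        if protocol is not None:
            protocol.apply(tissue, step, jmap)
        if mean_field:
            adhesion.resample_bonds(tissue, rng)
        else:
            removed = adhesion.turnover_step(tissue, 1.0, rng)
            added = adhesion.spawn_bonds(tissue, rng)
            if removed or added:
                trace.events.append((step, "bonds", {"removed": removed, "added": added}))
        report = equilibrate(tissue)
        if not report.converged and report.residual > 100 * tissue.params.tol:
            raise RuntimeError(
                f"equilibration failed at step {step}: residual {report.residual:.3g}"
            )
        jmap = obs.detect_junctions(tissue)
        row = {
            "step": step,
            "time": tissue.time,
            "energy": total_energy(tissue),
            "residual": report.residual,
            "n_bonds": len(tissue.bonds),
            "signed_t1": obs.signed_t1_length(jmap),
        }
        for lp in tissue.loops:
            row[f"area_{lp.cell_id}"] = lp.area()
        if observer is not None:
            extra = observer(tissue, step, jmap, report)
            if extra:
                row.update(extra)
        rows.append(row)
        if snapshot_every and step % snapshot_every == 0:
            trace.snapshots.append((step, tissue.copy()))
            trace.junction_maps.append((step, jmap))
        if stop_when is not None and stop_when(tissue, step, jmap):
            break
        viscoelastic_step(tissue)
        if remesh_every and (step + 1) % remesh_every == 0:
            rediscretise_tissue(tissue)

    trace.observables = pd.DataFrame(rows)
    return trace


def settle(tissue: Tissue, max_cycles: int = 200, length_tol: float = 1e-4,
           mean_field: bool = True, rng: np.random.Generator | None = None,
           beta: float = 0.5, do_remesh: bool = True) -> int:
    """Recurrent relaxation to the rest-length fixed point (static problems).

    Alternates equilibration and viscoelastic rest-length updates until the
    total cortex length changes by less than ``length_tol`` per cycle (the
    termination criterion used for the vertex-geometry map).  Uses the
    deterministic instantaneous nearest-partner rebinding unless a
    stochastic rng is supplied.  ``beta`` under-relaxes the rest-length
    update (lhat <- lhat + beta*(d - lhat)): same fixed point, damped
    approach.  Returns the number of cycles used.
    """
    gamma_fields = {lp.cell_id: lp.gamma.copy() for lp in tissue.loops}
    prev_len = sum(lp.perimeter() for lp in tissue.loops)
    for cycle in range(max_cycles):
        if mean_field:
            adhesion.rebind_nearest(tissue)
        else:
            adhesion.turnover_step(tissue, 1.0, rng)
            adhesion.spawn_bonds(tissue, rng)
            tissue.time += 1.0
        equilibrate(tissue)
        cur_len = sum(lp.perimeter() for lp in tissue.loops)
        done = abs(cur_len - prev_len) < length_tol
        prev_len = cur_len
        for lp in tissue.loops:
            lp.lhat = lp.lhat + beta * (lp.seg_lengths() - lp.lhat)
            lp.gamma = gamma_fields[lp.cell_id].copy()  # sustained activity
        if done:
            return cycle + 1
        if do_remesh and (cycle + 1) % 5 == 0:
            rediscretise_tissue(tissue)
            gamma_fields = {
                lp.cell_id: np.full(lp.nseg, np.median(gamma_fields[lp.cell_id]))
                for lp in tissue.loops
            }
    return max_cycles
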