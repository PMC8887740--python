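"""Drivers for the reference experiments (vertex map, fracture, T1, rosette).

These functions wire fixtures, protocols and the solver together into the
standard computational experiments, at desk scale.  Static (fixed-point)
calculations use the deterministic instantaneous-rebinding adhesion route;
dynamic runs use the agent-based bond scheme with a seeded generator.  The
default problem sizes (cell edge 8 rest lengths, node spacing 0.4 for
dynamics; finer meshes for statics) are chosen so a full neighbour
exchange runs in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from . import factory, observables as obs, protocols
from .tissue import Tissue, settle, simulate

#: junction length below which a bonded run counts as part of a vertex
L_MIN = obs.MIN_JUNCTION_LENGTH


# ---------------------------------------------------------------------------
# vertex geometry (single cell in a hexagonal wall)
# ---------------------------------------------------------------------------


def hexagon_vertex_openings(tissue: Tissue) -> np.ndarray:
    """Inscribed-circle radius of the opening at every wall corner, plus a
    global maximal-inscribed-circle cross-check (last entry)."""
    wall = tissue.walls[0]
    out = [
        obs.vertex_opening(tissue, wall.points[cid], members=[1, -1])
        for cid in wall.corner_ids
    ]
    cell = shapely.make_valid(obs.cell_polygon(tissue.loops[0]))
    region = Polygon(wall.points).difference(cell)
    mic = shapely.maximum_inscribed_circle(region, tolerance=1e-4)
    out.append(mic.length)
    return np.array(out)


def vertex_opening_single_cell(
    kappa: float = 0.01,
    omega: float = 0.05,
    mesh: float = 0.15,
    side: float = 10.0,
    n_ramp: int = 5,
    max_cycles: int = 200,
) -> float:
    """Equilibrium vertex opening delta_vert for one cell in a hexagon.

    The adhesion strength is increased quasi-statically from ~0 to omega,
    then the cell is recurrently relaxed (equilibration + rest-length
    update) until the cortex length change per cycle falls below 1e-4.
    Returns the mean opening radius over the six wall corners, in units of
    the adhesion rest length.  Deterministic.
    """
    t = factory.single_cell_in_hexagon(kappa, omega, mesh=mesh, side=side)
    for w in np.geomspace(omega / 2 ** (n_ramp - 1), omega, n_ramp):
        t.params.omega = float(w)
        settle(t, max_cycles=20, length_tol=1e-3)
    t.params.omega = omega
    settle(t, max_cycles=max_cycles, length_tol=1e-4)
    radii = hexagon_vertex_openings(t)
    return float(np.mean(radii[:6]))


def vertex_map(kappas, omegas, mesh: float = 0.2, side: float = 10.0) -> np.ndarray:
    """delta_vert over a (kappa, omega) grid (the vertex-geometry map)."""
    out = np.zeros((len(kappas), len(omegas)))
    for i, k in enumerate(kappas):
        for j, w in enumerate(omegas):
            out[i, j] = vertex_opening_single_cell(k, w, mesh=mesh, side=side)
    return out


def isoline_openings(
    kappa2_over_omega: float = 0.002,
    omegas=(0.025, 0.05, 0.1),
    mesh: float = 0.2,
) -> list[tuple[float, float, float]]:
    """(kappa, omega, delta_vert) samples along a kappa^2/omega isoline."""
    out = []
    for w in omegas:
        k = float(np.sqrt(kappa2_over_omega * w))
        out.append((k, w, vertex_opening_single_cell(k, w, mesh=mesh)))
    return out


# ---------------------------------------------------------------------------
# uniform-contractility fracture (3-cell tissue)
# ---------------------------------------------------------------------------


@dataclass
class FractureScan:
    gamma_crit: float | None
    gammas: list = field(default_factory=list)
    openings: list = field(default_factory=list)
    kind: str | None = None


def fracture_gamma_three_cell(
    kappa: float = 0.01,
    omega: float = 0.05,
    gamma_step: float = 0.005,
    gamma_floor: float = 0.85,
    edge: float = 6.0,
    mesh: float = 0.25,
    cycles_per_gamma: int = 4,
) -> FractureScan:
    """Quasi-static whole-cortex contractility ramp until first fracture.

    gamma decreases from 1 in small increments on all three cortices; the
    tissue is recurrently relaxed between increments.  Fracture is
    detected when the interior vertex opening exceeds delta_max, when any
    formerly adhered interface separates beyond delta_max, or when the
    interior 3-way vertex disappears (vertex blow-open).  Deterministic
    (instantaneous nearest-partner rebinding).
    """
    t = factory.three_cell_tissue(kappa, omega, edge=edge, mesh=mesh, pinned=False)
    for lp in t.loops:
        lp.gamma[:] = t.params.gamma0
    settle(t, max_cycles=12, length_tol=1e-4)
    cen = np.mean([lp.centroid() for lp in t.loops], axis=0)
    scan = FractureScan(None)
    g = 1.0
    while g > gamma_floor:
        for lp in t.loops:
            lp.gamma[:] = g
        settle(t, max_cycles=cycles_per_gamma, length_tol=1e-5)
        jmap = obs.detect_junctions(t, min_length=1.0)
        v3 = [v for v in jmap.vertices if len([c for c in v.cells if c >= 0]) >= 3]
        if v3:
            vi = min(v3, key=lambda v: float(np.hypot(*(v.position - cen))))
            opening = obs.vertex_opening(t, vi)
        else:
            opening = np.nan
        scan.gammas.append(g)
        scan.openings.append(opening)
        ruptured = any(
            obs.min_ring_distance(t.loop_by_id(a), t.loop_by_id(b)) > t.params.delta_max
            for a, b in [(1, 2), (1, 3), (2, 3)]
        )
        if ruptured or not v3 or opening > t.params.delta_max:
            scan.gamma_crit = g
            scan.kind = "junction" if ruptured else "vertex"
            return scan
        g = round(g - gamma_step, 10)
    return scan


# ---------------------------------------------------------------------------
# T1 / neighbour-exchange runs (14-cell fixture)
# ---------------------------------------------------------------------------


def prepared_fourteen_cell(
    kappa: float = 0.01,
    omega: float = 0.05,
    tau_adh: float = 10.0,
    gamma0: float = 1.0 - 2e-4,
    edge: float = 8.0,
    mesh: float = 0.4,
    seed: int = 0,
    settle_cycles: int = 12,
    **params,
) -> Tissue:
    """Build and passively settle the 14-cell fixture under gamma0."""
    params.setdefault("tol", 1e-4)
    t = factory.fourteen_cell_tissue(
        kappa, omega, gamma0=gamma0, edge=edge, mesh=mesh, tau_adh=tau_adh, **params
    )
    for lp in t.loops:
        lp.gamma[:] = gamma0
    if tau_adh < 1.0:
        settle(t, max_cycles=settle_cycles, length_tol=1e-4)
    else:
        rng = np.random.default_rng(seed)
        settle(t, max_cycles=settle_cycles, length_tol=1e-4, mean_field=False, rng=rng)
    return t


def _t1_observer(tissue0):
    areas0 = {lp.cell_id: abs(lp.area()) for lp in tissue0.loops}
    a12_0 = areas0[1] + areas0[2]

    def observer(tis, step, jmap, rep):
        j12, j34 = jmap.get(1, 2), jmap.get(3, 4)
        return {
            "L12": j12.length if j12 else 0.0,
            "L34": j34.length if j34 else 0.0,
            "A12": (abs(tis.loop_by_id(1).area()) + abs(tis.loop_by_id(2).area())) / a12_0,
        }

    return observer


def run_t1(
    tissue: Tissue | None = None,
    gamma_active: float = 0.94,
    tau_adh: float = 10.0,
    n_steps: int = 150,
    seed: int = 0,
    snapshot_every: int = 10,
    protocol=None,
    stop_when=None,
    **fixture_kw,
):
    """The standard neighbour-exchange run: contract junction {1, 2}.

    Records per step the junction lengths L12/L34 and the mean area of
    cells 1 & 2 normalised to the settled fixture ('A12').
    """
    if tissue is None:
        tissue = prepared_fourteen_cell(tau_adh=tau_adh, seed=seed, **fixture_kw)
    if protocol is None:
        protocol = protocols.JunctionContractility((1, 2), gamma_active)
    trace = simulate(
        tissue,
        protocol,
        n_steps,
        seed=seed + 1,
        snapshot_every=snapshot_every,
        observer=_t1_observer(tissue),
        stop_when=stop_when,
    )
    return tissue, trace


def t1_area_loss(
    tau_adh: float = 10.0,
    seed: int = 0,
    n_steps: int = 120,
    **fixture_kw,
) -> dict:
    """Minimum normalised mean area of cells 1 & 2 during a T1.

    Returns the minimum of the per-step normalised area (the transient
    area loss the intercalating pair suffers while their shared junction
    is removed), plus the trace for inspection.
    """
    tissue, trace = run_t1(tau_adh=tau_adh, seed=seed, n_steps=n_steps, **fixture_kw)
    df = trace.observables
    return {
        "min_norm_area": float(df["A12"].min()),
        "loss_percent": 100.0 * (1.0 - float(df["A12"].min())),
        "trace": trace,
        "tissue": tissue,
    }


def extension_angles(tissue, jmap=None) -> list[float]:
    """Internal angles between the {3,4} junction and its neighbours."""
    if jmap is None:
        jmap = obs.detect_junctions(tissue)
    return obs.junction_vertex_angles(tissue, jmap, (3, 4))


def stall_run(
    seed: int = 0,
    n_stall: int = 1000,
    gamma_active: float = 0.94,
    tau_adh: float = 10.0,
    max_prep_steps: int = 80,
    **fixture_kw,
) -> dict:
    """Remove contractility at the unresolved 4-way and count stalled steps.

    Runs the standard T1 until junction {1,2} has shrunk to zero length
    but {3,4} has not yet formed, then sets gamma back to gamma0
    everywhere and keeps stepping.  Returns the number of consecutive
    steps for which neither {1,2} nor {3,4} exists in the junction map.
    """
    tissue = prepared_fourteen_cell(tau_adh=tau_adh, seed=seed, **fixture_kw)

    def at_four_way(tis, step, jmap):
        # require the {1,2} junction to have truly collapsed (not merely
        # dipped under the junction-length threshold) and no {3,4} yet
        fine = obs.detect_junctions(tis, min_length=0.5)
        j12 = fine.get(1, 2)
        return (j12 is None or j12.length < 1.0) and not jmap.has(3, 4)

    tissue, trace = run_t1(
        tissue=tissue, gamma_active=gamma_active, tau_adh=tau_adh,
        n_steps=max_prep_steps, seed=seed, stop_when=at_four_way,
    )
    prep_steps = len(trace.observables)
    background = protocols.BackgroundTension(tissue.params.gamma0)
    count = [0]
    streak = [0]  # consecutive steps with a (re-)formed junction

    def stop(tis, step, jmap):
        count[0] += 1
        if not jmap.has(1, 2) and not jmap.has(3, 4):
            streak[0] = 0
            return False
        # brief threshold flickers of the junction map are not resolution;
        # a junction persisting many consecutive steps is
        streak[0] += 1
        return streak[0] >= 10

    trace2 = simulate(tissue, background, n_stall, seed=seed + 2, stop_when=stop)
    # stalled duration: steps until a junction persisted (or window end)
    stalled = count[0] - (streak[0] if streak[0] >= 10 else 0)
    return {
        "stalled_steps": stalled,
        "prep_steps": prep_steps,
        "tissue": tissue,
        "trace": trace2,
    }


def t1_until_new_junction(
    seed: int = 0,
    gamma_active: float = 0.94,
    n_first: int = 170,
    **fixture_kw,
) -> Tissue:
    """Run the standard T1 and stop just as the {3,4} junction has formed."""
    tissue = prepared_fourteen_cell(tau_adh=10.0, seed=seed, **fixture_kw)

    def trigger(tis, step, jmap):
        return jmap.has(3, 4)

    tissue, _ = run_t1(
        tissue=tissue, gamma_active=gamma_active, n_steps=n_first,
        seed=seed, stop_when=trigger,
    )
    return tissue


def second_exchange(
    tissue: Tissue,
    tau_adh: float,
    seed: int = 0,
    gamma_active: float = 0.94,
    n_steps: int = 150,
) -> dict:
    """Contract the {1,3} junction of a freshly resolved T1 state.

    With fast turnover the second exchange completes (a new junction forms
    between the cells flanking {1,3}, i.e. 4 and 7); with slow turnover
    (high friction mu_adh = omega*tau_adh) the extension of the young
    {3,4} junction cannot keep up, its vertices are dragged together and
    merge into a rosette — a vertex shared by five cells.

    Returns outcome ('exchange' | 'rosette' | 'unresolved') and the
    maximal member-cell count over vertices involving the active cells.
    """
    tissue.params.tau_adh = tau_adh
    second = protocols.JunctionContractility((1, 3), gamma_active)
    best = {"n_cells": 0, "outcome": "unresolved", "step": None}

    def watch(tis, step, jmap):
        # a rosette exists when the young vertices have merged: no {1,3},
        # no {3,4} junction remains and >= 5 cells share one vertex cluster
        merged = not jmap.has(1, 3) and not jmap.has(3, 4) and not jmap.has(1, 2)
        if merged:
            for v in jmap.vertices:
                cells = {c for c in v.cells if c >= 0}
                if {3, 4} <= cells and len(cells) > best["n_cells"]:
                    best["n_cells"] = len(cells)
                    best["step"] = step
        if best["n_cells"] >= 5:
            best["outcome"] = "rosette"
            return True
        # second exchange: the cells flanking {1,3} (4 and 7) join up
        if jmap.has(4, 7) and not jmap.has(1, 3):
            best["outcome"] = "exchange"
            return True
        return False

    trace = simulate(tissue, second, n_steps, seed=seed + 3, stop_when=watch)
    jmap = obs.detect_junctions(tissue)
    return {
        "outcome": best["outcome"],
        "n_cells_at_vertex": best["n_cells"],
        "tissue": tissue,
        "jmap": jmap,
        "trace_second": trace,
    }


def sequential_run(
    tau_adh_second: float = 100.0,
    seed: int = 0,
    gamma_active: float = 0.94,
    n_first: int = 170,
    n_second: int = 150,
    **fixture_kw,
) -> dict:
    """Sequential contraction: {1,2} T1 to resolution, then contract {1,3}."""
    tissue = t1_until_new_junction(
        seed=seed, gamma_active=gamma_active, n_first=n_first, **fixture_kw
    )
    return second_exchange(
        tissue, tau_adh_second, seed=seed, gamma_active=gamma_active,
        n_steps=n_second,
    )


def delta_max_rupture_scan(
    values=(2.0, 3.0, 4.0, 6.0),
    seed: int = 0,
    delta_gamma: float = 4.0,
    gamma_active: float = 0.94,
    tau_adh: float = 10.0,
    n_steps: int = 60,
    **fixture_kw,
) -> dict:
    """Scan delta_max for mid-junction rupture of the shrinking {1,2}.

    The sensing range delta_gamma is held fixed (default 4) while the
    maximum binding length varies.  A rupture is recorded when the {1,2}
    junction disappears while the two cortices have separated beyond
    delta_max before any new {3,4} junction exists.  Returns per-value
    outcomes and the largest delta_max at which the junction ruptured.
    """
    outcomes = {}
    for dmax in values:
        tissue = prepared_fourteen_cell(
            tau_adh=tau_adh, seed=seed, delta_max=dmax, delta_gamma=delta_gamma,
            **fixture_kw,
        )
        state = {"ruptured": False}

        def stop(tis, step, jmap, state=state, dmax=dmax):
            if jmap.has(3, 4):
                return True  # exchange proceeding normally
            if not jmap.has(1, 2):
                d12 = obs.min_ring_distance(tis.loop_by_id(1), tis.loop_by_id(2))
                if d12 > dmax:
                    state["ruptured"] = True
                    return True
            return False

        run_t1(
            tissue=tissue, gamma_active=gamma_active, tau_adh=tau_adh,
            n_steps=n_steps, seed=seed, stop_when=stop,
        )
        outcomes[dmax] = "rupture" if state["ruptured"] else "intact"
    ruptured = [d for d, o in outcomes.items() if o == "rupture"]
    return {
        "outcomes": outcomes,
        "largest_rupturing": max(ruptured) if ruptured else None,
    }
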