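"""Derived measurements: junction topology, vertex openings, tensions.

A *vertex* here is the geometric point where three or more cells' cortices
approach each other — not a material point: cortical material can flow
past it.  A *bicellular junction* is a maximal contiguous run of adhesion
bonds between the cortices of exactly two cells; bonded runs shorter than
the vertex-opening scale are treated as part of a vertex (bonds legitimately
form across an open vertex, so raw bond topology alone cannot distinguish
a short junction from a vertex).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.optimize import minimize
from shapely.geometry import LineString, Point, Polygon

from .cortex import CortexLoop, segment_geometry

#: bonded runs shorter than this arc length (units of delta_0) belong to a
#: vertex, not a junction
MIN_JUNCTION_LENGTH = 2.0
#: vertex candidates closer than this are clustered into one vertex
VERTEX_CLUSTER_RADIUS = 2.0


def ring(loop: CortexLoop) -> LineString:
    """Closed shapely polyline of the cortex."""
    pts = np.vstack([loop.x, loop.x[:1]]) if loop.closed else loop.x
    return LineString(pts)


def cell_polygon(loop: CortexLoop) -> Polygon:
    return Polygon(loop.x)


def cell_area(loop: CortexLoop) -> float:
    """Enclosed cell area (shoelace), translation invariant."""
    return abs(loop.area())


def cell_perimeter(loop: CortexLoop) -> float:
    return loop.perimeter()


def cortical_tension(loop: CortexLoop) -> np.ndarray:
    """Per-segment tension T = eps = alpha - 1 (tangential internal force)."""
    return segment_geometry(loop)["eps"]


def min_ring_distance(la: CortexLoop, lb: CortexLoop) -> float:
    return float(ring(la).distance(ring(lb)))


@dataclass
class Junction:
    """A bicellular junction: contiguous bonded interval between two cells."""

    pair: frozenset
    nodes: dict  # cell_id -> np.ndarray of bonded node indices (cyclic run)
    length: float  # arc length of the bonded interval midline
    side_lengths: dict  # cell_id -> arc length on that cortex


@dataclass
class Vertex:
    """Geometric meeting point of >= 3 cells (rosette when >= 5)."""

    cells: frozenset
    position: np.ndarray
    candidates: list = field(default_factory=list)

    @property
    def is_rosette(self) -> bool:
        return len([c for c in self.cells if c >= 0]) >= 5


@dataclass
class JunctionMap:
    junctions: list
    vertices: list

    def get(self, a: int, b: int):
        pair = frozenset((a, b))
        for j in self.junctions:
            if j.pair == pair:
                return j
        return None

    def has(self, a: int, b: int) -> bool:
        return self.get(a, b) is not None

    def pairs(self) -> set:
        return {j.pair for j in self.junctions}


def _cyclic_runs(flags: np.ndarray) -> list[np.ndarray]:
    """Maximal cyclic runs of True indices."""
    n = len(flags)
    if flags.all():
        return [np.arange(n)]
    if not flags.any():
        return []
    # rotate so position 0 is False, then find contiguous blocks
    start = int(np.argmin(flags))
    rolled = np.roll(flags, -start)
    idx = np.where(rolled)[0]
    runs = []
    block = [idx[0]]
    for k in idx[1:]:
        if k == block[-1] + 1:
            block.append(k)
        else:
            runs.append(block)
            block = [k]
    runs.append(block)
    return [np.array([(k + start) % n for k in b]) for b in runs]


def _arc_length(loop: CortexLoop, nodes: np.ndarray) -> float:
    d = loop.seg_lengths()
    if len(nodes) < 2:
        return 0.0
    # nodes are cyclically consecutive; sum segment lengths between them
    return float(sum(d[nodes[k] % loop.nseg] for k in range(len(nodes) - 1)))


def detect_junctions(
    tissue,
    min_length: float = MIN_JUNCTION_LENGTH,
    gap_tol: int = 2,
    cluster_radius: float = VERTEX_CLUSTER_RADIUS,
) -> JunctionMap:
    """Build the junction/vertex map from the live bond set.

    Per cortex, each node is labelled by its (nearest-bond) partner cell;
    maximal cyclic runs of a common partner, merged across unbonded gaps of
    up to ``gap_tol`` nodes, define junction intervals.  Intervals of arc
    length >= ``min_length`` on either side become junctions; transitions
    between intervals and sub-threshold runs contribute vertex candidates,
    clustered within ``cluster_radius`` into vertices.  Deterministic for a
    given snapshot.
    """
    loops = tissue.loops
    idx_of_cell = {lp.cell_id: i for i, lp in enumerate(loops)}
    b = tissue.bonds

    # partner cell id per node (by nearest bond); -10**9 marks unbonded
    NONE = -(10**9)
    off = tissue.loop_offsets()
    n_tot = tissue.n_nodes()
    pflat = np.full(n_tot, NONE)

    if len(b):
        x_all = tissue.stacked_positions()
        cc = b.b_loop >= 0
        ga = off[b.a_loop] + b.a_node
        xa = x_all[ga]
        xb = np.empty((len(b), 2))
        if cc.any():
            xb[cc] = x_all[off[b.b_loop[cc]] + b.b_node[cc]]
        if (~cc).any():
            idx = np.where(~cc)[0]
            xb[idx] = np.array(
                [tissue.walls[-1 - b.b_loop[k]].points[b.b_node[k]] for k in idx]
            )
        delta = np.hypot(*(xb - xa).T)
        cell_ids = np.array([lp.cell_id for lp in loops])
        part_a = np.where(cc, cell_ids[np.where(cc, b.b_loop, 0)], b.b_loop)
        nodes = np.concatenate([ga, off[b.b_loop[cc]] + b.b_node[cc]])
        parts = np.concatenate([part_a, cell_ids[b.a_loop[cc]]])
        dels = np.concatenate([delta, delta[cc]])
        ok = dels <= tissue.params.delta_max
        nodes, parts, dels = nodes[ok], parts[ok], dels[ok]
        order = np.argsort(-dels)  # nearest bond written last wins
        pflat[nodes[order]] = parts[order]

    partner = [pflat[off[i] : off[i] + lp.n] for i, lp in enumerate(loops)]

    # merge unbonded gaps of <= gap_tol nodes flanked by the same partner
    for i, lp in enumerate(loops):
        p = partner[i]
        n = len(p)
        if gap_tol > 0 and n:
            gaps = _cyclic_runs(p == NONE)
            for gap in gaps:
                if len(gap) <= gap_tol:
                    before = p[(gap[0] - 1) % n]
                    after = p[(gap[-1] + 1) % n]
                    if before == after and before != NONE:
                        p[gap] = before

    # junction intervals per (cell pair): runs on each side
    runs_by_pair: dict[frozenset, dict[int, list[np.ndarray]]] = {}
    interval_seq: dict[int, list[tuple[np.ndarray, int]]] = {}
    for i, lp in enumerate(loops):
        p = partner[i]
        seq = []
        for other in np.unique(p[p != NONE]):
            for run in _cyclic_runs(p == other):
                seq.append((run, int(other)))
                pair = frozenset((lp.cell_id, int(other)))
                runs_by_pair.setdefault(pair, {}).setdefault(lp.cell_id, []).append(run)
        seq.sort(key=lambda t: t[0][0])
        interval_seq[i] = seq

    junctions = []
    candidates = []  # (position, cell set)
    for pair, sides in runs_by_pair.items():
        ids = sorted(pair)
        if ids[0] < 0 and ids[1] < 0:
            continue
        side_nodes = {}
        side_len = {}
        for cid, runs in sides.items():
            lp = loops[idx_of_cell[cid]]
            longest = max(runs, key=lambda r: _arc_length(lp, r))
            side_nodes[cid] = longest
            side_len[cid] = _arc_length(lp, longest)
        length = float(np.mean(list(side_len.values())))
        if length >= min_length:
            junctions.append(Junction(pair, side_nodes, length, side_len))
        else:
            for cid, run in side_nodes.items():
                lp = loops[idx_of_cell[cid]]
                pos = lp.x[run[len(run) // 2]]
                candidates.append((pos, set(pair)))

    # vertex candidates at partner transitions along each cortex
    for i, lp in enumerate(loops):
        seq = interval_seq[i]
        if len(seq) < 2:
            continue
        for k in range(len(seq)):
            run1, p1 = seq[k]
            run2, p2 = seq[(k + 1) % len(seq)]
            if p1 == p2:
                continue
            a = lp.x[run1[-1]]
            c = lp.x[run2[0]]
            candidates.append((0.5 * (a + c), {lp.cell_id, p1, p2}))

    # cluster candidates into vertices (union-find on proximity)
    m = len(candidates)
    parent = list(range(m))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(m):
        for c in range(a + 1, m):
            if np.hypot(*(candidates[a][0] - candidates[c][0])) <= cluster_radius:
                ra, rc = find(a), find(c)
                if ra != rc:
                    parent[ra] = rc

    groups: dict[int, list[int]] = {}
    for a in range(m):
        groups.setdefault(find(a), []).append(a)
    vertices = []
    for members in groups.values():
        # refine against single-linkage chaining: keep only candidates
        # within the cluster radius of the (re-estimated) centroid
        sel = list(members)
        for _ in range(2):
            pos = np.mean([candidates[k][0] for k in sel], axis=0)
            kept = [
                k for k in sel
                if np.hypot(*(candidates[k][0] - pos)) <= cluster_radius
            ]
            if kept:
                sel = kept
        cells = set()
        for k in sel:
            cells |= candidates[k][1]
        if len(cells) >= 3:
            pos = np.mean([candidates[k][0] for k in sel], axis=0)
            vertices.append(Vertex(frozenset(cells), pos, [candidates[k] for k in sel]))

    return JunctionMap(junctions, vertices)


def vertex_opening(tissue, vertex: Vertex | np.ndarray, members=None) -> float:
    """Radius of the largest circle inscribed in the cortex-free opening.

    Maximises the minimum distance to the member cortices (and walls) over
    the circle centre, starting from the vertex position; centres falling
    inside a member cell are rejected.  This is the dashed-circle
    construction used to read the vertex size off simulation snapshots.
    """
    if isinstance(vertex, Vertex):
        start = np.asarray(vertex.position, dtype=float)
        members = vertex.cells
    else:
        start = np.asarray(vertex, dtype=float)
        if members is None:
            members = [lp.cell_id for lp in tissue.loops]

    geoms = []
    polys = []
    wall_polys = []
    for m in members:
        if m >= 0:
            lp = tissue.loop_by_id(m)
            geoms.append(ring(lp))
            polys.append(cell_polygon(lp))
        else:
            wall = tissue.walls[-1 - m]
            pts = np.vstack([wall.points, wall.points[:1]]) if wall.closed else wall.points
            geoms.append(LineString(pts))
            if wall.closed:
                wall_polys.append(Polygon(wall.points))

    bound = 2.0 * tissue.params.delta_max

    def neg_clearance(c):
        drift = np.hypot(*(c - start))
        if drift > bound:
            return drift  # keep the search local to the vertex
        pt = Point(c)
        r = min(g.distance(pt) for g in geoms)
        for poly in polys:
            if poly.contains(pt):
                return r  # inside a cell: penalise by the (positive) depth
        for wp in wall_polys:
            if not wp.contains(pt):
                return r
        return -r

    res = minimize(
        neg_clearance,
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400},
    )
    return float(np.clip(-res.fun, 0.0, bound))


def signed_t1_length(
    jmap: JunctionMap,
    shrinking: tuple[int, int] = (1, 2),
    growing: tuple[int, int] = (3, 4),
) -> float:
    """Signed T1 junction length L_{grow} - L_{shrink}.

    Negative while the shrinking junction exists, positive once the new
    junction extends; passes through 0 at the 4-way configuration.
    """
    js = jmap.get(*shrinking)
    jg = jmap.get(*growing)
    return (jg.length if jg else 0.0) - (js.length if js else 0.0)


def _junction_end_directions(tissue, j: Junction):
    """(endpoint position, unit direction pointing into the junction) for
    both ends of a junction, measured on each member cortex and averaged."""
    ends = []
    reach = 8
    for k in (0, -1):
        pts, dirs = [], []
        for cid, run in j.nodes.items():
            if len(run) < 3:
                continue
            lp = tissue.loop_by_id(cid)
            p = lp.x[run[k]]
            q = lp.x[run[min(reach, len(run) - 1)] if k == 0 else run[max(-1 - reach, -len(run))]]
            v = q - p
            nv = np.linalg.norm(v)
            if nv > 0:
                pts.append(p)
                dirs.append(v / nv)
        if pts:
            d = np.mean(dirs, axis=0)
            nd = np.linalg.norm(d)
            if nd > 0:
                ends.append((np.mean(pts, axis=0), d / nd))
    return ends


def junction_vertex_angles(tissue, jmap: JunctionMap, pair: tuple[int, int]) -> list[float]:
    """Internal angles (radians) between junction ``pair`` and each of its
    neighbouring junctions at its two end vertices.

    At mechanical equilibrium with equal line tensions a 3-way vertex
    forms angles of 2*pi/3; the passive extension of a new T1 junction
    halts when its neighbouring junctions reach this angle.
    """
    j = jmap.get(*pair)
    if j is None:
        return []
    angles = []
    for p_end, d_end in _junction_end_directions(tissue, j):
        for other in jmap.junctions:
            if other.pair == j.pair or not (other.pair & j.pair):
                continue
            for p2, d2 in _junction_end_directions(tissue, other):
                if np.hypot(*(p2 - p_end)) <= 2.0 * VERTEX_CLUSTER_RADIUS:
                    cosang = float(np.clip(d_end @ d2, -1.0, 1.0))
                    angles.append(float(np.arccos(cosang)))
    return angles


class SlippageTracker:
    """Tangential shear (slippage) between apposed cortices of a junction.

    Marks the material points initially apposed at the junction centre and
    reports their signed tangential separation as the cortices slide; zero
    for rigidly coupled cortices, antisymmetric under swapping the two
    sides.
    """

    def __init__(self, tissue, pair: tuple[int, int], jmap: JunctionMap | None = None):
        if jmap is None:
            jmap = detect_junctions(tissue)
        j = jmap.get(*pair)
        if j is None:
            raise ValueError(f"junction {pair} not present")
        self.pair = pair
        ca, cb = sorted(pair)
        la, lb = tissue.loop_by_id(ca), tissue.loop_by_id(cb)
        run_a = j.nodes[ca]
        na = run_a[len(run_a) // 2]
        xa = la.x[na]
        nb = int(np.argmin(np.hypot(*(lb.x - xa).T)))
        self.lab_a = la.labels[na]
        self.lab_b = lb.labels[nb]

    def _locate(self, loop: CortexLoop, lab: float) -> np.ndarray:
        per = loop.label_period
        d = np.abs(loop.labels - lab)
        d = np.minimum(d, per - d)
        return loop.x[int(np.argmin(d))]

    def shear(self, tissue) -> float:
        ca, cb = sorted(self.pair)
        la, lb = tissue.loop_by_id(ca), tissue.loop_by_id(cb)
        xa = self._locate(la, self.lab_a)
        xb = self._locate(lb, self.lab_b)
        # junction tangent from cortex a local geometry near xa
        ia = int(np.argmin(np.hypot(*(la.x - xa).T)))
        t = la.x[(ia + 1) % la.n] - la.x[ia - 1]
        t = t / max(np.linalg.norm(t), 1e-12)
        return float((xb - xa) @ t)


def material_kymograph(trace, cell_id: int):
    """Material-coordinate kymograph of one cortex across a simulation.

    For every stored snapshot, records each junction's extent in material
    labels on this cortex (rows kind='junction') and the geometric arc
    position of every material label (rows kind='label').  Labels crossing
    junction extents over time indicate cortical material flowing past a
    vertex between junctions.
    """
    import pandas as pd

    rows = []
    for step, tis in trace.snapshots:
        lp = tis.loop_by_id(cell_id)
        jmap = detect_junctions(tis)
        for j in jmap.junctions:
            if cell_id not in j.nodes:
                continue
            run = j.nodes[cell_id]
            other = [c for c in j.pair if c != cell_id][0]
            rows.append(
                {
                    "step": step,
                    "kind": "junction",
                    "partner": other,
                    "lab_start": lp.labels[run[0]],
                    "lab_end": lp.labels[run[-1]],
                    "n_nodes": len(run),
                }
            )
        s = np.concatenate([[0.0], np.cumsum(lp.seg_lengths())])[: lp.n]
        for lab, arc in zip(lp.labels, s):
            rows.append({"step": step, "kind": "label", "label": lab, "arc": arc})
    return pd.DataFrame(rows)


def cell_stress(loop: CortexLoop, tissue) -> tuple[float, np.ndarray, np.ndarray]:
    """Virial cell stress from boundary (adhesion + wall) forces.

    sigma = (1/A) * sum_nodes f (x - centroid)^T over the cell's cortex
    nodes; returns (P_cell, principal axis, sigma).  P_cell = tr(sigma)/2
    is the isotropic stress magnitude; the principal axis is the leading
    eigenvector of the symmetrised tensor.  Qualitative use only.
    """
    from . import adhesion as adh

    i = tissue.loops.index(loop)
    off = tissue.loop_offsets()
    f = adh.adhesion_force(tissue)[off[i] : off[i] + loop.n]
    r = loop.x - loop.centroid()
    sigma = (f[:, :, None] * r[:, None, :]).sum(axis=0) / cell_area(loop)
    sym = 0.5 * (sigma + sigma.T)
    p_cell = 0.5 * float(np.trace(sym))
    w, v = np.linalg.eigh(sym)
    axis = v[:, int(np.argmax(np.abs(w)))]
    return p_cell, axis, sigma


def slippage_shear(tissue, pair: tuple[int, int], tracker: SlippageTracker | None = None) -> float:
    """Tangential shear between the apposed cortices of a junction.

    Convenience wrapper: with no tracker, marks the currently apposed
    material points at the junction centre and returns 0 by construction;
    pass a tracker created earlier to measure accumulated slippage.
    """
    if tracker is None:
        tracker = SlippageTracker(tissue, pair)
    return tracker.shear(tissue)
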