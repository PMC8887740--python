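"""Deterministic construction of the reference tissue fixtures.

Cells are laid out on a hexagonal packing (pointy-top, edge length ``edge``
in units of the adhesion rest length delta_0); each cortex is the cell
polygon offset inward by half a rest length, so that apposed cortices and
cortex-wall gaps start at the adhesion rest length and the fixtures begin
near mechanical equilibrium.  Cell labelling is fixed: in the 14-cell
patch the central junction is {1, 2} with flanking cells 3 and 4.
"""

from __future__ import annotations

import warnings

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

from .cortex import CortexLoop
from .tissue import Params, Tissue, Wall

SQRT3 = np.sqrt(3.0)


def hex_center(q: int, r: int, edge: float) -> np.ndarray:
    return np.array([SQRT3 * edge * (q + r / 2.0), 1.5 * edge * r])


def hex_corners(center: np.ndarray, edge: float) -> np.ndarray:
    ang = np.deg2rad(30 + 60 * np.arange(6))
    return center + edge * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def _resample_ring(poly: Polygon, spacing: float) -> np.ndarray:
    """Evenly spaced points along the (CCW) exterior of a polygon."""
    poly = orient(poly, 1.0)
    bd = poly.exterior
    n = max(12, int(round(bd.length / spacing)))
    t = np.arange(n) * bd.length / n
    pts = shapely.line_interpolate_point(bd, t)
    return shapely.get_coordinates(pts)


def loop_from_polygon(poly: Polygon, cell_id: int, kappa: float, spacing: float,
                      inset: float = 0.5) -> CortexLoop:
    """Cortex loop: cell polygon offset inward by half a bond rest length."""
    inner = poly.buffer(-inset, join_style="mitre")
    x = _resample_ring(inner, spacing)
    d = np.hypot(*np.diff(np.vstack([x, x[:1]]), axis=0).T)
    return CortexLoop(cell_id=cell_id, x=x, lhat=d.copy(), gamma=np.ones(len(d)), kappa=kappa)


def circle_loop(center: np.ndarray, radius: float, cell_id: int, kappa: float,
                spacing: float) -> CortexLoop:
    n = max(12, int(round(2 * np.pi * radius / spacing)))
    ang = 2 * np.pi * np.arange(n) / n
    x = center + radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    d = np.hypot(*np.diff(np.vstack([x, x[:1]]), axis=0).T)
    return CortexLoop(cell_id=cell_id, x=x, lhat=d.copy(), gamma=np.ones(n), kappa=kappa)


def wall_from_polygon(poly: Polygon, spacing: float, offset_out: float = 0.0) -> Wall:
    """Discretised fixed wall along a polygon boundary, corners preserved."""
    if offset_out:
        poly = poly.buffer(offset_out, join_style="mitre")
    poly = orient(poly, 1.0)
    corners = np.asarray(poly.exterior.coords)[:-1]
    pts: list[np.ndarray] = []
    corner_ids: list[int] = []
    m = len(corners)
    for k in range(m):
        a, b = corners[k], corners[(k + 1) % m]
        corner_ids.append(len(pts))
        pts.append(a)
        seg = b - a
        L = np.hypot(*seg)
        nseg = max(1, int(round(L / spacing)))
        for j in range(1, nseg):
            pts.append(a + seg * (j / nseg))
    return Wall(points=np.array(pts), corner_ids=np.array(corner_ids), closed=True)


def single_cell_in_hexagon(
    kappa: float = 0.01,
    omega: float = 0.05,
    mesh: float = 0.1,
    side: float = 10.0,
    **params,
) -> Tissue:
    """A circular cortex inside a regular hexagonal wall.

    The cell is initialised as a circle inscribed in the hexagon, one rest
    length inside the wall, with no elastic pre-strain.  The adhesion
    strength is intended to be ramped quasi-statically from 0 to ``omega``
    (see ``acam.replicate.vertex_opening_single_cell``); the opening that
    develops at the wall corners measures kappa^2/omega.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0, omega >= 0")
    if mesh > 0.5:
        warnings.warn(
            f"mesh spacing {mesh} is too coarse to resolve a vertex opening "
            "of order 1.4 rest lengths", stacklevel=2,
        )
    params.setdefault("area_stiffness", 0.0)  # pure bending-vs-adhesion fixture
    p = Params(kappa=kappa, omega=omega, mesh_spacing=mesh, **params)
    wall_poly = Polygon(hex_corners(np.zeros(2), side))
    wall = wall_from_polygon(wall_poly, mesh)
    apothem = side * SQRT3 / 2.0
    cell = circle_loop(np.zeros(2), apothem - 1.0, cell_id=1, kappa=kappa, spacing=mesh)
    return Tissue(loops=[cell], params=p, walls=[wall])


def three_cell_tissue(
    kappa: float = 0.01,
    omega: float = 0.05,
    edge: float = 6.0,
    mesh: float = 0.25,
    pinned: bool = False,
    **params,
) -> Tissue:
    """Three mutually adhered hexagonal cells with one interior vertex."""
    p = Params(kappa=kappa, omega=omega, mesh_spacing=mesh, **params)
    axial = [(0, 0), (1, 0), (0, 1)]
    loops = [
        loop_from_polygon(Polygon(hex_corners(hex_center(q, r, edge), edge)), i + 1, kappa, mesh)
        for i, (q, r) in enumerate(axial)
    ]
    walls = []
    if pinned:
        union = shapely.union_all(
            [Polygon(hex_corners(hex_center(q, r, edge), edge)) for q, r in axial]
        )
        walls.append(wall_from_polygon(union, mesh, offset_out=0.5))
    t = Tissue(loops=loops, params=p, walls=walls)
    for lp in t.loops:
        lp.area0 = lp.area()
    if pinned:
        add_boundary_pins(t)
    return t


#: axial coordinates of the 14-cell patch; order fixes the cell labelling
FOURTEEN_CELL_AXIAL = [
    (0, 0),    # 1: shares the shrinking junction
    (1, 0),    # 2: shares the shrinking junction
    (0, 1),    # 3: flanking, above
    (1, -1),   # 4: flanking, below
    (-1, 0), (0, -1), (-1, 1),          # 5-7: remaining neighbours of 1
    (2, 0), (1, 1), (2, -1),            # 8-10: remaining neighbours of 2
    (0, 2), (-1, 2),                    # 11-12: remaining neighbours of 3
    (1, -2), (2, -2),                   # 13-14: remaining neighbours of 4
]


def fourteen_cell_tissue(
    kappa: float = 0.01,
    omega: float = 0.05,
    gamma0: float = 1.0 - 2e-4,
    edge: float = 6.0,
    mesh: float = 0.25,
    **params,
) -> Tissue:
    """The 14-cell neighbour-exchange fixture with a pinned outer boundary.

    Cells 1 and 2 share the central junction; cells 3 and 4 flank it; every
    cell adjacent to the exchanging quartet is itself surrounded.  All
    cortices carry the background pre-stress gamma0, imposed each step by
    the protocol.
    """
    p = Params(kappa=kappa, omega=omega, gamma0=gamma0, mesh_spacing=mesh, **params)
    polys = [
        Polygon(hex_corners(hex_center(q, r, edge), edge)) for q, r in FOURTEEN_CELL_AXIAL
    ]
    loops = [loop_from_polygon(poly, i + 1, kappa, mesh) for i, poly in enumerate(polys)]
    union = shapely.union_all(polys)
    wall = wall_from_polygon(union, mesh, offset_out=0.5)
    t = Tissue(loops=loops, params=p, walls=[wall])
    for lp in t.loops:
        lp.area0 = lp.area()
    add_boundary_pins(t)
    return t


def add_boundary_pins(tissue: Tissue, wall_index: int = 0) -> int:
    """Pin the tissue to wall angular points with extra-stiff adhesions.

    At every wall corner, the nearest cortex node of each cell within the
    binding range receives a permanent bond of stiffness ``pin_factor *
    omega`` (default 50x), holding tissue vertices at boundary angular
    points.  Ordinary wall adhesions elsewhere form through the normal
    binding dynamics.  Returns the number of pins created.
    """
    wall = tissue.walls[wall_index]
    dmax = tissue.params.delta_max
    n_pins = 0
    for cid in wall.corner_ids:
        cpt = wall.points[cid]
        for i, lp in enumerate(tissue.loops):
            d = np.hypot(*(lp.x - cpt).T)
            j = int(np.argmin(d))
            if d[j] <= dmax:
                tissue.bonds.add(
                    i, j, -1 - wall_index, int(cid),
                    tissue.params.pin_factor * tissue.params.mesh_spacing,
                    tissue.time, np.inf, pin=True,
                )
                n_pins += 1
    return n_pins


def parameter_grid(kappa_range, omega_range, n: int) -> list[tuple[float, float]]:
    """Log-uniform (kappa, omega) sample grid for the vertex-geometry map."""
    if n == 1:
        ks = [kappa_range[0]]
        ws = [omega_range[0]]
    else:
        ks = np.geomspace(kappa_range[0], kappa_range[1], n)
        ws = np.geomspace(omega_range[0], omega_range[1], n)
    return [(float(k), float(w)) for k in ks for w in ws]
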