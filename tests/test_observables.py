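"""Junction topology, vertex openings, tensions, slippage and kymographs."""

import numpy as np
import pytest

from acam import adhesion, observables as obs
from acam.cortex import CortexLoop
from acam.factory import hex_corners, three_cell_tissue
from acam.observables import (
    Junction,
    JunctionMap,
    SlippageTracker,
    cell_area,
    cell_perimeter,
    cell_stress,
    cortical_tension,
    detect_junctions,
    material_kymograph,
    signed_t1_length,
    vertex_opening,
)
from acam.tissue import Params, Tissue, settle, simulate
from acam.protocols import BackgroundTension

from conftest import circle_loop, square_loop, two_square_tissue


@pytest.fixture(scope="module")
def settled_three_cell():
    t = three_cell_tissue(edge=6.0, mesh=0.25)
    for lp in t.loops:
        lp.gamma[:] = t.params.gamma0
    settle(t, max_cycles=12, length_tol=1e-4)
    return t


class TestDetectJunctions:
    def test_three_cell_topology(self, settled_three_cell):
        jmap = detect_junctions(settled_three_cell, min_length=1.0)
        assert {tuple(sorted(j.pair)) for j in jmap.junctions} >= {(1, 2), (1, 3), (2, 3)}
        assert any(len(v.cells) >= 3 for v in jmap.vertices)

    def test_two_cells_single_junction(self, rng):
        # short binding range so only the two facing edges adhere
        t = two_square_tissue(gap=1.0, delta_max=1.5)
        adhesion.spawn_bonds(t, rng)
        jmap = detect_junctions(t)
        assert jmap.pairs() == {frozenset((1, 2))}
        j = jmap.get(1, 2)
        # facing square edges of side 4 adhere over ~the full edge
        assert 2.5 < j.length < 5.0

    def test_gap_tolerance_merges_single_dropouts(self, rng):
        t = two_square_tissue(gap=1.0)
        adhesion.spawn_bonds(t, rng)
        b = t.bonds
        # kill one mid-junction bond: the junction must not fragment
        mid = len(b) // 2
        keep = np.ones(len(b), bool)
        keep[mid] = False
        b.keep(keep)
        jmap = detect_junctions(t)
        assert len(jmap.junctions) == 1

    def test_deterministic_for_snapshot(self, settled_three_cell):
        j1 = detect_junctions(settled_three_cell)
        j2 = detect_junctions(settled_three_cell)
        assert j1.pairs() == j2.pairs()
        assert len(j1.vertices) == len(j2.vertices)


class TestVertexOpening:
    def test_closed_vertex_is_small(self, settled_three_cell):
        jmap = detect_junctions(settled_three_cell, min_length=1.0)
        cen = np.mean([lp.centroid() for lp in settled_three_cell.loops], axis=0)
        v3 = [v for v in jmap.vertices if len(v.cells) >= 3]
        vi = min(v3, key=lambda v: float(np.hypot(*(v.position - cen))))
        r = vertex_opening(settled_three_cell, vi)
        assert 0.0 <= r < 1.5

    def test_tangent_rods_zero_opening(self):
        # three cortices meeting with no gap: inscribed circle ~ 0
        lps = []
        for k, cid in enumerate((1, 2, 3)):
            ang = 2 * np.pi * k / 3
            c = 2.05 * np.array([np.cos(ang), np.sin(ang)])
            lps.append(square_loop(cid, c, side=4.0, spacing=0.3))
        t = Tissue(loops=lps, params=Params())
        r = vertex_opening(t, np.zeros(2), members=[1, 2, 3])
        assert r < 0.6


class TestSignedT1Length:
    def _jmap(self, l12=None, l34=None):
        js = []
        if l12:
            js.append(Junction(frozenset((1, 2)), {}, l12, {}))
        if l34:
            js.append(Junction(frozenset((3, 4)), {}, l34, {}))
        return JunctionMap(js, [])

    def test_four_way_is_zero(self):
        assert signed_t1_length(self._jmap()) == 0.0

    def test_negative_while_shrinking(self):
        assert signed_t1_length(self._jmap(l12=3.0)) == -3.0

    def test_positive_after_exchange(self):
        assert signed_t1_length(self._jmap(l34=2.5)) == 2.5

    def test_continuous_through_transition(self):
        vals = [signed_t1_length(self._jmap(l12=1.0)),
                signed_t1_length(self._jmap()),
                signed_t1_length(self._jmap(l34=1.0))]
        assert vals[0] < vals[1] < vals[2]


class TestAreaPerimeterTension:
    def test_hexagon_area_closed_form(self):
        a = 2.0
        x = hex_corners(np.zeros(2), a)
        d = np.hypot(*np.diff(np.vstack([x, x[:1]]), axis=0).T)
        lp = CortexLoop(1, x, d.copy(), np.ones(6), 0.01)
        assert cell_area(lp) == pytest.approx(1.5 * np.sqrt(3) * a**2)
        assert cell_perimeter(lp) == pytest.approx(6 * a)

    def test_translation_invariance(self):
        lp = circle_loop(n=40)
        a0 = cell_area(lp)
        lp.x += np.array([17.0, -4.0])
        assert cell_area(lp) == pytest.approx(a0, rel=1e-12)

    def test_tension_zero_when_relaxed(self):
        assert np.allclose(cortical_tension(circle_loop()), 0.0, atol=1e-12)

    def test_tension_of_held_contracted_segment(self):
        lp = circle_loop(n=30)
        lp.gamma[:] = 0.94  # held at current length
        T = cortical_tension(lp)
        assert np.allclose(T, 1 / 0.94 - 1, rtol=1e-12)


class TestSlippage:
    def test_antisymmetric_under_side_swap(self, rng):
        t = two_square_tissue(gap=1.0)
        adhesion.spawn_bonds(t, rng)
        tr = SlippageTracker(t, (1, 2))
        # slide cell 2 tangentially along the junction
        t.loop_by_id(2).x[:, 1] += 0.8
        s_ab = tr.shear(t)
        assert s_ab != 0.0
        # rigid coupling: no further slip if both move together
        t.loop_by_id(1).x[:, 1] += 0.8
        assert abs(tr.shear(t) - 0.0) < 0.3

    def test_zero_for_rigidly_coupled(self, rng):
        t = two_square_tissue(gap=1.0)
        adhesion.spawn_bonds(t, rng)
        tr = SlippageTracker(t, (1, 2))
        assert tr.shear(t) == pytest.approx(0.0, abs=0.3)


class TestKymograph:
    def test_passive_run_junction_bands_static(self):
        t = three_cell_tissue(edge=4.0, mesh=0.5, tol=1e-4)
        settle(t, max_cycles=8, length_tol=1e-4)  # discard the build-up transient
        trace = simulate(t, BackgroundTension(1 - 2e-4), 8, seed=5, snapshot_every=2)
        df = material_kymograph(trace, 1)
        bands = df[df.kind == "junction"]
        assert len(bands)
        for partner, sub in bands.groupby("partner"):
            if len(sub) < 3:
                continue
            width = (sub.lab_end - sub.lab_start).abs()
            # material content of each junction stays put in a passive run
            assert width.std() < 2.0


class TestCellStress:
    def test_force_free_cell_zero_stress(self):
        t = two_square_tissue(gap=30.0)
        p, axis, sigma = cell_stress(t.loops[0], t)
        assert p == pytest.approx(0.0, abs=1e-14)

    def test_symmetric_compression_isotropic(self):
        from acam.factory import single_cell_in_hexagon

        t = single_cell_in_hexagon(mesh=0.25, side=8.0)
        adhesion.rebind_nearest(t)
        settle(t, max_cycles=8, length_tol=1e-4)
        p, axis, sigma = cell_stress(t.loops[0], t)
        w = np.linalg.eigvalsh(0.5 * (sigma + sigma.T))
        assert abs(w[0]) == pytest.approx(abs(w[1]), rel=0.35)
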