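"""Geometry, energetics and internal forces of a single cortex rod."""

import numpy as np
import pytest

from acam.cortex import (
    CortexLoop,
    apply_active_contraction,
    elastic_energy,
    internal_force,
    rediscretise,
    remesh,
    segment_geometry,
)

from conftest import circle_loop, open_rod


def hexagon_loop(side=1.0, gamma=1.0):
    ang = np.deg2rad(60 * np.arange(6) + 30)
    x = side * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    d = np.hypot(*np.diff(np.vstack([x, x[:1]]), axis=0).T)
    return CortexLoop(1, x, d.copy(), np.full(6, gamma), kappa=0.1)


class TestSegmentGeometry:
    def test_regular_hexagon_is_unstrained_and_closes(self):
        lp = hexagon_loop()
        geo = segment_geometry(lp)
        assert np.allclose(geo["eps"], 0.0, atol=1e-12)
        assert np.isclose(geo["theta"].sum(), 2 * np.pi)

    def test_circle_curvature_converges_to_inverse_radius(self):
        R = 3.0
        errs = []
        for n in (64, 256):
            geo = segment_geometry(circle_loop(n=n, R=R))
            errs.append(abs(geo["c"].mean() - 1.0 / R) / (1.0 / R))
        assert errs[1] < errs[0]
        assert errs[1] < 0.01

    def test_free_active_contraction_is_stress_free(self):
        # segment with natural length 1, gamma=0.94, current length 0.94
        x = np.array([[0.0, 0.0], [0.94, 0.0], [0.94, 1.0], [0.0, 1.0]])
        d = np.hypot(*np.diff(np.vstack([x, x[:1]]), axis=0).T)
        lhat = d.copy()
        lhat[0] = 1.0
        lp = CortexLoop(1, x, lhat, np.array([0.94, 1, 1, 1]), kappa=0.1)
        geo = segment_geometry(lp)
        assert np.isclose(geo["alpha"][0], 1.0)
        assert np.isclose(geo["eps"][0], 0.0)

    def test_degenerate_segment_raises_with_cell_id(self):
        x = np.array([[0, 0], [0, 0], [1, 0], [1, 1]], float)
        lp = CortexLoop(9, x, np.ones(4), np.ones(4), 0.1)
        with pytest.raises(ValueError, match="cell 9"):
            segment_geometry(lp)

    def test_tangents_unit_norm_and_normals_leftward(self):
        geo = segment_geometry(circle_loop(n=32))
        assert np.allclose(np.hypot(*geo["d3"].T), 1.0)
        # CCW circle: left normal points inward (towards the centre)
        lp = circle_loop(n=32)
        mids = 0.5 * (lp.x + np.roll(lp.x, -1, axis=0))
        assert np.all((geo["d1"] * (-mids)).sum(axis=1) > 0)


class TestElasticEnergy:
    def test_straight_unstretched_rod_is_zero(self):
        assert elastic_energy(open_rod()) == pytest.approx(0.0, abs=1e-15)

    def test_uniform_stretch_energy(self):
        rod = open_rod(n=11, length=10.0)
        rod.x[:, 0] *= 1.1  # stretch alpha = 1.1 at zero curvature
        L = rod.lhat.sum()
        assert elastic_energy(rod) == pytest.approx(0.005 * L, rel=1e-12)

    def test_circle_bending_energy_converges(self):
        R, kap = 3.0, 0.05
        exact = np.pi * kap**2 / R
        errs = []
        for n in (100, 400):
            e = elastic_energy(circle_loop(n=n, R=R, kappa=kap))
            errs.append(abs(e - exact) / exact)
        assert errs[1] < errs[0]
        assert errs[1] < 0.01


class TestInternalForce:
    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_numeric_gradient(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        ang = 2 * np.pi * np.arange(n) / n
        x = np.stack([np.cos(ang), np.sin(ang)], 1) + 0.05 * rng.standard_normal((n, 2))
        lp = CortexLoop(1, x, np.full(n, 1.0), np.full(n, 0.97), kappa=0.3)
        f = internal_force(lp)
        h = 1e-6
        for i in range(n):
            for k in range(2):
                for s, store in ((+h, "p"), (-h, "m")):
                    xs = x.copy()
                    xs[i, k] += s
                    e = elastic_energy(CortexLoop(1, xs, lp.lhat, lp.gamma, 0.3))
                    if store == "p":
                        ep = e
                    else:
                        em = e
                g = (ep - em) / (2 * h)
                assert abs(-g - f[i, k]) <= 1e-6 * max(1.0, np.abs(f).max())

    def test_closed_loop_force_sums_to_zero(self):
        f = internal_force(circle_loop(n=40, R=2.0))
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_straight_rod_interior_nodes_force_free(self):
        f = internal_force(open_rod())
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_frame_indifference(self):
        lp = circle_loop(n=24, R=1.5)
        lp.x[3] += 0.1  # break symmetry
        e0 = elastic_energy(lp)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lp2 = lp.copy()
        lp2.x = lp.x @ rot.T + np.array([5.0, -2.0])
        assert abs(elastic_energy(lp2) - e0) < 1e-10


class TestActiveContraction:
    def test_gamma_one_is_noop(self):
        lp = circle_loop(n=16)
        e0 = elastic_energy(lp)
        apply_active_contraction(lp, slice(None), 1.0)
        assert elastic_energy(lp) == pytest.approx(e0)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.2])
    def test_invalid_gamma_rejected(self, bad):
        with pytest.raises(ValueError):
            apply_active_contraction(circle_loop(n=16), slice(None), bad)

    def test_held_fixed_contraction_builds_strain(self):
        # held at current shape, gamma = 0.94 -> alpha = 1/0.94, eps ~ 0.0638
        lp = circle_loop(n=32)
        apply_active_contraction(lp, slice(None), 0.94)
        geo = segment_geometry(lp)
        assert np.allclose(geo["alpha"], 1 / 0.94, rtol=1e-12)
        assert np.allclose(geo["eps"], 1 / 0.94 - 1, rtol=1e-12)
        # total stretch factorises: lambda = gamma * alpha = 1 when held
        assert np.allclose(geo["lam"], 1.0, rtol=1e-12)

    def test_lambda_identity_after_operations(self):
        lp = circle_loop(n=20)
        apply_active_contraction(lp, np.arange(5), 0.9)
        lp.x *= 1.03
        geo = segment_geometry(lp)
        assert np.allclose(geo["lam"], lp.gamma * geo["alpha"], rtol=1e-14)


class TestRemesh:
    def test_uniform_loop_unchanged(self):
        lp = circle_loop(n=60, R=3.0)
        spacing = lp.seg_lengths().mean()
        out, node_map = remesh(lp, spacing)
        assert out.n == lp.n
        assert np.array_equal(node_map, np.arange(lp.n))

    def test_stretched_segment_split_conserves_material(self):
        lp = circle_loop(n=40, R=3.0)
        lp.x[5] = 0.5 * (lp.x[4] + lp.x[6]) + np.array([1.5, 0.0])
        total = lp.lhat.sum()
        out, _ = remesh(lp, lp.seg_lengths().mean())
        assert out.n > lp.n
        assert out.lhat.sum() == pytest.approx(total, rel=1e-9)

    def test_repeated_remesh_is_idempotent(self):
        lp = circle_loop(n=40, R=3.0)
        lp.x[5] += np.array([0.9, 0.0])
        spacing = 0.5
        once, _ = remesh(lp, spacing)
        twice, node_map = remesh(once, spacing)
        assert twice.n == once.n
        assert np.array_equal(node_map, np.arange(once.n))


class TestRediscretise:
    def test_conserves_material_and_nearly_conserves_area(self):
        lp = circle_loop(n=50, R=3.0)
        rng = np.random.default_rng(1)
        lp.x += 0.05 * rng.standard_normal(lp.x.shape)
        a0, l0 = lp.area(), lp.lhat.sum()
        lp.area0 = a0
        out = rediscretise(lp, 0.4, smooth_sigma=0.5)
        assert out.lhat.sum() == pytest.approx(l0, rel=1e-9)  # material exact
        assert out.area() == pytest.approx(a0, rel=5e-2)  # smoothing-limited

    def test_smoothing_removes_subresolution_zigzag(self):
        lp = circle_loop(n=100, R=3.0)
        zig = 0.15 * (-1.0) ** np.arange(100)
        nrm = lp.x / np.hypot(*lp.x.T)[:, None]
        lp.x = lp.x + zig[:, None] * nrm
        out = rediscretise(lp, 0.2, smooth_sigma=0.5)
        r_out = np.hypot(*out.x.T)
        assert r_out.std() < 0.02  # zigzag ironed out

    def test_labels_remain_cyclically_ordered(self):
        lp = circle_loop(n=48, R=2.0)
        out = rediscretise(lp, 0.3, smooth_sigma=0.5)
        lab = np.unwrap(out.labels, period=out.label_period)
        assert np.all(np.diff(lab) > 0)


class TestRandomLoopProperties:
    """Invariants on randomly perturbed small loops (derandomised)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @staticmethod
    def _loop(seed, gamma):
        rng = np.random.default_rng(seed)
        n = 8
        ang = 2 * np.pi * np.arange(n) / n
        x = np.stack([np.cos(ang), np.sin(ang)], 1) + 0.08 * rng.standard_normal((n, 2))
        return CortexLoop(1, x, np.full(n, 0.8), np.full(n, gamma), kappa=0.2)

    @given(seed=st.integers(0, 10**6), gamma=st.floats(0.5, 1.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_stretch_factorisation_holds(self, seed, gamma):
        geo = segment_geometry(self._loop(seed, gamma))
        lp = self._loop(seed, gamma)
        assert np.allclose(geo["lam"], lp.gamma * geo["alpha"], rtol=1e-13)
        assert np.isclose(geo["theta"].sum() % (2 * np.pi), 0.0, atol=1e-9) or \
            np.isclose(geo["theta"].sum(), 2 * np.pi, atol=1e-9)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=15, derandomize=True, deadline=None)
    def test_energy_frame_indifferent(self, seed):
        lp = self._loop(seed, 0.9)
        e0 = elastic_energy(lp)
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lp.x = lp.x @ rot.T + np.array([3.0, -7.0])
        assert abs(elastic_energy(lp) - e0) < 1e-10
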