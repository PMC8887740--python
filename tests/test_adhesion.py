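"""Bond energetics, binding kernel, turnover and emergent friction."""

import numpy as np
import pytest

from acam import adhesion
from acam.adhesion import (
    AdhesionBond,
    BindingKernel,
    bond_energy,
    bond_force,
    build_mean_field_bonds,
    mean_field_adhesion_force,
    rebind_nearest,
    spawn_bonds,
    turnover_step,
)
from acam.cortex import CortexLoop
from acam.tissue import Params, Tissue, Wall

from conftest import open_rod, square_loop, two_square_tissue


def make_bond(xa, xb, omega=0.05, delta_max=4.0):
    return AdhesionBond((1, 0), (2, 0), np.asarray(xa, float), np.asarray(xb, float),
                        omega, delta_max)


def parallel_rod_tissue(gap=1.2, n=40, length=12.0, **params):
    p = Params(mesh_spacing=length / (n - 1), **params)
    a = open_rod(n=n, length=length, y=0.0)
    b = open_rod(n=n, length=length, y=gap)
    b.cell_id = 2
    return Tissue(loops=[a, b], params=p)


class TestBondEnergy:
    def test_rest_length_zero(self):
        assert bond_energy(1.0, 0.05, 4.0) == 0.0

    def test_hookean_value(self):
        assert bond_energy(2.0, 0.05, 4.0) == pytest.approx(0.025)

    def test_saturation_beyond_delta_max(self):
        assert bond_energy(4.0 + 5.0, 0.05, 4.0) == bond_energy(4.0, 0.05, 4.0)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            bond_energy(-0.1, 0.05, 4.0)


class TestBondForce:
    def test_zero_at_rest_length(self):
        fa, fb = bond_force(make_bond([0, 0], [1, 0]))
        assert np.allclose(fa, 0) and np.allclose(fb, 0)

    def test_newton_third_law(self):
        fa, fb = bond_force(make_bond([0, 0], [2.5, 1.0]))
        assert np.allclose(fa + fb, 0.0)

    def test_zero_beyond_delta_max(self):
        fa, _ = bond_force(make_bond([0, 0], [5.5, 0]))
        assert np.allclose(fa, 0.0)

    def test_repulsive_below_rest_length(self):
        fa, _ = bond_force(make_bond([0, 0], [0.5, 0]))
        assert fa[0] < 0  # endpoint a pushed away from b

    def test_magnitude_matches_energy_derivative(self):
        for delta in (0.7, 1.3, 2.4, 3.9):
            fa, _ = bond_force(make_bond([0, 0], [delta, 0]))
            h = 1e-7
            dW = (bond_energy(delta + h, 0.05, 4.0) - bond_energy(delta - h, 0.05, 4.0)) / (2 * h)
            assert abs(np.hypot(*fa) - abs(dW)) < 1e-8


class TestBindingKernel:
    def test_inverse_weights_normalised_and_cut(self):
        k = BindingKernel(4.0)
        w = k.weights(np.array([1.0, 2.0, 5.0]))
        assert w[2] == 0.0
        assert w.sum() == pytest.approx(1.0)
        assert w[0] / w[1] == pytest.approx(2.0)

    def test_uniform_alternative(self):
        k = BindingKernel(4.0, mode="uniform")
        w = k.weights(np.array([1.0, 3.0]))
        assert np.allclose(w, 0.5)


class TestSpawn:
    def test_single_candidate_always_bound(self, rng):
        t = parallel_rod_tissue(gap=1.0)
        n_new = spawn_bonds(t, rng)
        assert n_new > 0
        # every bond spans the two rods at the local gap
        assert set(t.bonds.a_loop) <= {0, 1}
        deltas = [
            np.hypot(*(t.loops[bl].x[bn] - t.loops[al].x[an]))
            for al, an, bl, bn in zip(t.bonds.a_loop, t.bonds.a_node,
                                      t.bonds.b_loop, t.bonds.b_node)
        ]
        assert np.allclose(deltas, 1.0, atol=0.3)

    def test_equidistant_cells_chosen_evenly(self):
        # one seeker node exactly between two foreign cortices
        counts = {2: 0, 3: 0}
        n_trials = 1500
        for s in range(n_trials):
            seeker = CortexLoop(1, np.array([[0.0, 0.0], [0.3, 0.0], [0.15, 0.2]]),
                                np.ones(3), np.ones(3), 0.01)
            up = square_loop(2, (0.15, 2.6))
            dn = square_loop(3, (0.15, -2.6))
            t = Tissue(loops=[seeker, up, dn], params=Params(mesh_spacing=0.3))
            spawn_bonds(t, np.random.default_rng(s))
            b = t.bonds
            k = np.where(b.a_loop == 0)[0]
            if len(k):
                counts[t.loops[b.b_loop[k[0]]].cell_id] += 1
        total = counts[2] + counts[3]
        # binomial: p=1/2 within 3 sigma
        sigma = 0.5 * np.sqrt(total)
        assert abs(counts[2] - total / 2) < 3 * sigma

    def test_no_candidates_beyond_range(self, rng):
        t = parallel_rod_tissue(gap=6.0)  # beyond delta_max = 4
        assert spawn_bonds(t, rng) == 0

    def test_paired_nodes_do_not_reseek(self, rng):
        t = parallel_rod_tissue(gap=1.0)
        spawn_bonds(t, rng)
        n1 = len(t.bonds)
        assert spawn_bonds(t, rng) == 0  # everyone paired now
        assert len(t.bonds) == n1

    def test_occlusion_blocks_third_cell(self, rng):
        p = Params(mesh_spacing=0.3)
        a = open_rod(n=30, length=9.0, y=0.0)
        mid = open_rod(n=30, length=9.0, y=1.0)
        mid.cell_id = 2
        c = open_rod(n=30, length=9.0, y=2.0)
        c.cell_id = 3
        t = Tissue(loops=[a, mid, c], params=p)
        spawn_bonds(t, rng)
        pairs = {
            frozenset((t.loops[al].cell_id, t.loops[bl].cell_id))
            for al, bl in zip(t.bonds.a_loop, t.bonds.b_loop)
        }
        assert frozenset((1, 3)) not in pairs  # rod 2 shadows 1 <-> 3


class TestTurnover:
    def test_infinite_tau_never_removes(self, rng):
        t = parallel_rod_tissue(gap=1.0, tau_adh=np.inf)
        spawn_bonds(t, rng)
        n0 = len(t.bonds)
        for _ in range(50):
            t.time += 1.0
            assert turnover_step(t, 1.0, rng) == 0
        assert len(t.bonds) == n0

    def test_exponential_survival(self):
        tau = 5.0
        t = parallel_rod_tissue(gap=1.0, n=5000, length=1500.0, tau_adh=tau)
        spawn_bonds(t, np.random.default_rng(0))
        n0 = len(t.bonds)
        assert n0 > 3000
        rng = np.random.default_rng(1)
        for _ in range(int(tau)):
            turnover_step(t, 1.0, rng)
            t.time += 1.0
        frac = len(t.bonds) / n0
        p = np.exp(-1.0)
        sigma = np.sqrt(p * (1 - p) / n0)
        assert abs(frac - p) < 3 * sigma

    def test_single_step_removal_fraction(self):
        tau = 50.0
        t = parallel_rod_tissue(gap=1.0, n=4000, length=1200.0, tau_adh=tau)
        spawn_bonds(t, np.random.default_rng(2))
        n0 = len(t.bonds)
        removed = turnover_step(t, 1.0, np.random.default_rng(3))
        expected = n0 * (1 - np.exp(-1 / tau))
        assert abs(removed - expected) < 4 * np.sqrt(expected)


class TestForcesAndEnergy:
    def test_total_adhesion_force_vanishes(self, rng):
        t = two_square_tissue(gap=0.8)
        rebind_nearest(t)
        f = adhesion.adhesion_force(t)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)

    def test_adhesion_energy_counts_each_bond_once(self):
        t = parallel_rod_tissue(gap=2.0)
        h = t.params.mesh_spacing
        t.bonds.add([0, 0], [0, 1], [1, 1], [0, 1], [h, h], 0.0, np.inf)
        # two bonds at delta = 2: each 0.5*omega*h*(2-1)^2
        expect = 2 * 0.5 * t.params.omega * h
        assert adhesion.adhesion_energy(t) == pytest.approx(expect)

    def test_saturated_bonds_transmit_no_force(self):
        t = parallel_rod_tissue(gap=5.0)
        t.bonds.add([0], [3], [1], [3], [1.0], 0.0, np.inf)  # delta = 5 > 4
        f = adhesion.adhesion_force(t)
        assert np.allclose(f, 0.0)


class TestMeanField:
    def test_single_candidate_pair_equals_discrete_bond(self):
        t = parallel_rod_tissue(gap=1.5)
        f_mf = mean_field_adhesion_force(t)
        t2 = parallel_rod_tissue(gap=1.5)
        rebind_nearest(t2)
        f_d = adhesion.adhesion_force(t2)
        assert np.allclose(f_mf, f_d, atol=1e-12)

    def test_symmetric_candidates_tangential_components_cancel(self):
        # a mirror-symmetric cell between two candidate cortices straddling
        # its normal: the kernel-weighted tangential components cancel
        seeker = CortexLoop(1, np.array([[-0.15, 0.0], [0.15, 0.0], [0.0, 0.2]]),
                            np.full(3, 0.3), np.ones(3), 0.01)
        left = CortexLoop(2, np.array([[-2.0, 1.0], [-2.0, 3.0], [-2.2, 2.0]]),
                          np.ones(3), np.ones(3), 0.01)
        right = CortexLoop(3, np.array([[2.0, 1.0], [2.0, 3.0], [2.2, 2.0]]),
                           np.ones(3), np.ones(3), 0.01)
        t = Tissue(loops=[seeker, left, right], params=Params(mesh_spacing=0.3))
        f = mean_field_adhesion_force(t)
        assert abs(f[:3].sum(axis=0)[0]) < 1e-8  # net tangential force zero
        assert f[:3].sum(axis=0)[1] > 0  # normal components add up

    def test_matches_time_average_of_fast_bond_scheme(self):
        # frozen two-rod geometry, instantaneous rebinding each round
        t = parallel_rod_tissue(gap=1.6, tau_adh=0.01)
        f_mf = mean_field_adhesion_force(t)
        acc = np.zeros_like(f_mf)
        n_rounds = 400
        for s in range(n_rounds):
            adhesion.resample_bonds(t, np.random.default_rng(100 + s))
            acc += adhesion.adhesion_force(t)
        f_avg = acc / n_rounds
        scale = np.abs(f_mf).max()
        assert np.abs(f_avg - f_mf).max() <= 0.02 * scale


class TestEmergentFriction:
    @staticmethod
    def sliding_force(omega, tau, v=0.002, n=120, steps=650, seed=5):
        """Time-averaged tangential resistance of a rod sliding over a wall.

        tau must be well above the unit step for the discrete-time bond-age
        distribution to approach its continuum (exponential) limit.
        """
        length = 36.0
        p = Params(mesh_spacing=length / (n - 1), omega=omega, tau_adh=tau)
        rod = open_rod(n=n, length=length, y=2.0)
        wall_pts = np.stack([np.linspace(-20, 56, 4 * n), np.zeros(4 * n)], 1)
        t = Tissue(loops=[rod], params=p, walls=[Wall(points=wall_pts, closed=False)])
        rng = np.random.default_rng(seed)
        f_sum, count = 0.0, 0
        for step in range(steps):
            turnover_step(t, 1.0, rng)
            spawn_bonds(t, rng)
            t.time += 1.0
            if step > 3 * tau:  # burn-in to steady bond-age distribution
                f = adhesion.adhesion_force(t)
                f_sum += f[:, 0].sum()
                count += 1
            rod.x[:, 0] += v
        return -f_sum / count  # resistance opposes the motion

    def test_linear_in_tau_over_a_decade(self):
        f1 = self.sliding_force(0.05, 10.0)
        f2 = self.sliding_force(0.05, 100.0)
        assert f1 > 0 and f2 > 0
        assert f2 / f1 == pytest.approx(10.0, rel=0.1)

    def test_linear_in_omega_over_a_decade(self):
        f1 = self.sliding_force(0.02, 10.0, steps=300, seed=9)
        f2 = self.sliding_force(0.2, 10.0, steps=300, seed=9)
        assert f2 / f1 == pytest.approx(10.0, rel=0.1)
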