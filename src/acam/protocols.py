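"""Time-dependent activity fields gamma(segment, t).

Each protocol re-imposes its gamma field at the start of every simulation
step (the viscoelastic relaxation resets gamma to 1 along with the rest
lengths).  Contractility is "identity sensing": a cortex segment becomes
contractile when it lies within the receptor range ``delta_gamma`` of a
specific partner cell's cortex, so the contractile region shrinks with the
junction and vanishes once the partners separate.
"""

from __future__ import annotations

import numpy as np
import shapely

from .observables import detect_junctions, min_ring_distance, ring

__all__ = [
    "BackgroundTension",
    "UniformContractilityRamp",
    "JunctionContractility",
    "AsymmetricCables",
    "LinearRampT1",
    "SequentialT1",
    "PROTOCOLS",
]


def _set_background(tissue, gamma0: float) -> None:
    if not (0 < gamma0 <= 1):
        raise ValueError("gamma0 must be in (0, 1]")
    for lp in tissue.loops:
        lp.gamma = np.full(lp.nseg, gamma0)


def pair_has_bonds(tissue, a: int, b: int) -> bool:
    """True while the two cells share at least one live adhesion bond.

    In the fast-adhesion (resampled-bond) regime bonds are re-formed every
    step wherever the cortices are within delta_max, so this reduces to a
    range test.
    """
    ia = tissue.loops.index(tissue.loop_by_id(a))
    ib = tissue.loops.index(tissue.loop_by_id(b))
    bs = tissue.bonds
    m = ((bs.a_loop == ia) & (bs.b_loop == ib)) | ((bs.a_loop == ib) & (bs.b_loop == ia))
    if m.any():
        return True
    if tissue.params.tau_adh < 1.0:  # bonds are resampled next step anyway
        return min_ring_distance(tissue.loops[ia], tissue.loops[ib]) <= tissue.params.delta_max
    return False


def _segments_near(loop, target_ring, rng: float) -> np.ndarray:
    """Boolean mask of segments whose midpoint lies within rng of a ring."""
    a, b = loop.seg_indices()
    mids = 0.5 * (loop.x[a] + loop.x[b])
    d = shapely.distance(shapely.points(mids), target_ring)
    return d <= rng


class BackgroundTension:
    """Uniform low-level pre-stress in all cortices (passive tissue)."""

    def __init__(self, gamma0: float = 1.0):
        self.gamma0 = gamma0

    def apply(self, tissue, step: int, jmap=None) -> None:
        _set_background(tissue, self.gamma0)


class UniformContractilityRamp:
    """Whole-cortex contractility in all cells, gamma following a schedule.

    ``schedule`` maps the step index to a gamma value in (0, 1]; the driver
    is expected to equilibrate between increments (quasi-static ramp).
    """

    def __init__(self, schedule):
        self.schedule = schedule if callable(schedule) else (lambda s, a=schedule: a[min(s, len(a) - 1)])

    def apply(self, tissue, step: int, jmap=None) -> None:
        g = float(self.schedule(step))
        if not (0 < g <= 1):
            raise ValueError(f"schedule produced gamma={g} outside (0, 1]")
        _set_background(tissue, g)


class JunctionContractility:
    """Identity-sensing contractility on a single bicellular junction.

    Both cortices of ``pair`` become contractile (gamma = gamma_active)
    wherever they lie within ``delta_gamma`` of the partner cortex; all
    other cortex everywhere carries the background gamma0.  The sensing is
    purely range-based (surface receptors with reach delta_gamma), so the
    contractile region shrinks with the junction, persists across the
    4-way configuration (where it drives resolution), and empties
    naturally once the new junction's extension separates the pair beyond
    delta_gamma.
    """

    def __init__(self, pair=(1, 2), gamma_active: float = 0.94,
                 gamma0: float | None = None, delta_gamma: float | None = None):
        if not (0 < gamma_active < 1):
            raise ValueError("gamma_active must be in (0, 1)")
        self.pair = pair
        self.gamma_active = gamma_active
        self.gamma0 = gamma0
        self.delta_gamma = delta_gamma
        self._checked = False

    def apply(self, tissue, step: int, jmap=None) -> None:
        g0 = tissue.params.gamma0 if self.gamma0 is None else self.gamma0
        rng = tissue.params.delta_gamma if self.delta_gamma is None else self.delta_gamma
        a, b = self.pair
        la, lb = tissue.loop_by_id(a), tissue.loop_by_id(b)
        if not self._checked:
            if min_ring_distance(la, lb) > tissue.params.delta_max:
                raise ValueError(f"cells {self.pair} are not adhered at protocol start")
            self._checked = True
        _set_background(tissue, g0)
        ga = self.gamma_active
        ra, rb = ring(la), ring(lb)
        la.gamma[_segments_near(la, rb, rng)] = ga
        lb.gamma[_segments_near(lb, ra, rng)] = ga


class AsymmetricCables:
    """Two contractile cables with asymmetric strength across junctions.

    Cables {{1,3},{1,2},{1,4}} and {{2,3},{1,2},{2,4}}: the strong cells
    (1, 2) contract at gamma_strong wherever they share adhesive range with
    any cable partner; the weak cells (3, 4) contract at gamma_weak along
    their junctions with the strong cells only.  Bicellular junctions like
    {1, 3} thus carry different tension on their two cortices.
    """

    def __init__(self, strong_cells=(1, 2), weak_cells=(3, 4),
                 gamma_strong: float = 0.99, gamma_weak: float = 0.9975,
                 gamma0: float | None = None, delta_gamma: float | None = None):
        self.strong = tuple(strong_cells)
        self.weak = tuple(weak_cells)
        self.g_strong = gamma_strong
        self.g_weak = gamma_weak
        self.gamma0 = gamma0
        self.delta_gamma = delta_gamma

    def apply(self, tissue, step: int, jmap=None) -> None:
        g0 = tissue.params.gamma0 if self.gamma0 is None else self.gamma0
        rng = tissue.params.delta_gamma if self.delta_gamma is None else self.delta_gamma
        _set_background(tissue, g0)
        rings = {c: ring(tissue.loop_by_id(c)) for c in self.strong + self.weak}
        for c in self.strong:
            lp = tissue.loop_by_id(c)
            mask = np.zeros(lp.nseg, dtype=bool)
            for o in self.strong + self.weak:
                if o != c:
                    mask |= _segments_near(lp, rings[o], rng)
            lp.gamma[mask] = self.g_strong
        for c in self.weak:
            lp = tissue.loop_by_id(c)
            mask = np.zeros(lp.nseg, dtype=bool)
            for o in self.strong:
                mask |= _segments_near(lp, rings[o], rng)
            lp.gamma[mask] = self.g_weak


class LinearRampT1(JunctionContractility):
    """Junction contractility whose magnitude 1-gamma grows linearly in time,
    mimicking gradual Myosin loading; shrinkage speed increases over time."""

    def __init__(self, pair=(1, 2), rate: float = 5e-4, gamma_min: float = 0.9,
                 gamma0: float | None = None, delta_gamma: float | None = None):
        super().__init__(pair, 0.99, gamma0, delta_gamma)
        if rate < 0:
            raise ValueError("rate must be non-negative")
        self.rate = rate
        self.gamma_min = gamma_min

    def apply(self, tissue, step: int, jmap=None) -> None:
        self.gamma_active = max(self.gamma_min, 1.0 - self.rate * step)
        if self.gamma_active >= 1.0:  # rate 0: pure background
            g0 = tissue.params.gamma0 if self.gamma0 is None else self.gamma0
            _set_background(tissue, g0)
            return
        super().apply(tissue, step, jmap)


class SequentialT1:
    """Contract junction {1,2}; once the new junction appears, switch the
    contractile target to a second pair (rosette assay).

    The trigger is the first step at which the ``trigger_pair`` junction
    exists in the junction map; with slow adhesion turnover the second
    contraction drags the two young vertices together into a rosette, with
    fast turnover it drives a second neighbour exchange.
    """

    def __init__(self, first=(1, 2), second=(1, 3), trigger_pair=(3, 4),
                 gamma_active: float = 0.94, gamma0: float | None = None,
                 delta_gamma: float | None = None):
        self.first = JunctionContractility(first, gamma_active, gamma0, delta_gamma)
        self.second = JunctionContractility(second, gamma_active, gamma0, delta_gamma)
        self.trigger_pair = trigger_pair
        self.triggered_at: int | None = None

    def apply(self, tissue, step: int, jmap=None) -> None:
        if self.triggered_at is None:
            if jmap is None:
                jmap = detect_junctions(tissue)
            if jmap.has(*self.trigger_pair):
                self.triggered_at = step
        if self.triggered_at is None:
            self.first.apply(tissue, step, jmap)
        else:
            self.second.apply(tissue, step, jmap)


#: registry keyed by the experiment each protocol reproduces
PROTOCOLS = {
    "background": BackgroundTension,
    "uniform-ramp": UniformContractilityRamp,
    "junction-t1": JunctionContractility,
    "asymmetric-cables": AsymmetricCables,
    "linear-ramp-t1": LinearRampT1,
    "sequential-t1": SequentialT1,
}
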